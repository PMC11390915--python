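"""Sequence-level annotation: L2 motifs, zinc sites, tails, transmembrane
segments, α1-face basic residues and MSA conservation profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO, SeqIO

from .fold_detect import HistoneFoldAnnotation
from .structure_io import StructureModel

__all__ = [
    "MotifHit",
    "TailAnnotation",
    "ZincSiteHit",
    "ConservationProfile",
    "scan_l2_motif",
    "find_basic_alpha1_residues",
    "find_p_loop",
    "detect_tails",
    "detect_zinc_motifs",
    "detect_transmembrane",
    "conservation_profile",
    "read_fasta",
    "read_msa",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

TM_WINDOW = 19
TM_THRESHOLD = 1.6

TAIL_MIN_LEN = 5
TAIL_DISORDER_PLDDT = 50.0
TAIL_CHARGE_FRACTION = 0.2

EXPOSURE_MAX_NEIGHBORS = 14
EXPOSURE_RADIUS = 10.0


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
    return seq


def read_fasta(path) -> Dict[str, str]:
    """id -> sequence for every record in a FASTA file."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_msa(path, fmt: str = "auto") -> List[str]:
    """Aligned rows from a FASTA or Stockholm alignment."""
    if fmt == "auto":
        fmt = "stockholm" if str(path).endswith((".sto", ".stk", ".stockholm")) else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq).upper() for rec in aln]


# --------------------------------------------------------------------------
# L2 motif


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str  # RxTxxxxD | RKTxxxxD
    anchor_position: int  # 1-based position of the R
    matched_positions: Dict[str, int]
    structurally_anchored: Optional[bool]


def scan_l2_motif(
    sequence: str,
    fold: Optional[HistoneFoldAnnotation] = None,
    d_offset: int = 7,
) -> List[MotifHit]:
    """All RxTxxxxD motif matches (R anchor; T at R+2; D at R+``d_offset``).

    A K immediately after the R upgrades the hit to RKTxxxxD.  When a fold
    annotation is supplied, hits whose T lies within L2 ± 2 residues are
    flagged as structurally anchored.
    """
    seq = _check_sequence(sequence)
    hits: List[MotifHit] = []
    l2_window = None
    if fold is not None:
        l2_window = (fold.alpha2.end + 1 - 2, fold.alpha3.start - 1 + 2)
    for i in range(len(seq) - d_offset):
        if seq[i] == "R" and seq[i + 2] == "T" and seq[i + d_offset] == "D":
            name = "RKTxxxxD" if seq[i + 1] == "K" else "RxTxxxxD"
            anchor = i + 1
            t_pos = i + 3
            matched = {"R": anchor, "T": t_pos, "D": i + d_offset + 1}
            if name == "RKTxxxxD":
                matched["K"] = anchor + 1
            anchored = None
            if l2_window is not None:
                anchored = l2_window[0] <= t_pos <= l2_window[1]
            hits.append(MotifHit(name, anchor, matched, anchored))
    return hits


# --------------------------------------------------------------------------
# α1-face basics / P-loop


def find_basic_alpha1_residues(
    sequence: str,
    fold: HistoneFoldAnnotation,
    model: Optional[StructureModel] = None,
) -> List[int]:
    """K/R positions in α1 ∪ L1 ∪ L2 (candidate DNA-binding residues).

    With a structure, buried positions (more than 14 Cα neighbours within
    10 Å) are filtered out.
    """
    seq = _check_sequence(sequence)
    positions = set(fold.alpha1.positions())
    positions.update(range(fold.alpha1.end + 1, fold.alpha2.start))  # L1
    positions.update(range(fold.alpha2.end + 1, fold.alpha3.start))  # L2
    hits = [p for p in sorted(positions) if p <= len(seq) and seq[p - 1] in "KR"]
    if model is not None:
        chain = model.chains[fold.chain_id]
        ca = chain.ca_coords()
        from scipy.spatial.distance import cdist

        dmat = cdist(ca, ca)
        exposed = []
        for p in hits:
            neigh = int(np.sum(dmat[p - 1] <= EXPOSURE_RADIUS)) - 1
            if neigh <= EXPOSURE_MAX_NEIGHBORS:
                exposed.append(p)
        hits = exposed
    return hits


def find_p_loop(sequence: str, region: Optional[Tuple[int, int]] = None) -> List[int]:
    """1-based anchor positions of Walker-A P-loop matches GxxxxGK[ST]."""
    seq = _check_sequence(sequence)
    lo, hi = (1, len(seq)) if region is None else region
    hits = []
    for i in range(lo - 1, min(hi, len(seq) - 7)):
        if seq[i] == "G" and seq[i + 5] == "G" and seq[i + 6] == "K" and seq[i + 7] in "ST":
            hits.append(i + 1)
    return hits


# --------------------------------------------------------------------------
# tails


@dataclass(frozen=True)
class TailAnnotation:
    terminus: str  # N | C
    length: int
    net_charge: float
    mean_plddt: Optional[float]
    disordered: Optional[bool]
    charge_class: str  # positive | negative | neutral


def net_charge(segment: str) -> float:
    """K,R = +1; D,E = -1; H = 0."""
    return float(sum(CHARGE.get(a, 0.0) for a in segment))


def _classify_charge(q: float, length: int) -> str:
    frac = q / length if length else 0.0
    if frac >= TAIL_CHARGE_FRACTION:
        return "positive"
    if frac <= -TAIL_CHARGE_FRACTION:
        return "negative"
    return "neutral"


def detect_tails(
    sequence: str,
    fold: HistoneFoldAnnotation,
    plddt: Optional[Sequence[float]] = None,
    exclude_compact: Sequence[str] = (),
) -> List[TailAnnotation]:
    """Flanking segments of >= 5 residues outside the fold span.

    Termini listed in ``exclude_compact`` ("N"/"C") are skipped — they were
    recognised as compact fused domains, not tails.  Disorder is the mean
    pLDDT falling below 50 (``None`` when no pLDDT track is given).
    """
    seq = _check_sequence(sequence)
    start, end = fold.fold_span
    tails: List[TailAnnotation] = []
    spans = {"N": (1, start - 1), "C": (end + 1, len(seq))}
    for terminus, (lo, hi) in spans.items():
        length = hi - lo + 1
        if length < TAIL_MIN_LEN or terminus in exclude_compact:
            continue
        segment = seq[lo - 1 : hi]
        q = net_charge(segment)
        mean_plddt = disordered = None
        if plddt is not None:
            mean_plddt = float(np.mean(np.asarray(plddt, dtype=float)[lo - 1 : hi]))
            disordered = mean_plddt < TAIL_DISORDER_PLDDT
        tails.append(
            TailAnnotation(
                terminus=terminus,
                length=length,
                net_charge=q,
                mean_plddt=mean_plddt,
                disordered=disordered,
                charge_class=_classify_charge(q, length),
            )
        )
    return tails


# --------------------------------------------------------------------------
# ZZ-type zinc sites


@dataclass(frozen=True)
class ZincSiteHit:
    site_type: str  # C4 | C2H2
    positions: Tuple[int, int, int, int]
    spatially_clustered: Optional[bool]


# spacing bands (position differences) for the interleaved ZZ arrangement
#   C1-x(1-4)-C2 ... Ca-x(2-6)-Cb ... C3-x(1-6)-C4 ... H1-x(1-7)-H2
_ZZ_C4_GAP1 = (2, 5)
_ZZ_C4_GAP2 = (2, 7)
_ZZ_C2H2_C_GAP = (3, 7)
_ZZ_C2H2_H_GAP = (2, 8)
_ZZ_WINDOW = 60
_ZZ_CLUSTER_CUTOFF = 8.0


def _sidechain_proxy(model: StructureModel, chain_id: str, position: int) -> np.ndarray:
    res = model.chains[chain_id].residues[position - 1]
    return res.atoms.get("CB", res.atoms["CA"])


def detect_zinc_motifs(
    sequence: str,
    model: Optional[StructureModel] = None,
    chain_id: Optional[str] = None,
) -> List[ZincSiteHit]:
    """ZZ-type interleaved zinc sites: a C4 site split around a C2H2 site.

    Along the sequence the arrangement is C C | C C | C C | H H, where
    positions 1, 2, 5, 6 form the C4 site and positions 3, 4, 7, 8 the
    C2H2 site, all within a 60-residue window.  Returns the C4 and C2H2
    hit for the lexicographically smallest valid assignment of each
    non-overlapping region.  With a structure, sites whose side-chain
    proxies (Cβ, Cα for Gly) are mutually within 8 Å are flagged
    spatially clustered.
    """
    seq = _check_sequence(sequence)
    cys = [i + 1 for i, a in enumerate(seq) if a == "C"]
    his = [i + 1 for i, a in enumerate(seq) if a == "H"]
    if len(cys) < 6 or len(his) < 2:
        return []

    def within(positions: List[int], lo: int, hi: int) -> List[int]:
        return [p for p in positions if lo <= p <= hi]

    best = None
    for c1 in cys:
        if best is not None:
            break  # tuples sort by c1 first, so the first hit chain is minimal
        win_hi = c1 + _ZZ_WINDOW
        for c2 in within(cys, c1 + _ZZ_C4_GAP1[0], min(c1 + _ZZ_C4_GAP1[1], win_hi)):
            for ca_ in within(cys, c2 + 1, win_hi):
                for cb in within(cys, ca_ + _ZZ_C2H2_C_GAP[0], min(ca_ + _ZZ_C2H2_C_GAP[1], win_hi)):
                    for c3 in within(cys, cb + 1, win_hi):
                        for c4 in within(cys, c3 + _ZZ_C4_GAP2[0], min(c3 + _ZZ_C4_GAP2[1], win_hi)):
                            for h1 in within(his, c4 + 1, win_hi):
                                for h2 in within(his, h1 + _ZZ_C2H2_H_GAP[0], min(h1 + _ZZ_C2H2_H_GAP[1], win_hi)):
                                    cand = (c1, c2, ca_, cb, c3, c4, h1, h2)
                                    if best is None or cand < best:
                                        best = cand
    if best is None:
        return []
    c1, c2, ca_, cb, c3, c4, h1, h2 = best
    c4_site = (c1, c2, c3, c4)
    c2h2_site = (ca_, cb, h1, h2)

    def clustered(positions: Tuple[int, ...]) -> Optional[bool]:
        if model is None:
            return None
        cid = chain_id or model.chain_ids[0]
        pts = np.array([_sidechain_proxy(model, cid, p) for p in positions])
        from scipy.spatial.distance import pdist

        return bool(np.all(pdist(pts) < _ZZ_CLUSTER_CUTOFF))

    return [
        ZincSiteHit("C4", c4_site, clustered(c4_site)),
        ZincSiteHit("C2H2", c2h2_site, clustered(c2h2_site)),
    ]


# --------------------------------------------------------------------------
# transmembrane segments


def hydropathy_windows(sequence: str, window: int = TM_WINDOW) -> np.ndarray:
    """Mean Kyte-Doolittle hydropathy for every full window (length N-w+1)."""
    seq = _check_sequence(sequence)
    values = np.array([KYTE_DOOLITTLE[a] for a in seq])
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def detect_transmembrane(
    sequence: str, window: int = TM_WINDOW, threshold: float = TM_THRESHOLD
) -> List[Tuple[int, int]]:
    """Candidate transmembrane segments from windowed hydropathy.

    Maximal runs of residues covered by windows whose mean exceeds the
    threshold; only runs of at least the window length are reported.
    Returns 1-based inclusive (start, end) pairs.
    """
    seq = _check_sequence(sequence)
    if len(seq) < window:
        raise ValueError(f"sequence shorter than window ({window})")
    means = hydropathy_windows(seq, window)
    covered = np.zeros(len(seq), dtype=bool)
    for i, m in enumerate(means):
        if m > threshold:
            covered[i : i + window] = True
    segments = []
    start = None
    for i, v in enumerate(covered):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= window:
                segments.append((start + 1, i))
            start = None
    if start is not None and len(seq) - start >= window:
        segments.append((start + 1, len(seq)))
    return segments


# --------------------------------------------------------------------------
# conservation profiles


@dataclass(frozen=True)
class ProfileColumn:
    reference_position: Optional[int]  # None for gap columns
    frequencies: Dict[str, float]
    information_content: float


@dataclass
class ConservationProfile:
    columns: List[ProfileColumn]

    def to_table(self) -> str:
        """Tab-separated logo table: position, 20 frequencies, IC."""
        header = "position\t" + "\t".join(AMINO_ACIDS) + "\tinformation_content"
        lines = [header]
        for col in self.columns:
            pos = "-" if col.reference_position is None else str(col.reference_position)
            freqs = "\t".join(f"{col.frequencies[a]:.6f}" for a in AMINO_ACIDS)
            lines.append(f"{pos}\t{freqs}\t{col.information_content:.6f}")
        return "\n".join(lines) + "\n"


PSEUDOCOUNT = 0.5
MAX_IC = math.log2(20.0)
GAP_COLUMN_FRACTION = 0.5
_GAP_CHARS = set("-.")


def conservation_profile(msa: Sequence[str]) -> ConservationProfile:
    """Pseudocounted per-column frequencies and information content.

    Each column gets frequencies (count + 0.5) / (n_nongap + 10) over the
    20 amino acids and IC = log2(20) − Shannon entropy.  Columns with more
    than 50% gaps are gap columns with no reference position; reference
    positions count ungapped columns of the first sequence.
    """
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: rows differ in length")
    rows = [row.upper() for row in msa]
    for row in rows:
        bad = set(row) - _AA_SET - _GAP_CHARS
        if bad:
            raise ValueError(f"unexpected alignment symbols: {sorted(bad)}")

    columns: List[ProfileColumn] = []
    ref_pos = 0
    for j in range(width):
        col = [row[j] for row in rows]
        nongap = [a for a in col if a not in _GAP_CHARS]
        counts = {a: 0 for a in AMINO_ACIDS}
        for a in nongap:
            counts[a] += 1
        total = len(nongap) + PSEUDOCOUNT * 20
        freqs = {a: (counts[a] + PSEUDOCOUNT) / total for a in AMINO_ACIDS}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        ic = max(0.0, MAX_IC - entropy)
        is_gap_col = (len(col) - len(nongap)) / len(col) > GAP_COLUMN_FRACTION
        if rows[0][j] not in _GAP_CHARS:
            ref_pos += 1
            ref = None if is_gap_col else ref_pos
        else:
            ref = None
        columns.append(ProfileColumn(ref, freqs, ic))
    return ConservationProfile(columns)
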