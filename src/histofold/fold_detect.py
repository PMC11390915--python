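"""Histone-fold detection from Cα geometry.

Secondary structure is assigned from Cα(i)→Cα(i+3) distances and virtual
torsion angles (P-SEA-style); the fold is the α1–L1–α2–L2–α3 triple of
helix runs, and the family call (nucleosomal vs α3-truncated) follows from
the α3 helix length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .structure_io import StructureModel

__all__ = [
    "HelixSegment",
    "HistoneFoldAnnotation",
    "assign_secondary_structure",
    "detect_histone_fold",
    "classify_fold_family",
]

# Cα(i)->Cα(i+3) distance band and virtual-torsion band for a helical window
HELIX_D13 = (4.6, 6.4)
HELIX_TORSION_DEG = (35.0, 75.0)
MIN_HELIX_RUN = 4

# fold-element length bands (residues)
ALPHA1_BAND = (6, 16)
ALPHA2_BAND = (18, 34)
ALPHA3_BAND = (2, 14)
LINKER_BAND = (1, 8)
# α3-family thresholds on the α3 helix length
ALPHA3_MAX = 5
NUCLEOSOMAL_MIN = 8
# α2 shortening (corroborating evidence only)
ALPHA2_SHORT_MAX = 26

MIN_FOLD_CHAIN_LEN = 30


@dataclass(frozen=True)
class HelixSegment:
    chain_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("helix end before start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class HistoneFoldAnnotation:
    alpha1: HelixSegment
    alpha2: HelixSegment
    alpha3: HelixSegment
    l1_length: int
    l2_length: int
    fold_span: Tuple[int, int]
    fold_family: str  # nucleosomal | alpha3 | ambiguous

    @property
    def chain_id(self) -> str:
        return self.alpha1.chain_id

    def alpha2_tail8(self) -> range:
        """Positions of the last 8 residues of α2."""
        start = max(self.alpha2.start, self.alpha2.end - 7)
        return range(start, self.alpha2.end + 1)

    def in_fold(self, position: int) -> bool:
        return self.fold_span[0] <= position <= self.fold_span[1]


def _virtual_torsion(p0, p1, p2, p3) -> float:
    """Dihedral of four points in degrees, NaN if degenerate."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-9 or n2n < 1e-9 or b1n < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b1 / b1n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def _window_passes(ca: np.ndarray, i: int) -> bool:
    d = float(np.linalg.norm(ca[i + 3] - ca[i]))
    if not (HELIX_D13[0] <= d <= HELIX_D13[1]):
        return False
    tor = _virtual_torsion(ca[i], ca[i + 1], ca[i + 2], ca[i + 3])
    return HELIX_TORSION_DEG[0] <= tor <= HELIX_TORSION_DEG[1]


def _helix_runs(ca: np.ndarray) -> List[Tuple[int, int]]:
    """0-based inclusive helix runs from chained passing windows.

    Passing 4-residue windows are clustered when they overlap (share at
    least one residue); each cluster spans from its first window start to
    its last window end.  Two back-to-back helices whose junction window
    fails therefore stay separate runs even with no coil between them.
    """
    idxs = [i for i in range(len(ca) - 3) if _window_passes(ca, i)]
    runs: List[Tuple[int, int]] = []
    for i in idxs:
        if runs and i <= runs[-1][1]:  # window overlaps previous cluster
            runs[-1] = (runs[-1][0], i + 3)
        else:
            runs.append((i, i + 3))
    return [r for r in runs if r[1] - r[0] + 1 >= MIN_HELIX_RUN]


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """0-based inclusive (start, end) runs of True."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def assign_secondary_structure(model: StructureModel, chain_id: str) -> str:
    """Per-residue H/C state string for one chain.

    A residue is helical when it is covered by a 4-residue Cα window whose
    end-to-end distance lies in [4.6, 6.4] Å and whose virtual torsion lies
    in [35°, 75°]; H runs shorter than 4 are smoothed to C.
    """
    if chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} not in model")
    chain = model.chains[chain_id]
    if len(chain) < 5:
        raise ValueError(f"chain {chain_id!r} has fewer than 5 residues")
    ca = chain.ca_coords()
    states = ["C"] * len(ca)
    for start, end in _helix_runs(ca):
        for i in range(start, end + 1):
            states[i] = "H"
    return "".join(states)


def _short_helix_run_after(
    ca: np.ndarray, begin0: int, max_gap: int
) -> Optional[Tuple[int, int]]:
    """Find a 2-3 residue helix-like stretch starting within ``max_gap``
    residues after 0-based position ``begin0`` (the residue after α2's end).

    Helix-like: consecutive Cα(i)->Cα(i+2) distance in a tight helical band.
    Used only for the truncated-α3 special case, where the run is below the
    global 4-residue helix minimum.
    """
    n = len(ca)
    lo, hi = 5.0, 6.2  # ideal helix d(i, i+2) ~ 5.4-5.6 Å; extended ~ 7.3
    for s in range(begin0, min(begin0 + max_gap, n - 2)):
        if s < 1:
            continue
        length = 2
        if lo <= np.linalg.norm(ca[s + 2] - ca[s]) <= hi:
            length = 3
            if s + 3 < n and lo <= np.linalg.norm(ca[s + 3] - ca[s + 1]) <= hi:
                length = 4
            d12 = np.linalg.norm(ca[s + 1] - ca[s])
            if 3.4 <= d12 <= 4.2:
                return (s, s + length - 1)
    return None


def detect_histone_fold(
    model: StructureModel, chain_id: str
) -> Optional[HistoneFoldAnnotation]:
    """Locate the α1–L1–α2–L2–α3 histone fold in one chain.

    Returns the best triple of consecutive helix runs with α1 in [6, 16],
    α2 in [18, 34], α3 in [2, 14] and linkers in [1, 8]; an H run of 2-3
    residues shortly after α2 is accepted as a truncated α3.  ``None`` when
    no triple qualifies.  Positions are 1-based sequential chain positions.
    """
    chain = model.chains.get(chain_id)
    if chain is None:
        raise KeyError(f"chain {chain_id!r} not in model")
    if len(chain) < MIN_FOLD_CHAIN_LEN:
        return None
    ca = chain.ca_coords()
    runs0 = _helix_runs(ca)  # 0-based; window-cluster segmentation

    candidates: List[HistoneFoldAnnotation] = []
    for j in range(len(runs0)):
        a2s, a2e = runs0[j]
        a2len = a2e - a2s + 1
        if not (ALPHA2_BAND[0] <= a2len <= ALPHA2_BAND[1]):
            continue
        # α1: the run immediately before α2
        if j == 0:
            continue
        a1s, a1e = runs0[j - 1]
        a1len = a1e - a1s + 1
        l1 = a2s - a1e - 1
        if not (ALPHA1_BAND[0] <= a1len <= ALPHA1_BAND[1]):
            continue
        if not (LINKER_BAND[0] <= l1 <= LINKER_BAND[1]):
            continue
        # α3: the run immediately after α2, or a short truncated run
        a3 = None
        next_run_adjacent = False
        if j + 1 < len(runs0):
            a3s, a3e = runs0[j + 1]
            a3len = a3e - a3s + 1
            l2 = a3s - a2e - 1
            if LINKER_BAND[0] <= l2 <= LINKER_BAND[1]:
                next_run_adjacent = True
                if ALPHA3_BAND[0] <= a3len <= ALPHA3_BAND[1]:
                    a3 = (a3s, a3e)
        if a3 is None and not next_run_adjacent:
            # truncated α3 (2-3 residues) falls below the 4-residue helix
            # minimum; only searched when no helix run follows at linker
            # distance
            short = _short_helix_run_after(ca, a2e + 2, LINKER_BAND[1])
            if short is not None:
                a3 = short
        if a3 is None:
            continue
        a3s, a3e = a3
        l2 = a3s - a2e - 1
        if not (LINKER_BAND[0] <= l2 <= LINKER_BAND[1]):
            continue
        ann = HistoneFoldAnnotation(
            alpha1=HelixSegment(chain_id, a1s + 1, a1e + 1),
            alpha2=HelixSegment(chain_id, a2s + 1, a2e + 1),
            alpha3=HelixSegment(chain_id, a3s + 1, a3e + 1),
            l1_length=l1,
            l2_length=l2,
            fold_span=(a1s + 1, a3e + 1),
            fold_family="unset",
        )
        candidates.append(ann)
    if not candidates:
        return None
    # prefer the longest α2, then the most N-terminal triple
    best = max(candidates, key=lambda a: (a.alpha2.length, -a.alpha1.start))
    return HistoneFoldAnnotation(
        alpha1=best.alpha1,
        alpha2=best.alpha2,
        alpha3=best.alpha3,
        l1_length=best.l1_length,
        l2_length=best.l2_length,
        fold_span=best.fold_span,
        fold_family=classify_fold_family(best),
    )


def classify_fold_family(ann: HistoneFoldAnnotation) -> str:
    """Call the fold family from the α3 helix length.

    α3-truncated folds have a 3-4 residue α3 against the 10-residue
    nucleosomal α3; the bands (<=5 / >=8, ambiguous between) absorb
    helix-end fraying.  α2 shortening is corroborating only.
    """
    if ann.alpha3.length <= ALPHA3_MAX:
        return "alpha3"
    if ann.alpha3.length >= NUCLEOSOMAL_MIN:
        return "nucleosomal"
    return "ambiguous"
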