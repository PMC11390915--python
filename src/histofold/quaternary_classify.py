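"""Quaternary-topology classification, interface-confidence filtering,
fused-domain flagging and the final per-protein category call."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .fold_detect import HistoneFoldAnnotation, assign_secondary_structure, _runs
from .structure_io import PaeMatrix, StructureModel

__all__ = [
    "InterfaceContactMap",
    "TopologyCall",
    "CategoryCall",
    "find_interchain_contacts",
    "detect_handshake_dimer",
    "detect_dimerizing_ctail",
    "interface_confidence",
    "classify_tetramer_topology",
    "detect_extra_domains",
    "estimate_wrapped_diameter",
    "assign_category",
]

CONTACT_CUTOFF = 8.0
HANDSHAKE_MIN_CONTACTS = 10
HANDSHAKE_ANGLE_BAND = (15.0, 60.0)
PAE_HIGH_THRESHOLD = 10.0
ELEMENT_DOMINANCE = 0.60
BUNDLE_CUTOFF = 12.0
INTERFACE_MIN_CONTACTS = 5
EXTRA_DOMAIN_MIN_LEN = 25
COMPACTNESS_FACTOR = 0.45
RAB_MIN_DOMAIN_LEN = 120
RDGC_MIN_CTERM_HELIX = 30

CATEGORIES = (
    "nucleosomal",
    "ftf",
    "bacterial_dimer",
    "zz",
    "rab_gtpase",
    "phage_like",
    "coiled_coil",
    "mc_like",
    "rdgc_like",
    "ihf_like",
    "transmembrane",
    "undefined",
)


@dataclass
class InterfaceContactMap:
    """Cα–Cα contacts between distinct chains at a distance cutoff."""

    cutoff: float
    pairs: List[Tuple[str, int, str, int]]  # (chain_a, pos_a, chain_b, pos_b), 1-based
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    def count(self, chain_a: str, chain_b: str) -> int:
        key = tuple(sorted((chain_a, chain_b)))
        return self.counts.get(key, 0)

    def between(self, chain_a: str, chain_b: str) -> List[Tuple[str, int, str, int]]:
        key = tuple(sorted((chain_a, chain_b)))
        return [p for p in self.pairs if tuple(sorted((p[0], p[2]))) == key]


@dataclass
class TopologyCall:
    topology: str  # handshake_dimer | ftf_torus | cc_bundle | ctail_tetramer | open_stack | none
    interfaces: List[Tuple[Tuple[str, str], str, int]]  # (chain pair, elements, contacts)
    confidence: str = "unknown"  # high | low | unknown
    dimer_pairing: Optional[Tuple[Tuple[str, str], Tuple[str, str]]] = None
    reason: str = ""


@dataclass
class CategoryCall:
    category: str
    evidence: List[Tuple[str, str]]
    confidence: str
    flags: List[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# contacts


def find_interchain_contacts(
    model: StructureModel, cutoff: float = CONTACT_CUTOFF
) -> InterfaceContactMap:
    """All deduplicated inter-chain Cα–Cα contacts at or below ``cutoff``.

    Positions are 1-based sequential positions within each chain.
    """
    if model.n_chains < 2:
        raise ValueError(
            "model has a single chain; use the monomer analysis path instead"
        )
    ids = model.chain_ids
    pairs: List[Tuple[str, int, str, int]] = []
    counts: Dict[Tuple[str, str], int] = {}
    for a, b in itertools.combinations(ids, 2):
        ca_a = model.chains[a].ca_coords()
        ca_b = model.chains[b].ca_coords()
        if len(ca_a) == 0 or len(ca_b) == 0:
            continue
        d = cdist(ca_a, ca_b)
        ii, jj = np.nonzero(d <= cutoff)
        for i, j in zip(ii.tolist(), jj.tolist()):
            pairs.append((a, i + 1, b, j + 1))
        counts[(a, b)] = len(ii)
    return InterfaceContactMap(cutoff=cutoff, pairs=pairs, counts=counts)


def _helix_axis(ca: np.ndarray) -> np.ndarray:
    """Unit direction of the least-squares line through Cα coordinates,
    oriented from the first to the last residue."""
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _crossing_angle(ca_a: np.ndarray, ca_b: np.ndarray) -> float:
    """Acute angle in degrees between two fitted helix axes (line angle)."""
    axis_a = _helix_axis(ca_a)
    axis_b = _helix_axis(ca_b)
    cosv = abs(float(np.dot(axis_a, axis_b)))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _alpha2_contacts(
    contacts: InterfaceContactMap,
    anns: Dict[str, HistoneFoldAnnotation],
    chain_a: str,
    chain_b: str,
) -> int:
    n = 0
    for ca_, pa, cb_, pb in contacts.between(chain_a, chain_b):
        ann_a, ann_b = anns.get(ca_), anns.get(cb_)
        if ann_a is None or ann_b is None:
            continue
        if pa in ann_a.alpha2.positions() and pb in ann_b.alpha2.positions():
            n += 1
    return n


def detect_handshake_dimer(
    model: StructureModel,
    anns: Dict[str, HistoneFoldAnnotation],
    contacts: Optional[InterfaceContactMap] = None,
    cutoff: float = CONTACT_CUTOFF,
) -> Tuple[bool, Optional[float]]:
    """Is this two-chain model a handshake dimer?  Returns (call, angle).

    True when at least 10 inter-chain α2↔α2 contacts exist and the α2 axis
    crossing angle lies in [15°, 60°].
    """
    if model.n_chains != 2:
        raise ValueError(f"expected exactly 2 chains, got {model.n_chains}")
    a, b = model.chain_ids
    if a not in anns or b not in anns or anns[a] is None or anns[b] is None:
        raise ValueError("both chains need a histone-fold annotation")
    if contacts is None:
        contacts = find_interchain_contacts(model, cutoff)
    n22 = _alpha2_contacts(contacts, anns, a, b)
    if n22 < HANDSHAKE_MIN_CONTACTS:
        return False, None
    sl_a = slice(anns[a].alpha2.start - 1, anns[a].alpha2.end)
    sl_b = slice(anns[b].alpha2.start - 1, anns[b].alpha2.end)
    angle = _crossing_angle(
        model.chains[a].ca_coords()[sl_a], model.chains[b].ca_coords()[sl_b]
    )
    ok = HANDSHAKE_ANGLE_BAND[0] <= angle <= HANDSHAKE_ANGLE_BAND[1]
    return ok, angle


# --------------------------------------------------------------------------
# PAE gating


def interface_confidence(
    pae: PaeMatrix, chain_a: str, chain_b: str, threshold: float = PAE_HIGH_THRESHOLD
) -> Tuple[float, str]:
    """Mean inter-chain PAE over both off-diagonal blocks; high iff < 10 Å."""
    for cid in (chain_a, chain_b):
        if cid not in pae.chain_spans:
            raise KeyError(f"chain {cid!r} not in PAE matrix")
    ab = pae.block(chain_a, chain_b)
    ba = pae.block(chain_b, chain_a)
    mean = float((ab.sum() + ba.sum()) / (ab.size + ba.size))
    return mean, ("high" if mean < threshold else "low")


# --------------------------------------------------------------------------
# tetramer topology


def _pair_into_dimers(
    model: StructureModel,
    anns: Dict[str, HistoneFoldAnnotation],
    contacts: InterfaceContactMap,
) -> Optional[Tuple[Tuple[str, str], Tuple[str, str]]]:
    """Partition 4 chains into 2 dimers maximising total α2↔α2 contacts."""
    ids = model.chain_ids
    best = None
    best_score = -1
    a = ids[0]
    for partner in ids[1:]:
        rest = [c for c in ids if c not in (a, partner)]
        score = _alpha2_contacts(contacts, anns, a, partner) + _alpha2_contacts(
            contacts, anns, rest[0], rest[1]
        )
        if score > best_score:
            best_score = score
            best = ((a, partner), (rest[0], rest[1]))
    if best is None or best_score < 2 * HANDSHAKE_MIN_CONTACTS:
        return None
    return best


def _contact_elements(
    pos: int, ann: Optional[HistoneFoldAnnotation]
) -> Tuple[bool, bool]:
    """(is FtF element, is post-fold C-terminal) for one residue position."""
    if ann is None:
        return False, False
    ftf = pos in ann.alpha3.positions() or pos in ann.alpha2_tail8()
    post_fold = pos > ann.fold_span[1]
    return ftf, post_fold


def _postfold_positions(
    model: StructureModel, ann: Optional[HistoneFoldAnnotation], chain_id: str
) -> np.ndarray:
    if ann is None:
        return np.empty((0, 3))
    ca = model.chains[chain_id].ca_coords()
    start = ann.fold_span[1]  # 0-based slice start == 1-based end position
    return ca[start:]


def classify_tetramer_topology(
    model: StructureModel,
    anns: Dict[str, HistoneFoldAnnotation],
    contacts: Optional[InterfaceContactMap] = None,
    cutoff: float = CONTACT_CUTOFF,
) -> TopologyCall:
    """Classify a 4-chain model into FtF torus / CC bundle / C-tail
    tetramer / open stack / none.

    Chains are paired into two handshake dimers by maximal α2↔α2 contact
    count; inter-dimer interfaces are then classified by the fold elements
    their contacts involve (α3 + last 8 of α2 = FtF-style; post-fold
    C-terminal residues = C-terminal tetramerisation, with a mutual 12 Å
    proximity of all four C-terminal segments distinguishing a coiled-coil
    bundle).
    """
    if model.n_chains != 4:
        raise ValueError(f"expected 4 chains, got {model.n_chains}")
    if contacts is None:
        contacts = find_interchain_contacts(model, cutoff)
    pairing = _pair_into_dimers(model, anns, contacts)
    if pairing is None:
        return TopologyCall(
            "none", [], reason="chains not pairable into handshake dimers"
        )
    (d1a, d1b), (d2a, d2b) = pairing
    cross_pairs = [(x, y) for x in (d1a, d1b) for y in (d2a, d2b)]

    n_cross = 0
    n_ftf = 0
    n_post = 0
    interfaces: List[Tuple[Tuple[str, str], str, int]] = []
    for x, y in cross_pairs:
        plist = contacts.between(x, y)
        if not plist:
            continue
        k_ftf = k_post = 0
        for ca_, pa, cb_, pb in plist:
            fa, qa = _contact_elements(pa, anns.get(ca_))
            fb, qb = _contact_elements(pb, anns.get(cb_))
            if fa or fb:
                k_ftf += 1
            if qa or qb:
                k_post += 1
        n_cross += len(plist)
        n_ftf += k_ftf
        n_post += k_post
        if len(plist) >= INTERFACE_MIN_CONTACTS:
            kind = "ftf" if k_ftf >= k_post else "cterm"
            interfaces.append(((x, y), kind, len(plist)))

    call = TopologyCall("none", interfaces, dimer_pairing=pairing)
    if n_cross == 0:
        call.reason = "no inter-dimer contacts"
        return call

    post_frac = n_post / n_cross
    ftf_frac = n_ftf / n_cross

    if post_frac >= ELEMENT_DOMINANCE:
        # bundle test: post-fold segments of all 4 chains mutually close
        segments = {
            cid: _postfold_positions(model, anns.get(cid), cid)
            for cid in model.chain_ids
        }
        bundled = all(len(seg) > 0 for seg in segments.values())
        if bundled:
            for x, y in itertools.combinations(model.chain_ids, 2):
                dmin = float(cdist(segments[x], segments[y]).min())
                if dmin >= BUNDLE_CUTOFF:
                    bundled = False
                    break
        call.topology = "cc_bundle" if bundled else "ctail_tetramer"
        return call

    if ftf_frac >= ELEMENT_DOMINANCE:
        n_interfaces = len(interfaces)
        if n_interfaces >= 2:
            call.topology = "ftf_torus"
        elif n_interfaces == 1:
            call.topology = "open_stack"
        else:
            call.reason = "FtF-style contacts but no interface above threshold"
        return call

    call.reason = (
        f"no element class dominates (ftf {ftf_frac:.2f}, post-fold {post_frac:.2f})"
    )
    return call


def detect_dimerizing_ctail(
    model: StructureModel,
    anns: Dict[str, HistoneFoldAnnotation],
    contacts: Optional[InterfaceContactMap] = None,
    cutoff: float = CONTACT_CUTOFF,
) -> bool:
    """Structured dimerising C-tail in a 2-chain model: each chain carries
    at least two post-fold helices and the post-fold regions of the two
    chains contact each other."""
    if model.n_chains != 2:
        return False
    a, b = model.chain_ids
    if anns.get(a) is None or anns.get(b) is None:
        return False
    for cid in (a, b):
        states = assign_secondary_structure(model, cid)
        post = states[anns[cid].fold_span[1] :]
        mask = np.array([s == "H" for s in post])
        if len(_runs(mask)) < 2:
            return False
    if contacts is None:
        contacts = find_interchain_contacts(model, cutoff)
    n_post = 0
    for ca_, pa, cb_, pb in contacts.between(a, b):
        if pa > anns[ca_].fold_span[1] and pb > anns[cb_].fold_span[1]:
            n_post += 1
    return n_post >= INTERFACE_MIN_CONTACTS


# --------------------------------------------------------------------------
# fused domains / wrapped diameter


def radius_of_gyration(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered ** 2).sum(axis=1).mean()))


def detect_extra_domains(
    model: StructureModel,
    ann: HistoneFoldAnnotation,
    min_len: int = EXTRA_DOMAIN_MIN_LEN,
) -> List[Tuple[str, int, bool]]:
    """Flanking segments >= 25 residues, flagged compact when their radius
    of gyration is below 0.45 × (length × 1.5 Å) — folded domain vs
    extended tail."""
    chain = model.chains[ann.chain_id]
    ca = chain.ca_coords()
    start, end = ann.fold_span
    out: List[Tuple[str, int, bool]] = []
    n_len = start - 1
    if n_len >= min_len:
        seg = ca[: start - 1]
        compact = radius_of_gyration(seg) < COMPACTNESS_FACTOR * (n_len * 1.5)
        out.append(("N", n_len, compact))
    c_len = len(chain) - end
    if c_len >= min_len:
        seg = ca[end:]
        compact = radius_of_gyration(seg) < COMPACTNESS_FACTOR * (c_len * 1.5)
        out.append(("C", c_len, compact))
    return out


def estimate_wrapped_diameter(
    model: StructureModel, dna_diameter: float = 2.0
) -> float:
    """DNA-wrapped tetramer diameter in nm.

    Maximal Cα–Cα extent within the torus plane (the plane orthogonal to
    the smallest principal axis of the Cα cloud), converted to nm, plus one
    DNA diameter on each side.
    """
    if model.n_chains < 4:
        raise ValueError(f"need a tetramer (4 chains), got {model.n_chains}")
    ca = model.all_ca()
    centered = ca - ca.mean(axis=0)
    if len(ca) < 2 or np.allclose(centered, 0.0):
        extent = 0.0
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        normal = vt[-1]  # smallest principal axis = torus axis
        in_plane = centered - np.outer(centered @ normal, normal)
        extent = float(cdist(in_plane, in_plane).max())
    return extent / 10.0 + 2.0 * dna_diameter


# --------------------------------------------------------------------------
# final category


@dataclass
class CategoryInputs:
    """Everything the decision tree looks at for one protein."""

    fold_family: Optional[str] = None  # nucleosomal | alpha3 | ambiguous | None
    dimer_is_handshake: Optional[bool] = None
    dimer_confidence: str = "unknown"
    dimer_has_dimerizing_ctail: bool = False
    tetramer_topology: Optional[str] = None
    tetramer_confidence: str = "unknown"
    extra_domains: List[Tuple[str, int, bool]] = field(default_factory=list)
    has_zz_sites: bool = False
    has_p_loop: bool = False
    basic_alpha1_positions: List[int] = field(default_factory=list)
    tm_segments: List[Tuple[int, int]] = field(default_factory=list)
    cterm_helix_len: int = 0


def _n_compact_domain(inputs: CategoryInputs) -> Optional[int]:
    for side, length, compact in inputs.extra_domains:
        if side == "N" and compact:
            return length
    return None


def assign_category(inputs: CategoryInputs) -> CategoryCall:
    """First-match decision tree over fold family, quaternary topology,
    fused domains and sequence features.

    A rule whose decisive multimer interface is low-confidence is skipped
    (low-quality interfaces are not considered for categorisation).
    """
    ev: List[Tuple[str, str]] = []
    flags: List[str] = []

    def result(category: str, confidence: str = "high") -> CategoryCall:
        return CategoryCall(category, ev, confidence, flags)

    fam = inputs.fold_family
    tet = inputs.tetramer_topology
    tet_high = inputs.tetramer_confidence == "high"
    dim_high = inputs.dimer_confidence == "high"
    dimer = bool(inputs.dimer_is_handshake) and dim_high
    if inputs.tetramer_topology is not None and not tet_high:
        ev.append(("tetramer_gate", f"low-confidence tetramer interface: {tet} ignored"))
        tet = None

    if fam is None:
        ev.append(("no_fold", "no histone fold detected"))
        return result("undefined", "low")

    # 1. transmembrane: no α1-face basics and a TM segment
    if not inputs.basic_alpha1_positions and inputs.tm_segments:
        ev.append(("transmembrane", f"TM segments {inputs.tm_segments}, no α1 basics"))
        return result("transmembrane")

    n_dom = _n_compact_domain(inputs)
    if fam == "alpha3":
        # 2. ZZ: N-terminal compact domain carrying ZZ zinc sites
        if n_dom is not None and inputs.has_zz_sites:
            ev.append(("zz", f"N compact domain ({n_dom} aa) with C4+C2H2 sites"))
            return result("zz")
        # 3. Rab GTPase: large N-terminal compact domain with a P-loop
        if n_dom is not None and n_dom >= RAB_MIN_DOMAIN_LEN and inputs.has_p_loop:
            ev.append(("rab_gtpase", f"N compact domain ({n_dom} aa) with P-loop"))
            return result("rab_gtpase")
        # 4. phage: C-terminal helix tetramerisation
        if tet in ("ctail_tetramer", "cc_bundle"):
            ev.append(("phage_like", f"α3 fold with C-terminal tetramerisation ({tet})"))
            return result("phage_like")
        # 5. FtF: torus tetramer at high confidence
        if tet == "ftf_torus":
            ev.append(("ftf", "α3 fold with face-to-face torus tetramer"))
            return result("ftf")
        # 6. bacterial dimer: handshake dimer only
        if dimer:
            ev.append(("bacterial_dimer", "α3 fold, confident dimer, no tetramer"))
            return result("bacterial_dimer")
        ev.append(("undefined", "α3 fold without confident quaternary evidence"))
        return result("undefined", "low")

    if fam in ("nucleosomal", "ambiguous"):
        # 7. coiled-coil (rdgc-like flag for long C-terminal helices)
        if tet == "cc_bundle":
            ev.append(("coiled_coil", "C-terminal helices form a 4-helix bundle"))
            if inputs.cterm_helix_len >= RDGC_MIN_CTERM_HELIX:
                flags.append("rdgc_like")
                ev.append(
                    ("rdgc_like_flag", f"C-terminal helix {inputs.cterm_helix_len} aa >= {RDGC_MIN_CTERM_HELIX}")
                )
            return result("coiled_coil")
        # 8. Mc-like: C-terminal tetramerisation without a bundle
        if tet == "ctail_tetramer":
            ev.append(("mc_like", "C-terminal tetramerisation domain"))
            return result("mc_like")
        # 9. IHF-like: dimer with a structured dimerising C-tail
        if dimer and inputs.dimer_has_dimerizing_ctail:
            ev.append(("ihf_like", "dimer with structured dimerising C-tail"))
            return result("ihf_like")
        # 10. nucleosomal: open stack, plain dimer, or monomer-only evidence
        if tet == "open_stack":
            ev.append(("nucleosomal", "open-stack tetramer (hypernucleosome-like)"))
            return result("nucleosomal")
        if dimer:
            ev.append(("nucleosomal", "handshake dimer, no larger assembly"))
            return result("nucleosomal")
        if inputs.dimer_is_handshake is None and inputs.tetramer_topology is None:
            ev.append(("nucleosomal", "monomer fold only; no multimer evidence"))
            flags.append("no_multimer_evidence")
            return result("nucleosomal", "low")
        if inputs.tetramer_topology == "none" or tet == "none":
            ev.append(("nucleosomal", "fold present; multimer predictions show no assembly"))
            flags.append("no_assembly")
            return result("nucleosomal", "low")

    ev.append(("undefined", "no decisive rule fired at high confidence"))
    return result("undefined", "low")
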