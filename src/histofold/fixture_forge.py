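"""Synthetic fixture generator.

Builds idealized histone-fold monomers, dimers and tetramers in every
supported quaternary topology, together with matching sequences, pLDDT
tracks and block-structured PAE matrices.  Fixtures aim for
classifier-unambiguous geometry, not physical realism.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Chain, PaeMatrix, Residue, StructureModel

__all__ = [
    "FlankSpec",
    "FoldArchitecture",
    "AssemblySpec",
    "ConfidenceSpec",
    "NUCLEOSOMAL_PRESET",
    "ALPHA3_PRESET",
    "build_fold_monomer",
    "assemble_oligomer",
    "synth_confidence",
    "synth_sequence_set",
    "synth_msa",
]

RISE = 1.5
TWIST = math.radians(100.0)
RADIUS = 2.3
MIN_CLEARANCE = 2.5

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# background alphabet: no R/T/D (motif), no C/H (zinc), no K/E (charge),
# no strongly hydrophobic residues (TM windows stay below threshold)
BACKGROUND_ALPHABET = "AGSNQP"


@dataclass(frozen=True)
class FlankSpec:
    length: int
    kind: str  # charged_tail | compact_domain | tm_segment | cc_extension | dimerizing_tail
    sign: int = 0  # for charged_tail: +1 or -1

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("flank length must be >= 0")


@dataclass(frozen=True)
class FoldArchitecture:
    alpha1_len: int = 11
    alpha2_len: int = 29
    alpha3_len: int = 10
    l1_len: int = 3
    l2_len: int = 3
    n_flank: Optional[FlankSpec] = None
    c_flank: Optional[FlankSpec] = None

    def __post_init__(self) -> None:
        for name in ("alpha1_len", "alpha2_len", "alpha3_len", "l1_len", "l2_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_flank_len(self) -> int:
        return self.n_flank.length if self.n_flank else 0

    @property
    def c_flank_len(self) -> int:
        return self.c_flank.length if self.c_flank else 0

    @property
    def fold_len(self) -> int:
        return (
            self.alpha1_len + self.l1_len + self.alpha2_len + self.l2_len + self.alpha3_len
        )

    @property
    def total_len(self) -> int:
        return self.n_flank_len + self.fold_len + self.c_flank_len

    def segments(self) -> Dict[str, Tuple[int, int]]:
        """1-based inclusive spans of every segment."""
        spans = {}
        pos = 1

        def put(name: str, length: int) -> None:
            nonlocal pos
            if length > 0:
                spans[name] = (pos, pos + length - 1)
            pos += length

        put("n_flank", self.n_flank_len)
        put("alpha1", self.alpha1_len)
        put("l1", self.l1_len)
        put("alpha2", self.alpha2_len)
        put("l2", self.l2_len)
        put("alpha3", self.alpha3_len)
        put("c_flank", self.c_flank_len)
        return spans


NUCLEOSOMAL_PRESET = FoldArchitecture(11, 29, 10, 3, 3)
ALPHA3_PRESET = FoldArchitecture(11, 25, 4, 3, 3)

TOPOLOGIES = (
    "monomer",
    "handshake_dimer",
    "ftf_tetramer",
    "cc_tetramer",
    "ctail_tetramer",
    "open_stack_tetramer",
    "separated_chains",
)


@dataclass(frozen=True)
class AssemblySpec:
    architecture: FoldArchitecture
    topology: str
    seed: int = 0
    jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


@dataclass(frozen=True)
class ConfidenceSpec:
    core_plddt: float = 90.0
    tail_plddt: float = 35.0
    intra_pae: float = 3.0
    inter_pae: float = 5.0

    def __post_init__(self) -> None:
        for name in ("core_plddt", "tail_plddt"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.intra_pae < 0 or self.inter_pae < 0:
            raise ValueError("PAE values must be >= 0")


# --------------------------------------------------------------------------
# geometry primitives


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def helix_points(
    n: int, start: np.ndarray, axis: np.ndarray, ref: np.ndarray, phase: float = 0.0
) -> np.ndarray:
    """Cα trace of an ideal α-helix: rise 1.5 Å, 100° twist, radius 2.3 Å.

    ``start`` is the axis point of the first residue's circle; ``ref`` fixes
    the phase origin (must not be parallel to ``axis``).
    """
    axis = _unit(np.asarray(axis, dtype=float))
    ref = np.asarray(ref, dtype=float)
    u = ref - np.dot(ref, axis) * axis
    u = _unit(u)
    v = np.cross(axis, u)
    i = np.arange(n)[:, None]
    # negative sense yields a right-handed helix (Cα virtual torsion ~ +50°)
    ang = phase - TWIST * np.arange(n)
    return (
        start
        + axis * (RISE * i)
        + RADIUS * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
    )


def _bridge(p: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """k linker points interpolated strictly between p and q."""
    if k == 0:
        return np.empty((0, 3))
    ts = np.arange(1, k + 1) / (k + 1)
    return p + ts[:, None] * (q - p)


def _zigzag(start: np.ndarray, direction: np.ndarray, n: int, perp: np.ndarray) -> np.ndarray:
    """Extended chain: ~3.3 Å advance per residue with an alternating
    perpendicular offset (never helix-like)."""
    direction = _unit(np.asarray(direction, dtype=float))
    perp = _unit(np.asarray(perp, dtype=float))
    i = np.arange(n)[:, None]
    wiggle = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)[:, None]
    return start + direction * (3.3 * i) + perp * (1.2 * wiggle)


def _snake_cube(center: np.ndarray, n: int, spacing: float = 3.8) -> np.ndarray:
    """Boustrophedon walk through a cubic lattice: a compact globule whose
    consecutive points stay ``spacing`` apart."""
    side = max(2, math.ceil(n ** (1.0 / 3.0)))
    pts = []
    count = 0
    for iz in range(side + 2):
        if count >= n:
            break
        for iy in range(side):
            if count >= n:
                break
            ys = iy if iz % 2 == 0 else side - 1 - iy
            xs = range(side) if iy % 2 == 0 else range(side - 1, -1, -1)
            for ix in xs:
                if count >= n:
                    break
                pts.append([ix * spacing, ys * spacing, iz * spacing])
                count += 1
    pts = np.asarray(pts, dtype=float)
    return pts - pts.mean(axis=0) + center


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(np.asarray(axis, dtype=float))
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def _c2(axis: np.ndarray, point: np.ndarray):
    """Return f(coords): 180° rotation about the line (point, axis)."""
    R = _rotation_about_axis(axis, math.pi)

    def apply(coords: np.ndarray) -> np.ndarray:
        return (coords - point) @ R.T + point

    return apply


# --------------------------------------------------------------------------
# monomer


def _fold_core_coords(arch: FoldArchitecture) -> Dict[str, np.ndarray]:
    """Coordinates of fold segments in the local monomer frame.

    α2 runs along +x with its axis on the x-axis; α1 and α3 pack
    antiparallel above (y=+9) and below (y=-9).
    """
    n1, n2, n3 = arch.alpha1_len, arch.alpha2_len, arch.alpha3_len
    a2 = helix_points(n2, np.array([0.0, 0.0, 0.0]), [1, 0, 0], [0, 0, 1])
    a2_end_x = RISE * (n2 - 1)
    # α1 antiparallel above, its C-terminal end near the α2 start; offset
    # (+13, -3) keeps it clear of the partner chain's α2 in the handshake
    a1_start = np.array([RISE * (n1 - 1) - 2.0, 13.0, -3.0])
    a1 = helix_points(n1, a1_start, [-1, 0, 0], [0, 0, 1])
    # α3 antiparallel below, N-terminal end near the α2 end
    a3_start = np.array([a2_end_x + 2.0, -12.0, 0.0])
    a3 = helix_points(max(n3, 0), a3_start, [-1, 0, 0], [0, 0, 1])
    out = {"alpha1": a1, "alpha2": a2, "alpha3": a3}
    out["l1"] = _bridge(a1[-1], a2[0], arch.l1_len)
    out["l2"] = _bridge(a2[-1], a3[0], arch.l2_len)
    return out


def _flank_coords(arch: FoldArchitecture, core: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    if arch.n_flank and arch.n_flank.length:
        spec = arch.n_flank
        anchor = core["alpha1"][0]
        if spec.kind == "compact_domain":
            size = (spec.length ** (1 / 3)) * 3.8
            center = anchor + np.array([4.0, 16.0 + size, 0.0])
            out["n_flank"] = _snake_cube(center, spec.length)
        else:  # charged_tail / tm_segment: extended
            far = anchor + np.array([3.0, 8.0, 0.0]) + np.array([0.6, 1.0, 0.0]) * (
                3.3 * (spec.length - 1) / 1.2
            )
            pts = _zigzag(far, -np.array([0.6, 1.0, 0.0]), spec.length, [0, 0, 1])
            out["n_flank"] = pts
    if arch.c_flank and arch.c_flank.length:
        spec = arch.c_flank
        anchor = core["alpha3"][-1] if len(core["alpha3"]) else core["alpha2"][-1]
        if spec.kind == "compact_domain":
            size = (spec.length ** (1 / 3)) * 3.8
            center = anchor + np.array([0.0, -16.0 - size, 0.0])
            out["c_flank"] = _snake_cube(center, spec.length)
        elif spec.kind == "cc_extension":
            # 8 Å jog breaks helical continuity at the α3/extension junction
            start = anchor + np.array([0.0, -8.0, 0.0])
            out["c_flank"] = helix_points(spec.length, start, [0, -1, 0], [1, 0, 0])
        elif spec.kind == "dimerizing_tail":
            out["c_flank"] = _dimer_tail_coords(
                spec.length, anchor + np.array([0.0, -8.0, 0.0]), [0, -1, 0], [1, 0, 0]
            )
        else:  # charged_tail / tm_segment
            start = anchor + np.array([0.0, -6.0, 0.0])
            out["c_flank"] = _zigzag(start, [0.3, -1.0, 0.0], spec.length, [0, 0, 1])
    return out


def _dimer_tail_coords(
    length: int, start: np.ndarray, axis, ref
) -> np.ndarray:
    """Two antiparallel helices joined by a short turn (helix-turn-helix)."""
    axis = _unit(np.asarray(axis, dtype=float))
    ref = _unit(np.asarray(ref, dtype=float))
    h = max(4, (length - 2) // 2)
    turn = length - 2 * h
    if turn < 1:
        h = (length - 1) // 2
        turn = length - 2 * h
    h1 = helix_points(h, start, axis, ref)
    # wide turn: clearly outside the helix-window bands, also after
    # coordinate rounding in PDB round-trips
    start2 = start + axis * (RISE * (h - 1) - 2.0) + ref * 10.5
    h2 = helix_points(length - h - turn, start2, -axis, ref)
    bridge = _bridge(h1[-1], h2[0], turn)
    return np.vstack([h1, bridge, h2])


def _chain_coords(arch: FoldArchitecture) -> Tuple[np.ndarray, Dict[str, Tuple[int, int]]]:
    core = _fold_core_coords(arch)
    flanks = _flank_coords(arch, core)
    order = ["n_flank", "alpha1", "l1", "alpha2", "l2", "alpha3", "c_flank"]
    blocks = []
    spans: Dict[str, Tuple[int, int]] = {}
    pos = 1
    for name in order:
        seg = flanks.get(name) if name in ("n_flank", "c_flank") else core.get(name)
        if seg is None or len(seg) == 0:
            continue
        blocks.append(seg)
        spans[name] = (pos, pos + len(seg) - 1)
        pos += len(seg)
    return np.vstack(blocks), spans


def _coords_to_chain(
    coords: np.ndarray, chain_id: str, sequence: Optional[str] = None, plddt: float = 90.0
) -> Chain:
    residues = []
    for i, xyz in enumerate(coords):
        aa = sequence[i] if sequence else "A"
        residues.append(
            Residue(
                index=i + 1,
                name=ONE_TO_THREE.get(aa, "ALA"),
                atoms={"CA": np.array(xyz, dtype=float)},
                plddt=plddt,
            )
        )
    return Chain(chain_id, residues)


def _apply_jitter(coords: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    """Smooth (chain-correlated) Gaussian jitter with amplitude ``sigma``.

    Noise is low-pass filtered along the residue axis so that sub-Å jitter
    displaces coordinates without distorting the local 4-residue window
    geometry that secondary-structure assignment relies on.
    """
    if sigma <= 0:
        return coords
    noise = rng.normal(0.0, 1.0, size=coords.shape)
    kernel = np.ones(7) / 7.0
    smooth = np.stack(
        [np.convolve(noise[:, k], kernel, mode="same") for k in range(3)], axis=1
    )
    scale = sigma / max(float(smooth.std()), 1e-12)
    return coords + smooth * scale


@dataclass
class MonomerTruth:
    architecture: FoldArchitecture
    segments: Dict[str, Tuple[int, int]]

    @property
    def fold_family(self) -> str:
        if self.architecture.alpha3_len <= 5:
            return "alpha3"
        if self.architecture.alpha3_len >= 8:
            return "nucleosomal"
        return "ambiguous"


def build_fold_monomer(
    arch: FoldArchitecture, seed: int = 0, jitter_sigma: float = 0.0
) -> Tuple[StructureModel, MonomerTruth]:
    """Single-chain idealized histone fold; deterministic for a fixed seed."""
    if arch.alpha2_len < 4 or arch.alpha1_len < 4:
        raise ValueError("α1 and α2 must be at least 4 residues")
    rng = np.random.default_rng(seed)
    coords, spans = _chain_coords(arch)
    coords = _apply_jitter(coords, rng, jitter_sigma)
    model = StructureModel({"A": _coords_to_chain(coords, "A")})
    return model, MonomerTruth(arch, spans)


# --------------------------------------------------------------------------
# oligomer assembly

DIMER_HALF_ANGLE = math.radians(15.0)  # α2 crossing = 2 × this
DIMER_AXIS_OFFSET = 5.0  # each α2 axis sits this far from the C2 axis


def _dimer_transforms(arch: FoldArchitecture):
    """Rigid placements of chains A and B forming an exact-C2 handshake.

    The dimer C2 axis u is tilted 15° from z toward x and passes through
    the α2 midpoint; each chain's α2 axis lies 4.5 Å from u, giving a 30°
    crossing at 9 Å axis separation.
    """
    mid_x = RISE * (arch.alpha2_len - 1) / 2.0
    u = np.array([math.sin(DIMER_HALF_ANGLE), 0.0, math.cos(DIMER_HALF_ANGLE)])
    c = np.array([mid_x, 0.0, 0.0])
    shift = np.array([0.0, -DIMER_AXIS_OFFSET, 0.0])

    def place_a(coords: np.ndarray) -> np.ndarray:
        return coords + shift

    c2 = _c2(u, c)

    def place_b(coords: np.ndarray) -> np.ndarray:
        return c2(coords + shift)

    return place_a, place_b, u, c


def _contact_count(a: np.ndarray, b: np.ndarray, cutoff: float = 8.0) -> int:
    if len(a) == 0 or len(b) == 0:
        return 0
    return int((cdist(a, b) <= cutoff).sum())


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return math.inf
    return float(cdist(a, b).min())


def _slice(coords: np.ndarray, span: Tuple[int, int]) -> np.ndarray:
    return coords[span[0] - 1 : span[1]]


def _end_elements(coords: np.ndarray, spans: Dict[str, Tuple[int, int]]) -> np.ndarray:
    """α3 plus the last 8 residues of α2 — the FtF dimer-end elements."""
    a2 = spans["alpha2"]
    tail8 = (max(a2[0], a2[1] - 7), a2[1])
    parts = [_slice(coords, tail8)]
    if "alpha3" in spans:
        parts.append(_slice(coords, spans["alpha3"]))
    return np.vstack(parts)


@dataclass
class AssemblyTruth:
    spec: AssemblySpec
    segments: Dict[str, Tuple[int, int]]  # per-chain (identical chains)
    topology: str  # expected TopologyCall.topology for multimers
    fold_family: str


def assemble_oligomer(spec: AssemblySpec) -> Tuple[StructureModel, AssemblyTruth]:
    """Build the requested oligomer; returns the model and its ground truth.

    Raises when the topology needs a C-terminal flank the architecture
    lacks (cc/ctail tetramers) or when no clash-free docking is found.
    """
    arch = spec.architecture
    rng = np.random.default_rng(spec.seed)
    coords0, spans = _chain_coords(arch)
    truth_topology = {
        "monomer": "monomer",
        "handshake_dimer": "handshake_dimer",
        "ftf_tetramer": "ftf_torus",
        "cc_tetramer": "cc_bundle",
        "ctail_tetramer": "ctail_tetramer",
        "open_stack_tetramer": "open_stack",
        "separated_chains": "none",
    }[spec.topology]
    family = MonomerTruth(arch, spans).fold_family

    if spec.topology in ("cc_tetramer", "ctail_tetramer") and not (
        arch.c_flank and arch.c_flank.length
    ):
        raise ValueError(f"{spec.topology} requires a C-terminal flank")

    if spec.topology == "monomer":
        chain_sets = {"A": coords0}
    elif spec.topology == "handshake_dimer":
        place_a, place_b, _, _ = _dimer_transforms(arch)
        chain_sets = {"A": place_a(coords0), "B": place_b(coords0)}
    elif spec.topology == "separated_chains":
        chain_sets = {
            cid: coords0 + np.array([0.0, 0.0, 120.0 * k])
            for k, cid in enumerate("ABCD")
        }
    elif spec.topology == "ftf_tetramer":
        chain_sets = _build_ftf(arch, coords0, spans)
    elif spec.topology == "open_stack_tetramer":
        chain_sets = _build_open_stack(arch, coords0, spans)
    elif spec.topology == "cc_tetramer":
        chain_sets = _build_cterm_tetramer(arch, coords0, spans, bundled=True)
    elif spec.topology == "ctail_tetramer":
        chain_sets = _build_cterm_tetramer(arch, coords0, spans, bundled=False)
    else:  # pragma: no cover
        raise ValueError(spec.topology)

    chains = {}
    for cid, coords in chain_sets.items():
        coords = _apply_jitter(coords, rng, spec.jitter_sigma)
        chains[cid] = _coords_to_chain(coords, cid)
    model = StructureModel(chains)
    return model, AssemblyTruth(spec, spans, truth_topology, family)


def _end_position_set(spans: Dict[str, Tuple[int, int]]) -> set:
    """1-based positions of the FtF dimer-end elements (α3 + α2 tail-8)."""
    a2 = spans["alpha2"]
    positions = set(range(max(a2[0], a2[1] - 7), a2[1] + 1))
    if "alpha3" in spans:
        positions.update(range(spans["alpha3"][0], spans["alpha3"][1] + 1))
    return positions


def _evaluate_tetramer(chains: Dict[str, np.ndarray], spans, congruent: bool = True) -> dict:
    """Run the real detectors over a candidate placement.

    Returns clearance, the topology call, sorted inter-dimer interface
    sizes, and the either-side FtF-element fraction of cross contacts.
    ``congruent``: all chains are rigid copies, so the fold is detected
    once and reused (secondary structure is rigid-invariant).
    """
    from .fold_detect import detect_histone_fold
    from .quaternary_classify import (
        classify_tetramer_topology,
        find_interchain_contacts,
    )

    clear = min(
        _min_dist(x, y) for x, y in itertools.combinations(chains.values(), 2)
    )
    model = StructureModel(
        {cid: _coords_to_chain(c, cid) for cid, c in chains.items()}
    )
    if congruent:
        first = model.chain_ids[0]
        ann = detect_histone_fold(model, first)
        anns = {cid: ann for cid in model.chain_ids}
    else:
        anns = {cid: detect_histone_fold(model, cid) for cid in model.chain_ids}
    if any(a is None for a in anns.values()):
        return {"clear": clear, "call": None, "sizes": [], "frac": 0.0}
    contacts = find_interchain_contacts(model)
    call = classify_tetramer_topology(model, anns, contacts)
    frac = 0.0
    if call.dimer_pairing is not None:
        ends = _end_position_set(spans)
        (d1a, d1b), (d2a, d2b) = call.dimer_pairing
        n_cross = n_ftf = 0
        for x in (d1a, d1b):
            for y in (d2a, d2b):
                for ca_, pa, cb_, pb in contacts.between(x, y):
                    n_cross += 1
                    if pa in ends or pb in ends:
                        n_ftf += 1
        frac = n_ftf / n_cross if n_cross else 0.0
    sizes = sorted((i[2] for i in call.interfaces), reverse=True)
    return {"clear": clear, "call": call, "sizes": sizes, "frac": frac}


def _build_ftf(arch, coords0, spans) -> Dict[str, np.ndarray]:
    """Close two handshake dimers into a torus.

    The tetramer carries D2 symmetry: B, C, D are 180° rotations of A
    about three mutually orthogonal axes.  A is slid along its α2
    direction; placements are scored with the real fold detector and
    topology classifier, demanding a two-interface torus with margins
    well beyond the classification thresholds.
    """
    place_a, _, u, c = _dimer_transforms(arch)
    base = place_a(coords0)
    v = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, v)
    rot_u = _c2(u, c)
    rot_v = _c2(v, c)
    rot_w = _c2(w, c)

    best = None
    for s in np.arange(-26.0, -16.0, 0.5):
        a = base + np.array([s, 0.0, 0.0])
        b = rot_u(a)
        c_base, d_base = rot_v(a), rot_w(a)
        for ty in np.arange(0.0, 6.5, 0.5):
            for tz in (0.0, 1.0, -1.0, 2.0):
                lift = np.array([0.0, ty, tz])
                chains = {"A": a, "B": b, "C": c_base + lift, "D": d_base + lift}
                ev = _evaluate_tetramer(chains, spans)
                if ev["clear"] < MIN_CLEARANCE or ev["call"] is None:
                    continue
                if ev["call"].topology != "ftf_torus" or len(ev["sizes"]) != 2:
                    continue
                if ev["sizes"][1] < 15 or ev["frac"] < 0.70:
                    continue
                score = (round(ev["frac"], 3), min(ev["sizes"][1], 60), ev["clear"])
                if best is None or score > best[0]:
                    best = (score, chains)
    if best is None:
        raise ValueError("no clash-free FtF docking found for this architecture")
    return best[1]


def _build_open_stack(arch, coords0, spans) -> Dict[str, np.ndarray]:
    """Two dimers joined through a single FtF-style end interface.

    The second dimer is generated by a local two-fold axis placed at one
    dimer end (the stacking dyad); the axis offset is scanned until the
    classifier reports an end-dominated single-interface open stack.
    """
    place_a, place_b, _, _ = _dimer_transforms(arch)
    a = place_a(coords0)
    b = place_b(coords0)
    end_a = _end_elements(a, spans)
    pivot0 = end_a.mean(axis=0)

    best = None
    for axis in (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])):
        for dx in np.arange(1.0, 14.0, 0.25):
            for dy in (-4.0, 0.0, 4.0):
                pivot = pivot0 + np.array([dx, dy, 0.0])
                rot = _c2(axis, pivot)
                chains = {"A": a, "B": b, "C": rot(a), "D": rot(b)}
                ev = _evaluate_tetramer(chains, spans)
                if ev["clear"] < MIN_CLEARANCE or ev["call"] is None:
                    continue
                if ev["call"].topology != "open_stack" or len(ev["sizes"]) != 1:
                    continue
                if ev["sizes"][0] < 12 or ev["frac"] < 0.70:
                    continue
                score = (round(ev["frac"], 3), min(ev["sizes"][0], 60), ev["clear"])
                if best is None or score > best[0]:
                    best = (score, chains)
    if best is None:
        raise ValueError("no clash-free open-stack docking found")
    return best[1]


def _build_cterm_tetramer(
    arch, coords0, spans, bundled: bool
) -> Dict[str, np.ndarray]:
    """Two well-separated dimers whose C-terminal flanks meet.

    ``bundled``: all four flank helices form one 4-helix bundle (mutual
    pairwise proximity < 12 Å).  Otherwise the flanks pair up at two
    distant sites, giving C-terminal tetramerisation without a bundle.
    """
    place_a, place_b, _, _ = _dimer_transforms(arch)
    a = place_a(coords0)
    b = place_b(coords0)
    sep = np.array([0.0, 0.0, 60.0])
    chains = {"A": a, "B": b, "C": a + sep, "D": b + sep}
    span_c = spans["c_flank"]
    length = span_c[1] - span_c[0] + 1
    mid = np.array([RISE * (arch.alpha2_len - 1) / 2.0, 0.0, 30.0])
    axis = np.array([1.0, 0.0, 0.0])
    ref = np.array([0.0, 1.0, 0.0])
    start0 = mid - axis * (RISE * (length - 1) / 2.0)
    if bundled:
        offsets = {
            "A": np.array([0.0, -4.0, -4.0]),
            "B": np.array([0.0, 4.0, -4.0]),
            "C": np.array([0.0, -4.0, 4.0]),
            "D": np.array([0.0, 4.0, 4.0]),
        }
    else:
        # two pair sites 60 Å apart: (A with C) and (B with D)
        offsets = {
            "A": np.array([-40.0, -4.0, 0.0]),
            "C": np.array([-40.0, 4.0, 0.0]),
            "B": np.array([40.0, -4.0, 0.0]),
            "D": np.array([40.0, 4.0, 0.0]),
        }
    out = {}
    for cid, coords in chains.items():
        coords = coords.copy()
        if arch.c_flank.kind == "dimerizing_tail":
            flank = _dimer_tail_coords(length, start0 + offsets[cid], axis, ref)
        else:
            flank = helix_points(length, start0 + offsets[cid], axis, ref)
        coords[span_c[0] - 1 : span_c[1]] = flank
        out[cid] = coords
    return out


def build_ihf_dimer(arch: FoldArchitecture, seed: int = 0, jitter_sigma: float = 0.0):
    """Handshake dimer whose two-helix C-tails dimerize with each other."""
    if not (arch.c_flank and arch.c_flank.kind == "dimerizing_tail"):
        raise ValueError("IHF dimer requires a dimerizing_tail C-flank")
    rng = np.random.default_rng(seed)
    coords0, spans = _chain_coords(arch)
    place_a, place_b, _, _ = _dimer_transforms(arch)
    a = place_a(coords0)
    b = place_b(coords0)
    span_c = spans["c_flank"]
    length = span_c[1] - span_c[0] + 1
    site = np.array([RISE * (arch.alpha2_len - 1) / 2.0, -30.0, 0.0])
    axis = np.array([1.0, 0.0, 0.0])
    ref = np.array([0.0, 0.0, 1.0])
    start0 = site - axis * (RISE * (max(4, (length - 2) // 2) - 1) / 2.0)
    for coords, off in ((a, np.array([0.0, 0.0, -4.0])), (b, np.array([0.0, 0.0, 4.0]))):
        coords[span_c[0] - 1 : span_c[1]] = _dimer_tail_coords(
            length, start0 + off, axis, ref
        )
    a = _apply_jitter(a, rng, jitter_sigma)
    b = _apply_jitter(b, rng, jitter_sigma)
    model = StructureModel(
        {"A": _coords_to_chain(a, "A"), "B": _coords_to_chain(b, "B")}
    )
    return model, AssemblyTruth(
        AssemblySpec(arch, "handshake_dimer", seed, jitter_sigma),
        spans,
        "handshake_dimer",
        MonomerTruth(arch, spans).fold_family,
    )


# --------------------------------------------------------------------------
# confidence tracks


def synth_confidence(
    model: StructureModel,
    conf: ConfidenceSpec,
    flank_spans: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> PaeMatrix:
    """Write pLDDT into the model and build a block-structured PAE matrix.

    Core residues get ``core_plddt``; residues inside ``flank_spans``
    (chain id -> list of 1-based spans) get ``tail_plddt``.  Intra-chain
    PAE blocks are ``intra_pae``, inter-chain blocks ``inter_pae``.
    """
    flank_spans = flank_spans or {}
    for cid, chain in model.chains.items():
        spans = flank_spans.get(cid, [])
        for pos, residue in enumerate(chain.residues, start=1):
            in_flank = any(lo <= pos <= hi for lo, hi in spans)
            residue.plddt = conf.tail_plddt if in_flank else conf.core_plddt
    lengths = model.chain_lengths()
    n = sum(lengths)
    values = np.full((n, n), conf.inter_pae, dtype=float)
    chain_spans: Dict[str, Tuple[int, int]] = {}
    start = 0
    for cid, length in zip(model.chain_ids, lengths):
        values[start : start + length, start : start + length] = conf.intra_pae
        chain_spans[cid] = (start, start + length)
        start += length
    return PaeMatrix(values, chain_spans)


# --------------------------------------------------------------------------
# sequences


@dataclass
class SequenceTruth:
    sequence: str
    motif_anchor: Optional[int] = None
    c4_positions: Optional[Tuple[int, int, int, int]] = None
    c2h2_positions: Optional[Tuple[int, int, int, int]] = None
    tail_span: Optional[Tuple[int, int]] = None
    tm_span: Optional[Tuple[int, int]] = None
    ploop_anchor: Optional[int] = None
    basic_alpha1: Tuple[int, ...] = ()


# relative ZZ-site layout within a compact N-terminal domain (1-based,
# domain-local): C4 at 10/13/41/43, C2H2 at 26/31/49/55
_ZZ_LAYOUT_C4 = (10, 13, 41, 43)
_ZZ_LAYOUT_C2H2 = (26, 31, 49, 55)


def synth_sequence_set(
    arch: FoldArchitecture,
    features: Optional[Dict[str, object]] = None,
    seed: int = 0,
) -> SequenceTruth:
    """Deterministic sequence matching ``arch`` with requested features.

    features keys (all optional): ``motif`` (bool, RxTxxxxD anchored at
    L2), ``zz_sites`` (bool, requires a compact N flank >= 60),
    ``tail_sign`` (+1/-1, charges the flagged charged_tail flank), ``tm``
    (bool, poly-L stretch in the tm_segment flank), ``ploop`` (bool,
    Walker A in the N flank), ``alpha1_basics`` (tuple of α1-local
    positions to set to K; default (3, 7)).  Background residues come from
    a neutral alphabet and re-drawing guarantees the implanted hits are
    the only matches.
    """
    features = dict(features or {})
    spans = arch.segments()
    n = arch.total_len
    rng = np.random.default_rng(seed)

    want_motif = bool(features.get("motif", False))
    want_zz = bool(features.get("zz_sites", False))
    want_tm = bool(features.get("tm", False))
    want_ploop = bool(features.get("ploop", False))
    tail_sign = features.get("tail_sign", None)
    alpha1_basics = tuple(features.get("alpha1_basics", (3, 7)))

    if want_zz:
        nf = arch.n_flank
        if not (nf and nf.kind == "compact_domain" and nf.length >= 60):
            raise ValueError("zz_sites need a compact N flank of >= 60 residues")
    if want_tm and not (
        (arch.n_flank and arch.n_flank.kind == "tm_segment")
        or (arch.c_flank and arch.c_flank.kind == "tm_segment")
    ):
        raise ValueError("tm feature needs a tm_segment flank")
    if want_ploop and not (arch.n_flank and arch.n_flank.length >= 20):
        raise ValueError("ploop needs an N flank of >= 20 residues")

    from . import seq_features as sf

    for _ in range(200):
        seq = list(rng.choice(list(BACKGROUND_ALPHABET), size=n))
        truth = SequenceTruth(sequence="")

        if alpha1_basics and "alpha1" in spans:
            a1 = spans["alpha1"]
            placed = []
            for local in alpha1_basics:
                pos = a1[0] + local - 1
                if pos <= a1[1]:
                    seq[pos - 1] = "K"
                    placed.append(pos)
            truth = replace(truth, basic_alpha1=tuple(placed))

        if want_motif:
            a2 = spans["alpha2"]
            l2 = spans.get("l2", (a2[1] + 1, a2[1] + 1))
            t_pos = (l2[0] + l2[1]) // 2
            r_pos = t_pos - 2
            d_pos = r_pos + 7
            if d_pos > n:
                raise ValueError("motif does not fit this architecture")
            seq[r_pos - 1] = "R"
            seq[t_pos - 1] = "T"
            seq[d_pos - 1] = "D"
            truth = replace(truth, motif_anchor=r_pos)

        if want_zz:
            lo = spans["n_flank"][0]
            c4 = tuple(lo + p - 1 for p in _ZZ_LAYOUT_C4)
            c2h2 = tuple(lo + p - 1 for p in _ZZ_LAYOUT_C2H2)
            for p in c4 + c2h2[:2]:
                seq[p - 1] = "C"
            for p in c2h2[2:]:
                seq[p - 1] = "H"
            truth = replace(truth, c4_positions=c4, c2h2_positions=c2h2)

        if want_ploop:
            lo = spans["n_flank"][0] + 2
            motif = "GAAAAGKS"
            for k, aa in enumerate(motif):
                seq[lo - 1 + k] = aa
            truth = replace(truth, ploop_anchor=lo)

        if tail_sign is not None:
            flank_name = None
            for name in ("n_flank", "c_flank"):
                spec = getattr(arch, name)
                if spec is not None and spec.kind == "charged_tail":
                    flank_name = name
                    break
            if flank_name is None:
                raise ValueError("tail_sign needs a charged_tail flank")
            lo, hi = spans[flank_name]
            aa = "K" if int(tail_sign) > 0 else "E"
            for p in range(lo, hi + 1):
                seq[p - 1] = aa
            truth = replace(truth, tail_span=(lo, hi))

        if want_tm:
            name = (
                "n_flank"
                if arch.n_flank and arch.n_flank.kind == "tm_segment"
                else "c_flank"
            )
            lo, hi = spans[name]
            mid = (lo + hi) // 2
            start = max(lo, mid - 12)
            end = min(hi, start + 24)
            for p in range(start, end + 1):
                seq[p - 1] = "L"
            truth = replace(truth, tm_span=(start, end))

        s = "".join(seq)
        # rejection sampling: accept only if every scanner reports exactly
        # the implanted features
        motifs = sf.scan_l2_motif(s)
        if want_motif:
            if len(motifs) != 1 or motifs[0].anchor_position != truth.motif_anchor:
                continue
        elif motifs:
            continue
        zz = sf.detect_zinc_motifs(s)
        if want_zz:
            if len(zz) != 2 or zz[0].positions != truth.c4_positions:
                continue
        elif zz:
            continue
        if len(s) >= 19:
            tm = sf.detect_transmembrane(s)
            if want_tm:
                if len(tm) != 1:
                    continue
            elif tm:
                continue
        ploops = sf.find_p_loop(s)
        if want_ploop:
            if len(ploops) != 1 or ploops[0] != truth.ploop_anchor:
                continue
        elif ploops:
            continue
        return replace(truth, sequence=s)
    raise RuntimeError("rejection sampling failed to produce a clean sequence")


# --------------------------------------------------------------------------
# MSAs


def synth_msa(
    profile: Sequence[Tuple[int, Optional[str]]],
    n_sequences: int,
    seed: int = 0,
    conservation: float = 0.95,
) -> List[str]:
    """Synthetic ungapped alignment.

    ``profile`` lists (position, residue-or-None) per column; conserved
    columns emit their residue with probability ``conservation``, free
    columns draw uniformly from the 20 amino acids.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    from .seq_features import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    width = len(profile)
    rows = []
    for _ in range(n_sequences):
        row = []
        for _, conserved in profile:
            if conserved is not None and rng.random() < conservation:
                row.append(conserved)
            else:
                row.append(str(rng.choice(list(AMINO_ACIDS))))
        rows.append("".join(row))
    return rows


# --------------------------------------------------------------------------
# golden suite


@dataclass(frozen=True)
class GoldenFixture:
    """One golden-suite entry: build recipe plus expected pipeline output."""

    fixture_id: str
    architecture: FoldArchitecture
    assemblies: Tuple[str, ...]  # subset of {monomer, dimer, tetramer}
    tetramer_topology: Optional[str] = None  # AssemblySpec topology name
    sequence_features: Dict[str, object] = field(default_factory=dict)
    inter_pae: float = 5.0
    tetramer_inter_pae: Optional[float] = None  # overrides inter_pae for the tetramer
    expected_category: str = "undefined"
    ihf_dimer: bool = False


def golden_suite() -> List[GoldenFixture]:
    """The fixture suite covering every implemented category and topology."""
    nuc, a3 = NUCLEOSOMAL_PRESET, ALPHA3_PRESET
    cc25 = replace(nuc, c_flank=FlankSpec(25, "cc_extension"))
    cc32 = replace(nuc, c_flank=FlankSpec(32, "cc_extension"))
    mc20 = replace(nuc, c_flank=FlankSpec(20, "cc_extension"))
    ph20 = replace(a3, c_flank=FlankSpec(20, "cc_extension"))
    zz60 = replace(a3, n_flank=FlankSpec(60, "compact_domain"))
    rab130 = replace(a3, n_flank=FlankSpec(130, "compact_domain"))
    tm30 = replace(nuc, c_flank=FlankSpec(30, "tm_segment"))
    ihf16 = replace(nuc, c_flank=FlankSpec(16, "dimerizing_tail"))
    motif = {"motif": True}
    return [
        GoldenFixture("nuc_monomer", nuc, ("monomer",),
                      sequence_features=motif, expected_category="nucleosomal"),
        GoldenFixture("a3_monomer", a3, ("monomer",),
                      sequence_features=motif, expected_category="undefined"),
        GoldenFixture("nuc_dimer", nuc, ("monomer", "dimer"),
                      sequence_features=motif, expected_category="nucleosomal"),
        GoldenFixture("a3_dimer", a3, ("monomer", "dimer"),
                      sequence_features=motif, expected_category="bacterial_dimer"),
        GoldenFixture("a3_ftf", a3, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="ftf_tetramer",
                      sequence_features=motif, expected_category="ftf"),
        GoldenFixture("a3_ftf_lowpae", a3, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="ftf_tetramer", tetramer_inter_pae=25.0,
                      sequence_features=motif, expected_category="bacterial_dimer"),
        GoldenFixture("nuc_cc", cc25, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="cc_tetramer",
                      sequence_features=motif, expected_category="coiled_coil"),
        GoldenFixture("nuc_rdgc", cc32, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="cc_tetramer",
                      sequence_features=motif, expected_category="coiled_coil"),
        GoldenFixture("nuc_mc", mc20, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="ctail_tetramer",
                      sequence_features=motif, expected_category="mc_like"),
        GoldenFixture("a3_phage", ph20, ("monomer", "dimer", "tetramer"),
                      tetramer_topology="ctail_tetramer",
                      sequence_features=motif, expected_category="phage_like"),
        GoldenFixture("nuc_open_stack", nuc, ("monomer", "tetramer"),
                      tetramer_topology="open_stack_tetramer",
                      sequence_features=motif, expected_category="nucleosomal"),
        GoldenFixture("nuc_separated", nuc, ("monomer", "tetramer"),
                      tetramer_topology="separated_chains", tetramer_inter_pae=25.0,
                      sequence_features=motif, expected_category="nucleosomal"),
        GoldenFixture("a3_zz", zz60, ("monomer", "dimer"),
                      sequence_features={"motif": True, "zz_sites": True},
                      expected_category="zz"),
        GoldenFixture("a3_rab", rab130, ("monomer", "dimer"),
                      sequence_features={"motif": True, "ploop": True},
                      expected_category="rab_gtpase"),
        GoldenFixture("nuc_tm", tm30, ("monomer",),
                      sequence_features={"tm": True, "alpha1_basics": ()},
                      expected_category="transmembrane"),
        GoldenFixture("nuc_ihf", ihf16, ("monomer", "dimer"),
                      sequence_features=motif, expected_category="ihf_like",
                      ihf_dimer=True),
    ]


def _tail_flank_spans(arch: FoldArchitecture) -> List[Tuple[int, int]]:
    """Spans that get low (disordered-tail) pLDDT."""
    spans = arch.segments()
    out = []
    if arch.n_flank and arch.n_flank.kind == "charged_tail":
        out.append(spans["n_flank"])
    if arch.c_flank and arch.c_flank.kind == "charged_tail":
        out.append(spans["c_flank"])
    return out


def build_golden_fixture(fx: GoldenFixture, seed: int = 42):
    """Build all artefacts for one golden fixture.

    Returns a dict with keys among {sequence_truth, monomer, dimer,
    tetramer} where each structure entry is (model, PaeMatrix or None).
    """
    from .structure_io import PaeMatrix

    arch = fx.architecture
    seq_truth = synth_sequence_set(arch, fx.sequence_features, seed=seed)
    out = {"sequence_truth": seq_truth, "fixture": fx}
    tails = _tail_flank_spans(arch)

    def finish(model, inter_pae):
        conf = ConfidenceSpec(core_plddt=90.0, tail_plddt=35.0,
                              intra_pae=3.0, inter_pae=inter_pae)
        flanks = {cid: tails for cid in model.chain_ids}
        pae = synth_confidence(model, conf, flanks)
        for chain in model.chains.values():
            for res, aa in zip(chain.residues, seq_truth.sequence):
                res.name = ONE_TO_THREE[aa]
        return model, pae

    if "monomer" in fx.assemblies:
        model, _ = build_fold_monomer(arch, seed=seed)
        out["monomer"] = finish(model, fx.inter_pae)
    if "dimer" in fx.assemblies:
        if fx.ihf_dimer:
            model, _ = build_ihf_dimer(arch, seed=seed)
        else:
            model, _ = assemble_oligomer(AssemblySpec(arch, "handshake_dimer", seed))
        out["dimer"] = finish(model, fx.inter_pae)
    if "tetramer" in fx.assemblies:
        model, _ = assemble_oligomer(AssemblySpec(arch, fx.tetramer_topology, seed))
        inter = fx.tetramer_inter_pae if fx.tetramer_inter_pae is not None else fx.inter_pae
        out["tetramer"] = finish(model, inter)
    return out


def write_golden_suite(out_dir, seed: int = 42) -> "Path":
    """Write the full golden suite (PDB + PAE JSON + FASTA + manifest +
    ground truth) to a directory; returns the manifest path."""
    from pathlib import Path
    from .structure_io import write_pae, write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for fx in golden_suite():
        built = build_golden_fixture(fx, seed=seed)
        seq = built["sequence_truth"].sequence
        fasta = out_dir / f"{fx.fixture_id}.fasta"
        fasta.write_text(f">{fx.fixture_id} seed={seed}\n{seq}\n")
        row = {"protein_id": fx.fixture_id, "fasta": fasta.name}
        for kind in ("monomer", "dimer", "tetramer"):
            if kind not in built:
                continue
            model, pae = built[kind]
            pdb_path = out_dir / f"{fx.fixture_id}_{kind}.pdb"
            write_structure(model, pdb_path)
            row[kind] = pdb_path.name
            if kind != "monomer" and pae is not None:
                pae_path = out_dir / f"{fx.fixture_id}_{kind}_pae.json"
                write_pae(pae, pae_path)
                row[f"{kind}_pae"] = pae_path.name
        manifest_rows.append(row)
        truth_rows.append(
            {
                "protein_id": fx.fixture_id,
                "expected_category": fx.expected_category,
                "architecture": f"{arch_str(fx.architecture)}",
                "topology": fx.tetramer_topology or "",
            }
        )
    import csv

    manifest = out_dir / "manifest.tsv"
    cols = ["protein_id", "monomer", "dimer", "tetramer", "hexamer",
            "dimer_pae", "tetramer_pae", "hexamer_pae", "fasta"]
    with open(manifest, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t", lineterminator="\n")
        w.writeheader()
        for row in manifest_rows:
            w.writerow({c: row.get(c, "") for c in cols})
    truth = out_dir / "truth.tsv"
    with open(truth, "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=["protein_id", "expected_category", "architecture", "topology"],
            delimiter="\t",
            lineterminator="\n",
        )
        w.writeheader()
        for row in truth_rows:
            w.writerow(row)
    return manifest


def arch_str(arch: FoldArchitecture) -> str:
    return (
        f"{arch.alpha1_len}/{arch.alpha2_len}/{arch.alpha3_len}"
        f"+L{arch.l1_len}/{arch.l2_len}"
    )
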