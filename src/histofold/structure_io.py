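"""Structure and confidence-data I/O plus Cα superposition.

Structures are held in a light-weight residue-centric model
(:class:`StructureModel`).  Parsing and serialisation of PDB/mmCIF is
delegated to :mod:`biotite`; predicted-aligned-error matrices are read
from the AlphaFold JSON dialect.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import biotite.structure.io.pdbx as pdbx

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "PaeMatrix",
    "StructureFormatError",
    "read_structure",
    "write_structure",
    "read_pae",
    "write_pae",
    "superpose_ca",
]


class StructureFormatError(ValueError):
    """Raised when a structure or PAE file violates the expected format."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom, as read from a coordinate file."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    b_value: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Residue:
    """One residue: author index, 3-letter name, atom map and pLDDT."""

    index: int
    name: str
    atoms: Dict[str, np.ndarray]
    plddt: float

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) array of Cα coordinates in residue order."""
        if not self.residues:
            return np.empty((0, 3))
        return np.stack([r.ca for r in self.residues])

    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues])

    def positions(self) -> List[int]:
        """1-based sequential positions (1..N)."""
        return list(range(1, len(self.residues) + 1))


@dataclass
class StructureModel:
    """Ordered chains of residues with Cα coordinates and pLDDT."""

    chains: Dict[str, Chain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chain in self.chains.values():
            idx = [r.index for r in chain.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(
                    f"residue indices not strictly increasing in chain {chain.chain_id}"
                )
            for r in chain.residues:
                if "CA" not in r.atoms:
                    raise ValueError(
                        f"residue {r.index} in chain {chain.chain_id} lacks CA"
                    )
                if not (0.0 <= r.plddt <= 100.0):
                    raise ValueError(f"pLDDT {r.plddt} outside [0, 100]")

    @property
    def chain_ids(self) -> List[str]:
        return list(self.chains.keys())

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def chain_lengths(self) -> List[int]:
        return [len(c) for c in self.chains.values()]

    def all_ca(self) -> np.ndarray:
        arrays = [c.ca_coords() for c in self.chains.values() if len(c)]
        return np.vstack(arrays) if arrays else np.empty((0, 3))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigidly transformed deep copy: x -> R x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_chains: Dict[str, Chain] = {}
        for cid, chain in self.chains.items():
            new_res = [
                Residue(
                    index=r.index,
                    name=r.name,
                    atoms={a: R @ xyz + t for a, xyz in r.atoms.items()},
                    plddt=r.plddt,
                )
                for r in chain.residues
            ]
            new_chains[cid] = Chain(cid, new_res)
        return StructureModel(new_chains)

    def subset(self, chain_ids: Sequence[str]) -> "StructureModel":
        return StructureModel({cid: self.chains[cid] for cid in chain_ids})


@dataclass
class PaeMatrix:
    """Square predicted-aligned-error matrix (Å) over all residues.

    ``chain_spans`` maps chain id to a half-open 0-based (start, end)
    row/column span in prediction order.  The matrix is kept asymmetric;
    consumers decide how to aggregate.
    """

    values: np.ndarray
    chain_spans: Dict[str, Tuple[int, int]]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise StructureFormatError(f"PAE matrix not square: shape {v.shape}")
        if np.any(v < 0):
            raise StructureFormatError("PAE values must be >= 0")
        self.values = v
        n = v.shape[0]
        covered = np.zeros(n, dtype=bool)
        for cid, (a, b) in self.chain_spans.items():
            if not (0 <= a < b <= n):
                raise StructureFormatError(f"span {a, b} for chain {cid} outside [0, {n})")
            if covered[a:b].any():
                raise StructureFormatError(f"span for chain {cid} overlaps another chain")
            covered[a:b] = True
        if not covered.all():
            raise StructureFormatError("chain spans do not tile the matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def block(self, chain_a: str, chain_b: str) -> np.ndarray:
        a0, a1 = self.chain_spans[chain_a]
        b0, b1 = self.chain_spans[chain_b]
        return self.values[a0:a1, b0:b1]


# --------------------------------------------------------------------------
# reading / writing


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def _atom_array_to_model(atoms: struc.AtomArray, path: Path) -> StructureModel:
    if atoms.array_length() == 0:
        raise StructureFormatError(f"{path}: empty model")
    ins = atoms.get_annotation("ins_code")
    if any(code.strip() for code in ins):
        raise StructureFormatError(f"{path}: insertion codes are not supported")

    chains: Dict[str, Chain] = {}
    n_dropped = 0
    for cid in np.unique(atoms.chain_id).tolist():
        chain_mask = atoms.chain_id == cid
        chain_atoms = atoms[chain_mask]
        residues: List[Residue] = []
        for res_id in np.unique(chain_atoms.res_id).tolist():
            res_atoms = chain_atoms[chain_atoms.res_id == res_id]
            atom_map = {
                name: coord
                for name, coord in zip(res_atoms.atom_name, np.asarray(res_atoms.coord, dtype=float))
            }
            if "CA" not in atom_map:
                n_dropped += 1
                logger.warning(
                    "%s: residue %s%d lacks a CA atom; dropped", path, cid, int(res_id)
                )
                continue
            ca_idx = int(np.flatnonzero(res_atoms.atom_name == "CA")[0])
            residues.append(
                Residue(
                    index=int(res_id),
                    name=str(res_atoms.res_name[0]),
                    atoms=atom_map,
                    plddt=float(res_atoms.b_factor[ca_idx]),
                )
            )
        if residues:
            chains[str(cid)] = Chain(str(cid), residues)
    if not chains:
        raise StructureFormatError(f"{path}: no residues with CA atoms")
    model = StructureModel(chains)
    plddts = np.concatenate([c.plddt() for c in model.chains.values()])
    if np.all(plddts <= 1.0):
        warnings.warn(
            f"{path}: all pLDDT values <= 1.0; input may use the 0-1 scale "
            "(values are NOT rescaled)",
            stacklevel=2,
        )
    return model


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read the first model of a PDB/mmCIF file.

    The B-factor column is mapped to per-residue pLDDT unchanged; residues
    lacking a Cα atom are dropped with a logged warning.  Only the first
    altloc is kept; insertion codes are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    try:
        if fmt == "pdb":
            f = pdb.PDBFile.read(str(path))
            atoms = f.get_structure(
                model=1, altloc="first", extra_fields=["b_factor"]
            )
        elif fmt == "mmcif":
            f = pdbx.CIFFile.read(str(path))
            atoms = pdbx.get_structure(
                f, model=1, altloc="first", extra_fields=["b_factor"]
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except StructureFormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    return _atom_array_to_model(atoms, path)


def _model_to_atom_array(model: StructureModel) -> struc.AtomArray:
    n_atoms = sum(len(r.atoms) for c in model.chains.values() for r in c.residues)
    atoms = struc.AtomArray(n_atoms)
    atoms.add_annotation("b_factor", dtype=float)
    i = 0
    for cid, chain in model.chains.items():
        for r in chain.residues:
            for atom_name, xyz in r.atoms.items():
                atoms.chain_id[i] = cid
                atoms.res_id[i] = r.index
                atoms.res_name[i] = r.name
                atoms.atom_name[i] = atom_name
                atoms.element[i] = atom_name[0] if atom_name else "C"
                atoms.coord[i] = xyz
                atoms.b_factor[i] = round(r.plddt, 2)
                i += 1
    atoms.hetero[:] = False
    return atoms


def write_structure(model: StructureModel, path, format: str = "pdb") -> None:
    """Write ``model`` so that :func:`read_structure` round-trips it.

    pLDDT goes into the B-factor column, rounded to 2 decimals.
    """
    if model.n_residues() == 0:
        raise ValueError("cannot write an empty model")
    path = Path(path)
    atoms = _model_to_atom_array(model)
    if format == "pdb":
        f = pdb.PDBFile()
        f.set_structure(atoms)
        f.write(str(path))
    elif format == "mmcif":
        f = pdbx.CIFFile()
        pdbx.set_structure(f, atoms)
        f.write(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_pae(path, chain_lengths: Sequence[int]) -> PaeMatrix:
    """Read an AlphaFold-style PAE JSON file.

    Accepts the top-level ``"predicted_aligned_error"`` key (fallback
    ``"pae"``), also when wrapped in a single-element list.  Chain spans
    are computed from ``chain_lengths`` in the given order, chains named
    A, B, C, ... unless span keys are provided explicitly.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if len(data) != 1:
            raise StructureFormatError(f"{path}: expected a single PAE object")
        data = data[0]
    raw = data.get("predicted_aligned_error", data.get("pae"))
    if raw is None:
        raise StructureFormatError(
            f"{path}: no 'predicted_aligned_error' or 'pae' key"
        )
    values = np.asarray(raw, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise StructureFormatError(f"{path}: PAE array is not square: {values.shape}")
    n = values.shape[0]
    if sum(chain_lengths) != n:
        raise StructureFormatError(
            f"{path}: chain lengths sum to {sum(chain_lengths)} but matrix is {n}x{n}"
        )
    spans: Dict[str, Tuple[int, int]] = {}
    start = 0
    for i, length in enumerate(chain_lengths):
        cid = chr(ord("A") + i)
        spans[cid] = (start, start + length)
        start += length
    return PaeMatrix(values, spans)


def write_pae(pae: PaeMatrix, path) -> None:
    """Serialise a PAE matrix in the AlphaFold JSON dialect."""
    with open(path, "w") as fh:
        json.dump(
            {"predicted_aligned_error": pae.values.tolist(), "max_predicted_aligned_error": float(pae.values.max(initial=0.0))},
            fh,
        )


# --------------------------------------------------------------------------
# superposition


def _paired_ca(
    mobile: StructureModel,
    reference: StructureModel,
    pairing,
) -> Tuple[np.ndarray, np.ndarray]:
    """Collect paired Cα coordinate arrays according to the pairing rule."""
    if pairing == "by_index":
        chain_map = {
            cid: cid for cid in mobile.chain_ids if cid in reference.chains
        }
    elif isinstance(pairing, Mapping):
        chain_map = dict(pairing)
    else:
        raise ValueError("pairing must be 'by_index' or a chain map")
    xs, ys = [], []
    for mob_cid, ref_cid in chain_map.items():
        mob_chain = mobile.chains[mob_cid]
        ref_chain = reference.chains[ref_cid]
        ref_by_index = {r.index: r for r in ref_chain.residues}
        for r in mob_chain.residues:
            other = ref_by_index.get(r.index)
            if other is not None:
                xs.append(r.ca)
                ys.append(other.ca)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 paired CA atoms, got {len(xs)}")
    return np.array(xs), np.array(ys)


def kabsch(mobile_xyz: np.ndarray, reference_xyz: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rmsd, rotation, translation)`` with
    ``rotation @ x + translation`` mapping mobile onto reference.
    """
    x = np.asarray(mobile_xyz, dtype=float)
    y = np.asarray(reference_xyz, dtype=float)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    h = x0.T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = yc - rot @ xc
    diff = (x0 @ rot.T) - y0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(x)))
    return rmsd, rot, t


def superpose_ca(
    mobile: StructureModel,
    reference: StructureModel,
    pairing="by_index",
) -> Tuple[float, Tuple[np.ndarray, np.ndarray]]:
    """Optimal rigid Cα superposition of ``mobile`` onto ``reference``.

    ``pairing`` is either ``"by_index"`` (match chains by id and residues
    by author index) or a mapping ``mobile_chain_id -> reference_chain_id``.
    Returns ``(rmsd, (rotation, translation))``.
    """
    xs, ys = _paired_ca(mobile, reference, pairing)
    rmsd, rot, t = kabsch(xs, ys)
    return rmsd, (rot, t)
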