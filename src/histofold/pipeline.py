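"""Batch classification pipeline: manifest of prediction records in,
per-protein category calls with an evidence trail out."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import fold_detect, quaternary_classify as qc, seq_features as sf
from .fold_detect import HistoneFoldAnnotation
from .structure_io import PaeMatrix, StructureModel, read_pae, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PredictionRecord",
    "ReportRow",
    "classify_record",
    "run_batch",
    "read_manifest",
    "write_report",
]

THREE_TO_ONE = {v: k for k, v in {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}.items()}


@dataclass
class PipelineConfig:
    """Every numeric threshold of the classification workflow."""

    contact_cutoff: float = 8.0
    pae_high_threshold: float = 10.0
    alpha3_max: int = 5
    nucleosomal_min: int = 8
    handshake_min_contacts: int = 10
    element_dominance: float = 0.60
    bundle_cutoff: float = 12.0
    tail_charge_fraction: float = 0.2
    tail_disorder_plddt: float = 50.0
    tm_window: int = 19
    tm_threshold: float = 1.6
    rdgc_min_cterm_helix: int = 30

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PredictionRecord:
    protein_id: str
    monomer: Optional[Path] = None
    dimer: Optional[Path] = None
    tetramer: Optional[Path] = None
    hexamer: Optional[Path] = None
    dimer_pae: Optional[Path] = None
    tetramer_pae: Optional[Path] = None
    hexamer_pae: Optional[Path] = None
    fasta: Optional[Path] = None


@dataclass
class ReportRow:
    protein_id: str
    category: str = "undefined"
    confidence: str = "low"
    fold_family: str = ""
    helix_lengths: str = ""
    dimer_topology: str = ""
    tetramer_topology: str = ""
    dimer_pae_mean: str = ""
    tetramer_pae_mean: str = ""
    interface_quality: str = ""
    flags: str = ""
    evidence: str = ""
    warnings: str = ""

    FIELDS = (
        "protein_id", "category", "confidence", "fold_family", "helix_lengths",
        "dimer_topology", "tetramer_topology", "dimer_pae_mean",
        "tetramer_pae_mean", "interface_quality", "flags", "evidence", "warnings",
    )

    def as_tsv_row(self) -> List[str]:
        return [getattr(self, f) for f in self.FIELDS]


def _chain_sequence(model: StructureModel, chain_id: str) -> str:
    return "".join(
        THREE_TO_ONE.get(r.name, "A") for r in model.chains[chain_id].residues
    )


def _longest_postfold_helix(model: StructureModel, chain_id: str, ann) -> int:
    states = fold_detect.assign_secondary_structure(model, chain_id)
    post = states[ann.fold_span[1] :]
    best = cur = 0
    for s in post:
        cur = cur + 1 if s == "H" else 0
        best = max(best, cur)
    return best


def _multimer_anns(model: StructureModel) -> Dict[str, Optional[HistoneFoldAnnotation]]:
    return {cid: fold_detect.detect_histone_fold(model, cid) for cid in model.chain_ids}


def _tetramer_confidence(
    pae: Optional[PaeMatrix], call, model: StructureModel, config: PipelineConfig
) -> Tuple[str, str]:
    """(confidence, mean-PAE string) for the decisive tetramer interfaces."""
    if pae is None:
        return "unknown", ""
    pairs = [i[0] for i in call.interfaces] if call.interfaces else []
    if not pairs:  # fall back to all inter-chain blocks
        ids = model.chain_ids
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    means = [
        qc.interface_confidence(pae, a, b, config.pae_high_threshold)[0]
        for a, b in pairs
    ]
    mean = float(np.mean(means))
    quality = "high" if all(m < config.pae_high_threshold for m in means) else "low"
    return quality, f"{mean:.2f}"


def _best_tetramer_subset(model: StructureModel, cutoff: float) -> StructureModel:
    """Reduce a hexamer to its most-contacting 4-chain sub-assembly."""
    import itertools as it

    best, best_n = None, -1
    for subset in it.combinations(model.chain_ids, 4):
        sub = model.subset(subset)
        n = len(qc.find_interchain_contacts(sub, cutoff).pairs)
        if n > best_n:
            best, best_n = sub, n
    return best


def classify_record(rec: PredictionRecord, config: Optional[PipelineConfig] = None) -> ReportRow:
    """Classify one protein from its monomer/multimer predictions.

    Per-record failures (missing or unparsable member files) degrade to
    warnings; the row is still produced.
    """
    config = config or PipelineConfig()
    row = ReportRow(protein_id=rec.protein_id)
    warnings: List[str] = []
    evidence: List[str] = []
    inputs = qc.CategoryInputs()

    # ---- monomer -------------------------------------------------------
    monomer = None
    ann = None
    if rec.monomer is None:
        warnings.append("no monomer structure given")
    else:
        try:
            monomer = read_structure(rec.monomer)
        except Exception as exc:
            warnings.append(f"monomer unreadable: {exc}")
    if monomer is not None:
        cid = monomer.chain_ids[0]
        ann = fold_detect.detect_histone_fold(monomer, cid)
        if ann is None:
            warnings.append("no histone fold detected in monomer")
        else:
            inputs.fold_family = ann.fold_family
            row.fold_family = ann.fold_family
            row.helix_lengths = (
                f"{ann.alpha1.length}/{ann.alpha2.length}/{ann.alpha3.length}"
            )
            evidence.append(
                f"fold {row.helix_lengths} L1={ann.l1_length} L2={ann.l2_length}"
            )
            inputs.extra_domains = qc.detect_extra_domains(monomer, ann)
            for side, length, compact in inputs.extra_domains:
                evidence.append(
                    f"{side}-flank {length} aa {'compact' if compact else 'extended'}"
                )
            inputs.cterm_helix_len = _longest_postfold_helix(monomer, cid, ann)

    # ---- sequence ------------------------------------------------------
    sequence = None
    if rec.fasta is not None:
        try:
            records = sf.read_fasta(rec.fasta)
            sequence = next(iter(records.values()))
        except Exception as exc:
            warnings.append(f"fasta unreadable: {exc}")
    if sequence is None and monomer is not None:
        sequence = _chain_sequence(monomer, monomer.chain_ids[0])
    if sequence is not None:
        try:
            if len(sequence) >= config.tm_window:
                inputs.tm_segments = sf.detect_transmembrane(
                    sequence, config.tm_window, config.tm_threshold
                )
            zz = sf.detect_zinc_motifs(sequence)
            inputs.has_zz_sites = len(zz) == 2
            inputs.has_p_loop = bool(sf.find_p_loop(sequence))
            if ann is not None:
                inputs.basic_alpha1_positions = sf.find_basic_alpha1_residues(
                    sequence, ann, monomer
                )
                motifs = sf.scan_l2_motif(sequence, ann)
                for m in motifs:
                    evidence.append(
                        f"motif {m.pattern_name} at R{m.anchor_position}"
                        + (" (L2-anchored)" if m.structurally_anchored else "")
                    )
                plddt = monomer.chains[ann.chain_id].plddt() if monomer else None
                exclude = tuple(
                    side for side, _, compact in inputs.extra_domains if compact
                )
                for tail in sf.detect_tails(sequence, ann, plddt, exclude):
                    evidence.append(
                        f"{tail.terminus}-tail {tail.length} aa {tail.charge_class}"
                        f" charge {tail.net_charge:+.0f}"
                    )
        except ValueError as exc:
            warnings.append(f"sequence features skipped: {exc}")

    # ---- dimer ---------------------------------------------------------
    if rec.dimer is not None:
        try:
            dimer = read_structure(rec.dimer)
            anns = _multimer_anns(dimer)
            if any(a is None for a in anns.values()):
                warnings.append("dimer chain without histone fold; dimer skipped")
            else:
                contacts = qc.find_interchain_contacts(dimer, config.contact_cutoff)
                is_hs, angle = qc.detect_handshake_dimer(
                    dimer, anns, contacts, config.contact_cutoff
                )
                inputs.dimer_is_handshake = is_hs
                row.dimer_topology = "handshake_dimer" if is_hs else "none"
                if angle is not None:
                    evidence.append(f"dimer α2 crossing {angle:.0f}°")
                inputs.dimer_has_dimerizing_ctail = qc.detect_dimerizing_ctail(
                    dimer, anns, contacts, config.contact_cutoff
                )
                if rec.dimer_pae is not None:
                    pae = read_pae(rec.dimer_pae, dimer.chain_lengths())
                    a, b = dimer.chain_ids
                    mean, quality = qc.interface_confidence(
                        pae, a, b, config.pae_high_threshold
                    )
                    inputs.dimer_confidence = quality
                    row.dimer_pae_mean = f"{mean:.2f}"
                    evidence.append(f"dimer interface PAE {mean:.1f} ({quality})")
                else:
                    warnings.append("dimer PAE missing; dimer confidence unknown")
        except Exception as exc:
            warnings.append(f"dimer skipped: {exc}")

    # ---- tetramer (hexamers reduced to their best tetramer) ------------
    tet_path, tet_pae_path = rec.tetramer, rec.tetramer_pae
    if tet_path is None and rec.hexamer is not None:
        tet_path, tet_pae_path = rec.hexamer, None
        warnings.append("hexamer reduced to best tetramer sub-assembly")
    if tet_path is not None:
        try:
            tetramer = read_structure(tet_path)
            if tetramer.n_chains > 4:
                tetramer = _best_tetramer_subset(tetramer, config.contact_cutoff)
            anns = _multimer_anns(tetramer)
            if any(a is None for a in anns.values()):
                warnings.append("tetramer chain without histone fold; tetramer skipped")
            else:
                contacts = qc.find_interchain_contacts(tetramer, config.contact_cutoff)
                call = qc.classify_tetramer_topology(
                    tetramer, anns, contacts, config.contact_cutoff
                )
                inputs.tetramer_topology = call.topology
                row.tetramer_topology = call.topology
                if call.reason:
                    evidence.append(f"tetramer: {call.reason}")
                if tet_pae_path is not None:
                    pae = read_pae(tet_pae_path, tetramer.chain_lengths())
                    quality, mean_str = _tetramer_confidence(pae, call, tetramer, config)
                    inputs.tetramer_confidence = quality
                    row.tetramer_pae_mean = mean_str
                    evidence.append(f"tetramer interface PAE {mean_str} ({quality})")
                else:
                    warnings.append("tetramer PAE missing; tetramer rules skipped")
        except Exception as exc:
            warnings.append(f"tetramer skipped: {exc}")

    # ---- category ------------------------------------------------------
    call = qc.assign_category(inputs)
    row.category = call.category
    row.confidence = call.confidence
    row.flags = ",".join(call.flags)
    evidence.extend(f"{rule}: {value}" for rule, value in call.evidence)
    row.evidence = "; ".join(evidence)
    row.warnings = "; ".join(warnings)
    row.interface_quality = inputs.tetramer_confidence if row.tetramer_topology else inputs.dimer_confidence
    for w in warnings:
        logger.info("%s: warning: %s", rec.protein_id, w)
    logger.info("%s: category=%s (%s)", rec.protein_id, row.category, row.confidence)
    return row


MANIFEST_COLUMNS = (
    "protein_id", "monomer", "dimer", "tetramer", "hexamer",
    "dimer_pae", "tetramer_pae", "hexamer_pae", "fasta",
)


def read_manifest(path) -> List[PredictionRecord]:
    """TSV manifest -> records; file paths are resolved relative to the
    manifest's directory."""
    path = Path(path)
    base = path.parent
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "protein_id" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest needs a 'protein_id' column")
        for line in reader:
            kwargs = {"protein_id": line["protein_id"]}
            for col in MANIFEST_COLUMNS[1:]:
                value = (line.get(col) or "").strip()
                kwargs[col] = base / value if value else None
            records.append(PredictionRecord(**kwargs))
    return records


def write_report(rows: List[ReportRow], out_path, config: PipelineConfig) -> None:
    with open(out_path, "w", newline="") as fh:
        fh.write(f"# histofold report; config {config.digest()}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ReportRow.FIELDS)
        for row in rows:
            writer.writerow(row.as_tsv_row())


def run_batch(
    manifest_path, out_path, config: Optional[PipelineConfig] = None
) -> Tuple[List[ReportRow], Dict[str, int]]:
    """Classify every record of a manifest; deterministic row order.

    Per-record failures never abort the batch.  Returns the rows and the
    per-category counts.
    """
    config = config or PipelineConfig()
    records = read_manifest(manifest_path)
    rows = [classify_record(rec, config) for rec in records]
    counts: Dict[str, int] = {}
    for row in rows:
        counts[row.category] = counts.get(row.category, 0) + 1
    write_report(rows, out_path, config)
    summary = ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
    logger.info("classified %d records: %s", len(rows), summary)
    return rows, counts
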