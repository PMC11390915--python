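# histofold

Classification of prokaryotic histone-fold proteins from predicted
monomer/multimer structures (PDB/mmCIF + AlphaFold-style PAE JSON) and
sequences (FASTA), plus a synthetic fixture generator so the whole
pipeline is testable without any structure predictions or downloads.

The pipeline:

1. **fold_detect** — Cα-geometry secondary structure (P-SEA-style
   distance/torsion windows), histone-fold location (α1–L1–α2–L2–α3) and
   the fold-family call (*nucleosomal* vs *α3-truncated*, from the α3
   helix length: ≤5 → alpha3, ≥8 → nucleosomal).
2. **quaternary_classify** — inter-chain Cα contacts, handshake-dimer
   detection (α2 crossing angle), tetramer topology (face-to-face torus,
   coiled-coil bundle, C-terminal tetramer, open stack), PAE interface
   gating (mean inter-chain PAE < 10 Å = high quality), fused-domain
   flagging, wrapped-diameter estimate, and the final category decision
   tree (nucleosomal, ftf, bacterial_dimer, zz, rab_gtpase, phage_like,
   coiled_coil [+rdgc_like flag], mc_like, ihf_like, transmembrane,
   undefined).
3. **seq_features** — RxTxxxxD / RKTxxxxD motif scan, ZZ-type zinc sites
   (interleaved C4 + C2H2), charged/disordered tails, Kyte–Doolittle
   transmembrane segments, α1-face basic residues, P-loop, and
   pseudocounted information-content conservation profiles from MSAs.
4. **fixture_forge** — deterministic idealized monomers, dimers and
   tetramers in every topology, with matching sequences, pLDDT tracks and
   block PAE matrices (the "golden suite").
5. **pipeline/cli** — batch orchestration over a TSV manifest.

## CLI

```bash
# generate the synthetic golden suite (structures + PAE + FASTA + manifest)
histofold fixtures --suite golden --seed 42 --out suite/

# classify a manifest of prediction records
histofold classify --manifest suite/manifest.tsv --out report.tsv
# optional YAML config exposing every numeric threshold
histofold classify --manifest suite/manifest.tsv --out report.tsv --config cfg.yaml

# annotate a single structure
histofold inspect --structure suite/nuc_monomer_monomer.pdb
```

The manifest is a TSV with columns `protein_id`, `monomer`, `dimer`,
`tetramer`, `hexamer`, `dimer_pae`, `tetramer_pae`, `hexamer_pae`,
`fasta` (paths relative to the manifest; empty cells = absent). The
report is a TSV with one row per protein: fold family, helix lengths,
multimer topologies, interface PAE/quality, category, evidence and
warnings. Per-record errors degrade to warnings and never abort a batch.

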