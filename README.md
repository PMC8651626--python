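# aeropollen

A tested, reusable pipeline for molecular airborne-pollen monitoring:

- **Amplicon processing** — FLASH-style pair merging (min overlap 10,
  max mismatch ratio 0.25), IUPAC-aware primer trimming (0.2 mismatch
  budget), dereplication, and unoise-style abundance-skew denoising into
  zero-radius OTUs (α = 2, min abundance 10).
- **Taxonomy** — semi-global alignment against a local-priority pair of
  reference databases, max-score tie LCA, identity tiers (≥97% species,
  ≥90% genus, ≥80% family), marker-specific query-coverage gates
  (100% for the short plastid-like marker, 90% for the nuclear one), and
  aggregation of OTUs by assignment.
- **Contamination filtering** — the six-step cascade: (a) blank-dominant
  OTU removal, (b) <10 reads/PCR-repeat zeroing, (c) a data-driven
  leakage threshold solved so that every blank/negative count is zeroed,
  (d) <3000-read replicate removal, (e) off-target clade and contaminant
  taxa removal, (f) ≥2-of-3 replicate consensus — with a per-step report
  and a positive-control check.
- **Quantification** — replicate-averaged relative read abundances
  (RRA), morphotype-level aggregation, and least-squares regression of
  RRA against microscopic relative pollen abundances (per target and
  combined over all points >5% microscope relative abundance).
- **Community analysis** — Bray-Curtis dissimilarities, one-factor
  perMANOVA with permutation p-values (999 by default), and Kruskal
  stress-1 NMDS with isotonic regression, all first-principles
  implementations.
- **Synthetic data generator** — hierarchically diverged reference
  databases (species ≥97% identity within genus, 90–96% between genera,
  80–89% between families), amplification bias, Dirichlet-multinomial
  replicate overdispersion, read errors, tag-jump-like leakage into
  blanks, food/off-target contaminants, positive controls, and
  morphotype-resolution microscope counts — so the entire pipeline runs
  and is tested without any external data.

## CLI

```bash
# full synthetic study, end-to-end, into runs/demo
aeropollen all --seed 1 --outdir runs/demo

# stages are also runnable standalone from the previous stage's files
aeropollen simulate -o runs/demo
aeropollen process  -o runs/demo
aeropollen assign   -o runs/demo
aeropollen filter   -o runs/demo
aeropollen quantify -o runs/demo
aeropollen compare  -o runs/demo

# input well-formedness checks
aeropollen validate -o runs/demo
```

All parameters live in a single YAML config (see
`aeropollen.config.DEFAULT_CONFIG` for the schema and defaults; unknown
keys are rejected). CLI flags override the config. Exit codes: 0 ok,
2 validation error, 3 stage failure. A `manifest.json` with per-file
checksums is written per run; reruns with the same seed are
bit-identical.

Outputs per run directory: reference FASTA + lineage TSVs, per-occurrence
read FASTAs, OTU FASTA + OTU/taxon count tables, assignment TSV, filter
report TSV, positive-control JSON, RRA and morphotype-RRA tables,
regression TSV, Bray-Curtis matrix, NMDS coordinates and perMANOVA
summary TSVs.

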