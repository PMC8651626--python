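"""Synthetic aerobiological dataset generator.

Produces, for a configurable study design, everything the downstream
pipeline consumes: per-PCR-replicate amplicon reads (with amplification
bias, replicate overdispersion, point errors and tag-jump-like leakage
into blanks), extraction blank / PCR negative / positive-control
occurrences, morphotype-resolution microscope counts, and the ground
truth needed for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from aeropollen.amplicon import MARKERS, revcomp
from aeropollen.refdb import ReferenceDb

__all__ = [
    "StudyDesign",
    "TruthBundle",
    "SimulatedDataset",
    "simulate_dataset",
    "mutate_reads",
    "morphotype_of",
]

ROLES = ("sample", "extraction_blank", "pcr_negative", "positive_control")


@dataclass
class StudyDesign:
    """Parameters of one simulated monitoring study (single marker)."""

    species_pool: tuple[str, ...]
    marker: str = "nrITS2-like"
    sites: tuple[str, ...] = ("West", "SouthEast")
    seasons: tuple[str, ...] = ("spring", "fall")
    n_samples_per_cell: int = 3
    n_replicates: int = 3
    bias_sd: float = 0.3
    depth_mean: int = 5000
    error_rate: float = 0.002
    leakage_rate: float = 0.001
    contaminant_taxa: tuple[str, ...] = ()
    offtarget_taxa: tuple[str, ...] = ()
    contaminant_mean_reads: float = 0.0
    positive_control_taxon: str | None = None
    n_extraction_blanks: int = 2
    n_pcr_negatives: int = 2
    n_positive_controls: int = 2
    microscope_grains: int = 1000
    pollen_m3_scale: float = 5.0
    dirichlet_base_alpha: float = 0.4
    sample_concentration: float = 60.0
    # replicate-level Dirichlet-multinomial concentration; None disables
    # overdispersion (plain multinomial draws)
    replicate_concentration: float | None = 400.0
    family_level_morphotypes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("error_rate", "leakage_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be >= 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not self.species_pool:
            raise ValueError("species pool must be non-empty")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")


@dataclass
class TruthBundle:
    """Ground truth retained for recovery tests."""

    true_proportions: pd.DataFrame      # samples x species, rows sum to 1
    bias_factors: pd.Series             # per-species amplification factor
    leakage_rate: float
    contaminant_ids: tuple[str, ...]
    morphotype_map: dict[str, str]      # species -> morphotype

    def validate(self) -> None:
        p = self.true_proportions.to_numpy()
        if (p < 0).any():
            raise ValueError("true proportions must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true proportion rows must sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_proportions": {
                s: self.true_proportions.loc[s].to_dict()
                for s in self.true_proportions.index
            },
            "bias_factors": self.bias_factors.to_dict(),
            "leakage_rate": self.leakage_rate,
            "contaminant_ids": list(self.contaminant_ids),
            "morphotype_map": self.morphotype_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulatedDataset:
    """Everything one simulation run hands to the pipeline."""

    counts: pd.DataFrame                # species/taxa x occurrences (templates)
    reads: dict[str, list[tuple[str, str]]] | None
    sample_sheet: pd.DataFrame
    microscope: pd.DataFrame            # samples x morphotypes, pollen/m3/24h
    truth: TruthBundle
    marker: str


def morphotype_of(
    lineage_map: Mapping[str, tuple[str, str]],
    species: str,
    family_level: Sequence[str],
) -> str:
    """Morphotype label for a species: its genus, or the family for
    families declared morphologically unresolvable."""
    family, genus = lineage_map[species]
    return family if family in family_level else genus


def mutate_reads(
    template_counts: Mapping[str, int] | Sequence[tuple[str, int]],
    error_rate: float,
    seed: int | np.random.Generator,
) -> list[tuple[str, str]]:
    """Emit ``count`` copies of each template with independent per-base
    substitution errors.  Read ids record the template of origin."""
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    items = (
        template_counts.items()
        if isinstance(template_counts, Mapping)
        else template_counts
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out: list[tuple[str, str]] = []
    for t_idx, (template, count) in enumerate(items):
        if count < 0:
            raise ValueError("template counts must be non-negative")
        if count == 0:
            continue
        length = len(template)
        arr = np.frombuffer(template.encode(), dtype=np.uint8)
        n_err = (
            rng.binomial(length, error_rate, size=count)
            if error_rate > 0
            else np.zeros(count, dtype=int)
        )
        for i in range(count):
            rid = f"t{t_idx}_r{i}"
            k = int(n_err[i])
            if k == 0:
                out.append((rid, template))
                continue
            mutated = arr.copy()
            pos = rng.choice(length, size=k, replace=False)
            idx = np.searchsorted(bases, mutated[pos])
            shift = rng.integers(1, 4, size=k)
            mutated[pos] = bases[(idx + shift) % 4]
            out.append((rid, mutated.tobytes().decode()))
    return out


def _occurrence_frame(design: StudyDesign) -> pd.DataFrame:
    """Build the sample sheet skeleton (one row per occurrence)."""
    rows = []
    sample_no = 0
    date_by_season = {s: i for i, s in enumerate(design.seasons)}
    for site in design.sites:
        for season in design.seasons:
            for i in range(design.n_samples_per_cell):
                sample_no += 1
                sample_id = f"S{sample_no:03d}"
                month = 3 + 5 * date_by_season.get(season, 0)
                date = f"2019-{month:02d}-{(i % 27) + 1:02d}"
                for rep in range(1, design.n_replicates + 1):
                    rows.append(
                        {
                            "occurrence_id": f"{sample_id}_r{rep}",
                            "sample_id": sample_id,
                            "replicate": rep,
                            "role": "sample",
                            "site": site,
                            "season": season,
                            "date": date,
                        }
                    )
    for j in range(1, design.n_extraction_blanks + 1):
        rows.append(
            {
                "occurrence_id": f"EB{j:02d}",
                "sample_id": f"EB{j:02d}",
                "replicate": 1,
                "role": "extraction_blank",
                "site": "",
                "season": "",
                "date": "",
            }
        )
    for j in range(1, design.n_pcr_negatives + 1):
        rows.append(
            {
                "occurrence_id": f"NEG{j:02d}",
                "sample_id": f"NEG{j:02d}",
                "replicate": 1,
                "role": "pcr_negative",
                "site": "",
                "season": "",
                "date": "",
            }
        )
    for j in range(1, design.n_positive_controls + 1):
        rows.append(
            {
                "occurrence_id": f"POS{j:02d}",
                "sample_id": f"POS{j:02d}",
                "replicate": 1,
                "role": "positive_control",
                "site": "",
                "season": "",
                "date": "",
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    design: StudyDesign,
    local_db: ReferenceDb,
    generate_reads: bool = True,
) -> SimulatedDataset:
    """Simulate one marker run of the full study design.

    Template read counts per replicate are Dirichlet-multinomial draws
    from amplification-biased true proportions; a ``leakage_rate``
    fraction of every non-blank occurrence's reads is reassigned to
    blank occurrences; positive controls contain only the designated
    control taxon; microscope counts are multinomial subsamples of the
    true morphotype proportions rescaled to pollen/m3/24h.
    """
    db_species = set(local_db.species())
    for sp in design.species_pool:
        if sp not in db_species:
            raise ValueError(f"pool species {sp!r} absent from local db")
    extra = list(design.contaminant_taxa) + list(design.offtarget_taxa)
    for sp in extra:
        if sp not in db_species:
            raise ValueError(f"contaminant species {sp!r} absent from local db")
    control = design.positive_control_taxon
    if design.n_positive_controls > 0 and control is None:
        raise ValueError("positive_control_taxon required when controls > 0")
    if control is not None and control not in db_species:
        raise ValueError(f"control taxon {control!r} absent from local db")

    rng = np.random.default_rng(design.seed)
    sheet = _occurrence_frame(design)
    pool = list(design.species_pool)
    all_taxa = pool + [sp for sp in extra if sp not in pool]
    if control is not None and control not in all_taxa:
        all_taxa.append(control)
    n_pool = len(pool)

    sample_ids = sheet.loc[sheet.role == "sample", "sample_id"].unique().tolist()
    occ_ids = sheet.occurrence_id.tolist()
    counts = pd.DataFrame(
        0, index=all_taxa, columns=occ_ids, dtype=np.int64
    )

    # --- true community composition: one base composition per
    # (site, season) cell, per-sample Dirichlet jitter around it
    cell_base: dict[tuple[str, str], np.ndarray] = {}
    for site in design.sites:
        for season in design.seasons:
            cell_base[(site, season)] = rng.dirichlet(
                np.full(n_pool, design.dirichlet_base_alpha)
            )
    true_props = {}
    sample_rows = sheet[sheet.role == "sample"].drop_duplicates("sample_id")
    for _, row in sample_rows.iterrows():
        base = cell_base[(row.site, row.season)]
        alpha = base * design.sample_concentration + 1e-6
        true_props[row.sample_id] = rng.dirichlet(alpha)
    true_df = pd.DataFrame(true_props, index=pool).T
    true_df = true_df.div(true_df.sum(axis=1), axis=0)

    # --- per-species amplification bias (log-normal)
    bias = np.exp(rng.normal(0.0, design.bias_sd, size=n_pool))
    bias_s = pd.Series(bias, index=pool)

    # --- per-replicate template counts
    for _, row in sheet[sheet.role == "sample"].iterrows():
        p = true_df.loc[row.sample_id].to_numpy() * bias
        p = p / p.sum()
        if design.replicate_concentration is not None:
            p = rng.dirichlet(p * design.replicate_concentration + 1e-9)
        depth = max(1, int(rng.poisson(design.depth_mean)))
        counts.loc[pool, row.occurrence_id] = rng.multinomial(depth, p)

    # --- ambient contaminants (food taxa, off-target clades) in samples
    if extra and design.contaminant_mean_reads > 0:
        sample_occs = sheet.loc[sheet.role == "sample", "occurrence_id"]
        for sp in extra:
            counts.loc[sp, sample_occs] += rng.poisson(
                design.contaminant_mean_reads, size=len(sample_occs)
            )

    # --- positive controls: pure control taxon
    for occ in sheet.loc[sheet.role == "positive_control", "occurrence_id"]:
        depth = max(1, int(rng.poisson(design.depth_mean)))
        counts.loc[control, occ] = depth

    # --- leakage into blanks, proportional to source abundance
    blank_occs = sheet.loc[
        sheet.role.isin(["extraction_blank", "pcr_negative"]), "occurrence_id"
    ].tolist()
    if design.leakage_rate > 0 and blank_occs:
        source_occs = [o for o in occ_ids if o not in blank_occs]
        mat = counts.loc[:, source_occs].to_numpy()
        moved = rng.binomial(mat, design.leakage_rate)
        counts.loc[:, source_occs] = mat - moved
        per_species = moved.sum(axis=1)
        n_blanks = len(blank_occs)
        for i, sp in enumerate(counts.index):
            if per_species[i] > 0:
                counts.loc[sp, blank_occs] += rng.multinomial(
                    per_species[i], np.full(n_blanks, 1.0 / n_blanks)
                )

    # --- microscope counts at morphotype resolution
    lineage_map = {
        r.lineage.species: (r.lineage.family, r.lineage.genus)
        for r in local_db.records
    }
    morpho_map = {
        sp: morphotype_of(lineage_map, sp, design.family_level_morphotypes)
        for sp in all_taxa
    }
    pool_morphos = sorted({morpho_map[sp] for sp in pool})
    agg = np.zeros((len(sample_ids), len(pool_morphos)))
    morpho_idx = {m: j for j, m in enumerate(pool_morphos)}
    for i, sid in enumerate(sample_ids):
        for sp in pool:
            agg[i, morpho_idx[morpho_map[sp]]] += true_df.loc[sid, sp]
    micro_counts = np.vstack(
        [
            rng.multinomial(design.microscope_grains, agg[i] / agg[i].sum())
            for i in range(len(sample_ids))
        ]
    )
    microscope = pd.DataFrame(
        micro_counts * design.pollen_m3_scale,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pool_morphos,
    )

    truth = TruthBundle(
        true_proportions=true_df,
        bias_factors=bias_s,
        leakage_rate=design.leakage_rate,
        contaminant_ids=tuple(extra),
        morphotype_map=morpho_map,
    )
    truth.validate()

    reads = None
    if generate_reads:
        reads = _generate_reads(design, local_db, counts, rng)

    return SimulatedDataset(
        counts=counts,
        reads=reads,
        sample_sheet=sheet,
        microscope=microscope,
        truth=truth,
        marker=design.marker,
    )


def _generate_reads(
    design: StudyDesign,
    local_db: ReferenceDb,
    counts: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, list[tuple[str, str]]]:
    """Template counts -> error-bearing reads with primers attached."""
    params = MARKERS[design.marker]
    amplicons = {
        sp: params.fwd_primer
        + local_db.sequence_of_species(sp)
        + revcomp(params.rev_primer)
        for sp in counts.index
    }
    reads: dict[str, list[tuple[str, str]]] = {}
    for occ in counts.columns:
        col = counts[occ]
        templates = [
            (amplicons[sp], int(n)) for sp, n in col.items() if n > 0
        ]
        sp_names = [sp for sp, n in col.items() if n > 0]
        emitted = mutate_reads(templates, design.error_rate, rng)
        tagged = []
        for rid, seq in emitted:
            t_idx = int(rid.split("_")[0][1:])
            tagged.append((f"{occ}|{sp_names[t_idx]}|{rid}", seq))
        reads[occ] = tagged
    return reads


def write_reads_fasta(
    reads: Mapping[str, list[tuple[str, str]]], outdir: str | Path
) -> list[Path]:
    """One FASTA per occurrence; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for occ, entries in reads.items():
        path = outdir / f"{occ}.fasta"
        with open(path, "w") as fh:
            for rid, seq in entries:
                fh.write(f">{rid}\n{seq}\n")
        paths.append(path)
    return paths
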