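"""Stage functions composing the full pipeline, file-based between stages.

Every stage reads its inputs from and writes its outputs to a run
directory, so each is runnable standalone from the previous stage's
files.  All randomness flows from the single root seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from aeropollen import amplicon, community, filtering, quantify, taxonomy
from aeropollen.amplicon import MARKERS
from aeropollen.refdb import ReferenceDb, generate_reference_sets
from aeropollen.simulate import (
    StudyDesign,
    simulate_dataset,
    write_reads_fasta,
)

log = logging.getLogger("aeropollen")

__all__ = [
    "stage_simulate",
    "stage_process",
    "stage_assign",
    "stage_filter",
    "stage_quantify",
    "stage_compare",
    "run_all",
    "write_manifest",
    "validate_inputs",
]


def _markers(cfg) -> list[str]:
    return list(cfg["markers"].keys())


def _stage_seed(cfg: dict, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    digest = hashlib.sha256(f"{cfg['seed']}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# simulate

def _build_pool(local_db: ReferenceDb, cfg: dict) -> dict:
    """Partition database species into pool / contaminants / control."""
    dcfg = cfg["design"]
    # round-robin across genera so the pool spans families/morphotypes
    by_genus: dict[str, list[str]] = {}
    for r in local_db.records:
        if r.lineage.clade == "seed_plants":
            by_genus.setdefault(r.lineage.genus, []).append(r.lineage.species)
    plant_species: list[str] = []
    rank = 0
    while any(len(v) > rank for v in by_genus.values()):
        for genus in by_genus:
            if len(by_genus[genus]) > rank:
                plant_species.append(by_genus[genus][rank])
        rank += 1
    offtarget_species = [
        r.lineage.species
        for r in local_db.records
        if r.lineage.clade != "seed_plants"
    ]
    n_pool = min(dcfg["n_pool_species"], len(plant_species) - 1 - dcfg["n_contaminants"])
    if n_pool < 1:
        raise ValueError("reference database too small for the species pool")
    pool = plant_species[:n_pool]
    control = plant_species[n_pool]
    contaminants = plant_species[n_pool + 1: n_pool + 1 + dcfg["n_contaminants"]]
    return {
        "pool": tuple(pool),
        "control": control,
        "contaminants": tuple(contaminants),
        "offtarget": tuple(offtarget_species),
    }


def stage_simulate(cfg: dict, outdir: Path) -> dict[str, Path]:
    """Generate reference databases and one simulated run per marker."""
    outdir.mkdir(parents=True, exist_ok=True)
    rcfg, dcfg = cfg["reference"], cfg["design"]
    written: dict[str, Path] = {}
    community_seed = _stage_seed(cfg, "community")

    for m_idx, marker in enumerate(_markers(cfg)):
        mcfg = cfg["markers"][marker]
        seq_length = mcfg.get("seq_length", rcfg["seq_length"])
        local_db, global_db = generate_reference_sets(
            rcfg["n_families"],
            rcfg["n_genera_per_family"],
            rcfg["n_species_per_genus"],
            seq_length=seq_length,
            seed=_stage_seed(cfg, f"refdb:{marker}"),
            extra_global_families=rcfg["extra_global_families"],
            extra_global_species_per_genus=rcfg["extra_global_species_per_genus"],
            offtarget_clades=tuple(rcfg["offtarget_clades"]),
            n_offtarget_species_per_clade=rcfg["n_offtarget_species_per_clade"],
        )
        parts = _build_pool(local_db, cfg)
        design = StudyDesign(
            species_pool=parts["pool"],
            marker=marker,
            sites=tuple(dcfg["sites"]),
            seasons=tuple(dcfg["seasons"]),
            n_samples_per_cell=dcfg["n_samples_per_cell"],
            n_replicates=dcfg["n_replicates"],
            bias_sd=mcfg.get("bias_sd", 0.3),
            depth_mean=dcfg["depth_mean"],
            error_rate=dcfg["error_rate"],
            leakage_rate=dcfg["leakage_rate"],
            contaminant_taxa=parts["contaminants"],
            offtarget_taxa=parts["offtarget"],
            contaminant_mean_reads=dcfg["contaminant_mean_reads"],
            positive_control_taxon=parts["control"],
            n_extraction_blanks=dcfg["n_extraction_blanks"],
            n_pcr_negatives=dcfg["n_pcr_negatives"],
            n_positive_controls=dcfg["n_positive_controls"],
            microscope_grains=dcfg["microscope_grains"],
            pollen_m3_scale=dcfg["pollen_m3_scale"],
            dirichlet_base_alpha=dcfg["dirichlet_base_alpha"],
            sample_concentration=dcfg["sample_concentration"],
            replicate_concentration=dcfg["replicate_concentration"],
            family_level_morphotypes=tuple(dcfg["family_level_morphotypes"]),
            # one community seed for all markers: identical true
            # compositions, marker-specific bias and sampling
            seed=community_seed,
        )
        ds = simulate_dataset(design, local_db, generate_reads=True)

        local_db.write(
            outdir / f"ref_local_{marker}.fasta", outdir / f"ref_local_{marker}.tsv"
        )
        global_db.write(
            outdir / f"ref_global_{marker}.fasta", outdir / f"ref_global_{marker}.tsv"
        )
        write_reads_fasta(ds.reads, outdir / "reads" / marker)
        _write_table(ds.counts, outdir / f"template_counts_{marker}.tsv")
        ds.truth.to_json(outdir / f"truth_{marker}.json")
        if m_idx == 0:
            ds.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
            _write_table(ds.microscope, outdir / "microscope.tsv")
        meta = {
            "marker": marker,
            "control_taxon": parts["control"],
            "contaminant_taxa": list(parts["contaminants"]),
        }
        (outdir / f"simulate_meta_{marker}.json").write_text(
            json.dumps(meta, indent=1)
        )
        written[marker] = outdir
        log.info("simulated marker %s: %d occurrences", marker, ds.counts.shape[1])
    return written


# ---------------------------------------------------------------------------
# process

def stage_process(cfg: dict, outdir: Path) -> None:
    """Trim, length-filter, dereplicate and denoise reads per marker."""
    from Bio import SeqIO

    pcfg = cfg["process"]
    for marker in _markers(cfg):
        params = MARKERS[marker]
        reads_dir = outdir / "reads" / marker
        per_occ: dict[str, list[str]] = {}
        n_in = n_kept = 0
        for fasta in sorted(reads_dir.glob("*.fasta")):
            occ = fasta.stem
            kept = []
            for rec in SeqIO.parse(str(fasta), "fasta"):
                n_in += 1
                insert = amplicon.trim_primers(
                    str(rec.seq),
                    params.fwd_primer,
                    params.rev_primer,
                    max_mismatch_frac=pcfg["max_primer_mismatch_frac"],
                    min_len=params.min_insert_len,
                )
                if insert is not None:
                    kept.append(insert)
                    n_kept += 1
            per_occ[occ] = kept
        uniques = amplicon.dereplicate(per_occ)
        otus = amplicon.denoise_unoise(
            uniques,
            alpha=pcfg["alpha"],
            min_abundance=pcfg["min_abundance"],
            detect_chimeras=pcfg["detect_chimeras"],
        )
        otus = [o for o in otus if not o.is_chimera]
        occ_ids = sorted(per_occ.keys())
        table = pd.DataFrame(
            {occ: [o.count(occ) for o in otus] for occ in occ_ids},
            index=pd.Index([o.otu_id for o in otus], name="otu_id"),
            dtype=np.int64,
        )
        with open(outdir / f"otus_{marker}.fasta", "w") as fh:
            for o in otus:
                fh.write(f">{o.otu_id};size={o.total}\n{o.sequence}\n")
        _write_table(table, outdir / f"otu_table_{marker}.tsv")
        log.info(
            "processed %s: %d/%d reads kept, %d uniques, %d OTUs",
            marker, n_kept, n_in, len(uniques), len(otus),
        )


# ---------------------------------------------------------------------------
# assign

def stage_assign(cfg: dict, outdir: Path) -> None:
    """Dual-database tiered-LCA assignment and OTU aggregation."""
    from Bio import SeqIO

    for marker in _markers(cfg):
        local_db = ReferenceDb.read(
            outdir / f"ref_local_{marker}.fasta",
            outdir / f"ref_local_{marker}.tsv",
            "local",
        )
        global_db = ReferenceDb.read(
            outdir / f"ref_global_{marker}.fasta",
            outdir / f"ref_global_{marker}.tsv",
            "global",
        )
        otu_table = _read_table(outdir / f"otu_table_{marker}.tsv")
        seqs = {
            rec.id.split(";")[0]: str(rec.seq)
            for rec in SeqIO.parse(str(outdir / f"otus_{marker}.fasta"), "fasta")
        }
        assignments = {
            otu_id: taxonomy.assign_taxonomy(
                seqs[otu_id], local_db, global_db, marker
            )
            for otu_id in otu_table.index
        }
        rows = [
            {
                "otu_id": otu_id,
                "rank": a.rank,
                "lineage": a.lineage.to_path(),
                "identity": a.identity,
                "scope": a.scope,
            }
            for otu_id, a in assignments.items()
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"assignments_{marker}.tsv", sep="\t", index=False
        )
        taxon_table, row_meta = taxonomy.aggregate_by_assignment(
            otu_table, assignments
        )
        _write_table(taxon_table, outdir / f"taxon_table_{marker}.tsv")
        _write_table(row_meta, outdir / f"taxon_meta_{marker}.tsv")
        log.info(
            "assigned %s: %d OTUs -> %d taxa", marker, len(otu_table), len(taxon_table)
        )


# ---------------------------------------------------------------------------
# filter

def _load_meta(outdir: Path, marker: str) -> pd.DataFrame:
    meta = pd.read_csv(
        outdir / f"taxon_meta_{marker}.tsv", sep="\t", index_col=0, dtype=str
    ).fillna("")
    return meta


def stage_filter(cfg: dict, outdir: Path) -> None:
    """Run the six-step cascade and the positive-control check."""
    fcfg = cfg["filter"]
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t").fillna("")
    for marker in _markers(cfg):
        table = _read_table(outdir / f"taxon_table_{marker}.tsv")
        meta = _load_meta(outdir, marker)
        sim_meta = json.loads(
            (outdir / f"simulate_meta_{marker}.json").read_text()
        )
        params = filtering.FilterParams(
            min_reads_per_repeat=fcfg["min_reads_per_repeat"],
            min_repeat_depth=fcfg["min_repeat_depth"],
            min_replicates_present=fcfg["min_replicates_present"],
            excluded_clades=tuple(fcfg["excluded_clades"]),
            contaminant_taxa=tuple(sim_meta["contaminant_taxa"]),
            leakage_denominator=fcfg["leakage_denominator"],
        )
        check = filtering.check_positive_controls(
            table, sheet, sim_meta["control_taxon"], row_meta=meta
        )
        filtered, report = filtering.run_filter_cascade(table, sheet, meta, params)
        _write_table(filtered, outdir / f"filtered_{marker}.tsv")
        report_frame = report.to_frame()
        report_frame.to_csv(outdir / f"filter_report_{marker}.tsv", sep="\t", index=False)
        (outdir / f"positive_control_{marker}.json").write_text(
            json.dumps(
                {"passed": check.passed, "details": check.details}, indent=1
            )
        )
        (outdir / f"filter_flags_{marker}.json").write_text(
            json.dumps(
                {
                    "leakage_threshold": report.leakage_threshold,
                    "single_replicate_samples": report.single_replicate_samples,
                },
                indent=1,
            )
        )
        for step in report.steps:
            log.info(
                "filter %s %s: -%d OTUs, -%d reads",
                marker, step.label, step.otus_removed, step.reads_removed,
            )


# ---------------------------------------------------------------------------
# quantify

def _morphotype_map_from_meta(
    meta: pd.DataFrame, family_level: tuple[str, ...]
) -> dict[str, str]:
    """Total map taxon-row -> microscope morphotype ('other' when the
    molecular row cannot correspond to a counted morphotype)."""
    out: dict[str, str] = {}
    for taxon, row in meta.iterrows():
        if row["family"] and row["family"] in family_level:
            out[taxon] = row["family"]
        elif row["genus"]:
            out[taxon] = row["genus"]
        elif row["family"]:
            out[taxon] = row["family"]
        else:
            out[taxon] = "other"
    return out


def stage_quantify(cfg: dict, outdir: Path) -> None:
    """RRA conversion, morphotype mapping and regressions."""
    acfg = cfg["analysis"]
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t").fillna("")
    microscope = _read_table(outdir / "microscope.tsv")
    family_level = tuple(cfg["design"]["family_level_morphotypes"])

    rra_by_marker: dict[str, pd.DataFrame] = {}
    maps: dict[str, dict[str, str]] = {}
    for marker in _markers(cfg):
        filtered = _read_table(outdir / f"filtered_{marker}.tsv")
        meta = _load_meta(outdir, marker)
        rra = quantify.to_rra(filtered, sheet)
        _write_table(rra, outdir / f"rra_{marker}.tsv")
        mmap = _morphotype_map_from_meta(meta.loc[filtered.index], family_level)
        morpho = quantify.map_to_morphotypes(rra, mmap)
        _write_table(morpho, outdir / f"rra_morphotypes_{marker}.tsv")
        pd.Series(mmap, name="morphotype").rename_axis("taxon").to_csv(
            outdir / f"morphotype_map_{marker}.tsv", sep="\t"
        )
        rra_by_marker[marker] = rra
        maps[marker] = mmap

    # targets: the most abundant microscope morphotypes
    mean_rel = quantify.microscope_relative_abundance(microscope).mean(axis=0)
    targets = mean_rel.sort_values(ascending=False).index[
        : acfg["n_target_morphotypes"]
    ].tolist()
    fits = quantify.quantification_report(
        rra_by_marker,
        microscope,
        # per-marker maps are identical label-wise; merge them
        {k: v for mmap in maps.values() for k, v in mmap.items()},
        targets,
        combined_min_frac=acfg["combined_min_frac"],
    )
    fits.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
    log.info("quantified %d regression fits (targets: %s)", len(fits), targets)


# ---------------------------------------------------------------------------
# compare

def stage_compare(cfg: dict, outdir: Path) -> None:
    """Bray-Curtis, perMANOVA (site and season) and NMDS per marker."""
    acfg = cfg["analysis"]
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t").fillna("")
    sample_info = (
        sheet[sheet.role == "sample"]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    perm_rows = []
    for marker in _markers(cfg):
        rra = _read_table(outdir / f"rra_{marker}.tsv")
        dist = community.bray_curtis(rra)
        _write_table(dist, outdir / f"braycurtis_{marker}.tsv")
        for factor in ("site", "season"):
            groups = sample_info.loc[dist.index, factor]
            sizes = groups.value_counts()
            if len(sizes) < 2 or (sizes < 2).any():
                log.warning(
                    "skipping perMANOVA on %s/%s: not enough samples per group",
                    marker, factor,
                )
                continue
            res = community.permanova(
                dist,
                groups,
                n_perm=acfg["n_permutations"],
                seed=_stage_seed(cfg, f"permanova:{marker}:{factor}"),
            )
            perm_rows.append(
                {
                    "marker": marker,
                    "factor": factor,
                    "pseudo_F": res.pseudo_f,
                    "r_squared": res.r_squared,
                    "p_value": res.p_value,
                    "n_permutations": res.n_permutations,
                    "seed": res.seed,
                }
            )
        nm = community.nmds(
            dist,
            k=2,
            n_starts=acfg["nmds_starts"],
            max_iter=acfg["nmds_max_iter"],
            seed=_stage_seed(cfg, f"nmds:{marker}"),
        )
        coords = pd.DataFrame(
            nm.coordinates, index=dist.index, columns=["nmds1", "nmds2"]
        )
        coords["stress"] = nm.stress
        coords["converged"] = nm.converged
        _write_table(coords, outdir / f"nmds_{marker}.tsv")
        log.info("NMDS %s stress %.4f", marker, nm.stress)
    pd.DataFrame(perm_rows).to_csv(outdir / "permanova.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest & validation

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(cfg: dict, outdir: Path) -> Path:
    from aeropollen import __version__

    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def run_all(cfg: dict, outdir: Path) -> Path:
    """Execute every stage in order and write the run manifest."""
    stages = [
        ("simulate", stage_simulate),
        ("process", stage_process),
        ("assign", stage_assign),
        ("filter", stage_filter),
        ("quantify", stage_quantify),
        ("compare", stage_compare),
    ]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            fn(cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return write_manifest(cfg, outdir)


def validate_inputs(outdir: Path) -> list[str]:
    """Non-destructive well-formedness checks; returns a problem list."""
    problems: list[str] = []
    sheet_path = outdir / "sample_sheet.tsv"
    if not sheet_path.exists():
        problems.append(f"missing sample sheet: {sheet_path}")
        return problems
    sheet = pd.read_csv(sheet_path, sep="\t").fillna("")
    required = {"occurrence_id", "sample_id", "replicate", "role"}
    missing_cols = required - set(sheet.columns)
    if missing_cols:
        problems.append(f"sample sheet missing columns: {sorted(missing_cols)}")
        return problems
    from aeropollen.simulate import ROLES

    bad_roles = sorted(set(sheet.role) - set(ROLES))
    if bad_roles:
        problems.append(f"unknown roles in sample sheet: {bad_roles}")
    if sheet.occurrence_id.duplicated().any():
        problems.append("duplicate occurrence ids in sample sheet")

    for fasta in sorted(outdir.glob("ref_*.fasta")):
        try:
            from Bio import SeqIO

            n = sum(1 for _ in SeqIO.parse(str(fasta), "fasta"))
            if n == 0:
                problems.append(f"empty FASTA: {fasta.name}")
        except Exception as exc:
            problems.append(f"unreadable FASTA {fasta.name}: {exc}")

    for table_path in sorted(outdir.glob("taxon_table_*.tsv")) + sorted(
        outdir.glob("otu_table_*.tsv")
    ):
        table = _read_table(table_path)
        unknown = [c for c in table.columns if c not in set(sheet.occurrence_id)]
        if unknown:
            problems.append(
                f"{table_path.name}: occurrence columns absent from sheet: "
                f"{unknown[:3]}"
            )
        if (table.to_numpy() < 0).any():
            problems.append(f"{table_path.name}: negative counts")

    for map_path in sorted(outdir.glob("morphotype_map_*.tsv")):
        marker = map_path.stem.replace("morphotype_map_", "")
        rra_path = outdir / f"rra_{marker}.tsv"
        if rra_path.exists():
            mmap = pd.read_csv(map_path, sep="\t", index_col=0)
            rra = _read_table(rra_path)
            unmapped = [c for c in rra.columns if c not in mmap.index]
            if unmapped:
                problems.append(
                    f"{map_path.name}: taxa missing from map: {unmapped[:3]}"
                )
    return problems
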