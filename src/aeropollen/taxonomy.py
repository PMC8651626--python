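"""Dual-database taxonomic assignment with identity tiers and max-score LCA.

Queries are aligned semi-globally against a local-priority reference
database; surviving hits at the maximum raw score define an LCA lineage
whose rank is capped by the best percent identity (>=97 species, >=90
genus, >=80 family).  A global database is consulted only when no local
hit survives the coverage/identity gates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from aeropollen.amplicon import MARKERS
from aeropollen.lineage import Lineage, UNASSIGNED, lca
from aeropollen.refdb import ReferenceDb

__all__ = [
    "Hit",
    "Assignment",
    "align_identity",
    "compute_hits",
    "assign_taxonomy",
    "assign_from_hits",
    "aggregate_by_assignment",
    "load_hit_table",
    "write_hit_table",
    "IDENTITY_TIERS",
]

#: (minimum percent identity, rank depth on the 4-level ladder).
IDENTITY_TIERS = ((97.0, 4), (90.0, 3), (80.0, 2))

#: Identity below which hits are discarded entirely.
MIN_IDENTITY = 80.0


@dataclass(frozen=True)
class Hit:
    """One query-vs-reference comparison."""

    ref_id: str
    score: float
    identity: float   # percent, 0-100
    coverage: float   # percent of query bases aligned, 0-100

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0 and 0.0 <= self.coverage <= 100.0):
            raise ValueError("identity and coverage must be in [0, 100]")


@dataclass(frozen=True)
class Assignment:
    """Final taxonomic call for one OTU."""

    lineage: Lineage
    rank: str                  # species / genus / family / unassigned
    identity: float | None = None
    scope: str | None = None   # local / global / None

    @property
    def key(self) -> str:
        """Aggregation key: resolved lineage path (or '' when unassigned)."""
        return self.lineage.to_path()


# ---------------------------------------------------------------------------
# alignment

_ALIGNER = None


def _get_aligner():
    # built lazily: importing Bio.Align is comparatively slow
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -3
        # gap of length L costs 5 + 2L
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
        # free end gaps: a query may sit inside a longer reference and a
        # partial reference record may cover only part of the query; the
        # unaligned span shows up as reduced coverage, not as penalties
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aligner.end_gap_score = 0
        _ALIGNER = aligner
    return _ALIGNER


def align_identity(query: str, reference: str) -> tuple[float, float, float]:
    """Semi-global alignment of ``query`` against ``reference``.

    Scoring: match +2, mismatch -3, gap open -5, gap extend -2, with free
    end gaps on the reference.  Returns ``(identity %, coverage %, raw
    score)`` where identity is matches over the alignment columns
    spanning the query (internal gap columns count as mismatches) and
    coverage is the fraction of query bases inside the aligned span.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _get_aligner()
    aln = aligner.align(reference.upper(), query.upper())[0]
    ref_blocks, q_blocks = aln.aligned
    if len(q_blocks) == 0:
        return 0.0, 0.0, float(aln.score)
    ref_seq, q_seq = reference.upper(), query.upper()
    matches = 0
    columns = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        columns += re_ - rs
        matches += sum(
            1 for a, b in zip(ref_seq[rs:re_], q_seq[qs:qe]) if a == b
        )
    # inter-block gap columns (each unaligned base occupies one column)
    for i in range(1, len(q_blocks)):
        columns += (ref_blocks[i][0] - ref_blocks[i - 1][1]) + (
            q_blocks[i][0] - q_blocks[i - 1][1]
        )
    identity = 100.0 * matches / columns
    covered = q_blocks[-1][1] - q_blocks[0][0]
    coverage = 100.0 * covered / len(q_seq)
    return identity, coverage, float(aln.score)


def compute_hits(query: str, db: ReferenceDb) -> list[Hit]:
    """Align ``query`` against every record of ``db`` (no filtering)."""
    return [
        Hit(rec.record_id, score, identity, coverage)
        for rec in db.records
        for identity, coverage, score in (align_identity(query, rec.sequence),)
    ]


# ---------------------------------------------------------------------------
# assignment

def _tier_depth(identity: float) -> int:
    for min_ident, depth in IDENTITY_TIERS:
        if identity >= min_ident:
            return depth
    return 0


def _surviving(hits: Iterable[Hit], min_coverage: float) -> list[Hit]:
    return [
        h
        for h in hits
        if h.coverage >= min_coverage - 1e-9 and h.identity >= MIN_IDENTITY
    ]


def assign_from_hits(
    local_hits: Iterable[Hit],
    global_hits: Iterable[Hit],
    local_lineages: Mapping[str, Lineage],
    global_lineages: Mapping[str, Lineage],
    min_coverage: float,
) -> Assignment:
    """Assignment logic on precomputed hit tables (BLAST-style input path).

    Local hits have absolute priority: the global table is consulted only
    when no local hit passes the coverage and identity gates.  Among
    survivors, the hits sharing the maximum raw score form the candidate
    set; their LCA is truncated to the rank tier allowed by the best
    candidate identity.
    """
    for hits, lineages, scope in (
        (local_hits, local_lineages, "local"),
        (global_hits, global_lineages, "global"),
    ):
        survivors = _surviving(hits, min_coverage)
        if not survivors:
            continue
        max_score = max(h.score for h in survivors)
        candidates = [h for h in survivors if h.score == max_score]
        best_identity = max(h.identity for h in candidates)
        consensus = lca([lineages[h.ref_id] for h in candidates])
        depth = min(consensus.depth, _tier_depth(best_identity))
        lineage = consensus.truncate(depth)
        if lineage.depth == 0:
            # clade-level disagreement: treated as unassigned
            return Assignment(Lineage(), UNASSIGNED, best_identity, scope)
        return Assignment(lineage, lineage.rank, best_identity, scope)
    return Assignment(Lineage(), UNASSIGNED, None, None)


def assign_taxonomy(
    query: str,
    local_db: ReferenceDb,
    global_db: ReferenceDb,
    marker: str,
) -> Assignment:
    """Assign one query sequence using the two-database tiered-LCA rule."""
    if not local_db.records or not global_db.records:
        raise ValueError("reference databases must be non-empty")
    params = MARKERS[marker] if isinstance(marker, str) else marker
    local_hits = compute_hits(query, local_db)
    # the global database is only aligned when needed
    survivors = _surviving(local_hits, params.min_coverage)
    if survivors:
        global_hits: list[Hit] = []
    else:
        global_hits = compute_hits(query, global_db)
    return assign_from_hits(
        local_hits,
        global_hits,
        local_db.lineage_by_id(),
        global_db.lineage_by_id(),
        params.min_coverage,
    )


# ---------------------------------------------------------------------------
# aggregation

def aggregate_by_assignment(
    otu_table: pd.DataFrame,
    assignments: Mapping[str, Assignment],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum OTU rows sharing a taxonomic assignment.

    ``otu_table`` has OTU ids as index and occurrence ids as columns.
    Returns ``(taxon_table, row_meta)`` where ``row_meta`` carries the
    lineage, rank and member-OTU count per output row.  Unassigned OTUs
    are kept as individual rows flagged ``unassigned``.
    """
    missing = [otu for otu in otu_table.index if otu not in assignments]
    if missing:
        raise ValueError(f"missing assignments for OTUs: {missing[:5]}")

    groups: dict[str, list[str]] = {}
    meta: dict[str, Assignment] = {}
    for otu_id in otu_table.index:
        a = assignments[otu_id]
        key = a.key if a.rank != UNASSIGNED else f"unassigned:{otu_id}"
        groups.setdefault(key, []).append(otu_id)
        meta[key] = a

    rows = []
    meta_rows = []
    for key, otu_ids in groups.items():
        a = meta[key]
        summed = otu_table.loc[otu_ids].sum(axis=0)
        summed.name = key
        rows.append(summed)
        meta_rows.append(
            {
                "taxon": key,
                "rank": a.rank,
                "clade": a.lineage.clade,
                "family": a.lineage.family,
                "genus": a.lineage.genus,
                "species": a.lineage.species,
                "name": a.lineage.name,
                "identity": a.identity,
                "scope": a.scope,
                "n_otus": len(otu_ids),
            }
        )
    taxon_table = pd.DataFrame(rows, columns=otu_table.columns)
    taxon_table.index.name = "taxon"
    row_meta = pd.DataFrame(meta_rows).set_index("taxon")
    return taxon_table, row_meta


def load_hit_table(path) -> dict[str, list[Hit]]:
    """Read a BLAST-outfmt-6-like TSV of precomputed hits.

    Expected columns: query id, subject id, % identity, % query
    coverage, raw score.  Returns hits grouped per query, usable with
    :func:`assign_from_hits` in place of alignment.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        names=["query", "subject", "identity", "coverage", "score"],
        header=None,
        comment="#",
    )
    hits: dict[str, list[Hit]] = {}
    for row in frame.itertuples(index=False):
        hits.setdefault(row.query, []).append(
            Hit(row.subject, float(row.score), float(row.identity),
                float(row.coverage))
        )
    return hits


def write_hit_table(hits_by_query: Mapping[str, Sequence[Hit]], path) -> None:
    """Inverse of :func:`load_hit_table`."""
    rows = [
        (query, h.ref_id, h.identity, h.coverage, h.score)
        for query, hits in hits_by_query.items()
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["query", "subject", "identity", "coverage", "score"]
    ).to_csv(path, sep="\t", header=False, index=False)
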