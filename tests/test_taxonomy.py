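import numpy as np
import pandas as pd
import pytest

from aeropollen.lineage import Lineage, UNASSIGNED, lca
from aeropollen.refdb import ReferenceDb, ReferenceRecord
from aeropollen.taxonomy import (
    Assignment,
    Hit,
    aggregate_by_assignment,
    align_identity,
    assign_from_hits,
    assign_taxonomy,
    compute_hits,
)


def mutate(seq, n, rng):
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


class TestAlignIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 25
        ident, cov, score = align_identity(seq, seq)
        assert (ident, cov, score) == (100.0, 100.0, 200.0)

    def test_single_substitution(self):
        seq = "ACGT" * 25
        query = "T" + seq[1:]
        ident, cov, _ = align_identity(query, seq)
        assert ident == pytest.approx(99.0)
        assert cov == 100.0

    def test_hand_computed_gap_alignment(self):
        # AAAA--TTTT vs AAAACCTTTT: 8 matches over 10 columns,
        # score 8*2 - (5 + 2*2) = 7
        ident, cov, score = align_identity("AAAATTTT", "AAAACCTTTT")
        assert ident == pytest.approx(80.0)
        assert cov == 100.0
        assert score == 7.0

    def test_query_inside_longer_reference_full_coverage(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), size=200))
        query = ref[50:150]
        ident, cov, score = align_identity(query, ref)
        assert ident == 100.0
        assert cov == 100.0
        assert score == 200.0  # free end gaps on the reference

    def test_truncated_reference_reduces_coverage(self):
        rng = np.random.default_rng(1)
        query = "".join(rng.choice(list("ACGT"), size=100))
        ref = query[:90]  # partial reference record
        ident, cov, _ = align_identity(query, ref)
        assert ident == 100.0
        assert cov == pytest.approx(90.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_identity("", "ACGT")


def db_from(records, scope="local"):
    return ReferenceDb(scope, records)


def rec(rid, family, genus, species, seq, clade="seed_plants"):
    return ReferenceRecord(rid, Lineage(clade, family, genus, species), seq)


@pytest.fixture(scope="module")
def toy_dbs():
    rng = np.random.default_rng(42)
    base = "".join(rng.choice(list("ACGT"), size=200))
    other = mutate(base, 60, rng)       # distant family
    sib = mutate(base, 4, rng)          # congeneric species, ~98%
    cousin = mutate(base, 16, rng)      # same family, different genus, ~92%
    local = db_from(
        [
            rec("L1", "Betulaceae", "Alnus", "Alnus glutinosa", base),
            rec("L2", "Betulaceae", "Alnus", "Alnus incana", sib),
            rec("L3", "Betulaceae", "Betula", "Betula pendula", cousin),
            rec("L4", "Pinaceae", "Pinus", "Pinus sylvestris", other),
        ]
    )
    global_ = db_from(
        local.records
        + [rec("G1", "Betulaceae", "Alnus", "Alnus cordata", mutate(base, 2, rng))],
        scope="global",
    )
    return base, local, global_


class TestAssignTaxonomy:
    def test_local_priority_over_better_global_hit(self, toy_dbs):
        base, local, global_ = toy_dbs
        rng = np.random.default_rng(7)
        query = mutate(base, 3, rng)  # ~98.5% to L1; G1 may be closer
        a = assign_taxonomy(query, local, global_, "nrITS2-like")
        assert a.scope == "local"

    def test_exact_match_species_rank(self, toy_dbs):
        base, local, global_ = toy_dbs
        a = assign_taxonomy(base, local, global_, "nrITS2-like")
        assert a.rank == "species"
        assert a.lineage.species == "Alnus glutinosa"
        assert a.identity == pytest.approx(100.0)

    def test_identity_tier_caps_rank(self, toy_dbs):
        base, local, global_ = toy_dbs
        rng = np.random.default_rng(8)
        query = mutate(base, 10, rng)  # ~95%: genus tier
        a = assign_taxonomy(query, local, global_, "nrITS2-like")
        assert a.rank == "genus"
        query = mutate(base, 30, rng)  # ~85%: family tier
        a = assign_taxonomy(query, local, global_, "nrITS2-like")
        assert a.rank == "family"

    def test_below_family_tier_unassigned(self, toy_dbs):
        base, local, global_ = toy_dbs
        rng = np.random.default_rng(9)
        query = "".join(rng.choice(list("ACGT"), size=200))
        a = assign_taxonomy(query, local, global_, "nrITS2-like")
        assert a.rank == UNASSIGNED

    def test_full_coverage_gate_drops_partial_hits(self, toy_dbs):
        base, local, global_ = toy_dbs
        # query extends 10 bases past every reference: coverage ~95%
        query = base + "ACGTACGTAC"
        strict = assign_taxonomy(query, local, global_, "trnL-like")
        lenient = assign_taxonomy(query, local, global_, "nrITS2-like")
        assert strict.rank == UNASSIGNED
        assert lenient.rank == "species"

    def test_global_fallback_used_when_local_empty(self, toy_dbs):
        base, local, global_ = toy_dbs
        # a query matching only the global-only record region: use a db
        # whose local part is distant
        rng = np.random.default_rng(10)
        distant_local = db_from(
            [rec("X1", "F", "G", "G s", "".join(rng.choice(list("ACGT"), 200)))]
        )
        a = assign_taxonomy(base, distant_local, global_, "nrITS2-like")
        assert a.scope == "global"

    def test_tied_scores_trigger_lca(self):
        seq = "ACGT" * 50
        local = db_from(
            [
                rec("A", "Betulaceae", "Alnus", "Alnus glutinosa", seq),
                rec("B", "Betulaceae", "Alnus", "Alnus incana", seq),
            ]
        )
        a = assign_taxonomy(seq, local, local, "nrITS2-like")
        assert a.rank == "genus"
        assert a.lineage.genus == "Alnus"

    def test_rank_depth_never_increases_with_mutations(self, toy_dbs):
        base, local, global_ = toy_dbs
        rng = np.random.default_rng(11)
        depths = []
        rank_depth = {"species": 4, "genus": 3, "family": 2, UNASSIGNED: 0}
        for n_mut in (0, 5, 12, 25, 45):
            query = mutate(base, n_mut, rng)
            a = assign_taxonomy(query, local, global_, "nrITS2-like")
            depths.append(rank_depth[a.rank])
        assert depths == sorted(depths, reverse=True)


# ---------------------------------------------------------------------------
# brute-force oracle

def oracle_assign(local_hits, global_hits, local_lin, global_lin, min_cov):
    """Exhaustive re-derivation: filter, max score, LCA, tier cap."""
    for hits, lineages, scope in (
        (local_hits, local_lin, "local"),
        (global_hits, global_lin, "global"),
    ):
        ok = [h for h in hits if h.coverage >= min_cov - 1e-9 and h.identity >= 80.0]
        if not ok:
            continue
        top = max(h.score for h in ok)
        cands = [h for h in ok if h.score == top]
        ident = max(h.identity for h in cands)
        tier = 4 if ident >= 97 else 3 if ident >= 90 else 2 if ident >= 80 else 0
        consensus = lca([lineages[h.ref_id] for h in cands])
        depth = min(consensus.depth, tier)
        lineage = consensus.truncate(depth)
        if depth == 0:
            return Assignment(Lineage(), UNASSIGNED, ident, scope)
        return Assignment(lineage, lineage.rank, ident, scope)
    return Assignment(Lineage(), UNASSIGNED, None, None)


def test_assignment_matches_oracle_on_random_queries(medium_dbs):
    local, global_ = medium_dbs
    local_lin, global_lin = local.lineage_by_id(), global_.lineage_by_id()
    rng = np.random.default_rng(99)
    seqs = [r.sequence for r in global_.records]
    n_checked = 0
    for _ in range(60):
        src = seqs[rng.integers(len(seqs))]
        n_mut = int(rng.integers(0, 60))
        query = mutate(src, n_mut, rng)
        if rng.random() < 0.2:
            query = query[: int(rng.integers(150, 201))]  # truncation
        lh = compute_hits(query, local)
        gh = compute_hits(query, global_)
        for marker, cov in (("trnL-like", 100.0), ("nrITS2-like", 90.0)):
            got = assign_from_hits(lh, gh, local_lin, global_lin, cov)
            want = oracle_assign(lh, gh, local_lin, global_lin, cov)
            assert got == want
            n_checked += 1
    assert n_checked == 120


# ---------------------------------------------------------------------------
# aggregation

class TestAggregate:
    def make_assignment(self, species=None, genus="Urtica", rank="species"):
        if rank == UNASSIGNED:
            return Assignment(Lineage(), UNASSIGNED)
        lin = Lineage("seed_plants", "Urticaceae", genus, species or "")
        return Assignment(lin, lin.rank, 99.0, "local")

    def test_same_assignment_summed(self):
        table = pd.DataFrame(
            {"S1_r1": [100, 50], "S1_r2": [10, 20]},
            index=pd.Index(["OTU_1", "OTU_2"], name="otu_id"),
        )
        a = self.make_assignment("Urtica dioica")
        out, meta = aggregate_by_assignment(table, {"OTU_1": a, "OTU_2": a})
        assert out.shape == (1, 2)
        assert out.iloc[0].tolist() == [150, 30]
        assert meta.iloc[0]["n_otus"] == 2

    def test_distinct_assignments_unchanged(self):
        table = pd.DataFrame(
            {"S1_r1": [100, 50]}, index=pd.Index(["OTU_1", "OTU_2"], name="otu_id")
        )
        out, _ = aggregate_by_assignment(
            table,
            {
                "OTU_1": self.make_assignment("Urtica dioica"),
                "OTU_2": self.make_assignment("Urtica urens"),
            },
        )
        assert sorted(out["S1_r1"].tolist()) == [50, 100]

    def test_unassigned_kept_separate(self):
        table = pd.DataFrame(
            {"S1_r1": [5, 7]}, index=pd.Index(["OTU_1", "OTU_2"], name="otu_id")
        )
        out, meta = aggregate_by_assignment(
            table,
            {
                "OTU_1": self.make_assignment(rank=UNASSIGNED),
                "OTU_2": self.make_assignment(rank=UNASSIGNED),
            },
        )
        assert len(out) == 2
        assert (meta["rank"] == UNASSIGNED).all()

    def test_column_sums_conserved(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            rng.integers(0, 100, size=(6, 4)),
            index=pd.Index([f"OTU_{i}" for i in range(6)], name="otu_id"),
            columns=[f"S{i}_r1" for i in range(4)],
        )
        assignments = {
            f"OTU_{i}": self.make_assignment(f"Urtica sp{i % 2}") for i in range(6)
        }
        out, _ = aggregate_by_assignment(table, assignments)
        assert out.sum(axis=0).tolist() == table.sum(axis=0).tolist()

    def test_missing_assignment_rejected(self):
        table = pd.DataFrame({"S1_r1": [1]}, index=pd.Index(["OTU_1"]))
        with pytest.raises(ValueError, match="missing"):
            aggregate_by_assignment(table, {})


def test_hit_range_validation():
    with pytest.raises(ValueError):
        Hit("x", 10.0, 120.0, 100.0)


def test_hit_table_roundtrip_drives_assignment(tmp_path, toy_dbs):
    from aeropollen.taxonomy import load_hit_table, write_hit_table

    base, local, global_ = toy_dbs
    hits = {"q1": compute_hits(base, local)}
    path = tmp_path / "hits.tsv"
    write_hit_table(hits, path)
    back = load_hit_table(path)
    assert back["q1"] == hits["q1"]
    a = assign_from_hits(
        back["q1"], [], local.lineage_by_id(), {}, 90.0
    )
    assert a.rank == "species"
    assert a.lineage.species == "Alnus glutinosa"
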