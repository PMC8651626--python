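import numpy as np
import pandas as pd
import pytest

from aeropollen.refdb import generate_reference_sets
from aeropollen.simulate import StudyDesign, simulate_dataset


@pytest.fixture(scope="session")
def small_dbs():
    """(local, global) reference pair: 2 families x 2 genera x 2 species."""
    return generate_reference_sets(2, 2, 2, seq_length=300, seed=7)


@pytest.fixture(scope="session")
def medium_dbs():
    """Larger pair with off-target clades, for assignment tests."""
    return generate_reference_sets(
        3, 2, 2, seq_length=300, seed=11,
        offtarget_clades=("fungi",), n_offtarget_species_per_clade=2,
    )


def make_design(local_db, **overrides):
    plants = [
        r.lineage.species for r in local_db.records
        if r.lineage.clade == "seed_plants"
    ]
    defaults = dict(
        species_pool=tuple(plants[:6]),
        positive_control_taxon=plants[6],
        marker="nrITS2-like",
        n_samples_per_cell=2,
        n_replicates=3,
        bias_sd=0.2,
        depth_mean=4000,
        error_rate=0.0,
        leakage_rate=0.001,
        microscope_grains=2000,
        seed=3,
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)


@pytest.fixture()
def small_dataset(small_dbs):
    local, _ = small_dbs
    design = make_design(local)
    return design, simulate_dataset(design, local, generate_reads=False)


def random_count_table(rng, n_otus=12, n_samples=4, n_reps=3, n_blanks=2):
    """Random OTU x occurrence table plus a matching sample sheet."""
    rows = []
    occ_ids = []
    for s in range(1, n_samples + 1):
        for r in range(1, n_reps + 1):
            occ = f"S{s:02d}_r{r}"
            occ_ids.append(occ)
            rows.append(
                {
                    "occurrence_id": occ, "sample_id": f"S{s:02d}",
                    "replicate": r, "role": "sample",
                    "site": "A" if s <= n_samples // 2 else "B",
                    "season": "spring", "date": "",
                }
            )
    for b in range(1, n_blanks + 1):
        occ = f"EB{b:02d}"
        occ_ids.append(occ)
        rows.append(
            {
                "occurrence_id": occ, "sample_id": occ, "replicate": 1,
                "role": "extraction_blank", "site": "", "season": "",
                "date": "",
            }
        )
    sheet = pd.DataFrame(rows)
    counts = rng.integers(0, 2000, size=(n_otus, len(occ_ids)))
    # sparse blanks: small counts, mostly zero
    for j in range(len(occ_ids) - n_blanks, len(occ_ids)):
        counts[:, j] = rng.integers(0, 4, size=n_otus) * (
            rng.random(n_otus) < 0.4
        )
    table = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index([f"OTU_{i:03d}" for i in range(n_otus)], name="otu_id"),
        columns=occ_ids,
    )
    return table, sheet
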