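"""Reference databases and their hierarchical synthetic generator.

Synthetic references are produced by mutating a shared ancestor per
family, per genus and per species so that expected pairwise identities
fall into the bands used by the assignment tiers: species of one genus
>= 97% identical, genera of one family 90-96%, families 80-89%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from aeropollen.lineage import Lineage

__all__ = ["ReferenceRecord", "ReferenceDb", "generate_reference_sets"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Per-branch substitution rates.  Pairwise divergence stacks two branches
# of each level: species pairs ~1.2%, genus pairs ~7%, family pairs ~15.5%,
# centering the three identity bands with room for binomial noise at
# sequence lengths >= 300.
_SPECIES_RATE = 0.006
_GENUS_RATE = 0.029
_FAMILY_RATE = 0.0425

#: Clades used for simulated off-target (non seed-plant) references.
OFFTARGET_CLADES = ("fungi", "bryophytes", "green_algae")


@dataclass(frozen=True)
class ReferenceRecord:
    record_id: str
    lineage: Lineage
    sequence: str


@dataclass
class ReferenceDb:
    """A set of reference sequences with full species-level lineages."""

    scope: str  # local / global
    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference record ids must be unique")
        for r in self.records:
            if r.lineage.depth != 4:
                raise ValueError(
                    f"record {r.record_id} lacks a species-level lineage"
                )

    def lineage_by_id(self) -> dict[str, Lineage]:
        return {r.record_id: r.lineage for r in self.records}

    def species(self) -> list[str]:
        return [r.lineage.species for r in self.records]

    def sequence_of_species(self, species: str) -> str:
        for r in self.records:
            if r.lineage.species == species:
                return r.sequence
        raise KeyError(species)

    # ---- I/O (plain-text FASTA + lineage TSV) ----

    def write(self, fasta_path: str | Path, lineage_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.record_id}\n{r.sequence}\n")
        rows = [
            {
                "record_id": r.record_id,
                "clade": r.lineage.clade,
                "family": r.lineage.family,
                "genus": r.lineage.genus,
                "species": r.lineage.species,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(lineage_path, sep="\t", index=False)

    @classmethod
    def read(
        cls, fasta_path: str | Path, lineage_path: str | Path, scope: str
    ) -> "ReferenceDb":
        from Bio import SeqIO

        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        lin = pd.read_csv(lineage_path, sep="\t", dtype=str).fillna("")
        records = [
            ReferenceRecord(
                row["record_id"],
                Lineage(row["clade"], row["family"], row["genus"], row["species"]),
                seqs[row["record_id"]],
            )
            for _, row in lin.iterrows()
        ]
        return cls(scope=scope, records=records)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        # substitute to one of the three other bases
        idx = np.searchsorted(_BASES, out[hits])
        shift = rng.integers(1, 4, size=hits.size)
        out[hits] = _BASES[(idx + shift) % 4]
    return out


def generate_reference_sets(
    n_families: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    seq_length: int = 300,
    seed: int = 0,
    extra_global_families: int = 1,
    extra_global_species_per_genus: int = 1,
    offtarget_clades: tuple[str, ...] = (),
    n_offtarget_species_per_clade: int = 2,
) -> tuple[ReferenceDb, ReferenceDb]:
    """Generate a (local, global) reference database pair.

    The global database is a superset of the local one: it adds whole
    families and extra congeneric species that are absent locally,
    mimicking a worldwide sequence repository.  Off-target clades (fungi
    etc.) are present in both so clade-based exclusion can be exercised.
    """
    for name, value in (
        ("n_families", n_families),
        ("n_genera_per_family", n_genera_per_family),
        ("n_species_per_genus", n_species_per_genus),
    ):
        if value < 1:
            raise ValueError(f"{name} must be >= 1, got {value}")
    if seq_length < 60:
        raise ValueError(
            "seq_length below 60 cannot resolve the identity bands "
            "(one substitution exceeds the band width)"
        )

    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, seq_length)

    local_records: list[ReferenceRecord] = []
    global_only: list[ReferenceRecord] = []

    def add_family(fam_idx: int, local: bool) -> None:
        fam_root = _mutate(rng, ancestor, _FAMILY_RATE)
        family = f"Family{fam_idx:02d}"
        for g in range(1, n_genera_per_family + 1):
            gen_root = _mutate(rng, fam_root, _GENUS_RATE)
            genus = f"Genus{fam_idx:02d}{g:02d}"
            n_sp = n_species_per_genus + (
                extra_global_species_per_genus if local else 0
            )
            for s in range(1, n_sp + 1):
                seq = _mutate(rng, gen_root, _SPECIES_RATE)
                species = f"{genus}_sp{s:02d}"
                rec = ReferenceRecord(
                    record_id=f"ref_{species}",
                    lineage=Lineage("seed_plants", family, genus, species),
                    sequence=seq.tobytes().decode(),
                )
                if local and s <= n_species_per_genus:
                    local_records.append(rec)
                else:
                    global_only.append(rec)

    for f in range(1, n_families + 1):
        add_family(f, local=True)
    for f in range(n_families + 1, n_families + 1 + extra_global_families):
        add_family(f, local=False)

    # distant off-target references, shared by both scopes
    for clade in offtarget_clades:
        fam = f"{clade.capitalize()}aceae"
        gen_root = _random_seq(rng, seq_length)
        for s in range(1, n_offtarget_species_per_clade + 1):
            seq = _mutate(rng, gen_root, _SPECIES_RATE)
            species = f"{clade}_sp{s:02d}"
            local_records.append(
                ReferenceRecord(
                    record_id=f"ref_{species}",
                    lineage=Lineage(clade, fam, f"{clade.capitalize()}us", species),
                    sequence=seq.tobytes().decode(),
                )
            )

    local_db = ReferenceDb("local", list(local_records))
    global_db = ReferenceDb("global", list(local_records) + global_only)
    return local_db, global_db
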