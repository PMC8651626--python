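"""Amplicon read processing: pair merging, primer trimming, dereplication
and abundance-skew denoising into zero-radius OTUs.

All stages are native re-implementations of the usual read-processing
steps (FLASH-style overlap merging, cutadapt-style primer removal,
vsearch-style dereplication, unoise-style denoising) so the pipeline has
no external binary dependencies and fully deterministic behaviour.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MarkerParams",
    "MARKERS",
    "revcomp",
    "merge_pairs",
    "trim_primers",
    "UniqueSequence",
    "Otu",
    "dereplicate",
    "denoise_unoise",
    "beta_threshold",
    "levenshtein",
]

# ---------------------------------------------------------------------------
# marker registry

@dataclass(frozen=True)
class MarkerParams:
    """Per-marker processing parameters.

    ``min_insert_len`` is the post-trimming length gate; ``min_coverage``
    is the query-coverage gate applied during taxonomic assignment (the
    short plastid-like marker requires full coverage, the nuclear one
    tolerates partial reference records).
    """

    name: str
    fwd_primer: str
    rev_primer: str
    min_insert_len: int
    min_coverage: float


#: Built-in marker models: a short plastid-like loop and a longer
#: nuclear ribosomal spacer-like region.
MARKERS: dict[str, MarkerParams] = {
    "trnL-like": MarkerParams(
        name="trnL-like",
        fwd_primer="GGGCAATCCTGAGCCAA",
        rev_primer="CCATTGAGTCTCTGCACCTATC",
        min_insert_len=8,
        min_coverage=100.0,
    ),
    "nrITS2-like": MarkerParams(
        name="nrITS2-like",
        fwd_primer="ACGAATTCATGGTCCGGTGAAG",
        rev_primer="TCCTCCGCTTATTGATATGC",
        min_insert_len=150,
        min_coverage=90.0,
    ),
}


# ---------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: IUPAC code -> set of concrete bases it matches.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# pair merging

def merge_pairs(
    fwd: str,
    rev: str,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.25,
    fwd_qual: Sequence[int] | None = None,
    rev_qual: Sequence[int] | None = None,
) -> str | None:
    """Overlap-merge a read pair; ``None`` means the pair is rejected.

    The reverse read is reverse-complemented, candidate overlaps of at
    least ``min_overlap`` bases with a mismatch ratio at most
    ``max_mismatch_ratio`` are enumerated, and the longest acceptable
    overlap wins.  Overlap mismatches are resolved toward the base with
    higher quality; without qualities (or on ties) the forward base wins.
    """
    fwd = fwd.upper()
    rc = revcomp(rev.upper())
    rc_qual = list(rev_qual)[::-1] if rev_qual is not None else None
    max_ov = min(len(fwd), len(rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        f_tail = fwd[-ov:]
        r_head = rc[:ov]
        mismatches = sum(a != b for a, b in zip(f_tail, r_head))
        if mismatches / ov <= max_mismatch_ratio:
            overlap = list(f_tail)
            if mismatches:
                off = len(fwd) - ov
                for i in range(ov):
                    if f_tail[i] != r_head[i]:
                        fq = fwd_qual[off + i] if fwd_qual is not None else 0
                        rq = rc_qual[i] if rc_qual is not None else 0
                        if rq > fq:
                            overlap[i] = r_head[i]
            return fwd[:-ov] + "".join(overlap) + rc[ov:]
    return None


# ---------------------------------------------------------------------------
# primer trimming

def _compile_primer(primer: str) -> list[frozenset]:
    try:
        return [IUPAC[c] for c in primer.upper()]
    except KeyError as exc:  # pragma: no cover - input validation
        raise ValueError(f"invalid IUPAC code in primer {primer!r}") from exc


def _mismatches_at(read: str, pat: list[frozenset], pos: int, budget: int) -> int:
    """Mismatch count of ``pat`` at ``pos``; returns budget+1 on early exit."""
    mism = 0
    for i, allowed in enumerate(pat):
        if read[pos + i] not in allowed:
            mism += 1
            if mism > budget:
                return mism
    return mism


def _best_occurrence(
    read: str, pat: list[frozenset], budget: int, prefer_right: bool
) -> int | None:
    """Start position of the best (fewest-mismatch) occurrence, or None.

    Ties go to the leftmost match, or the rightmost when
    ``prefer_right`` (used for the reverse primer at the 3' end).
    """
    plen = len(pat)
    if plen == 0 or len(read) < plen:
        return None
    best_pos, best_mism = None, budget + 1
    positions = range(len(read) - plen, -1, -1) if prefer_right else range(
        len(read) - plen + 1
    )
    for pos in positions:
        mism = _mismatches_at(read, pat, pos, best_mism - 1)
        if mism < best_mism:
            best_pos, best_mism = pos, mism
            if mism == 0:
                break
    return best_pos


def trim_primers(
    read: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch_frac: float = 0.2,
    min_len: int = 1,
) -> str | None:
    """Locate and strip both primers; reject reads failing the gates.

    Both primers must be found within a mismatch budget of
    ``floor(max_mismatch_frac * primer_length)`` (the forward primer near
    the 5' end, the reverse-complemented reverse primer near the 3' end);
    inserts shorter than ``min_len`` are rejected.  Rejection returns
    ``None``.
    """
    read = read.upper()
    fpat = _compile_primer(fwd_primer)
    rpat = _compile_primer(revcomp(rev_primer))
    f_budget = math.floor(max_mismatch_frac * len(fpat))
    r_budget = math.floor(max_mismatch_frac * len(rpat))

    # fast path: primers sitting exactly at the read ends
    if (
        len(read) >= len(fpat) + len(rpat)
        and _mismatches_at(read, fpat, 0, f_budget) <= f_budget
        and _mismatches_at(read, rpat, len(read) - len(rpat), r_budget)
        <= r_budget
    ):
        insert = read[len(fpat): len(read) - len(rpat)]
        return insert if len(insert) >= min_len else None

    f_pos = _best_occurrence(read, fpat, f_budget, prefer_right=False)
    if f_pos is None:
        return None
    tail_start = f_pos + len(fpat)
    tail = read[tail_start:]
    r_pos = _best_occurrence(tail, rpat, r_budget, prefer_right=True)
    if r_pos is None:
        return None
    insert = tail[:r_pos]
    return insert if len(insert) >= min_len else None


# ---------------------------------------------------------------------------
# dereplication

@dataclass
class UniqueSequence:
    """An exact sequence with its total and per-occurrence abundances."""

    sequence: str
    total: int
    counts: dict[str, int] = field(default_factory=dict)

    def count(self, occurrence_id: str) -> int:
        return self.counts.get(occurrence_id, 0)


def dereplicate(reads_per_occurrence: Mapping[str, Iterable[str]]) -> list[UniqueSequence]:
    """Exact-sequence dereplication, sorted by decreasing total abundance.

    Abundance ties break lexicographically by sequence for determinism.
    """
    per_seq: dict[str, dict[str, int]] = {}
    for occ, reads in reads_per_occurrence.items():
        for seq, n in Counter(reads).items():
            per_seq.setdefault(seq, {})[occ] = n
    uniques = [
        UniqueSequence(seq, sum(counts.values()), counts)
        for seq, counts in per_seq.items()
    ]
    uniques.sort(key=lambda u: (-u.total, u.sequence))
    return uniques


# ---------------------------------------------------------------------------
# denoising

def beta_threshold(d: int, alpha: float = 2.0) -> float:
    """Maximum abundance skew at which a variant at edit distance ``d``
    may be folded into a centroid: ``1 / 2**(alpha * d + 1)``."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def levenshtein(a: str, b: str, max_dist: int) -> int | None:
    """Banded Levenshtein distance; ``None`` if it exceeds ``max_dist``."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if abs(la - lb) > max_dist:
        return None
    if la > lb:  # keep the inner loop over the longer string's band
        a, b, la, lb = b, a, lb, la
    big = max_dist + 1
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        lo = max(1, i - max_dist)
        hi = min(lb, i + max_dist)
        cur = [big] * (lb + 1)
        cur[0] = i if i <= max_dist else big
        ca = a[i - 1]
        row_min = cur[0] if lo == 1 else big
        for j in range(lo, hi + 1):
            cost = 0 if ca == b[j - 1] else 1
            v = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            cur[j] = v
            if v < row_min:
                row_min = v
        if row_min > max_dist:
            return None
        prev = cur
    d = prev[lb]
    return d if d <= max_dist else None


@dataclass
class Otu:
    """A zero-radius OTU: centroid plus folded-in error variants."""

    otu_id: str
    sequence: str
    total: int
    counts: dict[str, int] = field(default_factory=dict)
    members: list[UniqueSequence] = field(default_factory=list)
    is_chimera: bool = False

    def count(self, occurrence_id: str) -> int:
        return self.counts.get(occurrence_id, 0)


# β(d) is largest at d=1, so the deepest useful band for a given skew r
# is d ≤ (log2(1/r) - 1) / α; nothing beyond MAX_BAND is ever mergeable.
MAX_BAND = 10


def denoise_unoise(
    uniques: Sequence[UniqueSequence],
    alpha: float = 2.0,
    min_abundance: int = 10,
    detect_chimeras: bool = False,
) -> list[Otu]:
    """Greedy abundance-skew denoising into zero-radius OTUs.

    Uniques below ``min_abundance`` total reads are discarded before
    clustering.  Remaining uniques are visited in decreasing-abundance
    order; a unique at edit distance ``d >= 1`` from a centroid ``C`` is
    folded into ``C`` when ``abundance/abundance(C) <= beta(d)``, choosing
    the centroid with the largest margin ``beta(d) * abundance(C)`` (ties
    go to the most abundant centroid); otherwise it seeds a new centroid.

    With ``detect_chimeras`` a centroid whose sequence is an exact
    two-segment concatenation of a prefix and a suffix of two distinct
    more-abundant centroids is flagged (not removed).
    """
    totals = [u.total for u in uniques]
    if any(totals[i] < totals[i + 1] for i in range(len(totals) - 1)):
        raise ValueError("uniques must be sorted by decreasing abundance")

    kept = [u for u in uniques if u.total >= min_abundance]
    otus: list[Otu] = []
    for u in kept:
        best: Otu | None = None
        best_key = (-math.inf, -math.inf)
        for otu in otus:
            ratio = u.total / otu.total
            if ratio > beta_threshold(1, alpha):
                continue  # cannot merge at any d >= 1
            dmax = min(MAX_BAND, int((math.log2(1.0 / ratio) - 1.0) / alpha))
            if dmax < 1:
                continue
            d = levenshtein(u.sequence, otu.sequence, dmax)
            if d is None or d < 1:
                continue
            # margin of the skew test; ties go to the larger centroid
            key = (beta_threshold(d, alpha) * otu.total, otu.total)
            if key > best_key:
                best, best_key = otu, key
        if best is not None:
            best.total += u.total
            for occ, n in u.counts.items():
                best.counts[occ] = best.counts.get(occ, 0) + n
            best.members.append(u)
        else:
            otus.append(
                Otu(
                    otu_id=f"OTU_{len(otus) + 1:04d}",
                    sequence=u.sequence,
                    total=u.total,
                    counts=dict(u.counts),
                    members=[u],
                )
            )

    if detect_chimeras:
        _flag_chimeras(otus)
    return otus


def _flag_chimeras(otus: list[Otu]) -> None:
    """Flag centroids that are exact two-parent concatenations."""
    for idx, otu in enumerate(otus):
        parents = [p for p in otus[:idx] if p.total > otu.total]
        seq = otu.sequence
        found = False
        for i in range(1, len(seq)):
            head, tail = seq[:i], seq[i:]
            for pa in parents:
                if not pa.sequence.startswith(head):
                    continue
                for pb in parents:
                    if pb is not pa and pb.sequence.endswith(tail):
                        found = True
                        break
                if found:
                    break
            if found:
                break
        otu.is_chimera = found
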