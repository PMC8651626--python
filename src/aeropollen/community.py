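"""Community comparison: Bray-Curtis distances, one-factor perMANOVA with
permutation p-values, and Kruskal-style NMDS, all first-principles
implementations."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "bray_curtis",
    "PermanovaResult",
    "permanova",
    "NmdsResult",
    "nmds",
    "isotonic_fit",
]


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity of table rows:
    ``d(x, y) = sum|x-y| / sum(x+y)``."""
    x = table.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative data")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        raise ValueError(
            "two all-zero rows: Bray-Curtis undefined for that pair"
        )
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# perMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _f_and_r2(d2: np.ndarray, order: np.ndarray, group_slices) -> tuple[float, float]:
    """Pseudo-F and R^2 for group memberships given by ``order`` indices."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for sl in group_slices:
        idx = order[sl]
        sub = d2[np.ix_(idx, idx)]
        n_g = idx.size
        ss_within += sub[np.triu_indices(n_g, 1)].sum() / n_g
    ss_between = ss_total - ss_within
    a = len(group_slices)
    if ss_within == 0.0:
        return math.inf, ss_between / ss_total
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int | None = None,
    permutations: str = "random",
) -> PermanovaResult:
    """One-factor perMANOVA on a distance matrix.

    ``p = (1 + #{permuted F >= observed F}) / (1 + n_perm)`` with labels
    shuffled uniformly at random; ``permutations="all"`` enumerates every
    label ordering instead (p becomes the exhaustive tail probability,
    the identity ordering included).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    groups = np.asarray(list(groups))
    if groups.size != n:
        raise ValueError("one group label per row required")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")

    d2 = d**2
    # canonical ordering: indices sorted by group, groups as contiguous slices
    order0 = np.argsort(groups, kind="stable")
    slices = []
    start = 0
    for c in counts:
        slices.append(slice(start, start + c))
        start += c
    f_obs, r2 = _f_and_r2(d2, order0, slices)

    if permutations == "all":
        count_ge = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f_p, _ = _f_and_r2(d2, np.asarray(perm), slices)
            total += 1
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        return PermanovaResult(f_obs, r2, count_ge / total, total, seed)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _ = _f_and_r2(d2, perm, slices)
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)


# ---------------------------------------------------------------------------
# NMDS

def isotonic_fit(values: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators fit of ``values`` ordered by
    ``keys``; tied keys are pooled first (primary tie treatment with
    averaging within tie blocks)."""
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    sorted_vals = values[order]
    # pool tie blocks of the ordering key
    block_vals: list[float] = []
    block_w: list[int] = []
    block_members: list[list[int]] = []
    i = 0
    m = len(sorted_keys)
    while i < m:
        j = i
        while j < m and sorted_keys[j] == sorted_keys[i]:
            j += 1
        block_vals.append(float(sorted_vals[i:j].mean()))
        block_w.append(j - i)
        block_members.append(list(range(i, j)))
        i = j
    # PAVA over blocks
    vals: list[float] = []
    ws: list[int] = []
    members: list[list[int]] = []
    for v, w, mem in zip(block_vals, block_w, block_members):
        vals.append(v)
        ws.append(w)
        members.append(list(mem))
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2 = (vals[-2] * ws[-2] + vals[-1] * ws[-1]) / (ws[-2] + ws[-1])
            w2 = ws[-2] + ws[-1]
            mem2 = members[-2] + members[-1]
            vals = vals[:-2] + [v2]
            ws = ws[:-2] + [w2]
            members = members[:-2] + [mem2]
    fitted_sorted = np.empty(m)
    for v, mem in zip(vals, members):
        for k in mem:
            fitted_sorted[k] = v
    fitted = np.empty(m)
    fitted[order] = fitted_sorted
    return fitted


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    best_start: int
    seed: int | None
    stress_trace: list[float] = field(default_factory=list)


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _stress1(delta: np.ndarray, dhat: np.ndarray) -> float:
    denom = (delta**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dhat - delta) ** 2).sum() / denom)


def nmds(
    dist: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NmdsResult:
    """Nonmetric MDS minimising Kruskal stress-1.

    Each random start alternates a monotone (pool-adjacent-violators)
    regression of configuration distances on the rank order of the input
    dissimilarities with a Guttman-transform configuration update;
    step-halving toward the previous configuration guarantees the stress
    trace is non-increasing within a start.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 4:
        raise ValueError("need a square distance matrix with n >= 4")
    iu = np.triu_indices(n, 1)
    diss = d[iu]

    rng = np.random.default_rng(seed)
    best: NmdsResult | None = None
    for start in range(n_starts):
        x = rng.normal(size=(n, k))
        delta_m = _config_distances(x)
        delta = delta_m[iu]
        dhat = isotonic_fit(delta, diss)
        stress = _stress1(delta, dhat)
        trace = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform toward the current disparities
            dhat_m = np.zeros_like(d)
            dhat_m[iu] = dhat
            dhat_m += dhat_m.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(delta_m > 0, dhat_m / delta_m, 0.0)
            b = -ratio
            np.fill_diagonal(b, 0.0)
            np.fill_diagonal(b, -b.sum(axis=1))
            x_new = b @ x / n

            # step-halve if normalised stress would increase
            accepted = False
            for _half in range(12):
                delta_m_new = _config_distances(x_new)
                delta_new = delta_m_new[iu]
                dhat_new = isotonic_fit(delta_new, diss)
                stress_new = _stress1(delta_new, dhat_new)
                if stress_new <= stress + 1e-15:
                    accepted = True
                    break
                x_new = 0.5 * (x_new + x)
            if not accepted:
                converged = True
                break
            improvement = stress - stress_new
            x, delta_m, delta, dhat, stress = (
                x_new, delta_m_new, delta_new, dhat_new, stress_new,
            )
            trace.append(stress)
            if improvement < tol:
                converged = True
                break
        x = x - x.mean(axis=0)
        if best is None or stress < best.stress:
            best = NmdsResult(
                coordinates=x,
                stress=stress,
                converged=converged,
                best_start=start,
                seed=seed,
                stress_trace=trace,
            )
    assert best is not None
    return best
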