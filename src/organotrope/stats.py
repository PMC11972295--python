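"""Exact and rank statistics shared by all pipeline stages.

Contains the 2 x k Fisher exact test (the k = 3 case is the Freeman-Halton
extension, computed by full enumeration of the margin-conditioned table
space), Benjamini-Hochberg step-up FDR control, the Kruskal-Wallis omnibus
test with Dunn post-hoc z tests, and the log2 frequency ratio used in the
cohort comparison tables.

Two-sidedness of the exact tests follows the "probability at most that of
the observed table" rule: the p-value sums the hypergeometric probabilities
of every table with the observed margins whose probability does not exceed
the observed table's (within a relative tolerance of 1e-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

_REL_TOL = 1e-7


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact test for a 2 x k table (k = 2 or 3).

    Rows are event present/absent, columns are groups (metastatic sites).
    The null conditions on all margins; the table probability is the
    multivariate hypergeometric mass.  Any zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("expected a 2 x k table with k >= 2")
    if (t < 0).any():
        raise ValueError("negative count in contingency table")
    col = t.sum(axis=0)
    r = int(t[0].sum())
    n = int(t.sum())
    if r == 0 or r == n or (col == 0).any():
        return 1.0

    # enumerate all first-row compositions a with 0 <= a_j <= col_j, sum = r
    k = t.shape[1]
    grids = np.meshgrid(
        *[np.arange(c + 1) for c in col[:-1]], indexing="ij"
    )
    a_partial = np.stack([g.ravel() for g in grids], axis=1) if k > 1 else None
    last = r - a_partial.sum(axis=1)
    ok = (last >= 0) & (last <= col[-1])
    a = np.column_stack([a_partial[ok], last[ok]])

    logp = _log_comb(col[None, :], a).sum(axis=1) - _log_comb(n, r)
    obs = _log_comb(col, t[0]).sum() - _log_comb(n, r)
    keep = logp <= obs + np.log1p(_REL_TOL)
    p = float(np.exp(logp[keep]).sum())
    return min(p, 1.0)


@dataclass
class PValueSet:
    """Raw p-values with their BH-adjusted counterparts."""

    raw: np.ndarray
    adjusted: np.ndarray
    method: str = "BH"


def bh_adjust(raw) -> PValueSet:
    """Benjamini-Hochberg step-up adjustment, monotonized and capped at 1."""
    p = np.asarray(raw, dtype=float)
    if p.size == 0:
        return PValueSet(raw=p, adjusted=p.copy())
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return PValueSet(raw=p, adjusted=adj)


@dataclass
class KruskalDunnResult:
    """Omnibus Kruskal-Wallis H plus pairwise Dunn z tests (BH-adjusted)."""

    h: float
    omnibus_p: float
    pairs: list[tuple[int, int]]
    z: np.ndarray
    pairwise_p: np.ndarray
    pairwise_q: np.ndarray


def kruskal_dunn(groups) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with two-sided Dunn post-hoc tests.

    Tie correction is applied to both the omnibus statistic (via scipy) and
    the Dunn z denominators; pairwise p-values use the normal approximation
    and are BH-adjusted across the k(k-1)/2 pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, omni_p = 0.0, 1.0
    else:
        h, omni_p = sps.kruskal(*groups)

    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term

    pairs, zs, ps = [], [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((i, j))
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(abs(z)))
    adj = bh_adjust(ps).adjusted
    return KruskalDunnResult(
        h=float(h), omnibus_p=float(omni_p), pairs=pairs,
        z=np.array(zs), pairwise_p=np.array(ps), pairwise_q=adj,
    )


def log2_frequency_ratio(f_num: float, f_den: float) -> float:
    """log2 of a frequency ratio; both frequencies must lie in (0, 1].

    Callers must apply the minimum-occurrence filter first so neither
    frequency is zero.
    """
    if not (0.0 < f_num <= 1.0) or not (0.0 < f_den <= 1.0):
        raise ValueError("frequencies must lie in (0, 1]")
    return float(np.log2(f_num / f_den))
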