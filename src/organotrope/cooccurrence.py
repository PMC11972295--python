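"""Exact probabilistic pairwise co-occurrence testing of binary genomic events.

For two events observed in ``n_a`` and ``n_b`` of ``N`` samples, the null
distribution of the number of joint carriers ``j`` conditions on both
marginal counts: placements of the two event sets are exchangeable, giving
the hypergeometric mass

    P(j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b)

over the feasible range ``max(0, n_a + n_b - N) <= j <= min(n_a, n_b)``.
Both tail probabilities include the observed ``j`` (so p_lt + p_gt >= 1):
a significantly large upper tail is a positive association (co-occurrence),
a significantly small lower tail a negative one (mutual exclusivity).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ci_data import CIMatrix
from .stats import bh_adjust, _log_comb

logger = logging.getLogger(__name__)


def cooccurrence_distribution(N: int, n_a: int, n_b: int):
    """Null pmf of the joint-carrier count.

    Returns ``(j_values, pmf)`` over the feasible range; computed in log
    space.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError("need 0 <= n_a, n_b <= N")
    j_lo = max(0, n_a + n_b - N)
    j_hi = min(n_a, n_b)
    j = np.arange(j_lo, j_hi + 1)
    logp = (
        _log_comb(n_a, j)
        + _log_comb(N - n_a, n_b - j)
        - _log_comb(N, n_b)
    )
    return j, np.exp(logp)


@dataclass
class PairCooccurrence:
    """Result of the exact co-occurrence test for one event pair."""

    event_a: str
    event_b: str
    N: int
    n_a: int
    n_b: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    q_lt: float = np.nan
    q_gt: float = np.nan
    label: str = "ns"  # "positive" | "negative" | "ns"


def test_pair(x_a, x_b, event_a: str = "a", event_b: str = "b",
              alpha: float = 0.05) -> PairCooccurrence:
    """Exact two-tailed co-occurrence test on two binary columns.

    Inputs are presence vectors (nonzero = event present).  A constant
    column yields a degenerate null and p = 1 in both tails ("ns").
    When used stand-alone (no screen-wide BH), q equals the raw p and the
    label is assigned at *alpha* on the raw tails.
    """
    a = np.asarray(x_a) > 0
    b = np.asarray(x_b) > 0
    if a.shape != b.shape:
        raise ValueError("columns differ in length")
    N = int(a.size)
    n_a, n_b = int(a.sum()), int(b.sum())
    j_obs = int((a & b).sum())
    j, pmf = cooccurrence_distribution(N, n_a, n_b)
    p_lt = float(pmf[j <= j_obs].sum())
    p_gt = float(pmf[j >= j_obs].sum())
    p_lt, p_gt = min(p_lt, 1.0), min(p_gt, 1.0)
    res = PairCooccurrence(
        event_a=event_a, event_b=event_b, N=N, n_a=n_a, n_b=n_b,
        j_obs=j_obs, expected=n_a * n_b / N if N else 0.0,
        p_lt=p_lt, p_gt=p_gt, q_lt=p_lt, q_gt=p_gt,
    )
    constant = n_a in (0, N) or n_b in (0, N)
    if not constant:
        if res.q_gt < alpha:
            res.label = "positive"
        elif res.q_lt < alpha:
            res.label = "negative"
    return res


def _structurally_exclusive(label_a: str, label_b: str) -> bool:
    """Gain and loss of the same region can never co-occur by encoding."""
    if label_a[0] == label_b[0]:
        return False

    def region(label: str) -> str:
        return label.lstrip("+-").removesuffix(" amp")

    return region(label_a) == region(label_b)


@dataclass
class CooccurrenceScreen:
    """All-pairs co-occurrence screen with joint BH control."""

    table: pd.DataFrame
    n_candidate_pairs: int
    alpha: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def signed_matrix(self) -> pd.DataFrame:
        """Square matrix of signed -log10(q) for heat-mapping.

        Positive associations carry +, negative -, non-significant 0.
        """
        names = sorted(set(self.table["event_a"]) | set(self.table["event_b"]))
        m = pd.DataFrame(0.0, index=names, columns=names)
        for row in self.table.itertuples():
            if row.label == "positive":
                v = -np.log10(max(row.q_gt, 1e-300))
            elif row.label == "negative":
                v = -(-np.log10(max(row.q_lt, 1e-300)))
            else:
                continue
            m.loc[row.event_a, row.event_b] = v
            m.loc[row.event_b, row.event_a] = v
        return m


def cooccurrence_screen(
    matrix: CIMatrix,
    extra_tracks: pd.DataFrame | None = None,
    min_freq: int = 3,
    min_expected: float = 1.0,
    alpha: float = 0.05,
) -> CooccurrenceScreen:
    """Test all unordered event pairs for positive/negative co-occurrence.

    Binary tracks (e.g. mutation indicators) may be appended via
    *extra_tracks* (DataFrame indexed like the matrix samples).  Pairs where
    either event occurs fewer than *min_freq* times, or whose expected joint
    count is below *min_expected*, are excluded; gain/loss pairs of the same
    region are structurally exclusive and skipped.  BH is applied jointly
    over both tails of every retained pair.
    """
    cols = matrix.binary()
    if extra_tracks is not None:
        extra = extra_tracks.reindex(cols.index)
        if extra.isna().any().any():
            raise ValueError("extra tracks missing samples present in matrix")
        cols = pd.concat([cols, (extra > 0).astype(np.int8)], axis=1)
    names = list(cols.columns)
    X = cols.to_numpy()
    N = X.shape[0]
    counts = X.sum(axis=0)

    results: list[PairCooccurrence] = []
    n_candidates = 0
    n_skipped_structural = 0
    for i, k in itertools.combinations(range(len(names)), 2):
        n_candidates += 1
        if _structurally_exclusive(names[i], names[k]):
            n_skipped_structural += 1
            continue
        if counts[i] < min_freq or counts[k] < min_freq:
            continue
        if counts[i] * counts[k] / N < min_expected:
            continue
        results.append(test_pair(X[:, i], X[:, k], names[i], names[k]))
    if n_skipped_structural:
        logger.info(
            "skipped %d structurally exclusive gain/loss pair(s)",
            n_skipped_structural,
        )

    if results:
        raw = np.array([[r.p_lt, r.p_gt] for r in results]).ravel()
        q = bh_adjust(raw).adjusted.reshape(-1, 2)
        for r, (q_lt, q_gt) in zip(results, q):
            r.q_lt, r.q_gt = float(q_lt), float(q_gt)
            if r.n_a in (0, r.N) or r.n_b in (0, r.N):
                r.label = "ns"
            elif r.q_gt < alpha:
                r.label = "positive"
            elif r.q_lt < alpha:
                r.label = "negative"
            else:
                r.label = "ns"

    table = pd.DataFrame(
        [
            {
                "event_a": r.event_a, "event_b": r.event_b, "N": r.N,
                "n_a": r.n_a, "n_b": r.n_b, "j_obs": r.j_obs,
                "expected": r.expected, "p_lt": r.p_lt, "p_gt": r.p_gt,
                "q_lt": r.q_lt, "q_gt": r.q_gt, "label": r.label,
            }
            for r in results
        ],
        columns=["event_a", "event_b", "N", "n_a", "n_b", "j_obs",
                 "expected", "p_lt", "p_gt", "q_lt", "q_gt", "label"],
    )
    return CooccurrenceScreen(table=table, n_candidate_pairs=n_candidates,
                              alpha=alpha)
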