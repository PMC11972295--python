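"""The organotropic map: site-enrichment analysis of CI events.

Each CI event observed in the metastasis cohort (one lesion per patient) is
tested for unequal relative frequency across the three secondary sites
(liver, lung, brain) with an omnibus 2 x 3 Fisher exact test, BH-adjusted
across events.  For omnibus-significant events, the top-frequency site is
compared pairwise (2 x 2 Fisher, BH across all pairwise tests) against the
other two; the enriched-site set is the top site plus every site not
significantly below it.  Barycentric (ternary) coordinates
``c_s = f_s / sum(f)`` position each event in the liver-lung-brain simplex
for plotting; the bubble size is the event's overall frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ci_data import SITES, CIMatrix, CohortTable, select_one_met_per_patient
from .stats import bh_adjust, fisher_exact

logger = logging.getLogger(__name__)


def compute_site_frequencies(
    matrix: CIMatrix,
    meta: CohortTable,
    min_count: int = 3,
    include_sex_chromosomes: bool = False,
) -> pd.DataFrame:
    """Per-event counts and relative frequencies per metastatic site.

    *meta* must contain metastasis samples only, one per patient (apply
    :func:`organotrope.ci_data.select_one_met_per_patient` first).  Events
    observed fewer than *min_count* times across all metastases are dropped;
    gains and losses of the same arm are distinct events.  Sex-chromosome
    events are excluded by default.
    """
    t = meta.table
    if (t["site"] == "primary").any():
        raise ValueError("meta must be restricted to metastases")
    if t["patient"].duplicated().any():
        raise ValueError("meta must hold one metastasis per patient")
    n_site = {s: int((t["site"] == s).sum()) for s in SITES}
    for s, n in n_site.items():
        if n == 0:
            raise ValueError(f"site {s!r} has no samples")

    sub = matrix.subset_samples(list(t["sample"]))
    present = sub.binary().to_numpy()
    site_of = t["site"].to_numpy()

    rows = []
    for j, ev in enumerate(sub.events):
        if not include_sex_chromosomes and ev.chromosome in ("X", "Y"):
            continue
        counts = {s: int(present[site_of == s, j].sum()) for s in SITES}
        total = sum(counts.values())
        if total < min_count:
            continue
        row = {"event": ev.canonical()}
        for s in SITES:
            row[f"count_{s}"] = counts[s]
            row[f"n_{s}"] = n_site[s]
            row[f"f_{s}"] = counts[s] / n_site[s]
        row["f_overall"] = total / sum(n_site.values())
        rows.append(row)
    cols = ["event"]
    for s in SITES:
        cols += [f"count_{s}", f"n_{s}", f"f_{s}"]
    cols.append("f_overall")
    return pd.DataFrame(rows, columns=cols)


@dataclass
class OrganotropicMapResult:
    """Fitted organotropic map.

    ``table`` has one row per retained event with counts, frequencies,
    ternary coordinates, omnibus p/q, pairwise q's against the top site,
    the enriched-site set (semicolon-joined; empty when q >= alpha) and the
    bubble size (overall frequency).
    """

    table: pd.DataFrame
    alpha: float
    min_count: int

    @property
    def enriched_events(self) -> pd.DataFrame:
        return self.table[self.table["enriched_sites"] != ""]

    def enriched_sites(self, event: str) -> frozenset:
        row = self.table[self.table["event"] == event]
        if row.empty:
            raise KeyError(event)
        s = row["enriched_sites"].iloc[0]
        return frozenset(s.split(";")) if s else frozenset()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n_sig = int((self.table["enriched_sites"] != "").sum())
        lines = [
            "Organotropic map",
            f"  events tested: {len(self.table)} (min_count={self.min_count})",
            f"  organotropic events (q < {self.alpha:g}): {n_sig}",
        ]
        for row in self.enriched_events.itertuples():
            lines.append(
                f"    {row.event:>12s}  q={row.q:0.3g}  "
                f"sites={row.enriched_sites}  "
                f"f=({row.f_liver:0.3f}, {row.f_lung:0.3f}, {row.f_brain:0.3f})"
            )
        return "\n".join(lines)


def organotropic_map(freqs: pd.DataFrame, alpha: float = 0.05,
                     min_count: int = 3) -> OrganotropicMapResult:
    """Enrichment testing and ternary projection of per-site frequencies.

    *freqs* is the output of :func:`compute_site_frequencies`.  Events with
    fewer than one surviving row yield an empty result.
    """
    if freqs.empty:
        empty = freqs.assign(
            **{c: pd.Series(dtype=float) for c in
               ("c_liver", "c_lung", "c_brain", "p", "q")},
            enriched_sites=pd.Series(dtype=str),
            bubble_size=pd.Series(dtype=float),
        )
        return OrganotropicMapResult(table=empty, alpha=alpha,
                                     min_count=min_count)

    freqs = freqs.reset_index(drop=True).copy()
    fsum = sum(freqs[f"f_{s}"] for s in SITES)
    for s in SITES:
        freqs[f"c_{s}"] = np.where(fsum > 0, freqs[f"f_{s}"] / fsum, np.nan)

    pvals = []
    for row in freqs.itertuples():
        tab = np.array(
            [
                [getattr(row, f"count_{s}") for s in SITES],
                [getattr(row, f"n_{s}") - getattr(row, f"count_{s}")
                 for s in SITES],
            ]
        )
        pvals.append(fisher_exact(tab))
    freqs["p"] = pvals
    freqs["q"] = bh_adjust(pvals).adjusted

    # pairwise follow-up for omnibus-significant events, BH pooled over all
    # pairwise tests
    pairwise: list[tuple[int, str, float]] = []  # (row idx, other site, p)
    top_site: dict[int, str] = {}
    for idx, row in freqs.iterrows():
        if row["q"] >= alpha:
            continue
        f_by_site = {s: row[f"f_{s}"] for s in SITES}
        s_top = max(SITES, key=lambda s: (f_by_site[s], -SITES.index(s)))
        top_site[idx] = s_top
        for other in SITES:
            if other == s_top:
                continue
            tab = np.array(
                [
                    [row[f"count_{s_top}"], row[f"count_{other}"]],
                    [
                        row[f"n_{s_top}"] - row[f"count_{s_top}"],
                        row[f"n_{other}"] - row[f"count_{other}"],
                    ],
                ]
            )
            pairwise.append((idx, other, fisher_exact(tab)))

    q_pair = (
        bh_adjust([p for (_, _, p) in pairwise]).adjusted
        if pairwise else np.array([])
    )
    pair_q_by_event: dict[int, dict[str, float]] = {}
    for (idx, other, _), q in zip(pairwise, q_pair):
        pair_q_by_event.setdefault(idx, {})[other] = float(q)

    enriched_col = []
    pair_cols: dict[str, list] = {f"q_vs_{s}": [] for s in SITES}
    for idx in freqs.index:
        for s in SITES:
            pair_cols[f"q_vs_{s}"].append(
                pair_q_by_event.get(idx, {}).get(s, np.nan)
            )
        if idx not in top_site:
            enriched_col.append("")
            continue
        s_top = top_site[idx]
        enriched = {s_top}
        for other, q in pair_q_by_event.get(idx, {}).items():
            if q >= alpha:  # not significantly below the top site
                enriched.add(other)
        enriched_col.append(";".join(s for s in SITES if s in enriched))
    freqs["enriched_sites"] = enriched_col
    for c, vals in pair_cols.items():
        freqs[c] = vals
    freqs["bubble_size"] = freqs["f_overall"]
    return OrganotropicMapResult(table=freqs, alpha=alpha, min_count=min_count)


class OrganotropicMap:
    """Model object: CI matrix + cohort metadata -> organotropic map.

    Applies the one-metastasis-per-patient filter, computes per-site event
    frequencies with the minimum-occurrence threshold, and fits the
    enrichment tests.  ``fit`` returns an :class:`OrganotropicMapResult`.
    """

    def __init__(self, matrix: CIMatrix, meta: CohortTable,
                 one_met_per_patient: bool = True):
        self.matrix = matrix
        self.meta = (
            select_one_met_per_patient(matrix, meta)
            if one_met_per_patient else meta
        )

    def fit(self, alpha: float = 0.05, min_count: int = 3,
            include_sex_chromosomes: bool = False) -> OrganotropicMapResult:
        freqs = compute_site_frequencies(
            self.matrix, self.meta, min_count=min_count,
            include_sex_chromosomes=include_sex_chromosomes,
        )
        return organotropic_map(freqs, alpha=alpha, min_count=min_count)
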