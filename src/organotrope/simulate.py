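"""Synthetic tumor-evolution cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a cohort of colorectal-cancer patients whose tumors accumulate CI
events along a shared oncogenetic tree (truncal losses/gains first, rarer
events deeper), disseminate to a metastatic site at a uniformly random
point of their acquisition order, and continue evolving at the secondary
site with site-specific enrichment multipliers on designated events.
Metastases therefore share truncal events with their primaries, designated
events are enriched at their sites, and the per-site CI burden is ordered
brain > liver > lung.  Observation noise flips each tree-event cell with a
symmetric rate ``epsilon``; focal events are added as independent
Bernoulli noise columns.

Every draw flows from a single seeded generator, so equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ci_data import SITES, CIEvent, CIMatrix, CohortTable
from .oncotree import ROOT, OncogeneticTreeResult, classify_event_timing

logger = logging.getLogger(__name__)

# CRC-like true tree: (event, parent, theta).  Truncal events (-18q, +13q,
# -17p children) are frequent; the four brain-designated events (-3q, +5q,
# -6q, +12p) sit deeper with small conditional probabilities, so they are
# late by construction.
DEFAULT_TREE: tuple[tuple[str, str, float], ...] = (
    ("-18q", ROOT, 0.75),
    ("+13q", ROOT, 0.70),
    ("-17p", ROOT, 0.55),
    ("+20q", "-18q", 0.65),
    ("-8p", "-18q", 0.60),
    ("-18p", "-18q", 0.50),
    ("+8q", "-8p", 0.80),
    ("+7p", "+13q", 0.55),
    ("+16p", "+13q", 0.40),
    ("+16q", "+16p", 0.70),
    ("+20p", "+20q", 0.55),
    ("-1p", "-17p", 0.45),
    ("-14q", "-17p", 0.40),
    ("-4q", "-1p", 0.45),
    ("-3q", "-17p", 0.30),
    ("+5q", "-17p", 0.28),
    ("-6q", "-17p", 0.26),
    ("+12p", "+7p", 0.33),
)

# the nine liver-and-brain-tropic events (enriched at both sites, more
# strongly in brain) and the four brain-tropic events (multiplier 3)
LIVER_BRAIN_EVENTS = ("+7p", "-8p", "+8q", "+13q", "+16p", "+16q", "-18p",
                      "+20p", "+20q")
BRAIN_EVENTS = ("-3q", "+5q", "-6q", "+12p")

DEFAULT_MULTIPLIERS: dict[str, dict[str, float]] = {
    **{e: {"liver": 1.5, "brain": 2.0} for e in LIVER_BRAIN_EVENTS},
    **{e: {"brain": 3.0} for e in BRAIN_EVENTS},
}

DEFAULT_FOCAL_EVENTS = ("+8q24", "-4p15", "+6p21", "-9p21", "+11q13",
                        "-10q23", "+17q21", "-2q22")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_patients: int = 200
    site_mix: dict[str, float] = field(
        default_factory=lambda: {"liver": 0.45, "lung": 0.35, "brain": 0.20}
    )
    tree: tuple[tuple[str, str, float], ...] = DEFAULT_TREE
    multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_MULTIPLIERS.items()}
    )
    epsilon: float = 0.01
    focal_events: tuple[str, ...] = DEFAULT_FOCAL_EVENTS
    focal_rate: float = 0.05
    p_primary_sample: float = 0.5
    p_second_met: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.site_mix.get(s, 0.0) for s in SITES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("site mix proportions must sum to 1")
        names = [e for e, _, _ in self.tree]
        if len(set(names)) != len(names):
            raise ValueError("duplicate event in tree")
        known = set(names) | {ROOT}
        for e, parent, theta in self.tree:
            if parent not in known:
                raise ValueError(f"event {e!r} has unknown parent {parent!r}")
            if not (0.0 < theta <= 1.0):
                raise ValueError(f"theta for {e!r} outside (0, 1]")
        for e in self.multipliers:
            if e not in known:
                raise ValueError(f"multiplier for unknown event {e!r}")

    @property
    def events(self) -> list[str]:
        return [e for e, _, _ in self.tree]

    @property
    def parent(self) -> dict[str, str]:
        return {e: p for e, p, _ in self.tree}

    @property
    def theta(self) -> dict[str, float]:
        return {e: t for e, _, t in self.tree}

    def multiplier(self, event: str, site: str) -> float:
        return self.multipliers.get(event, {}).get(site, 1.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    config: SimulationConfig
    enriched_sites: dict[str, frozenset]  # event -> designated sites
    timing_class: dict[str, int]  # true tree timing class (9 bins)
    parent: dict[str, str]  # true tree parent map
    patients: dict[str, dict]  # patient -> acquisition record

    def true_tree(self) -> OncogeneticTreeResult:
        cfg = self.config
        marginal = {}
        for e in cfg.events:
            f, v = 1.0, e
            while v != ROOT:
                f *= cfg.theta[v]
                v = cfg.parent[v]
            marginal[e] = f
        return OncogeneticTreeResult(
            events=list(cfg.events), parent=dict(cfg.parent),
            theta=dict(cfg.theta), epsilon=cfg.epsilon,
            loglik=float("nan"), frequencies=marginal, n_samples=0,
        )


def _topological_events(config: SimulationConfig) -> list[str]:
    order, placed = [], {ROOT}
    pending = list(config.events)
    while pending:
        for e in list(pending):
            if config.parent[e] in placed:
                order.append(e)
                placed.add(e)
                pending.remove(e)
    return order


def _effective_theta(config: SimulationConfig,
                     site: str | None) -> dict[str, float]:
    """Site-multiplied conditional probabilities, clipped to 1.

    Clipping is reported once (per call) as a warning.
    """
    if site is None:
        return dict(config.theta)
    out, clipped = {}, []
    for e in config.events:
        p = config.theta[e] * config.multiplier(e, site)
        if p > 1.0:
            clipped.append(e)
            p = 1.0
        out[e] = p
    if clipped:
        logger.warning(
            "site %s: theta x multiplier clipped to 1 for: %s",
            site, ", ".join(clipped),
        )
    return out


def _acquire(config: SimulationConfig, rng, base: set[str],
             theta: dict[str, float]) -> set[str]:
    """One top-down Bernoulli pass; events in *base* are kept."""
    acquired = set(base)
    for e in _topological_events(config):
        if e in acquired:
            continue
        if config.parent[e] != ROOT and config.parent[e] not in acquired:
            continue
        if rng.random() < theta[e]:
            acquired.add(e)
    return acquired


def _acquisition_order(config: SimulationConfig, rng,
                       acquired: set[str]) -> list[str]:
    """Uniform random linear extension of the tree order on *acquired*."""
    order: list[str] = []
    placed = {ROOT}
    remaining = set(acquired)
    while remaining:
        frontier = sorted(
            e for e in remaining if config.parent[e] in placed
        )
        pick = frontier[rng.integers(len(frontier))]
        order.append(pick)
        placed.add(pick)
        remaining.remove(pick)
    return order


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CIMatrix, CohortTable, GroundTruth]:
    """Simulate a metastatic cohort from the configured true tree.

    Per patient: the primary lineage accumulates events top-down along the
    tree; a dissemination index uniform over the acquisition order fixes
    the truncal events; the metastasis lineage inherits them and continues
    acquiring with site-multiplied conditional probabilities.  Each patient
    contributes one metastasis sample, a primary sample with probability
    ``p_primary_sample`` and a second metastasis with ``p_second_met``;
    observed tree-event cells are flipped with probability ``epsilon`` and
    focal noise events added independently.
    """
    rng = np.random.default_rng(config.seed)
    events = config.events
    site_probs = [config.site_mix.get(s, 0.0) for s in SITES]
    theta_primary = _effective_theta(config, None)
    theta_site = {s: _effective_theta(config, s) for s in SITES}

    sample_rows = []
    meta_rows = []
    patient_records: dict[str, dict] = {}

    for i in range(config.n_patients):
        patient = f"P{i + 1:03d}"
        site = SITES[rng.choice(len(SITES), p=site_probs)]
        primary_set = _acquire(config, rng, set(), theta_primary)
        order = _acquisition_order(config, rng, primary_set)
        k = int(rng.integers(len(order) + 1))
        truncal = set(order[:k])
        met_set = _acquire(config, rng, truncal, theta_site[site])
        timing = "synchronous" if rng.random() < 0.5 else "metachronous"

        emit_primary = rng.random() < config.p_primary_sample
        emit_second = rng.random() < config.p_second_met
        met2_set = (
            _acquire(config, rng, truncal, theta_site[site])
            if emit_second else None
        )

        record = {
            "site": site,
            "primary_events": order,
            "dissemination_index": k,
            "truncal": sorted(truncal),
            "met_events": {},
        }

        def emit(suffix: str, event_set: set[str], s_site: str,
                 s_timing: str):
            sample = f"{patient}-{suffix}"
            sample_rows.append((sample, event_set))
            meta_rows.append(
                {"sample": sample, "patient": patient, "site": s_site,
                 "timing": s_timing}
            )
            if s_site != "primary":
                record["met_events"][sample] = sorted(event_set)

        if emit_primary:
            emit("PR", primary_set, "primary", "primary")
        emit("M1", met_set, site, timing)
        if emit_second:
            emit("M2", met2_set, site, timing)
        patient_records[patient] = record

    # observation layer: flip noise on tree events, focal Bernoulli noise
    n_samples = len(sample_rows)
    tree_cols = np.zeros((n_samples, len(events)), dtype=np.int8)
    for r, (_, event_set) in enumerate(sample_rows):
        for c, e in enumerate(events):
            tree_cols[r, c] = 1 if e in event_set else 0
    if config.epsilon > 0 and n_samples:
        flips = rng.random(tree_cols.shape) < config.epsilon
        tree_cols = np.where(flips, 1 - tree_cols, tree_cols).astype(np.int8)
    focal_cols = (
        (rng.random((n_samples, len(config.focal_events)))
         < config.focal_rate).astype(np.int8)
        if config.focal_events else np.zeros((n_samples, 0), np.int8)
    )

    all_events = [CIEvent.parse(e) for e in events]
    all_events += [CIEvent.parse(e) for e in config.focal_events]
    values = np.hstack([tree_cols, focal_cols])
    matrix = CIMatrix([s for s, _ in sample_rows], all_events, values)
    meta = CohortTable(
        pd.DataFrame(meta_rows, columns=["sample", "patient", "site",
                                         "timing"])
        if meta_rows else
        pd.DataFrame(columns=["sample", "patient", "site", "timing"])
    )

    enriched = {
        e: frozenset(s for s in SITES if config.multiplier(e, s) > 1.0)
        for e in events
    }
    truth = GroundTruth(
        config=config, enriched_sites=enriched, timing_class={},
        parent=dict(config.parent), patients=patient_records,
    )
    timing = classify_event_timing(truth.true_tree(), n_classes=9)
    truth.timing_class = dict(zip(timing["event"], timing["class"]))
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# simple null / dependent-pair generators for calibration and power tests
# ---------------------------------------------------------------------------

_NULL_ARMS = tuple(
    f"{sign}{chrom}{arm}"
    for chrom in list(range(1, 13)) + [16, 17, 18, 19, 20]
    for arm in ("p", "q")
    for sign in ("+", "-")
)


def default_null_events(k: int) -> list[str]:
    """k distinct unmasked arm-level event labels for null simulations."""
    if k > len(_NULL_ARMS):
        raise ValueError(f"at most {len(_NULL_ARMS)} null events available")
    return list(_NULL_ARMS[:k])


def simulate_null_matrix(N: int, freqs, seed: int | None = None,
                         events: list[str] | None = None,
                         rng: np.random.Generator | None = None) -> CIMatrix:
    """Independent Bernoulli event columns (global-null CI matrix)."""
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if events is None:
        events = default_null_events(freqs.size)
    values = (rng.random((N, freqs.size)) < freqs[None, :]).astype(np.int8)
    return CIMatrix(
        [f"S{i + 1:04d}" for i in range(N)],
        [CIEvent.parse(e) for e in events], values,
    )


def simulate_dependent_pair(N: int, rate_a: float, rate_b: float,
                            log_odds: float, seed: int | None = None,
                            rng: np.random.Generator | None = None):
    """Two binary columns from a bivariate Bernoulli with given marginals
    and log odds ratio.  Returns (x_a, x_b)."""
    if not np.isfinite(log_odds):
        raise ValueError("log-odds coupling must be finite")
    for r in (rate_a, rate_b):
        if not (0.0 < r < 1.0):
            raise ValueError("marginal rates must lie in (0, 1)")
    lo = max(0.0, rate_a + rate_b - 1.0)
    hi = min(rate_a, rate_b)
    w = float(np.exp(log_odds))
    if abs(w - 1.0) < 1e-12:
        p11 = rate_a * rate_b
    else:
        a = w - 1.0
        b = -((w - 1.0) * (rate_a + rate_b) + 1.0)
        c = w * rate_a * rate_b
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError("infeasible marginal/odds combination")
        roots = [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
        feasible = [r for r in roots if lo - 1e-12 <= r <= hi + 1e-12]
        if not feasible:
            raise ValueError("infeasible marginal/odds combination")
        p11 = float(np.clip(feasible[0], lo, hi))
    probs = np.array(
        [1 - rate_a - rate_b + p11, rate_b - p11, rate_a - p11, p11]
    )
    if (probs < -1e-12).any():
        raise ValueError("infeasible marginal/odds combination")
    probs = np.clip(probs, 0, None)
    probs /= probs.sum()
    if rng is None:
        rng = np.random.default_rng(seed)
    cells = rng.multinomial(N, probs)
    x_a = np.repeat([0, 0, 1, 1], cells)
    x_b = np.repeat([0, 1, 0, 1], cells)
    perm = rng.permutation(N)
    return x_a[perm], x_b[perm]
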