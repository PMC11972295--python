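"""Cohort-level oncogenetic tree reconstruction and event-timing classes.

An oncogenetic tree is a rooted tree over CI events describing the
preferred order of accumulation in a tumor cohort: the root is the normal
state, and each edge carries the conditional probability ``theta_v`` that
event ``v`` is acquired given its parent event has occurred.  Observations
are cross-sectional presence/absence profiles with a symmetric per-cell
error rate ``epsilon``.

Reconstruction proceeds in two stages:

1. an initial topology from the maximum-weight spanning arborescence
   (Edmonds) of the complete digraph with root edges weighted ``log f_v``
   and event-event edges weighted by pointwise mutual information
   ``log f_uv - log f_u - log f_v`` (directed from the more frequent
   event), and
2. a deterministic hill-climb over single-parent reattachments that
   accepts strictly likelihood-improving moves under the latent
   tree-structured acquisition model with flip noise ``epsilon``.

Event timing is the root distance ``d_v`` (sum of ``-log theta`` along the
root path; improbable transitions are "later"), binned into a fixed number
of equal-width classes — class 1 is earliest, class 9 latest by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ci_data import CIMatrix

ROOT = "root"


def _edmonds_arborescence(weights: nx.DiGraph) -> dict[str, str]:
    """Parent map of the maximum-weight spanning arborescence rooted at ROOT."""
    arb = nx.maximum_spanning_arborescence(weights, attr="weight")
    return {v: u for u, v in arb.edges}


@dataclass
class OncogeneticTreeResult:
    """A fitted oncogenetic tree.

    ``parent`` maps each event to its parent (event label or ``"root"``),
    ``theta`` holds the per-edge conditional acquisition probabilities and
    ``loglik`` the model log-likelihood at the fitted ``epsilon``.
    """

    events: list[str]
    parent: dict[str, str]
    theta: dict[str, float]
    epsilon: float
    loglik: float
    frequencies: dict[str, float]
    n_samples: int

    def __post_init__(self):
        self._children: dict[str, list[str]] = {ROOT: []}
        for v in self.events:
            self._children[v] = []
        for v, u in self.parent.items():
            self._children[u].append(v)
        for ch in self._children.values():
            ch.sort()

    def children(self, node: str) -> list[str]:
        return self._children[node]

    def root_distance(self, event: str, metric: str = "weighted") -> float:
        """Distance from the root: -log(theta) path sum, or edge count."""
        d = 0.0
        v = event
        while v != ROOT:
            d += -math.log(self.theta[v]) if metric == "weighted" else 1.0
            v = self.parent[v]
        return d

    def timing_classes(self, n_classes: int = 9,
                       metric: str = "weighted") -> pd.DataFrame:
        return classify_event_timing(self, n_classes=n_classes, metric=metric)

    def to_newick(self) -> str:
        def clean(name: str) -> str:
            return name.replace(" ", "_")

        def rec(node: str) -> str:
            kids = self.children(node)
            inner = ("(" + ",".join(rec(k) for k in kids) + ")") if kids else ""
            if node == ROOT:
                return inner + "normal"
            length = -math.log(self.theta[node])
            return f"{inner}{clean(node)}:{length:.6g}"

        return rec(ROOT) + ";"

    def to_frame(self, n_classes: int = 9) -> pd.DataFrame:
        timing = self.timing_classes(n_classes=n_classes)
        timing = timing.set_index("event")
        rows = []
        for v in self.events:
            rows.append(
                {
                    "event": v,
                    "parent": self.parent[v],
                    "theta": self.theta[v],
                    "frequency": self.frequencies[v],
                    "d": timing.loc[v, "d"],
                    "class": int(timing.loc[v, "class"]),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Oncogenetic tree",
            f"  events: {len(self.events)}  samples: {self.n_samples}  "
            f"epsilon: {self.epsilon:g}",
            f"  log-likelihood: {self.loglik:.3f}",
            "  event        parent       theta   d      class",
        ]
        for row in self.to_frame().itertuples():
            lines.append(
                f"  {row.event:<12s} {row.parent:<12s} "
                f"{row.theta:0.3f}   {row.d:0.3f}  {row._6}"
            )
        return "\n".join(lines)


def _tree_loglik(events: list[str], parent: dict[str, str],
                 theta: dict[str, float], X: np.ndarray,
                 col: dict[str, int], epsilon: float) -> float:
    """Log-likelihood of binary profiles X under the latent acquisition model.

    Latent presence propagates root-down (v present with prob theta_v iff
    its parent is present); each observed cell is flipped independently
    with probability epsilon.  Computed by a single post-order pass with
    per-sample message vectors.
    """
    children: dict[str, list[str]] = {ROOT: []}
    for v in events:
        children[v] = []
    for v, u in parent.items():
        children[u].append(v)

    n = X.shape[0]

    def down(v: str) -> tuple[np.ndarray, np.ndarray]:
        # returns (g0, g1): P(observed subtree | parent latent absent/present)
        x = X[:, col[v]]
        e_match = np.where(x == 1, epsilon, 1.0 - epsilon)  # P(x | z=0)
        e_hit = np.where(x == 1, 1.0 - epsilon, epsilon)    # P(x | z=1)
        prod0 = np.ones(n)
        prod1 = np.ones(n)
        for c in children[v]:
            c0, c1 = down(c)
            prod0 *= c0
            prod1 *= c1
        g0 = e_match * prod0
        g1 = theta[v] * e_hit * prod1 + (1.0 - theta[v]) * e_match * prod0
        return g0, g1

    total = np.ones(n)
    for c in children[ROOT]:
        _, c1 = down(c)
        total *= c1
    return float(np.log(np.clip(total, 1e-300, None)).sum())


class OncogeneticTreeModel:
    """Fit an oncogenetic tree to a (site-restricted) CI matrix.

    Parameters
    ----------
    matrix:
        CI profiles of the cohort subset (e.g. all liver metastases, one
        per patient).
    top_k:
        Number of most frequent events to model (ties broken by label).
    epsilon:
        Symmetric observation flip rate of the error model.
    pseudocount:
        Added to marginal and joint counts when estimating frequencies.
    """

    def __init__(self, matrix: CIMatrix, top_k: int = 25,
                 epsilon: float = 0.01, pseudocount: float = 0.5,
                 hill_climb: bool = True):
        if top_k < 2:
            raise ValueError("top_k must be at least 2")
        self.matrix = matrix
        self.top_k = top_k
        self.epsilon = epsilon
        self.pseudocount = pseudocount
        self.hill_climb = hill_climb

    def fit(self) -> OncogeneticTreeResult:
        binary = self.matrix.binary()
        n = binary.shape[0]
        counts = binary.sum(axis=0)
        order = sorted(binary.columns, key=lambda c: (-counts[c], c))
        events = sorted(order[: self.top_k])
        if len(events) < 1:
            raise ValueError("no events to model")
        X = binary[events].to_numpy(dtype=np.int64)
        col = {v: j for j, v in enumerate(events)}
        pc = self.pseudocount

        f = {v: (counts[v] + pc) / (n + 2 * pc) for v in events}
        joint = (X.T @ X).astype(float)
        f_uv = {}
        for i, u in enumerate(events):
            for j, v in enumerate(events):
                if i < j:
                    f_uv[(u, v)] = (joint[i, j] + pc) / (n + 2 * pc)

        def fjoint(u, v):
            return f_uv[(u, v)] if (u, v) in f_uv else f_uv[(v, u)]

        # initial topology: maximum-weight arborescence on the PMI digraph
        g = nx.DiGraph()
        g.add_node(ROOT)
        for v in events:
            g.add_edge(ROOT, v, weight=math.log(f[v]))
        for u in events:
            for v in events:
                if u != v and f[u] >= f[v]:
                    w = math.log(fjoint(u, v)) - math.log(f[u]) - math.log(f[v])
                    g.add_edge(u, v, weight=w)
        parent = _edmonds_arborescence(g)

        def theta_for(u: str, v: str) -> float:
            if u == ROOT:
                return min(f[v], 1.0)
            return min(fjoint(u, v) / f[u], 1.0)

        theta = {v: theta_for(parent[v], v) for v in events}
        loglik = _tree_loglik(events, parent, theta, X, col, self.epsilon)

        if self.hill_climb and len(events) > 1:
            loglik = self._hill_climb(events, parent, theta, theta_for,
                                      X, col, loglik)

        return OncogeneticTreeResult(
            events=events, parent=parent, theta=theta, epsilon=self.epsilon,
            loglik=loglik, frequencies=f, n_samples=n,
        )

    def _hill_climb(self, events, parent, theta, theta_for, X, col,
                    loglik) -> float:
        """First-improvement sweeps over single-parent reattachments."""

        def descendants(v: str) -> set[str]:
            out, stack = set(), [v]
            while stack:
                x = stack.pop()
                for w in events:
                    if parent[w] == x and w not in out:
                        out.add(w)
                        stack.append(w)
            return out

        improved = True
        while improved:
            improved = False
            for v in events:  # fixed scan order
                forbidden = descendants(v) | {v}
                for u in [ROOT] + events:
                    if u == parent[v] or u in forbidden:
                        continue
                    old_parent, old_theta = parent[v], theta[v]
                    parent[v] = u
                    theta[v] = theta_for(u, v)
                    cand = _tree_loglik(events, parent, theta, X, col,
                                        self.epsilon)
                    if cand > loglik + 1e-12:
                        loglik = cand
                        improved = True
                        break
                    parent[v], theta[v] = old_parent, old_theta
        return loglik


def fit_oncotree(matrix: CIMatrix, top_k: int = 25, epsilon: float = 0.01,
                 **kwargs) -> OncogeneticTreeResult:
    """Functional wrapper around :class:`OncogeneticTreeModel`."""
    return OncogeneticTreeModel(matrix, top_k=top_k, epsilon=epsilon,
                                **kwargs).fit()


def classify_event_timing(tree: OncogeneticTreeResult, n_classes: int = 9,
                          metric: str = "weighted") -> pd.DataFrame:
    """Bin root distances into equal-width early-to-late timing classes.

    The interval [0, d_max] is split into *n_classes* equal bins,
    right-closed; an event at distance 0 is class 1 and the deepest event
    class *n_classes*.  A degenerate tree (all distances 0) is all class 1.
    """
    if metric not in ("weighted", "depth"):
        raise ValueError("metric must be 'weighted' or 'depth'")
    d = {v: tree.root_distance(v, metric=metric) for v in tree.events}
    d_max = max(d.values(), default=0.0)
    rows = []
    for v in tree.events:
        if d_max <= 0:
            cls = 1
        else:
            width = d_max / n_classes
            cls = int(min(n_classes, max(1, math.ceil(d[v] / width - 1e-9))))
        rows.append({"event": v, "d": d[v], "class": cls})
    return pd.DataFrame(rows, columns=["event", "d", "class"])


def compare_site_trees(trees: dict[str, OncogeneticTreeResult],
                       n_classes: int = 9,
                       metric: str = "weighted") -> pd.DataFrame:
    """Event x site table of timing classes; absent events are NaN."""
    all_events = sorted({v for t in trees.values() for v in t.events})
    out = pd.DataFrame(index=pd.Index(all_events, name="event"),
                       columns=list(trees), dtype=float)
    for site, tree in trees.items():
        timing = classify_event_timing(tree, n_classes=n_classes,
                                       metric=metric).set_index("event")
        out.loc[timing.index, site] = timing["class"].astype(float)
    return out
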