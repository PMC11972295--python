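"""Per-patient maximum-parsimony phylogenies from multi-sample CI profiles.

Each patient with multiple tumor samples (multi-region primaries,
recurrences, metastases) yields a rooted binary tree: the taxa are the
tumor samples plus a synthetic all-normal outgroup, characters are binary
event presences (a high-level amplification is a separate character), and
the tree minimizing the Fitch parsimony score is retained — exhaustively
for small patients, by branch and bound otherwise.  Characters may change
in both directions at equal cost (copy-number reversals occur).

Events are then mapped onto edges at their earliest most-parsimonious
placement (ambiguous changes are pushed toward the root), edges are
labelled trunk / branches / sub-branches by the number of tumor-lineage
branching nodes above them (0 / 1 / >=2), and each segment receives a CI
score: the mean oncogenetic timing class of the events mapped to it.  A
within-patient permutation test assesses whether CI scores rise from trunk
to sub-branches across patients.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ci_data import CIMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)

NORMAL = "normal"
SEGMENTS = ("trunk", "branches", "sub_branches")


# ---------------------------------------------------------------------------
# character matrix
# ---------------------------------------------------------------------------


@dataclass
class PatientCharacterMatrix:
    """Binary characters for one patient's samples plus the normal outgroup."""

    taxa: list[str]  # [NORMAL, tumor samples...]
    characters: list[str]
    values: np.ndarray  # (n_taxa, n_characters) in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.taxa[0] != NORMAL:
            raise ValueError("first taxon must be the normal outgroup")
        if self.values[0].any():
            raise ValueError("normal taxon must be all zeros")
        if len(self.taxa) < 3:
            raise ValueError("need at least 2 tumor samples")


def build_character_matrix(matrix: CIMatrix, samples) -> PatientCharacterMatrix:
    """Extract a patient's character matrix from the cohort CI matrix.

    Base characters are event presences (codes 1 and 2); where a code 2
    appears in a non-amplification column, an additional
    ``"<event> amp"`` character records the high-level state separately.
    Characters absent from every sample are dropped.
    """
    sub = matrix.subset_samples(list(samples))
    chars: list[str] = []
    cols: list[np.ndarray] = []
    for j, ev in enumerate(sub.events):
        v = sub.values[:, j]
        if (v > 0).any():
            chars.append(ev.canonical())
            cols.append((v > 0).astype(np.int8))
            if not ev.high_level and (v == 2).any():
                chars.append(ev.canonical() + " amp")
                cols.append((v == 2).astype(np.int8))
    values = np.column_stack(cols) if cols else np.zeros((len(sub.samples), 0),
                                                         np.int8)
    values = np.vstack([np.zeros((1, values.shape[1]), np.int8), values])
    return PatientCharacterMatrix(
        taxa=[NORMAL] + list(sub.samples), characters=chars, values=values,
    )


# ---------------------------------------------------------------------------
# topology enumeration and Fitch scoring (trees as nested tuples of leaves)
# ---------------------------------------------------------------------------


def _rooted_trees(leaves: tuple):
    """All rooted binary leaf-labeled trees: (2t-3)!! for t leaves."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for tree in _rooted_trees(rest):
        yield from _insert_everywhere(tree, first)


def _insert_everywhere(tree, leaf):
    yield (leaf, tree)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insert_everywhere(left, leaf):
            yield (sub, right)
        for sub in _insert_everywhere(right, leaf):
            yield (left, sub)


def _fitch_sets(tree, leaf_states: np.ndarray):
    """Fitch first pass: returns (state-set bitmask per char, score)."""
    if not isinstance(tree, tuple):
        return (leaf_states[tree] + 1).astype(np.int8), 0  # 0->{0}=1, 1->{1}=2
    acc_set = None
    score = 0
    for child in tree:
        s, sc = _fitch_sets(child, leaf_states)
        score += sc
        if acc_set is None:
            acc_set = s
        else:
            inter = acc_set & s
            union = acc_set | s
            empty = inter == 0
            acc_set = np.where(empty, union, inter).astype(np.int8)
            score += int(empty.sum())
    return acc_set, score


def _fitch_score(tumor_tree, leaf_states: np.ndarray) -> int:
    _, score = _fitch_sets((0, tumor_tree), leaf_states)
    return score


def _canonical(tree, names) -> str:
    if not isinstance(tree, tuple):
        return names[tree]
    parts = sorted(_canonical(c, names) for c in tree)
    return "(" + ",".join(parts) + ")"


def _search_exhaustive(leaves, leaf_states, names):
    best = None
    for t in _rooted_trees(tuple(leaves)):
        score = _fitch_score(t, leaf_states)
        key = (score, _canonical((0, t), names))
        if best is None or key < best[0]:
            best = (key, t)
    return best[1], best[0][0]


def _search_branch_and_bound(leaves, leaf_states, names):
    """Stepwise-insertion branch and bound; Fitch score never decreases
    when taxa are added, so a partial score bounds every completion."""
    leaves = list(leaves)
    # greedy stepwise addition for an initial upper bound
    tree = leaves[0]
    for leaf in leaves[1:]:
        tree = min(
            _insert_everywhere(tree, leaf),
            key=lambda t: (_fitch_score(t, leaf_states),
                           _canonical((0, t), names)),
        )
    best = [(_fitch_score(tree, leaf_states), _canonical((0, tree), names),
             tree)]

    def recurse(partial, remaining):
        score = _fitch_score(partial, leaf_states)
        if score > best[0][0]:
            return
        if not remaining:
            key = (score, _canonical((0, partial), names))
            if (key[0], key[1]) < (best[0][0], best[0][1]):
                best[0] = (key[0], key[1], partial)
            return
        nxt, rest = remaining[0], remaining[1:]
        for t in _insert_everywhere(partial, nxt):
            recurse(t, rest)

    recurse(leaves[0], leaves[1:])
    return best[0][2], best[0][0]


# ---------------------------------------------------------------------------
# explicit tree nodes for event mapping
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    id: int
    taxon: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self, lengths: dict[int, float] | None = None) -> str:
        def clean(s):
            return s.replace(" ", "_")

        if self.is_leaf:
            out = clean(self.taxon)
        else:
            out = "(" + ",".join(
                sorted(c.newick(lengths) for c in self.children)
            ) + ")"
        if lengths is not None and self.parent is not None:
            out += f":{lengths.get(self.id, 0.0):g}"
        return out


def _to_nodes(tree, names) -> TreeNode:
    counter = itertools.count()

    def rec(sub) -> TreeNode:
        if not isinstance(sub, tuple):
            return TreeNode(id=next(counter), taxon=names[sub])
        node = TreeNode(id=next(counter))
        # deterministic child order via canonical strings
        for child in sorted(sub, key=lambda c: _canonical(c, names)):
            cn = rec(child)
            cn.parent = node
            node.children.append(cn)
        return node

    return rec(tree)


# ---------------------------------------------------------------------------
# fitted phylogeny
# ---------------------------------------------------------------------------


@dataclass
class PatientPhylogeny:
    """A fitted per-patient parsimony tree with events mapped to edges."""

    patient: str
    chars: PatientCharacterMatrix
    root: TreeNode  # children: [normal leaf, tumor subtree]
    score: int
    edge_events: dict[int, list[str]]  # node id -> events gained on edge above
    edge_losses: dict[int, list[str]]
    edge_segment: dict[int, str]  # node id -> trunk/branches/sub_branches

    @property
    def newick(self) -> str:
        return self.root.newick() + ";"

    def trunk_events(self) -> list[str]:
        out = []
        for nid, seg in self.edge_segment.items():
            if seg == "trunk":
                out.extend(self.edge_events.get(nid, []))
        return sorted(out)

    def events_by_segment(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {s: [] for s in SEGMENTS}
        for nid, seg in self.edge_segment.items():
            out[seg].extend(self.edge_events.get(nid, []))
        return out

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for nid, seg in self.edge_segment.items():
            rows.append(
                {
                    "patient": self.patient,
                    "edge": nid,
                    "segment": seg,
                    "events": ";".join(sorted(self.edge_events.get(nid, []))),
                    "losses": ";".join(sorted(self.edge_losses.get(nid, []))),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        by_seg = self.events_by_segment()
        lines = [
            f"Patient phylogeny {self.patient}",
            f"  taxa: {', '.join(self.chars.taxa[1:])} (+ normal)",
            f"  parsimony score: {self.score}",
            f"  newick: {self.newick}",
        ]
        for seg in SEGMENTS:
            lines.append(f"  {seg}: {', '.join(sorted(by_seg[seg])) or '-'}")
        return "\n".join(lines)


class ParsimonyTreeModel:
    """Maximum-parsimony tree search for one patient.

    Exhaustive over all rooted topologies up to 8 taxa (normal included);
    branch and bound beyond.  Ties are broken by the lexicographically
    smallest canonical (sorted) newick string, making the result
    deterministic.
    """

    def __init__(self, chars: PatientCharacterMatrix):
        self.chars = chars

    def fit(self, patient: str | None = None) -> PatientPhylogeny:
        chars = self.chars
        names = chars.taxa
        leaf_states = chars.values
        tumor_idx = list(range(1, len(names)))
        if len(names) <= 8:
            tumor_tree, score = _search_exhaustive(tumor_idx, leaf_states,
                                                   names)
        else:
            tumor_tree, score = _search_branch_and_bound(
                tumor_idx, leaf_states, names)
        root = _to_nodes((0, tumor_tree), names)
        edge_events, edge_losses = _map_changes(root, chars)
        edge_segment = _segment_edges(root)
        return PatientPhylogeny(
            patient=patient or "patient", chars=chars, root=root, score=score,
            edge_events=edge_events, edge_losses=edge_losses,
            edge_segment=edge_segment,
        )


def fit_parsimony_tree(chars: PatientCharacterMatrix,
                       patient: str | None = None) -> PatientPhylogeny:
    """Functional wrapper around :class:`ParsimonyTreeModel`."""
    return ParsimonyTreeModel(chars).fit(patient=patient)


# ---------------------------------------------------------------------------
# event-to-edge mapping (earliest most-parsimonious placement)
# ---------------------------------------------------------------------------


def _map_changes(root: TreeNode, chars: PatientCharacterMatrix):
    """Sankoff DP per character with deterministic earliest-gain backtrace.

    The root state is fixed to normal (0) on ties; descending, a tied state
    choice prefers presence (1), which places ambiguous gains on the edge
    closest to the root.  Both gains (0->1) and losses (1->0) are recorded
    on the edges where they occur.
    """
    taxon_state = {t: i for i, t in enumerate(chars.taxa)}
    INF = 10**9

    edge_events: dict[int, list[str]] = {}
    edge_losses: dict[int, list[str]] = {}

    for k, char in enumerate(chars.characters):
        cost: dict[int, tuple[int, int]] = {}

        def up(node: TreeNode):
            if node.is_leaf:
                s = chars.values[taxon_state[node.taxon], k]
                cost[node.id] = (0, INF) if s == 0 else (INF, 0)
                return
            c0 = c1 = 0
            for child in node.children:
                up(child)
                k0, k1 = cost[child.id]
                c0 += min(k0, k1 + 1)
                c1 += min(k0 + 1, k1)
            cost[node.id] = (c0, c1)

        up(root)
        root_state = 0 if cost[root.id][0] <= cost[root.id][1] else 1

        def down(node: TreeNode, state: int):
            for child in node.children:
                k0, k1 = cost[child.id]
                t0 = k0 + (state != 0)
                t1 = k1 + (state != 1)
                child_state = 1 if t1 <= t0 else 0  # tie -> prefer presence
                if child_state == 1 and state == 0:
                    edge_events.setdefault(child.id, []).append(char)
                elif child_state == 0 and state == 1:
                    edge_losses.setdefault(child.id, []).append(char)
                down(child, child_state)

        down(root, root_state)

    return edge_events, edge_losses


def map_events_to_edges(phylo: PatientPhylogeny) -> dict[int, list[str]]:
    """Per-edge gained-event lists (edge identified by its child node id)."""
    return phylo.edge_events


# ---------------------------------------------------------------------------
# trunk / branches / sub-branches segmentation and CI scores
# ---------------------------------------------------------------------------


def _segment_edges(root: TreeNode) -> dict[int, str]:
    """Label each edge by the branching depth of its parent path.

    The count is the number of tumor-lineage branching nodes (internal
    nodes with two or more children, the root excluded) strictly between
    the root and the edge: 0 -> trunk, 1 -> branches, >=2 -> sub-branches.
    The edge to the normal outgroup leaf is not a tumor segment and is
    skipped.
    """
    segments: dict[int, str] = {}

    def rec(node: TreeNode, n_branchings: int):
        for child in node.children:
            if child.is_leaf and child.taxon == NORMAL:
                continue
            if n_branchings == 0:
                segments[child.id] = "trunk"
            elif n_branchings == 1:
                segments[child.id] = "branches"
            else:
                segments[child.id] = "sub_branches"
            rec(child, n_branchings + (0 if child.is_leaf
                                       else (len(child.children) >= 2)))

    rec(root, 0)
    return segments


def segment_and_score(phylo: PatientPhylogeny,
                      timing: dict[str, int] | pd.Series) -> dict[str, float]:
    """CI score (mean timing class of mapped events) per tree segment.

    *timing* maps event labels to oncogenetic timing classes, typically the
    patient's metastasis-site tree via
    :meth:`organotrope.oncotree.OncogeneticTreeResult.timing_classes`.
    Events without a class are excluded (logged); segments with no
    classified events get no score (NaN).
    """
    if isinstance(timing, pd.Series):
        timing = timing.to_dict()
    scores: dict[str, list[float]] = {s: [] for s in SEGMENTS}
    missing: set[str] = set()
    for nid, seg in phylo.edge_segment.items():
        for ev in phylo.edge_events.get(nid, []):
            base = ev.removesuffix(" amp")
            if ev in timing:
                scores[seg].append(float(timing[ev]))
            elif base in timing:
                scores[seg].append(float(timing[base]))
            else:
                missing.add(ev)
    if missing:
        logger.info(
            "patient %s: %d event(s) without timing class excluded from CI "
            "scores: %s", phylo.patient, len(missing),
            ", ".join(sorted(missing)),
        )
    return {
        seg: (float(np.mean(vals)) if vals else float("nan"))
        for seg, vals in scores.items()
    }


# ---------------------------------------------------------------------------
# segment trend test
# ---------------------------------------------------------------------------


@dataclass
class SegmentTrendResult:
    """Within-patient permutation test of CI-score differences."""

    omnibus_p: float
    pairs: list[tuple[str, str]]
    observed: np.ndarray  # pairwise mean differences (later - earlier)
    pairwise_p: np.ndarray
    pairwise_q: np.ndarray
    n_perm: int
    n_patients: int

    def summary(self) -> str:
        lines = [
            "Segment CI-score trend test (within-patient permutation)",
            f"  patients: {self.n_patients}   permutations: {self.n_perm}",
            f"  omnibus p: {self.omnibus_p:0.4g}",
        ]
        for (a, b), d, p, q in zip(self.pairs, self.observed,
                                   self.pairwise_p, self.pairwise_q):
            lines.append(f"  {b} - {a}: diff={d:+0.3f}  p={p:0.4g}  q={q:0.4g}")
        return "\n".join(lines)


class SegmentTrendTest:
    """Permutation test for a trunk -> branches -> sub-branches CI trend.

    The statistic for a segment pair is the difference of segment means
    pooled across patients; the null permutes segment labels within each
    patient (values stay with the patient).  The omnibus p-value uses the
    maximum absolute pairwise statistic; pairwise p-values are BH-adjusted.
    """

    def __init__(self, scores: pd.DataFrame):
        # scores: patients x SEGMENTS, NaN where a segment is unscored
        missing = set(SEGMENTS) - set(scores.columns)
        if missing:
            raise ValueError(f"scores missing segment column(s) {missing}")
        self.scores = scores[list(SEGMENTS)].astype(float)
        multi = (self.scores.notna().sum(axis=1) >= 2)
        if multi.sum() < 2:
            raise ValueError(
                "need at least two patients with >= 2 scored segments"
            )
        if multi.sum() < 5:
            logger.warning(
                "only %d patients with >= 2 scored segments; the permutation "
                "null is coarse", int(multi.sum()),
            )

    def fit(self, n_perm: int = 100_000, seed: int | None = None,
            rng: np.random.Generator | None = None) -> SegmentTrendResult:
        if rng is None:
            rng = np.random.default_rng(seed)
        S = self.scores.to_numpy()
        n_seg = S.shape[1]

        # per-patient observed (segment index, value) lists
        patients = []
        for row in S:
            idx = np.flatnonzero(~np.isnan(row))
            if idx.size >= 1:
                patients.append((idx, row[idx]))

        sums = np.zeros((n_perm + 1, n_seg))
        counts = np.zeros(n_seg)
        for idx, vals in patients:
            counts[idx] += 1
            sums[0, idx] += vals
            if idx.size > 1:
                order = np.argsort(rng.random((n_perm, idx.size)), axis=1)
                permuted = vals[order]
            else:
                permuted = np.broadcast_to(vals, (n_perm, 1))
            for pos, seg in enumerate(idx):
                sums[1:, seg] += permuted[:, pos]

        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts  # NaN where a segment has no scores

        pairs = [(i, j) for i in range(n_seg) for j in range(i + 1, n_seg)
                 if counts[i] > 0 and counts[j] > 0]
        diffs = np.stack([means[:, j] - means[:, i] for i, j in pairs], axis=1)
        obs = diffs[0]
        null = diffs[1:]

        pairwise_p = np.array([
            (1.0 + np.sum(np.abs(null[:, k]) >= abs(obs[k]) - 1e-12))
            / (n_perm + 1.0)
            for k in range(len(pairs))
        ])
        max_obs = np.max(np.abs(obs))
        max_null = np.max(np.abs(null), axis=1)
        omnibus_p = float(
            (1.0 + np.sum(max_null >= max_obs - 1e-12)) / (n_perm + 1.0)
        )
        q = bh_adjust(pairwise_p).adjusted
        return SegmentTrendResult(
            omnibus_p=omnibus_p,
            pairs=[(SEGMENTS[i], SEGMENTS[j]) for i, j in pairs],
            observed=obs, pairwise_p=pairwise_p, pairwise_q=q,
            n_perm=n_perm, n_patients=len(patients),
        )


def test_segment_trend(scores: pd.DataFrame, n_perm: int = 100_000,
                       seed: int | None = None) -> SegmentTrendResult:
    """Functional wrapper around :class:`SegmentTrendTest`."""
    return SegmentTrendTest(scores).fit(n_perm=n_perm, seed=seed)
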