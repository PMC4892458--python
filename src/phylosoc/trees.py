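"""Phylogeny handling: Newick I/O, pruning, polytomy grafting, rate
smoothing, and conversion to a Brownian-motion correlation matrix.

Trees are represented as :class:`dendropy.Tree` objects throughout;
this module adds the comparative-analysis operations around them.
Ultrametric trees (all root-to-tip path lengths equal) play a special
role: the expected correlation of a neutrally evolving trait between
two species is the depth of their most recent common ancestor divided
by the total tree depth, which is only a correlation (unit diagonal)
when the tree is ultrametric.  Phylograms measured in substitutions per
site are first converted to relative time with nonparametric rate
smoothing (:func:`nprs_ultrametricize`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "CorrelationMatrix",
    "CongenericDistances",
    "NewickParseError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tip_labels",
    "path_length_matrix",
    "prune_to_taxa",
    "is_ultrametric",
    "tree_depth",
    "graft_polytomy",
    "average_congeneric_distance",
    "nprs_ultrametricize",
    "correlation_from_tree",
]

#: default relative tolerance for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    pass


class NotUltrametricError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Species × species expected trait correlation under Brownian motion.

    ``values[i, j]`` is the depth of the most recent common ancestor of
    tips i and j, measured from the root, divided by the tree depth;
    symmetric with unit diagonal and positive semi-definite.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("correlation matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def reorder(self, labels: Sequence[str]) -> "CorrelationMatrix":
        idx = [self.labels.index(l) for l in labels]
        return CorrelationMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.12g")


@dataclass(frozen=True)
class CongenericDistances:
    """Patristic distances between congeneric tips: mean, min, max, pair count."""

    mean: float
    min: float
    max: float
    n_pairs: int


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick; returns the string, optionally writing it."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return parse_newick(write_newick(tree))


def path_length_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip-to-tip patristic distance matrix in tip-label order."""
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depths = _node_depths(tree)
    # d(i,j) = depth_i + depth_j - 2 * depth(MRCA(i,j))
    leaf_by_index = {index[leaf.taxon.label]: leaf for leaf in tree.leaf_node_iter()}
    mrca_depth = _mrca_depths(tree, depths, index)
    tip_depth = np.array([depths[leaf_by_index[i]] for i in range(n)])
    dist = tip_depth[:, None] + tip_depth[None, :] - 2.0 * mrca_depth
    np.fill_diagonal(dist, 0.0)
    return labels, dist


def _node_depths(tree: dendropy.Tree) -> dict:
    """Distance of every node from the root node (any root edge excluded)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def _mrca_depths(
    tree: dendropy.Tree,
    depths: Mapping[dendropy.Node, float],
    index: Mapping[str, int],
) -> np.ndarray:
    """Matrix of MRCA depths (distance root→MRCA) for all tip pairs."""
    n = len(index)
    mrca = np.zeros((n, n))
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            mrca[i, i] = depths[node]
            below[node] = [i]
            continue
        d = depths[node]
        groups = [below[c] for c in node.child_nodes()]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.array(groups[a])
                ib = np.array(groups[b])
                mrca[np.ix_(ia, ib)] = d
                mrca[np.ix_(ib, ia)] = d
        merged: list[int] = []
        for g in groups:
            merged.extend(g)
        below[node] = merged
    return mrca


def tree_depth(tree: dendropy.Tree) -> float:
    """Mean root-to-tip path length (any edge above the root excluded)."""
    depths = _node_depths(tree)
    return float(np.mean([depths[l] for l in tree.leaf_node_iter()]))


def is_ultrametric(
    tree: dendropy.Tree, rel_tol: float = ULTRAMETRIC_RTOL
) -> tuple[bool, float]:
    """Check whether all root-to-tip path lengths agree.

    Returns (flag, max relative deviation), deviation being
    (max depth - min depth) / mean depth.
    """
    node_depths = _node_depths(tree)
    depths = np.array([node_depths[l] for l in tree.leaf_node_iter()])
    mean = depths.mean()
    if mean <= 0:
        raise ValueError("zero-depth tree: all branch lengths vanish")
    deviation = float((depths.max() - depths.min()) / mean)
    return deviation <= rel_tol, deviation


def prune_to_taxa(tree: dendropy.Tree, keep: Sequence[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; path lengths between retained tips
    are unchanged and unbranched internal nodes are suppressed."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep must contain at least one tip label")
    present = set(tip_labels(tree))
    missing = [k for k in keep if k not in present]
    if missing:
        raise KeyError(f"labels absent from tree: {sorted(missing)}")
    pruned = _clone(tree)
    if set(keep) == present:
        return pruned
    pruned.retain_taxa_with_labels(keep)
    # dendropy may leave a unifurcating root; merge its single edge away
    root = pruned.seed_node
    while len(root.child_nodes()) == 1 and not root.is_leaf() and len(keep) > 1:
        child = root.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (root.edge.length or 0.0)
        pruned.seed_node = child
        child.parent_node = None
        root = child
    return pruned


def graft_polytomy(
    tree: dendropy.Tree,
    genus_tip: str,
    new_tips: Sequence[str],
    pendant_length: float,
) -> dendropy.Tree:
    """Expand a genus-level tip into a polytomy of congeneric species.

    The tip becomes an internal node whose children are the renamed
    original tip plus ``new_tips``, each on a pendant branch of
    ``pendant_length``; the stem above the new node is shortened by the
    same amount so every root-to-tip depth is preserved (an ultrametric
    input stays ultrametric).
    """
    if pendant_length < 0:
        raise ValueError("pendant_length must be non-negative")
    existing = set(tip_labels(tree))
    if genus_tip not in existing:
        raise KeyError(f"tip {genus_tip!r} not in tree")
    dupes = [t for t in new_tips if t in existing]
    if dupes:
        raise ValueError(f"new tip labels already present: {dupes}")
    if len(set(new_tips)) != len(new_tips):
        raise ValueError("duplicate labels in new_tips")
    out = _clone(tree)
    node = next(
        leaf for leaf in out.leaf_node_iter() if leaf.taxon.label == genus_tip
    )
    stem = node.edge.length or 0.0
    if pendant_length > stem + 1e-12:
        raise ValueError(
            f"pendant_length {pendant_length} exceeds available stem branch {stem} "
            f"above tip {genus_tip!r}"
        )
    node.edge.length = stem - pendant_length
    original_taxon = node.taxon
    node.taxon = None
    for label in [genus_tip, *new_tips]:
        child = node.new_child(edge_length=pendant_length)
        if label == genus_tip:
            child.taxon = original_taxon
        else:
            child.taxon = out.taxon_namespace.require_taxon(label=label)
    return out


def average_congeneric_distance(
    tree: dendropy.Tree, genus_map: Mapping[str, str]
) -> CongenericDistances:
    """Mean (and min/max) patristic distance over all within-genus tip pairs.

    Used to choose pendant branch lengths when grafting congeneric
    polytomies; the min/max support sensitivity variants.
    """
    labels, dist = path_length_matrix(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    pairs: list[float] = []
    by_genus: dict[str, list[str]] = {}
    for lab in labels:
        genus = genus_map.get(lab)
        if genus is not None:
            by_genus.setdefault(genus, []).append(lab)
    for members in by_genus.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append(dist[index[members[a]], index[members[b]]])
    if not pairs:
        raise ValueError("no congeneric tip pairs in tree")
    arr = np.array(pairs)
    return CongenericDistances(
        mean=float(arr.mean()), min=float(arr.min()), max=float(arr.max()),
        n_pairs=len(pairs),
    )


class NPRSError(RuntimeError):
    def __init__(self, message: str, penalty: float):
        super().__init__(message)
        self.penalty = penalty


def nprs_ultrametricize(
    tree: dendropy.Tree, root_age: float, gtol: float = 1e-10
) -> dendropy.Tree:
    """Convert a phylogram to an ultrametric tree by rate smoothing.

    Node ages (tips at 0, root fixed at ``root_age``) are chosen to
    minimise the sum of squared differences between the substitution
    rates of adjacent branches — the local rate of a branch being its
    input length divided by its time duration — with the root term taken
    as squared deviations of the root's child rates from their mean.
    Ages are optimised on a logistic scale relative to the parent age,
    which enforces parent-older-than-child ordering by construction.
    The objective is invariant to rescaling all input branch lengths,
    so only relative rates matter; the returned tree carries durations
    summing to ``root_age`` on every root-to-tip path.
    """
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    for leaf in tree.leaf_node_iter():
        if leaf.distance_from_root() <= 0:
            raise ValueError(
                f"tip {leaf.taxon.label!r} has non-positive root-to-tip path length"
            )

    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = np.array(
        [idx[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    )
    blen = np.array([(n.edge.length or 0.0) for n in nodes])
    is_leaf = np.array([n.is_leaf() for n in nodes])
    free = [i for i, n in enumerate(nodes) if not is_leaf[i] and parent[i] >= 0]

    # initial relative ages from input depths (exact for clock-like input)
    depth = np.zeros(len(nodes))
    for i in range(1, len(nodes)):
        depth[i] = depth[parent[i]] + blen[i]
    max_depth = depth[is_leaf].max()
    rel = np.clip(1.0 - depth / max_depth, 1e-6, 1.0 - 1e-6)

    def ages_from_theta(theta: np.ndarray) -> np.ndarray:
        ages = np.zeros(len(nodes))
        ages[0] = root_age
        frac = dict(zip(free, expit(theta)))
        for i in range(1, len(nodes)):
            if is_leaf[i]:
                ages[i] = 0.0
            else:
                ages[i] = frac[i] * ages[parent[i]]
        return ages

    children: list[list[int]] = [[] for _ in nodes]
    for i in range(1, len(nodes)):
        children[parent[i]].append(i)

    def penalty(theta: np.ndarray) -> float:
        ages = ages_from_theta(theta)
        dur = np.empty(len(nodes))
        dur[0] = 1.0
        dur[1:] = ages[parent[1:]] - ages[1:]
        rate = np.where(dur > 1e-300, blen / np.maximum(dur, 1e-300), 0.0)
        total = 0.0
        for k in free:  # internal non-root: compare children's rates to own
            for c in children[k]:
                total += (rate[c] - rate[k]) ** 2
        root_rates = rate[children[0]]
        total += float(np.sum((root_rates - root_rates.mean()) ** 2))
        return float(total)

    theta0 = np.array(
        [logit(np.clip(rel[i] / rel[parent[i]], 1e-6, 1 - 1e-6)) for i in free]
    )
    if len(free) == 0:
        best_theta = theta0
    else:
        res = minimize(penalty, theta0, method="L-BFGS-B", options={"gtol": gtol})
        p0, p1 = penalty(theta0), float(res.fun)
        if not np.isfinite(p1):
            raise NPRSError("rate-smoothing optimisation diverged", p0)
        best_theta = res.x if p1 <= p0 else theta0

    ages = ages_from_theta(best_theta)
    out = _clone(tree)
    out_nodes = list(out.preorder_node_iter())
    for i, node in enumerate(out_nodes):
        if parent[i] >= 0:
            node.edge.length = ages[parent[i]] - ages[i]
    out.nprs_penalty = penalty(best_theta)  # type: ignore[attr-defined]
    return out


def correlation_from_tree(
    tree: dendropy.Tree, rel_tol: float = ULTRAMETRIC_RTOL
) -> CorrelationMatrix:
    """Brownian-motion tip correlation matrix of an ultrametric tree.

    Entry (i, j) is depth(MRCA(i, j)) / depth(root-to-tip); the diagonal
    is exactly 1.  Multifurcations are handled natively.
    """
    ok, deviation = is_ultrametric(tree, rel_tol)
    if not ok:
        raise NotUltrametricError(
            f"tree is not ultrametric (relative depth deviation {deviation:.3g}); "
            "run nprs_ultrametricize first"
        )
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    depths = _node_depths(tree)
    total = float(np.mean([depths[l] for l in tree.leaf_node_iter()]))
    mrca = _mrca_depths(tree, depths, index)
    corr = mrca / total
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(tuple(labels), np.clip(corr, 0.0, 1.0))
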