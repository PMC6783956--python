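"""Independent brute-force reference implementations used as oracles.

Everything here works by explicit path-walking and double loops on
dendropy node structures, deliberately sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import dendropy


def _leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise KeyError(label)


def _path_to_root(node: dendropy.Node) -> list[dendropy.Node]:
    path = []
    while node.parent_node is not None:
        path.append(node)
        node = node.parent_node
    return path


def naive_patristic(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of edge lengths along the unique a-b path, by path walking."""
    pa = _path_to_root(_leaf(tree, a))
    pb = _path_to_root(_leaf(tree, b))
    ids_b = {id(n) for n in pb}
    shared = [n for n in pa if id(n) in ids_b]
    # distance = both full paths minus twice the shared root-ward part
    total = sum(n.edge.length for n in pa) + sum(n.edge.length for n in pb)
    return total - 2.0 * sum(n.edge.length for n in shared)


def naive_pd(tree: dendropy.Tree, present: Sequence[str], include_root: bool = True) -> float:
    """Faith's PD by unioning tip-to-root paths (node sets)."""
    paths = [_path_to_root(_leaf(tree, lab)) for lab in present]
    union: dict[int, float] = {}
    for path in paths:
        for n in path:
            union[id(n)] = n.edge.length
    total = sum(union.values())
    if include_root:
        return total
    common: set[int] | None = None
    for path in paths:
        ids = {id(n) for n in path}
        common = ids if common is None else (common & ids)
    rootward = sum(
        n.edge.length for path in paths[:1] for n in path if id(n) in (common or set())
    )
    return total - rootward


def naive_mpd(tree: dendropy.Tree, abund: Mapping[str, float]) -> float:
    """Abundance-weighted MPD by an explicit double loop over ordered pairs."""
    species = [s for s, f in abund.items() if f > 0]
    num = den = 0.0
    for i in species:
        for j in species:
            if i == j:
                continue
            d = naive_patristic(tree, i, j)
            num += d * abund[i] * abund[j]
            den += abund[i] * abund[j]
    return num / den


def naive_mntd(
    tree: dendropy.Tree, abund: Mapping[str, float], denominator: str = "relative_abundance"
) -> float:
    """Abundance-weighted MNTD by explicit per-species minima."""
    species = [s for s, f in abund.items() if f > 0]
    num = 0.0
    for i in species:
        nearest = min(naive_patristic(tree, i, j) for j in species if j != i)
        num += nearest * abund[i]
    if denominator == "relative_abundance":
        return num / sum(abund[s] for s in species)
    return num / len(species)


def exhaustive_null_moments(
    tree: dendropy.Tree,
    abund: Mapping[str, float],
    metric: str,
    include_root: bool = True,
    denominator: str = "relative_abundance",
) -> tuple[float, float]:
    """Exact mean and sample sd of a metric over *all* tip-label
    permutations of the pool (feasible for pools of <= 6-7 tips)."""
    pool = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    present = sorted(s for s, f in abund.items() if f > 0)
    values = []
    for perm in itertools.permutations(pool):
        mapping = dict(zip(pool, perm))
        shuffled = {mapping[s]: abund[s] for s in present}
        if metric == "pd":
            values.append(naive_pd(tree, list(shuffled), include_root=include_root))
        elif metric == "mpd":
            values.append(naive_mpd(tree, shuffled))
        elif metric == "mntd":
            values.append(naive_mntd(tree, shuffled, denominator=denominator))
        else:
            raise ValueError(metric)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)
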