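"""Phylogenetic alpha-diversity metrics per plot.

Three metrics are computed for each assemblage:

* **Faith's PD** — the sum of branch lengths of the minimal subtree
  spanning the species present.  By default the path up to the tree root
  is included (``include_root=True``), so even a single-species plot has
  a positive PD; a switch drops the root-ward path above the assemblage
  MRCA.

* **Abundance-weighted MPD** — the mean patristic distance over ordered
  heterospecific pairs, weighted by abundance products:
  ``sum_{i != j} d_ij f_i f_j / sum_{i != j} f_i f_j``.

* **Abundance-weighted MNTD** — each species' distance to its nearest
  heterospecific neighbour, averaged with abundance weights.  The default
  denominator is ``sum f_i`` (a true weighted mean, invariant to scaling
  all abundances); ``denominator="as_printed_n"`` divides the raw
  frequency-weighted sum by the species count instead, a literal variant
  kept for audit.

MPD and MNTD are undefined for plots with fewer than two species and are
reported as missing with a ``singleton`` flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import CommunityMatrix, patristic_distances, tip_labels

__all__ = [
    "faith_pd",
    "mpd_weighted",
    "mntd_weighted",
    "plot_phylo_metrics",
    "PhyloIndex",
]


class PhyloIndex:
    """Vectorised view of a tree: edge lengths, tip->ancestor-edge incidence
    and the patristic distance matrix, indexed by tip label.

    PD of a tip set is the total length of edges ancestral to at least
    one member; the root-ward path above the MRCA is exactly the set of
    edges ancestral to *all* members, which gives the ``include_root``
    switch a closed form.  Used directly by the null models, where the
    same structure is re-scored under thousands of label permutations.
    """

    def __init__(self, tree: dendropy.Tree):
        self.labels: list[str] = tip_labels(tree)
        self.index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        self.edge_lengths = np.array([e.length for e in edges], dtype=float)
        edge_pos = {id(e): k for k, e in enumerate(edges)}
        n, m = len(self.labels), len(edges)
        mask = np.zeros((n, m), dtype=bool)
        for leaf in tree.leaf_node_iter():
            i = self.index[leaf.taxon.label]
            node = leaf
            while node.edge is not None and node.edge.tail_node is not None:
                mask[i, edge_pos[id(node.edge)]] = True
                node = node.parent_node
        self.tip_edge_mask = mask
        self.dist = (
            patristic_distances(tree).loc[self.labels, self.labels].to_numpy()
            if n >= 2
            else np.zeros((1, 1))
        )

    # -- metric kernels on integer tip indices ------------------------------

    def pd_of(self, idx: np.ndarray, include_root: bool = True) -> float:
        sub = self.tip_edge_mask[idx]
        total = float(self.edge_lengths[sub.any(axis=0)].sum())
        if include_root:
            return total
        return total - float(self.edge_lengths[sub.all(axis=0)].sum())

    def mpd_of(self, idx: np.ndarray, weights: np.ndarray) -> float:
        d = self.dist[np.ix_(idx, idx)]
        w = np.outer(weights, weights).astype(float)
        np.fill_diagonal(w, 0.0)
        return float((d * w).sum() / w.sum())

    def mntd_of(
        self, idx: np.ndarray, weights: np.ndarray, denominator: str = "relative_abundance"
    ) -> float:
        d = self.dist[np.ix_(idx, idx)].astype(float)
        np.fill_diagonal(d, np.inf)
        mins = d.min(axis=1)
        w = weights.astype(float)
        if denominator == "relative_abundance":
            return float((mins * w).sum() / w.sum())
        if denominator == "as_printed_n":
            return float((mins * w).sum() / len(idx))
        raise ValueError(f"unknown denominator {denominator!r}")


def faith_pd(tree: dendropy.Tree, present: Iterable[str], include_root: bool = True) -> float:
    """Faith's PD: total branch length of the subtree spanning ``present``."""
    labels = set(present)
    if not labels:
        raise ValueError("empty species set")
    idx = PhyloIndex(tree)
    unknown = labels - set(idx.labels)
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    positions = np.array([idx.index[lab] for lab in sorted(labels)])
    return idx.pd_of(positions, include_root=include_root)


def _positive(abund: Mapping[str, float]) -> dict[str, float]:
    return {sp: f for sp, f in abund.items() if f > 0}


def mpd_weighted(dist: pd.DataFrame, abund: Mapping[str, float]) -> float:
    """Abundance-weighted mean pairwise distance (NaN for <2 species)."""
    ab = _positive(abund)
    if len(ab) < 2:
        return float("nan")
    species = sorted(ab)
    d = dist.loc[species, species].to_numpy()
    w = np.outer(list(map(ab.get, species)), list(map(ab.get, species))).astype(float)
    np.fill_diagonal(w, 0.0)
    return float((d * w).sum() / w.sum())


def mntd_weighted(
    dist: pd.DataFrame,
    abund: Mapping[str, float],
    denominator: str = "relative_abundance",
) -> float:
    """Abundance-weighted mean nearest-taxon distance (NaN for <2 species)."""
    ab = _positive(abund)
    if len(ab) < 2:
        return float("nan")
    species = sorted(ab)
    d = dist.loc[species, species].to_numpy().astype(float)
    np.fill_diagonal(d, np.inf)
    mins = d.min(axis=1)
    w = np.array([ab[sp] for sp in species], dtype=float)
    if denominator == "relative_abundance":
        return float((mins * w).sum() / w.sum())
    if denominator == "as_printed_n":
        return float((mins * w).sum() / len(species))
    raise ValueError(f"unknown denominator {denominator!r}")


def plot_phylo_metrics(
    matrix: CommunityMatrix,
    tree: dendropy.Tree,
    include_root: bool = True,
    mntd_denominator: str = "relative_abundance",
) -> pd.DataFrame:
    """PD / MPD / MNTD for every plot of a reconciled matrix--tree pair.

    Species present in a plot but missing from the tree are dropped from
    that plot's calculation and flagged; single-species plots get PD but
    missing MPD/MNTD.
    """
    idx = PhyloIndex(tree)
    tree_set = set(idx.labels)
    rows = []
    for plot_id in matrix.plot_ids:
        ab = matrix.plot_abundances(plot_id)
        flags = []
        dropped = [sp for sp in ab.index if sp not in tree_set]
        if dropped:
            flags.append("species_dropped")
            ab = ab[[sp for sp in ab.index if sp in tree_set]]
        n_used = len(ab)
        if n_used == 0:
            rows.append(
                {
                    "plot_id": plot_id,
                    "elevation_m": float(matrix.elevations.loc[plot_id]),
                    "pd": float("nan"),
                    "mpd": float("nan"),
                    "mntd": float("nan"),
                    "n_species_used": 0,
                    "flags": ";".join(flags + ["empty"]),
                }
            )
            continue
        positions = np.array([idx.index[sp] for sp in ab.index])
        weights = ab.to_numpy().astype(float)
        pd_val = idx.pd_of(positions, include_root=include_root)
        if n_used >= 2:
            mpd_val = idx.mpd_of(positions, weights)
            mntd_val = idx.mntd_of(positions, weights, denominator=mntd_denominator)
        else:
            mpd_val = mntd_val = float("nan")
            flags.append("singleton")
        rows.append(
            {
                "plot_id": plot_id,
                "elevation_m": float(matrix.elevations.loc[plot_id]),
                "pd": pd_val,
                "mpd": mpd_val,
                "mntd": mntd_val,
                "n_species_used": n_used,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)
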