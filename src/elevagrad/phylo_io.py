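"""Input/output and reconciliation of phylogenies and community matrices.

The pipeline's two primary inputs are a rooted phylogeny with branch
lengths (Newick) and a plot x species abundance table with per-plot
elevations (delimited text).  This module reads and validates both,
computes patristic distance matrices, prunes trees to taxon subsets, and
keeps tree and matrix label sets consistent when taxa are excluded or
when species lack a placement on the tree.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "ReconcileReport",
    "read_newick",
    "parse_newick",
    "write_newick",
    "read_community",
    "write_community",
    "total_tree_length",
    "patristic_distances",
    "prune_to_taxa",
    "exclude_taxa",
    "reconcile",
    "barcode_recovery_summary",
]


# ---------------------------------------------------------------------------
# community matrix container
# ---------------------------------------------------------------------------


@dataclass
class CommunityMatrix:
    """Plot x species abundance table with per-plot elevations.

    Parameters
    ----------
    counts
        DataFrame indexed by plot id (string), one column per species,
        integer stem counts >= 0.  Column order is the species-pool order.
    elevations
        Series of plot elevations in metres, indexed like ``counts``.
    """

    counts: pd.DataFrame
    elevations: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate plot_id: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate species column: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # allow float input only if every value is a whole number
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise ValueError("abundances must be non-negative integers")
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("abundances must be non-negative integers")
        elev = self.elevations.reindex(counts.index)
        if elev.isna().any():
            missing = elev.index[elev.isna()].tolist()
            raise ValueError(f"missing elevation for plots: {missing}")
        self.elevations = elev.astype(float)

    # -- derived quantities -------------------------------------------------

    @property
    def plot_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_plots(self) -> int:
        return len(self.counts.index)

    @property
    def total_stems(self) -> int:
        return int(self.counts.to_numpy().sum())

    def richness(self) -> pd.Series:
        """Species with abundance > 0, per plot."""
        return (self.counts > 0).sum(axis=1)

    def stems(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def empty_plots(self) -> list[str]:
        """Plots whose richness is zero (e.g. after taxon exclusion)."""
        r = self.richness()
        return list(r.index[r == 0])

    def plot_abundances(self, plot_id: str) -> pd.Series:
        """Non-zero abundance vector for one plot."""
        row = self.counts.loc[plot_id]
        return row[row > 0]

    def subset_plots(self, plot_ids: Iterable[str]) -> "CommunityMatrix":
        ids = list(plot_ids)
        return CommunityMatrix(self.counts.loc[ids], self.elevations.loc[ids])


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ValueError("every tip must carry a label")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            # the root's own edge; a missing length here means "no root edge"
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above {head}")
        if edge.length < 0:
            raise ValueError("negative branch length")
    return tree


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single Newick string into a validated rooted tree.

    Every edge must carry a branch length; a missing length is an error
    rather than an implicit zero, since silently zeroed edges would
    corrupt every branch-length-based metric downstream.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree)


def read_newick(path) -> dendropy.Tree:
    """Read one Newick tree with mandatory branch lengths from a file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialize a tree to Newick; write to ``path`` if given."""
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths in the tree."""
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# community matrix I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("plot_id", "elevation_m")


def read_community(path) -> CommunityMatrix:
    """Read a plot x species table from comma- or tab-delimited text.

    The first row is a header with columns ``plot_id``, ``elevation_m``
    and then one column per species; cells hold integer stem counts and
    blank cells are read as zero.  The delimiter is auto-detected from
    the header line.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype={"plot_id": str})
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df["plot_id"].isna().any():
        raise ValueError("missing plot_id")
    df = df.set_index("plot_id")
    elevations = pd.to_numeric(df["elevation_m"], errors="raise")
    if elevations.isna().any():
        raise ValueError("missing elevation")
    counts = df.drop(columns=["elevation_m"]).fillna(0)
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer abundance: {exc}") from exc
    # exact integrality check for float inputs like "3.5"
    raw = df.drop(columns=["elevation_m"]).fillna(0).astype(float)
    if not np.allclose(raw.to_numpy(), counts.to_numpy()):
        raise ValueError("non-integer abundance")
    return CommunityMatrix(counts, elevations)


def write_community(matrix: CommunityMatrix, path, sep: str = ",") -> None:
    df = matrix.counts.copy()
    df.insert(0, "elevation_m", matrix.elevations)
    df.index.name = "plot_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# tree operations
# ---------------------------------------------------------------------------


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric matrix of tip-to-tip path-length (patristic) distances."""
    labels = tip_labels(tree)
    if len(labels) < 2:
        raise ValueError("patristic distances require at least 2 tips")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``taxa``, keeping the path to the original root.

    Internal nodes left with a single child are collapsed, summing branch
    lengths.  The root-ward path of the retained clade is preserved, so a
    single-taxon assemblage keeps its full root-to-tip path length.
    """
    keep = set(taxa)
    if not keep:
        raise ValueError("empty taxon set")
    present = set(tip_labels(tree))
    unknown = keep - present
    if unknown:
        raise ValueError(f"unknown tip labels: {sorted(unknown)}")
    pruned = tree.clone(depth=1)
    if keep != present:
        pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


def exclude_taxa(
    matrix: CommunityMatrix, tree: dendropy.Tree, taxa: Iterable[str]
) -> tuple[CommunityMatrix, dendropy.Tree]:
    """Drop the named taxa from both the matrix columns and the tree tips.

    Plots whose richness drops to zero are retained (see
    ``CommunityMatrix.empty_plots``).  Excluding every species of the
    pool is an error.
    """
    drop = set(taxa)
    if not drop:
        return matrix, tree
    pool = set(matrix.species) | set(tip_labels(tree))
    keep_tree = [lab for lab in tip_labels(tree) if lab not in drop]
    keep_cols = [sp for sp in matrix.species if sp not in drop]
    if not keep_tree or not keep_cols:
        raise ValueError("cannot exclude the entire species pool")
    unknown = drop - pool
    if unknown:
        raise ValueError(f"taxa not in pool: {sorted(unknown)}")
    new_matrix = CommunityMatrix(matrix.counts[keep_cols], matrix.elevations)
    new_tree = prune_to_taxa(tree, keep_tree)
    return new_matrix, new_tree


@dataclass
class ReconcileReport:
    """Bookkeeping from matching the matrix species pool to the tree tips."""

    species_in_matrix: int
    species_in_tree: int
    species_retained: int
    dropped_from_matrix: list[str] = field(default_factory=list)
    dropped_from_tree: list[str] = field(default_factory=list)
    stems_dropped: int = 0
    stems_total: int = 0

    @property
    def fraction_species_dropped(self) -> float:
        """Fraction of matrix species without a tree placement."""
        return len(self.dropped_from_matrix) / self.species_in_matrix

    @property
    def percent_species_dropped(self) -> float:
        return 100.0 * self.fraction_species_dropped

    @property
    def fraction_individuals_dropped(self) -> float:
        """Fraction of stems belonging to species without a placement."""
        return self.stems_dropped / self.stems_total if self.stems_total else 0.0

    @property
    def percent_individuals_dropped(self) -> float:
        return 100.0 * self.fraction_individuals_dropped


def reconcile(
    matrix: CommunityMatrix, tree: dendropy.Tree
) -> tuple[CommunityMatrix, dendropy.Tree, ReconcileReport]:
    """Restrict matrix and tree to their shared species pool.

    Species recorded in the plots but absent from the phylogeny (e.g.
    taxa for which no barcode sequence could be recovered) are dropped
    from the matrix, and vice versa; the report records what was dropped
    and the fraction of individuals it represents.
    """
    mat_species = list(matrix.species)
    tree_species = tip_labels(tree)
    shared = [sp for sp in mat_species if sp in set(tree_species)]
    if not shared:
        raise ValueError("matrix and tree share no species")
    dropped_mat = [sp for sp in mat_species if sp not in set(shared)]
    dropped_tree = [sp for sp in tree_species if sp not in set(shared)]
    stems_total = matrix.total_stems
    stems_dropped = int(matrix.counts[dropped_mat].to_numpy().sum()) if dropped_mat else 0
    new_matrix = CommunityMatrix(matrix.counts[shared], matrix.elevations)
    new_tree = prune_to_taxa(tree, shared) if dropped_tree else tree
    report = ReconcileReport(
        species_in_matrix=len(mat_species),
        species_in_tree=len(tree_species),
        species_retained=len(shared),
        dropped_from_matrix=dropped_mat,
        dropped_from_tree=dropped_tree,
        stems_dropped=stems_dropped,
        stems_total=stems_total,
    )
    return new_matrix, new_tree, report


def barcode_recovery_summary(
    n_species_total: int, n_species_sequenced: int, n_dual_locus: int
) -> Mapping[str, float]:
    """Percent bookkeeping for barcode sequencing recovery.

    Given the species pool size, the number of species with at least one
    recovered locus, and the number with both loci, return the recovery
    percentages a survey would report.
    """
    if not 0 <= n_dual_locus <= n_species_sequenced <= n_species_total:
        raise ValueError("inconsistent recovery counts")
    return {
        "percent_unsequenced": 100.0 * (n_species_total - n_species_sequenced) / n_species_total,
        "percent_sequenced": 100.0 * n_species_sequenced / n_species_total,
        "percent_dual_locus": 100.0 * n_dual_locus / n_species_sequenced,
        "percent_single_locus": 100.0 * (n_species_sequenced - n_dual_locus) / n_species_sequenced,
    }
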