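"""Synthetic phylogenies and gradient-structured communities.

The generator emulates the shape of a montane-forest elevational
transect — 15 plots spanning 2440-3330 m, a pool of ~70-88 tree species
on one phylogeny, per-plot richness declining linearly with elevation,
17-100 stems per plot — with a *known* assembly mechanism, so every
downstream stage (diversity metrics, null models, gradient analyses) has
an input whose expected behaviour is controlled:

* ``neutral``   — species drawn uniformly without replacement; plots
  should look random to the tip-shuffle null.
* ``filtering`` — Brownian trait evolved on the tree; plots prefer
  species whose trait is near a linearly elevation-mapped optimum
  (Gaussian kernel, width ``filtering_strength``).  Because the trait
  carries phylogenetic signal, filtering co-selects clades and should
  produce negative SES (clustering).
* ``repulsion`` — species added sequentially with weight proportional to
  their minimum patristic distance to the species already chosen;
  should produce positive SES (overdispersion).

``fern_injection`` grafts two long-branch, highly abundant taxa next to
the root (mimicking tree ferns among angiosperms) into a contiguous
elevation band, which inflates basal pairwise distances in exactly the
plots that host them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import CommunityMatrix, patristic_distances, tip_labels

__all__ = [
    "AssemblyScenario",
    "simulate_tree",
    "evolve_trait",
    "attach_ferns",
    "simulate_communities",
    "simulate_scenario",
    "make_fixture",
    "FERN_LABELS",
]

FERN_LABELS = ("fern01", "fern02")


@dataclass(frozen=True)
class AssemblyScenario:
    """Parameters of the gradient-community generator.

    Defaults follow the transect template: 70 species, 15 plots over
    2440-3330 m, richness falling from ~17 species at the base at about
    7 species per km of ascent, geometric (rank-abundance) stem counts
    with mean ~1/abundance_param stems per species.
    """

    n_species: int = 70
    n_plots: int = 15
    elevation_min: float = 2440.0
    elevation_max: float = 3330.0
    richness_at_base: float = 17.0
    richness_slope: float = -7.0  # species per km, negative = decline
    assembly: str = "neutral"  # neutral | filtering | repulsion
    filtering_strength: float = 0.5  # Gaussian kernel width, trait units
    trait_rate: float = 1.0  # Brownian variance per unit branch length
    abundance_model: str = "geometric"  # geometric | log-series
    abundance_param: float = 0.25
    fern_injection: bool = False
    fern_abundance: int = 7
    fern_band: tuple[float, float] = (0.0, 0.6)  # fraction of the gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.n_plots < 3:
            raise ValueError("n_plots must be >= 3")
        if self.assembly not in ("neutral", "filtering", "repulsion"):
            raise ValueError(f"unknown assembly {self.assembly!r}")
        if self.abundance_model not in ("geometric", "log-series"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.target_richness(self.elevation_max) < 1:
            raise ValueError("expected richness < 1 at the top of the gradient")

    def target_richness(self, elevation: float) -> int:
        s = self.richness_at_base + self.richness_slope * (elevation - self.elevation_min) / 1000.0
        return int(round(s))

    def elevations(self) -> np.ndarray:
        return np.linspace(self.elevation_min, self.elevation_max, self.n_plots)


# ---------------------------------------------------------------------------
# tree and trait simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times.

    Starting from the root split, a uniformly chosen extant lineage
    splits after an Exp(birth_rate * k) wait (k = current lineage
    count); after the n-th tip appears all pendant edges are extended by
    one further waiting time, so the tree is ultrametric.  Tips are
    labelled sp001, sp002, ... in birth order; the same seed reproduces
    the same Newick string.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    t_now = 0.0
    # (node, birth_time) for extant lineages
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t_now))
    while len(active) < n_tips:
        k = len(active)
        t_now += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.edge.length = t_now - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t_now))
    t_end = t_now + rng.exponential(1.0 / (birth_rate * len(active)))
    width = len(str(max(n_tips, 999)))
    for j, (node, birth) in enumerate(active, start=1):
        node.edge.length = t_end - birth
        taxon = taxa.new_taxon(label=f"sp{j:0{width}d}")
        node.taxon = taxon
    root.edge.length = 0.0
    return tree


def evolve_trait(tree: dendropy.Tree, rate: float, seed: int) -> dict[str, float]:
    """Brownian-motion trait along the tree: tip variance = rate x depth."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(rate * length)) if rate > 0 and length > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
    return {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}


def attach_ferns(
    tree: dendropy.Tree, stem_factor: float = 1.5, cherry_factor: float = 0.5
) -> dendropy.Tree:
    """Graft a long-branch two-tip cherry next to the root.

    The cherry's stem is ``stem_factor`` x the maximum root-to-tip depth
    and each cherry edge ``cherry_factor`` x depth, so the grafted pair
    is far from every resident tip but close to each other — the
    signature of tree ferns inside an angiosperm phylogeny.
    """
    tree = tree.clone(depth=1)
    depth = max(
        leaf.distance_from_root() for leaf in tree.leaf_node_iter()
    )
    anc = dendropy.Node()
    tree.seed_node.add_child(anc)
    anc.edge.length = stem_factor * depth
    for label in FERN_LABELS:
        tip = dendropy.Node()
        anc.add_child(tip)
        tip.edge.length = cherry_factor * depth
        tip.taxon = tree.taxon_namespace.new_taxon(label=label)
    return tree


# ---------------------------------------------------------------------------
# community assembly
# ---------------------------------------------------------------------------


def _weighted_subset(
    rng: np.random.Generator, labels: list[str], weights: np.ndarray, k: int
) -> list[str]:
    """Weighted sampling without replacement via the Gumbel-top-k trick."""
    logw = np.log(np.clip(weights, 1e-300, None))
    keys = logw + rng.gumbel(size=len(labels))
    order = np.argsort(keys)[::-1][:k]
    return [labels[i] for i in order]


def _repulsion_subset(
    rng: np.random.Generator, labels: list[str], dist: np.ndarray, k: int
) -> list[str]:
    chosen = [int(rng.integers(len(labels)))]
    while len(chosen) < k:
        remaining = [i for i in range(len(labels)) if i not in set(chosen)]
        w = np.array([dist[i, chosen].min() for i in remaining], dtype=float)
        if w.sum() <= 0:
            w = np.ones(len(remaining))
        w = w / w.sum()
        chosen.append(int(rng.choice(remaining, p=w)))
    return [labels[i] for i in chosen]


def _abundances(rng: np.random.Generator, scenario: AssemblyScenario, k: int) -> np.ndarray:
    if scenario.abundance_model == "geometric":
        return rng.geometric(scenario.abundance_param, size=k)
    return rng.logseries(1.0 - scenario.abundance_param, size=k)


def simulate_communities(
    tree: dendropy.Tree,
    traits: Mapping[str, float] | None,
    scenario: AssemblyScenario,
) -> CommunityMatrix:
    """Assemble one plot per elevation step under the scenario's mechanism.

    The species pool is the tree's tips minus any injected fern labels;
    per-plot richness follows the linear elevational decline exactly, and
    stem counts come from the rank-abundance model.  With
    ``fern_injection`` the two fern tips are added, at high abundance,
    to every plot inside the configured elevation band.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(scenario.seed, 0x9E3779B9)))
    pool = [lab for lab in tip_labels(tree) if lab not in FERN_LABELS]
    if scenario.fern_injection:
        missing = set(FERN_LABELS) - set(tip_labels(tree))
        if missing:
            raise ValueError(f"fern_injection requires fern tips on the tree: {sorted(missing)}")
    elevations = scenario.elevations()
    if scenario.assembly == "filtering":
        if traits is None:
            raise ValueError("filtering assembly requires traits")
        tvec = np.array([traits[sp] for sp in pool], dtype=float)
        t_lo, t_hi = float(tvec.min()), float(tvec.max())
    elif scenario.assembly == "repulsion":
        dist_df = patristic_distances(tree)
        dist = dist_df.loc[pool, pool].to_numpy()

    e_lo, e_hi = scenario.elevation_min, scenario.elevation_max
    band_lo = e_lo + scenario.fern_band[0] * (e_hi - e_lo)
    band_hi = e_lo + scenario.fern_band[1] * (e_hi - e_lo)

    width = len(str(scenario.n_plots))
    plot_ids = [f"plot{i + 1:0{width}d}" for i in range(scenario.n_plots)]
    counts = pd.DataFrame(
         0, index=plot_ids, columns=list(tip_labels(tree)), dtype=np.int64
    )
    for plot_id, elev in zip(plot_ids, elevations):
        k = scenario.target_richness(elev)
        if k < 1:
            raise ValueError(f"target richness < 1 at {elev} m")
        if k > len(pool):
            raise ValueError(f"target richness {k} exceeds pool of {len(pool)}")
        if scenario.assembly == "neutral":
            chosen = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        elif scenario.assembly == "filtering":
            optimum = t_lo + (t_hi - t_lo) * (elev - e_lo) / (e_hi - e_lo)
            w = np.exp(-((tvec - optimum) ** 2) / (2.0 * scenario.filtering_strength**2))
            chosen = _weighted_subset(rng, pool, w, k)
        else:
            chosen = _repulsion_subset(rng, pool, dist, k)
        counts.loc[plot_id, chosen] = _abundances(rng, scenario, k)
        if scenario.fern_injection and band_lo <= elev <= band_hi:
            for fern in FERN_LABELS:
                counts.loc[plot_id, fern] = scenario.fern_abundance + int(rng.integers(0, 4))
    if not scenario.fern_injection:
        counts = counts[[c for c in counts.columns if c not in FERN_LABELS]]
    return CommunityMatrix(counts, pd.Series(elevations, index=plot_ids))


def simulate_scenario(
    scenario: AssemblyScenario,
) -> tuple[dendropy.Tree, CommunityMatrix, dict[str, float]]:
    """Tree + traits + communities for a scenario, from its single seed."""
    ss = np.random.SeedSequence(scenario.seed)
    tree_seed, trait_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    tree = simulate_tree(scenario.n_species, seed=tree_seed)
    if scenario.fern_injection:
        tree = attach_ferns(tree)
    traits = evolve_trait(tree, rate=scenario.trait_rate, seed=trait_seed)
    matrix = simulate_communities(tree, traits, scenario)
    return tree, matrix, traits


# ---------------------------------------------------------------------------
# deterministic transect-shaped fixture
# ---------------------------------------------------------------------------

_FIXTURE_SEED = 20190905  # fixed: the fixture must be byte-identical


def make_fixture(style: str = "table1_shape") -> tuple[dendropy.Tree, CommunityMatrix]:
    """Deterministic fixture mirroring the transect's printed margins.

    Per-plot stem counts and species richness equal the published
    summary-table columns (15 plots, 88-species pool, 595 stems in
    total); abundances are filled by a deterministic halving rule that
    respects those margins and yields a dominant-species structure.  The
    tree covers the 70 most abundant species (emulating the fraction of
    the pool with recovered barcode sequences), with the two most
    abundant taxa grafted near the root as long-branch fern analogues.
    """
    if style != "table1_shape":
        raise ValueError(f"unknown fixture style {style!r}")
    from .datasets import transect_summary

    summary = transect_summary()
    n_pool = 88
    species = [f"sp{i + 1:03d}" for i in range(n_pool)]
    counts = pd.DataFrame(
        0, index=summary["plot_id"].tolist(), columns=species, dtype=np.int64
    )
    n_plots = len(summary)
    for i, row in summary.iterrows():
        s, n = int(row["richness"]), int(row["n_stems"])
        start = round(i * (n_pool - s) / (n_plots - 1))
        chosen = species[start : start + s]
        ab = np.ones(s, dtype=np.int64)
        remaining = n - s
        j = 0
        while remaining > 0:
            give = (remaining + 1) // 2
            ab[j % s] += give
            remaining -= give
            j += 1
        counts.loc[row["plot_id"], chosen] = ab
    elevations = pd.Series(
        summary["elevation_m"].astype(float).tolist(), index=summary["plot_id"].tolist()
    )
    matrix = CommunityMatrix(counts, elevations)

    totals = matrix.counts.sum(axis=0)
    ranked = sorted(species, key=lambda sp: (-totals[sp], sp))
    sequenced = sorted(ranked[:70])
    fern_like = ranked[:2]  # most abundant taxa act as the fern analogues
    backbone = [sp for sp in sequenced if sp not in fern_like]
    tree = simulate_tree(len(backbone), seed=_FIXTURE_SEED)
    for leaf, label in zip(tree.leaf_node_iter(), backbone):
        leaf.taxon.label = label
    tree = attach_ferns(tree)
    relabel = dict(zip(FERN_LABELS, fern_like))
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in relabel:
            leaf.taxon.label = relabel[leaf.taxon.label]
    return tree, matrix
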