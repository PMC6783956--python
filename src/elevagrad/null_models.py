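"""Tip-label randomization null models and standardized effect sizes.

The null model permutes species names across *all* tips of the analysis
phylogeny while holding the community matrix fixed, so richness,
occupancy and abundance structure are preserved and only relatedness is
randomized.  Each observed metric is compared with the distribution of
the metric over ``reps`` (default 999) such permutations:

    SES (obs.z) = (observed - mean(null)) / sd(null)

with sd the sample standard deviation (n-1).  The quantile position
(obs.p) uses an add-one rank rule with ties split at half weight,

    obs.p = (#{null < obs} + 0.5 #{null = obs} + 1) / (reps + 1),

which avoids degenerate 0/1 p-values at finite replicate counts.  Plots
are classified clustered when obs.p < 0.05, overdispersed when
obs.p > 0.95, random otherwise; a null distribution with zero spread
(e.g. a star phylogeny, where every permutation is isometric) yields an
``undefined`` classification.

Randomization is reproducible: a master seed plus the plot id determine
each plot's permutation stream via a stable hash, independent of the
order in which plots are processed.  By default the same permutations
are reused across the three metrics of a plot, so cross-metric
comparisons are paired.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import CommunityMatrix
from .phylo_diversity import PhyloIndex

__all__ = [
    "NullEnsemble",
    "SESResult",
    "tip_shuffle",
    "null_distribution",
    "ses",
    "classify",
    "ses_table",
]

METRICS = ("pd", "mpd", "mntd")

CLUSTERED_BELOW = 0.05
OVERDISPERSED_ABOVE = 0.95


@dataclass
class NullEnsemble:
    metric: str
    plot_id: str
    observed: float
    null_values: np.ndarray
    reps: int
    seed: int

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if len(self.null_values) != self.reps:
            raise ValueError("null_values length must equal reps")


@dataclass
class SESResult:
    metric: str
    plot_id: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    quantile_p: float
    classification: str


def _plot_seed(master_seed: int, plot_id: str) -> np.random.SeedSequence:
    """Stable per-plot child seed, independent of processing order."""
    return np.random.SeedSequence(entropy=(int(master_seed), zlib.crc32(str(plot_id).encode())))


def tip_shuffle(pool: Sequence[str], rng: np.random.Generator) -> list[str]:
    """One uniformly random permutation of the tip-label pool."""
    pool = list(pool)
    if not pool:
        raise ValueError("empty tip pool")
    return [pool[i] for i in rng.permutation(len(pool))]


def classify(quantile_p: float) -> str:
    """Clustered / overdispersed / random by the 0.05 / 0.95 thresholds.

    The add-one rank rule keeps quantiles strictly above zero but an
    observation above every null value lands exactly at 1, so the valid
    domain is (0, 1].
    """
    if not 0.0 < quantile_p <= 1.0:
        raise ValueError(f"quantile_p must be in (0,1], got {quantile_p}")
    if quantile_p < CLUSTERED_BELOW:
        return "clustered"
    if quantile_p > OVERDISPERSED_ABOVE:
        return "overdispersed"
    return "random"


def ses(ensemble: NullEnsemble) -> SESResult:
    """Standardized effect size and quantile position of the observed value."""
    null = ensemble.null_values
    obs = ensemble.observed
    mean = float(np.mean(null))
    sd = float(np.std(null, ddof=1)) if len(null) > 1 else 0.0
    if not np.isfinite(obs) or sd == 0.0:
        return SESResult(
            ensemble.metric, ensemble.plot_id, obs, mean, sd,
            float("nan"), float("nan"), "undefined",
        )
    z = (obs - mean) / sd
    below = int(np.count_nonzero(null < obs))
    ties = int(np.count_nonzero(null == obs))
    p = (below + 0.5 * ties + 1.0) / (ensemble.reps + 1.0)
    return SESResult(ensemble.metric, ensemble.plot_id, obs, mean, sd, z, p, classify(p))


# ---------------------------------------------------------------------------
# ensemble construction
# ---------------------------------------------------------------------------


def _plot_ensembles(
    index: PhyloIndex,
    plot_id: str,
    abundances: pd.Series,
    metrics: Sequence[str],
    reps: int,
    seed: int,
    include_root: bool,
    mntd_denominator: str,
    shared_permutations: bool,
) -> dict[str, NullEnsemble]:
    """Null ensembles for one plot; permutations shared across metrics."""
    present = [sp for sp in abundances.index if sp in index.index]
    positions = np.array([index.index[sp] for sp in present], dtype=int)
    weights = abundances.loc[present].to_numpy().astype(float)
    n_pool = len(index.labels)

    def observed(metric: str) -> float:
        if len(positions) == 0:
            return float("nan")
        if metric == "pd":
            return index.pd_of(positions, include_root=include_root)
        if len(positions) < 2:
            return float("nan")
        if metric == "mpd":
            return index.mpd_of(positions, weights)
        if metric == "mntd":
            return index.mntd_of(positions, weights, denominator=mntd_denominator)
        raise ValueError(f"unknown metric {metric!r}")

    out: dict[str, NullEnsemble] = {}
    ss = _plot_seed(seed, plot_id)
    if shared_permutations:
        streams = {m: np.random.default_rng(ss) for m in metrics}
    else:
        children = ss.spawn(len(metrics))
        streams = {m: np.random.default_rng(c) for m, c in zip(metrics, children)}

    for metric in metrics:
        obs = observed(metric)
        rng = streams[metric]
        nulls = np.full(reps, np.nan)
        computable = np.isfinite(obs)
        for r in range(reps):
            perm = rng.permutation(n_pool)
            if not computable:
                continue
            mapped = perm[positions]
            if metric == "pd":
                nulls[r] = index.pd_of(mapped, include_root=include_root)
            elif metric == "mpd":
                nulls[r] = index.mpd_of(mapped, weights)
            else:
                nulls[r] = index.mntd_of(mapped, weights, denominator=mntd_denominator)
        out[metric] = NullEnsemble(metric, plot_id, obs, nulls, reps, seed)
    return out


def null_distribution(
    metric: str,
    plot_id: str,
    tree: dendropy.Tree,
    matrix: CommunityMatrix,
    reps: int = 999,
    seed: int = 0,
    include_root: bool = True,
    mntd_denominator: str = "relative_abundance",
) -> NullEnsemble:
    """Null ensemble of one metric for one plot under tip shuffling."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    index = PhyloIndex(tree)
    ab = matrix.plot_abundances(plot_id)
    ens = _plot_ensembles(
        index, plot_id, ab, (metric,), reps, seed, include_root, mntd_denominator, True
    )
    return ens[metric]


def ses_table(
    matrix: CommunityMatrix,
    tree: dendropy.Tree,
    metrics: Iterable[str] = METRICS,
    reps: int = 999,
    seed: int = 0,
    include_root: bool = True,
    mntd_denominator: str = "relative_abundance",
    shared_permutations: bool = True,
    scenario: str = "all_taxa",
) -> pd.DataFrame:
    """Tidy SES results: one row per (plot, metric).

    Columns: plot_id, elevation_m, metric, scenario, observed, null_mean,
    null_sd, ses, quantile_p, classification.
    """
    metrics = tuple(metrics)
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}")
    index = PhyloIndex(tree)
    rows = []
    for plot_id in matrix.plot_ids:
        ab = matrix.plot_abundances(plot_id)
        ens = _plot_ensembles(
            index, plot_id, ab, metrics, reps, seed,
            include_root, mntd_denominator, shared_permutations,
        )
        for m in metrics:
            res = ses(ens[m])
            rows.append(
                {
                    "plot_id": plot_id,
                    "elevation_m": float(matrix.elevations.loc[plot_id]),
                    "metric": m,
                    "scenario": scenario,
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "ses": res.ses,
                    "quantile_p": res.quantile_p,
                    "classification": res.classification,
                }
            )
    return pd.DataFrame(rows)
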