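"""Gradient correlations, plot-exclusion sensitivity, significance
summaries and species elevational-range statistics.

Diversity metrics are related to elevation by Pearson product-moment
correlation with a two-sided t test (n-2 df), significance at p < 0.05,
no multiple-testing correction.  Missing metric values (singleton plots,
undefined SES) are dropped pairwise before correlating, with the n used
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_io import CommunityMatrix

__all__ = [
    "GradientCorrelation",
    "SignificanceSummary",
    "pearson",
    "exclude_plots_rerun",
    "summarize_significance",
    "species_ranges",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GradientCorrelation:
    metric: str
    scenario: str
    n_plots: int
    r: float
    p_value: float
    excluded_plot_ids: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < SIGNIFICANCE_LEVEL


@dataclass
class SignificanceSummary:
    scenario: str
    clustered: int
    overdispersed: int

    @property
    def nonrandom(self) -> int:
        return self.clustered + self.overdispersed


def pearson(
    values: Sequence[float],
    elevations: Sequence[float],
    metric: str = "",
    scenario: str = "",
    excluded_plot_ids: Iterable[str] = (),
) -> GradientCorrelation:
    """Pearson r between a metric and elevation, two-sided p (t, n-2 df).

    Pairs with a missing value on either side are dropped listwise.
    Fewer than 3 complete pairs, or zero variance in either vector,
    yields an undefined (NaN) correlation.
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(elevations, dtype=float)
    if v.shape != e.shape:
        raise ValueError("values and elevations must have equal length")
    ok = np.isfinite(v) & np.isfinite(e)
    v, e = v[ok], e[ok]
    n = len(v)
    if n < 3 or np.std(v) == 0 or np.std(e) == 0:
        return GradientCorrelation(
            metric, scenario, n, float("nan"), float("nan"), tuple(excluded_plot_ids)
        )
    r, p = stats.pearsonr(v, e)
    return GradientCorrelation(metric, scenario, n, float(r), float(p), tuple(excluded_plot_ids))


def exclude_plots_rerun(
    table: pd.DataFrame,
    value_column: str,
    exclude_plot_ids: Iterable[str],
    metric: str = "",
    scenario: str = "",
) -> tuple[GradientCorrelation, GradientCorrelation]:
    """Correlation with all plots and with the named plots excluded.

    ``table`` needs columns ``plot_id``, ``elevation_m`` and
    ``value_column``.  Returns (full, subset); at least 3 plots must
    remain after exclusion.
    """
    for col in ("plot_id", "elevation_m", value_column):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    full = pearson(table[value_column], table["elevation_m"], metric, scenario)
    drop = {str(p) for p in exclude_plot_ids}
    unknown = drop - set(table["plot_id"].astype(str))
    if unknown:
        raise ValueError(f"unknown plot ids: {sorted(unknown)}")
    sub = table[~table["plot_id"].astype(str).isin(drop)]
    if len(sub) < 3:
        raise ValueError("fewer than 3 plots remain after exclusion")
    subset = pearson(
        sub[value_column], sub["elevation_m"], metric, scenario, excluded_plot_ids=sorted(drop)
    )
    return full, subset


def summarize_significance(classifications: pd.DataFrame, scenario: str = "") -> SignificanceSummary:
    """Count clustered / overdispersed cells across a (plot, metric) table.

    ``classifications`` needs a ``classification`` column with values in
    {clustered, overdispersed, random, undefined}; if a ``scenario``
    column exists and ``scenario`` is non-empty, rows are filtered to it.
    """
    df = classifications
    if scenario and "scenario" in df.columns:
        df = df[df["scenario"] == scenario]
    cls = df["classification"]
    bad = set(cls.unique()) - {"clustered", "overdispersed", "random", "undefined"}
    if bad:
        raise ValueError(f"unknown classification values: {sorted(bad)}")
    return SignificanceSummary(
        scenario=scenario,
        clustered=int((cls == "clustered").sum()),
        overdispersed=int((cls == "overdispersed").sum()),
    )


@dataclass
class SpeciesRangeRecord:
    species: str
    min_elevation: float
    max_elevation: float
    plots: tuple[str, ...] = field(default_factory=tuple)
    exclusive_to_focal: bool = False
    range_within_focal: bool = False


def species_ranges(
    matrix: CommunityMatrix,
    focal_plots: Iterable[str],
    containment: str = "upward",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Elevational occurrence ranges, with focal-plot overlap fractions.

    For the species that occur in ``focal_plots`` the summary reports the
    fraction that are (a) exclusive to those plots and (b) whose
    elevational range does not exceed them.  ``containment="upward"``
    (default) requires only the species' maximum elevation not to exceed
    the focal maximum — the reading natural for floras colliding from
    below; ``"two_sided"`` additionally bounds the minimum.
    """
    focal = {str(p) for p in focal_plots}
    if not focal:
        raise ValueError("empty focal plot set")
    unknown = focal - set(map(str, matrix.plot_ids))
    if unknown:
        raise ValueError(f"unknown focal plots: {sorted(unknown)}")
    if containment not in ("upward", "two_sided"):
        raise ValueError(f"unknown containment mode {containment!r}")

    elev = matrix.elevations
    focal_max = max(elev.loc[p] for p in focal)
    focal_min = min(elev.loc[p] for p in focal)

    records: list[SpeciesRangeRecord] = []
    for sp in matrix.species:
        col = matrix.counts[sp]
        plots = tuple(str(p) for p in col.index[col > 0])
        if not plots:
            continue
        elevs = elev.loc[list(plots)]
        in_focal = any(p in focal for p in plots)
        exclusive = in_focal and all(p in focal for p in plots)
        if containment == "upward":
            contained = in_focal and float(elevs.max()) <= focal_max
        else:
            contained = in_focal and float(elevs.max()) <= focal_max and float(elevs.min()) >= focal_min
        records.append(
            SpeciesRangeRecord(
                species=sp,
                min_elevation=float(elevs.min()),
                max_elevation=float(elevs.max()),
                plots=plots,
                exclusive_to_focal=exclusive,
                range_within_focal=contained,
            )
        )
    df = pd.DataFrame(
        {
            "species": [r.species for r in records],
            "min_elevation": [r.min_elevation for r in records],
            "max_elevation": [r.max_elevation for r in records],
            "n_plots": [len(r.plots) for r in records],
            "exclusive_to_focal": [r.exclusive_to_focal for r in records],
            "range_within_focal": [r.range_within_focal for r in records],
        }
    )
    occurs_in_focal = [
        r for r in records if any(p in focal for p in r.plots)
    ]
    n_focal_species = len(occurs_in_focal)
    summary = {
        "n_focal_species": float(n_focal_species),
        "fraction_exclusive": (
            sum(r.exclusive_to_focal for r in occurs_in_focal) / n_focal_species
            if n_focal_species
            else float("nan")
        ),
        "fraction_range_within": (
            sum(r.range_within_focal for r in occurs_in_focal) / n_focal_species
            if n_focal_species
            else float("nan")
        ),
    }
    return df, summary
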