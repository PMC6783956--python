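"""Per-plot taxonomic alpha-diversity: richness, Shannon-Weaver H',
Simpson's dominance D2 (inverse Simpson) and Simpson's evenness E = D2/S.

Shannon uses the natural logarithm (the vegan convention), so H' is in
nats and bounded by ln S.  D2 = 1 / sum(p_i^2) is the effective number of
equally common species, bounded by [1, S]; E = D2/S lies in (0, 1].
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .phylo_io import CommunityMatrix

__all__ = [
    "shannon",
    "simpson_dominance",
    "simpson_evenness",
    "plot_metrics",
    "round_half_up",
    "format_metrics_table",
]


def _proportions(abundances) -> np.ndarray:
    f = np.asarray(abundances, dtype=float)
    if f.ndim != 1:
        raise ValueError("abundance vector must be 1-D")
    if np.any(f < 0):
        raise ValueError("negative abundance")
    total = f.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    f = f[f > 0]  # zero columns contribute to the pool, not to p_i
    return f / total


def shannon(abundances) -> float:
    """Shannon-Weaver diversity H' = -sum(p_i ln p_i), in nats."""
    p = _proportions(abundances)
    return float(-(p * np.log(p)).sum())


def simpson_dominance(abundances) -> float:
    """Inverse Simpson index D2 = 1 / sum(p_i^2) (effective species)."""
    p = _proportions(abundances)
    return float(1.0 / (p**2).sum())


def simpson_evenness(d2: float, richness: int) -> float:
    """Simpson's evenness E = D2 / S."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if not 1.0 <= d2 <= richness + 1e-9:
        raise ValueError(f"D2={d2} outside [1, S={richness}]")
    return d2 / richness


def plot_metrics(matrix: CommunityMatrix) -> pd.DataFrame:
    """One row per plot: stems, richness, H', D2 and E.

    Plots with zero stems (possible after taxon exclusion) get NaN for
    the three indices and richness 0.
    """
    rows = []
    for plot_id in matrix.plot_ids:
        ab = matrix.plot_abundances(plot_id).to_numpy()
        n_stems = int(ab.sum())
        s = int((ab > 0).sum())
        if n_stems > 0:
            h = shannon(ab)
            d2 = simpson_dominance(ab)
            e = simpson_evenness(d2, s)
        else:
            h = d2 = e = float("nan")
        rows.append(
            {
                "plot_id": plot_id,
                "elevation_m": float(matrix.elevations.loc[plot_id]),
                "n_stems": n_stems,
                "richness": s,
                "shannon_H": h,
                "simpson_D2": d2,
                "simpson_E": e,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching printed report conventions."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_metrics_table(df: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Round the floating index columns for report output (half-up)."""
    out = df.copy()
    for col in ("shannon_H", "simpson_D2", "simpson_E"):
        if col in out:
            out[col] = [
                round_half_up(v, ndigits) if np.isfinite(v) else v for v in out[col]
            ]
    return out
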