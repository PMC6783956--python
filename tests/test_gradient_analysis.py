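import math

import numpy as np
import pandas as pd
import pytest

from elevagrad import (
    CommunityMatrix,
    exclude_plots_rerun,
    pearson,
    species_ranges,
    summarize_significance,
)
from elevagrad.datasets import (
    OFF_TREND_PLOTS,
    transect_structure_classifications,
    transect_summary,
)


class TestPearson:
    def test_exact_linearity(self):
        elev = np.array([2400.0, 2600.0, 2800.0, 3000.0])
        res = pearson(2 * elev + 1, elev)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_constant_values_undefined(self):
        res = pearson([5.0, 5.0, 5.0], [2400.0, 2600.0, 2800.0])
        assert math.isnan(res.r)

    def test_textbook_expansion_n4(self):
        """r and the two-sided t-transform p agree with the product-moment
        formula expanded by hand."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        dx, dy = x - x.mean(), y - y.mean()
        r_hand = (dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum())
        res = pearson(y, x)
        assert res.r == pytest.approx(r_hand, rel=1e-12)
        t = r_hand * math.sqrt(2) / math.sqrt(1 - r_hand**2)
        from scipy import stats

        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=2), rel=1e-9)

    def test_missing_pairs_dropped_listwise(self):
        res = pearson([1.0, float("nan"), 3.0, 4.0], [2400.0, 2500.0, 2600.0, 2700.0])
        assert res.n_plots == 3

    def test_too_few_pairs_undefined(self):
        res = pearson([1.0, 2.0], [2400.0, 2500.0])
        assert math.isnan(res.r) and res.n_plots == 2


class TestExcludePlotsRerun:
    @pytest.fixture
    def trend_with_outliers(self):
        elev = np.linspace(2400, 3300, 12)
        rng = np.random.default_rng(0)
        vals = -0.002 * elev + rng.normal(0, 0.05, size=12)
        vals[7] += 3.0  # injected off-trend plots
        vals[8] += 3.0
        return pd.DataFrame(
            {"plot_id": [str(i + 1) for i in range(12)], "elevation_m": elev, "v": vals}
        )

    def test_empty_exclusion_is_identity(self, trend_with_outliers):
        full, sub = exclude_plots_rerun(trend_with_outliers, "v", set())
        assert full.r == pytest.approx(sub.r)
        assert full.n_plots == sub.n_plots

    def test_removing_injected_outliers_strengthens_correlation(self, trend_with_outliers):
        full, sub = exclude_plots_rerun(trend_with_outliers, "v", {"8", "9"})
        assert abs(sub.r) > abs(full.r)
        assert sub.n_plots == 10
        assert sub.excluded_plot_ids == ("8", "9")

    def test_too_few_remaining_plots(self, trend_with_outliers):
        with pytest.raises(ValueError):
            exclude_plots_rerun(trend_with_outliers, "v", set(trend_with_outliers.plot_id[:-2]))

    def test_off_trend_removal_flips_published_ses_trend_shape(self):
        """On the published no-fern observed MPD column, removing the two
        off-trend plots strengthens the negative elevational trend."""
        cls = transect_structure_classifications()
        tab = cls[(cls.metric == "mpd") & (cls.scenario == "no_ferns")][
            ["plot_id", "elevation_m", "observed"]
        ]
        full, sub = exclude_plots_rerun(tab, "observed", set(OFF_TREND_PLOTS))
        assert abs(sub.r) > abs(full.r)


class TestSummarizeSignificance:
    def test_counts_on_published_flags(self):
        cls = transect_structure_classifications()
        wf = summarize_significance(cls, "with_ferns")
        assert (wf.overdispersed, wf.clustered, wf.nonrandom) == (14, 3, 17)
        nf = summarize_significance(cls, "no_ferns")
        assert (nf.clustered, nf.overdispersed, nf.nonrandom) == (11, 2, 13)

    def test_all_random_table(self):
        df = pd.DataFrame({"classification": ["random"] * 10})
        s = summarize_significance(df)
        assert (s.clustered, s.overdispersed, s.nonrandom) == (0, 0, 0)

    def test_row_order_invariance(self):
        cls = transect_structure_classifications()
        shuffled = cls.sample(frac=1, random_state=3)
        a = summarize_significance(cls, "with_ferns")
        b = summarize_significance(shuffled, "with_ferns")
        assert (a.clustered, a.overdispersed) == (b.clustered, b.overdispersed)

    def test_unknown_labels_rejected(self):
        df = pd.DataFrame({"classification": ["clustered", "bogus"]})
        with pytest.raises(ValueError):
            summarize_significance(df)


class TestSpeciesRanges:
    @pytest.fixture
    def matrix(self):
        counts = pd.DataFrame(
            {
                "low": [3, 0, 0, 0],       # only in p1
                "wide": [1, 1, 1, 1],      # everywhere
                "focal_only": [0, 2, 0, 0],  # only in focal p2
                "up_to_focal": [2, 1, 0, 0],  # p1..p2, max at focal
            },
            index=["p1", "p2", "p3", "p4"],
        )
        elev = pd.Series([2400.0, 2600.0, 2800.0, 3000.0], index=counts.index)
        return CommunityMatrix(counts, elev)

    def test_single_plot_species(self, matrix):
        df, _ = species_ranges(matrix, {"p1"})
        row = df[df.species == "low"].iloc[0]
        assert row.min_elevation == row.max_elevation == 2400.0
        assert row.exclusive_to_focal

    def test_focal_fractions_hand_enumeration(self, matrix):
        df, summary = species_ranges(matrix, {"p2"})
        # species in p2: wide, focal_only, up_to_focal
        assert summary["n_focal_species"] == 3
        assert summary["fraction_exclusive"] == pytest.approx(1 / 3)
        # upward containment: focal_only and up_to_focal (max 2600 <= 2600)
        assert summary["fraction_range_within"] == pytest.approx(2 / 3)

    def test_exclusivity_implies_containment(self, matrix):
        df, summary = species_ranges(matrix, {"p2", "p3"})
        assert summary["fraction_exclusive"] <= summary["fraction_range_within"] + 1e-12
        assert df.loc[df.exclusive_to_focal, "range_within_focal"].all()

    def test_all_plots_focal_gives_full_containment(self, matrix):
        _, summary = species_ranges(matrix, set(matrix.plot_ids))
        assert summary["fraction_range_within"] == pytest.approx(1.0)

    def test_two_sided_containment_is_stricter(self, matrix):
        _, up = species_ranges(matrix, {"p2"}, containment="upward")
        _, two = species_ranges(matrix, {"p2"}, containment="two_sided")
        assert two["fraction_range_within"] <= up["fraction_range_within"]

    def test_empty_focal_rejected(self, matrix):
        with pytest.raises(ValueError):
            species_ranges(matrix, set())


def test_printed_index_columns_reproduce_reported_gradient():
    """The published per-plot richness and H' columns correlate negatively
    with elevation at the reported strengths."""
    ts = transect_summary()
    r_rich = pearson(ts["richness"], ts["elevation_m"])
    assert r_rich.r == pytest.approx(-0.53, abs=0.01)
    assert r_rich.significant
    r_h = pearson(ts["shannon_H"], ts["elevation_m"])
    assert r_h.r == pytest.approx(-0.58, abs=0.01)
    assert r_h.significant
    # D2 and E show no significant elevational trend
    assert not pearson(ts["simpson_D2"], ts["elevation_m"]).significant
    assert not pearson(ts["simpson_E"], ts["elevation_m"]).significant
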