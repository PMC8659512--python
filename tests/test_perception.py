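"""Rating taxonomy, inter-rater agreement bins, and correlation
statistics against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from breathvoice.core import SignalError
from breathvoice.perception import (agreement_distribution,
                                    average_and_classify, class_descriptives,
                                    classify, grid_class_counts, pearson,
                                    score_grid, spearman)


class TestTaxonomy:
    @pytest.mark.parametrize("r1,r2,avg,cls", [
        (0.5, 0.5, 0.5, 0),
        (0.5, 1.0, 0.75, 1),   # boundary is inclusive upward
        (1.5, 1.5, 1.5, 1),
        (2.0, 2.5, 2.25, 2),
        (3.0, 3.5, 3.25, 3),
        (3.5, 3.5, 3.5, 4),
        (4.0, 4.0, 4.0, 4),
        (0.0, 0.0, 0.0, 0),
    ])
    def test_average_and_class(self, r1, r2, avg, cls):
        rec = average_and_classify(r1, r2)
        assert rec.average == avg
        assert rec.cls == cls
        assert round(rec.average / 0.25) * 0.25 == rec.average

    def test_off_grid_scores_rejected(self):
        with pytest.raises(SignalError):
            average_and_classify(0.3, 1.0)
        with pytest.raises(SignalError):
            average_and_classify(1.0, 4.5)

    def test_classifier_is_monotone_step_function(self):
        grid = score_grid()
        classes = [classify(v) for v in grid]
        assert classes == sorted(classes)

    def test_grid_has_17_quarter_step_values(self):
        grid = score_grid()
        assert grid.size == 17
        assert np.allclose(np.diff(grid), 0.25)

    half_points = st.integers(0, 8).map(lambda k: k * 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(r1=half_points, r2=half_points)
    def test_any_half_point_pair_classifies_consistently(self, r1, r2):
        """For every attainable rater pair the average lands on the
        0.25 grid and the class respects the printed boundaries."""
        rec = average_and_classify(r1, r2)
        assert rec.average == (r1 + r2) / 2
        assert round(rec.average / 0.25) * 0.25 == pytest.approx(rec.average)
        bounds = (0.75, 1.5, 2.25, 3.25, 4.0)
        if rec.cls == 0:
            assert rec.average < bounds[0]
        else:
            assert bounds[rec.cls - 1] <= rec.average <= bounds[rec.cls]

    def test_extreme_classes_hold_three_values_each(self):
        counts = grid_class_counts()
        assert counts[0] == 3 and counts[4] == 3
        assert all(c in (3, 4) for c in counts)
        assert sum(counts) == 17


class TestAgreement:
    def test_reported_distribution_reproduced(self):
        """456 rating pairs with deviations 291/104/54/7/0 across the bins
        yield 63.8 / 22.8 / 1.5 / 0.0 percent, with the 2-3-step bin at
        11.8 by direct rounding (11.9 as the complement of the other
        rounded bins)."""
        pairs = ([(2.0, 2.0)] * 291 + [(2.0, 2.5)] * 104
                 + [(2.0, 3.0)] * 54 + [(2.0, 4.0)] * 7)
        table = agreement_distribution(pairs)
        assert table["count"].tolist() == [291, 104, 54, 7, 0]
        pct = table["percent"].tolist()
        assert pct[0] == 63.8 and pct[1] == 22.8
        assert pct[3] == 1.5 and pct[4] == 0.0
        assert pct[2] == 11.8
        complement = round(100.0 - pct[0] - pct[1] - pct[3] - pct[4], 1)
        assert complement == 11.9

    def test_identical_raters_all_exact(self):
        table = agreement_distribution([(1.0, 1.0)] * 10)
        assert table["percent"].tolist()[0] == 100.0

    def test_maximal_disagreement_in_top_bin(self):
        table = agreement_distribution([(0.0, 4.0)])
        assert table.loc[table["bin"] == "6-8 steps", "count"].item() == 1

    def test_bin_conservation(self):
        rng = np.random.default_rng(0)
        pairs = [(float(a), float(b))
                 for a, b in rng.integers(0, 9, (200, 2)) * 0.5]
        table = agreement_distribution(pairs)
        assert table["count"].sum() == 200
        assert abs(table["percent"].sum() - 100.0) < 0.3

    def test_empty_input_rejected(self):
        with pytest.raises(SignalError):
            agreement_distribution([])


class TestCorrelations:
    def test_linear_relation_perfect_scores(self):
        x = np.arange(10.0)
        y = 2 * x + 1
        assert pearson(x, y)[0] == pytest.approx(1.0, abs=1e-12)
        assert spearman(x, y)[0] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonlinear_rank_identity(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = x ** 3
        r, _ = pearson(x, y)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert r < 1.0

    def test_pearson_matches_brute_force_formula(self):
        """Direct covariance formula and t-test p-value agree with the
        module to 1e-12 on random vectors."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            x, y = rng.standard_normal((2, 40))
            r, p = pearson(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
            t = r_oracle * np.sqrt((len(x) - 2) / (1 - r_oracle ** 2))
            p_oracle = 2 * stats.t.sf(abs(t), len(x) - 2)
            assert abs(r - r_oracle) < 1e-12
            assert abs(p - p_oracle) < 1e-12

    def test_spearman_matches_rank_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x, y = rng.standard_normal((2, 35))
            rho, _ = spearman(x, y)
            rx = stats.rankdata(x)
            ry = stats.rankdata(y)
            rxc, ryc = rx - rx.mean(), ry - ry.mean()
            oracle = np.sum(rxc * ryc) / np.sqrt(np.sum(rxc ** 2) * np.sum(ryc ** 2))
            assert abs(rho - oracle) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SignalError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(SignalError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDescriptives:
    def test_single_class_constant_features(self):
        rows = pd.DataFrame({"cls": [2, 2, 2], "cpps": [10.0, 10.0, 10.0]})
        table = class_descriptives(rows)
        assert len(table) == 1
        assert table["cpps"].iloc[0] == 10.0

    def test_empty_class_absent_from_output(self):
        rows = pd.DataFrame({"cls": [0, 0, 4], "cpps": [19.0, 18.0, 9.0]})
        table = class_descriptives(rows)
        assert set(table["cls"]) == {0, 4}

    def test_monotone_cohort_gives_decreasing_cpps_means(self):
        rng = np.random.default_rng(5)
        cls = np.repeat(np.arange(5), 20)
        cpps = 19.0 - 2.3 * cls + 0.1 * rng.standard_normal(cls.size)
        table = class_descriptives(pd.DataFrame({"cls": cls, "cpps": cpps}))
        means = table["cpps"].to_numpy()
        assert np.all(np.diff(means) < 0)
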