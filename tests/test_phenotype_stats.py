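import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myofractal.phenotype_stats import (
    category_anova,
    correlation_matrix,
    growth_rates,
    no_oxidation_rate,
    normality_gate,
    phenotype_frame,
    spearman_exact,
)


class TestGrowthRates:
    def test_broiler_reference_row(self):
        gr2, gr4 = growth_rates(47.5, 305.0, 1157.0)
        assert round(gr2, 2) == 6.42
        assert round(gr4, 2) == 24.36

    def test_cornish_reference_row(self):
        _, gr4 = growth_rates(49.3, 291.7, 1287.5)
        assert round(gr4, 2) == 26.12

    def test_constant_weight_gives_unity(self):
        assert growth_rates(10.0, 10.0, 10.0) == (1.0, 1.0)

    def test_zero_day_old_weight_rejected(self):
        with pytest.raises(ValueError):
            growth_rates(0.0, 1.0, 2.0)

    def test_all_reference_rows_round_to_published(self, phenotypes):
        published = {
            "BR": (6.42, 24.36), "WC": (5.92, 26.12), "PRW": (5.91, 23.57),
            "YC": (2.60, 6.15), "BB": (2.81, 6.33), "OMF": (2.62, 4.73),
            "LR": (1.88, 5.25), "UG": (2.24, 5.42),
        }
        for p in phenotypes:
            gr2, gr4 = growth_rates(p.bw1, p.bw14, p.bw28)
            exp2, exp4 = published[p.breed]
            assert gr2 == pytest.approx(exp2, abs=0.005), p.breed
            assert gr4 == pytest.approx(exp4, abs=0.005), p.breed


class TestNoOxidation:
    def test_no_nitrate_is_zero_percent(self):
        assert no_oxidation_rate(50.0, 0.0) == 0

    def test_equal_levels_are_fifty_percent(self):
        assert no_oxidation_rate(100.0, 100.0) == 50

    def test_brahma_reference_levels(self):
        # direct evaluation of the metabolite-ratio formula
        assert no_oxidation_rate(36.0, 100.0) == pytest.approx(73.5, abs=0.05)

    def test_no_metabolites_undefined(self):
        with pytest.raises(ZeroDivisionError):
            no_oxidation_rate(0.0, 0.0)


class TestNormalityGate:
    def test_breed_weights_reject_normality(self, phenotypes):
        bw28 = [p.bw28 for p in phenotypes]
        pvals, method = normality_gate({"bw28": bw28})
        assert pvals["bw28"] < 0.05
        assert method == "spearman"

    def test_gaussian_draws_pass(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(0, 1, size=50)
        pvals, method = normality_gate({"z": sample})
        assert pvals["z"] > 0.05
        assert method == "pearson"

    def test_constant_vector_degenerate(self):
        pvals, method = normality_gate({"c": [1.0, 1.0, 1.0, 1.0]})
        assert math.isnan(pvals["c"])
        assert method == "spearman"

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            normality_gate({"v": [1.0, 2.0]})


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho_up, _ = spearman_exact(x, [2.0, 4.0, 9.0, 16.0, 30.0])
        rho_down, _ = spearman_exact(x, [30.0, 16.0, 9.0, 4.0, 2.0])
        assert rho_up == 1
        assert rho_down == -1

    def test_statistic_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            rho, _ = spearman_exact(x, y)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic,
                                        abs=1e-12)

    def test_exact_p_matches_naive_enumeration(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 5.0, 1.0, 3.5]
        rho, p = spearman_exact(x, y)
        from scipy import stats

        rx, ry = stats.rankdata(x), stats.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = sum(
            abs(np.corrcoef(rx, np.asarray(ry)[list(perm)])[0, 1])
            >= observed - 1e-12
            for perm in itertools.permutations(range(5))
        )
        assert p == pytest.approx(count / math.factorial(5))

    @given(st.permutations(list(range(6))))
    @settings(derandomize=True, max_examples=30)
    def test_rank_invariance_under_monotone_transform(self, perm):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [float(v) for v in perm]
        rho_raw, p_raw = spearman_exact(x, y)
        rho_exp, p_exp = spearman_exact([math.exp(v) for v in x],
                                        [v ** 3 for v in y])
        assert rho_exp == pytest.approx(rho_raw, abs=1e-12)
        assert p_exp == pytest.approx(p_raw, abs=1e-12)


class TestCorrelationMatrix:
    def test_reference_index_vs_growth_sign(self, expression, phenotypes):
        from myofractal.datasets import DEFAULT_INTERCEPT_MODES
        from myofractal.rank_model import breed_index_table

        rows = breed_index_table(expression, DEFAULT_INTERCEPT_MODES)
        frame = phenotype_frame(phenotypes)
        frame["mgei"] = [idx.mgei for idx, *_ in rows]
        report = correlation_matrix(frame[["mgei", "gr4wk", "bw28"]])
        assert report.rho.loc["mgei", "gr4wk"] < 0
        assert report.p.loc["mgei", "gr4wk"] < 0.05

    def test_matrix_invariants(self, phenotypes):
        frame = phenotype_frame(phenotypes)[["bw1", "bw14", "bw28", "gr2wk"]]
        report = correlation_matrix(frame)
        rho = report.rho
        assert np.allclose(rho.values, rho.values.T)
        assert np.allclose(np.diag(rho.values), 1.0)
        assert ((rho.values >= -1) & (rho.values <= 1)).all()

    def test_tied_variable_reported_missing(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                              "b": [5.0, 5.0, 5.0, 5.0]})
        report = correlation_matrix(frame)
        assert math.isnan(report.rho.loc["a", "b"])

    def test_bh_annotation_present_when_requested(self, phenotypes):
        frame = phenotype_frame(phenotypes)[["bw1", "bw14", "bw28"]]
        report = correlation_matrix(frame, bh_adjust=True)
        assert report.q is not None
        off_diag = report.q.loc["bw1", "bw14"]
        assert 0 <= off_diag <= 1


class TestCategoryAnova:
    def test_identical_group_means_give_zero_f(self):
        f, p = category_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_reference_ln_slope_separates_meat_breeds(
            self, expression, phenotypes):
        from myofractal.datasets import DEFAULT_INTERCEPT_MODES
        from myofractal.rank_model import breed_index_table

        rows = breed_index_table(expression, DEFAULT_INTERCEPT_MODES)
        k_br = {idx.breed: idx.k_breast for idx, *_ in rows}
        labels = [p.categories["breed_type"] for p in phenotypes]
        values = [math.log(k_br[p.breed]) for p in phenotypes]
        f, p = category_anova(values, labels)
        assert p < 0.05

    def test_f_equals_squared_t_for_two_groups(self):
        from scipy import stats

        g1 = [3.1, 2.9, 3.4, 3.0]
        g2 = [4.2, 4.0, 4.5]
        f, p_f = category_anova(g1 + g2, ["a"] * 4 + ["b"] * 3)
        t, p_t = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t ** 2, rel=1e-12)
        assert p_f == pytest.approx(p_t, rel=1e-12)

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    @settings(derandomize=True, max_examples=25)
    def test_location_scale_invariance(self, shift, scale):
        values = np.array([1.0, 2.0, 4.0, 8.0, 3.0, 9.0])
        labels = ["a", "a", "a", "b", "b", "b"]
        f0, _ = category_anova(values, labels)
        f1, _ = category_anova(values * scale + shift, labels)
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_all_singleton_groups_rejected(self):
        with pytest.raises(ValueError):
            category_anova([1.0, 2.0], ["a", "b"])
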