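"""Regression stages: closed-form limits, oracles and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ednacongruence.models import (LaplaceMixedModel, _BetaFamily,
                                   compact_letter_display, dunn_test,
                                   exact_contingency_2xk, fit_abundance_mixed,
                                   fit_beta_glm, fit_beta_glm_fixed,
                                   fit_nb_glmm_richness, group_tests,
                                   rank_sum_test, sensitivity_filter,
                                   smooth_proportions)
from ednacongruence.simulate import (SimulationConfig, generate_collection,
                                     simulate_congruence_proportions,
                                     simulate_nb_glmm)


class TestNbGlmm:
    def test_intercept_only_constant_response(self):
        y = np.full(200, 7)
        ids = np.repeat([f"d{i}" for i in range(10)], 20)
        fit = fit_nb_glmm_richness(np.zeros(200), y, ids)
        assert fit.coef("intercept") == pytest.approx(np.log(7), abs=1e-6)

    def test_zero_variance_limit_matches_direct_nb_mle(self):
        import statsmodels.api as sm
        from statsmodels.discrete.discrete_model import NegativeBinomial
        df = simulate_nb_glmm(30, 30, 2.0, 0.5, 0.0, 5.0,
                              np.random.default_rng(3))
        fit = fit_nb_glmm_richness(df["x"], df["y"], df["group"],
                                   fix_sigma_zero=True)
        oracle = NegativeBinomial(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert np.abs(fit.params["estimate"].to_numpy()
                      - np.asarray(oracle.params)[:2]).max() < 1e-3

    def test_parameter_recovery_single_replicate(self):
        df = simulate_nb_glmm(50, 20, 2.0, 0.5, 0.4, 5.0,
                              np.random.default_rng(10))
        fit = fit_nb_glmm_richness(df["x"], df["y"], df["group"])
        assert fit.converged
        lo, hi = fit.conf_int("original_richness")
        assert lo < 0.5 < hi
        assert fit.sigma2_u == pytest.approx(0.4, abs=0.25)
        assert fit.r2_conditional >= fit.r2_marginal

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            fit_nb_glmm_richness([1, 2], [1, 2], ["d", "d"])


class TestBetaGlm:
    def test_constant_half_response_gives_zero_intercept(self):
        df = pd.DataFrame({"p": np.full(101, 0.5)})
        fit = fit_beta_glm(df, "p", predictors=())
        assert fit.coef("intercept") == pytest.approx(0.0, abs=1e-6)

    def test_smoothing_keeps_boundaries_inside(self):
        y = smooth_proportions(np.array([0.0, 0.5, 1.0]))
        assert 0 < y[0] < y[1] < y[2] < 1
        assert y[1] == 0.5

    def test_year_effect_recovered_from_generated_proportions(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(2)
        df = simulate_congruence_proportions(cfg, 300, rng)
        fit = fit_beta_glm(df, "p_sp")
        assert fit.coef("year") > 0
        assert fit.pvalue("year") < 0.05
        assert fit.dispersion == pytest.approx(cfg.beta_precision, rel=0.4)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"p": np.full(5, 0.4)})
        with pytest.raises(ValueError):
            fit_beta_glm(df, "p", predictors=())


class TestAbundanceMixed:
    def test_zero_variance_limit_matches_fixed_beta_glm(self):
        rng = np.random.default_rng(4)
        n_groups, n_per = 30, 40
        x = rng.random(n_groups * n_per)
        eta = -1.0 + 0.8 * x
        mu = 1 / (1 + np.exp(-eta))
        phi = 20.0
        y = rng.beta(mu * phi, (1 - mu) * phi)
        ids = np.repeat([f"d{i}" for i in range(n_groups)], n_per)
        model = LaplaceMixedModel(y, np.column_stack([np.ones_like(x), x]),
                                  ids, _BetaFamily)
        fit = model.fit(np.array([0.0, 0.0]), start_log_aux=1.0,
                        term_names=["intercept", "x"], fix_log_sigma=-7.0)
        oracle = fit_beta_glm_fixed(y, np.column_stack([np.ones_like(x), x]),
                                    ["intercept", "x"])
        assert np.abs(fit.params["estimate"].to_numpy()
                      - oracle.params["estimate"].to_numpy()).max() < 1e-3

    def test_detects_unique_species_penalty(self, default_collection):
        from ednacongruence.congruence import abundance_table
        coll, truth = default_collection
        ab = abundance_table(coll)
        fit = fit_abundance_mixed(ab, index="a")
        assert fit.converged
        assert fit.coef("unique") < 0
        assert fit.pvalue("unique") < 0.05
        assert fit.r2_conditional >= fit.r2_marginal


class TestSensitivityFilter:
    def test_examples(self, small_collection):
        coll, _ = small_collection
        same, report = sensitivity_filter(coll, 0)
        assert len(same) == len(coll) and report.empty
        medians = sorted(d.metadata.median_fish_reads for d in coll.datasets)
        thresh = medians[2] + 1  # removes exactly the three smallest
        filtered, report = sensitivity_filter(coll, thresh)
        assert len(filtered) == len(coll) - 3 and len(report) == 3
        with pytest.raises(ValueError):
            sensitivity_filter(coll, max(medians) + 1)


class TestGroupTests:
    def test_identical_groups_share_one_letter(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        res = group_tests(v, g)
        assert len(set(res.letters.values())) == 1

    def test_three_separated_groups_distinct_letters(self):
        v = np.concatenate([np.arange(10), np.arange(10) + 100,
                            np.arange(10) + 200])
        g = np.repeat(["a", "b", "c"], 10)
        res = group_tests(v, g)
        assert res.p_value < 0.001
        assert sorted(res.letters.values()) == ["a", "b", "c"]

    def test_rank_sum_exact_minimal_p_for_disjoint_groups(self):
        x = np.arange(10, dtype=float)
        y = np.arange(10, dtype=float) + 100
        res = rank_sum_test(x, y)
        from math import comb
        assert res.p_value == pytest.approx(2 / comb(20, 10))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests(np.array([1.0, 2.0]), np.array(["a", "a"]))

    def test_dunn_pairwise_symmetric_and_valid(self):
        rng = np.random.default_rng(5)
        v = rng.random(30)
        g = np.repeat(["a", "b", "c"], 10)
        out = dunn_test(v, g)
        assert len(out) == 3
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
        flipped = dunn_test(v, g[::-1].copy() if False else g)
        assert np.allclose(out["p"], flipped["p"])

    def test_letter_display_on_known_graph(self):
        # a-b differ, b-c differ, a-c do not: a and c share a letter
        pw = pd.DataFrame([
            {"group1": "a", "group2": "b", "z": 5, "p": 0.001},
            {"group1": "b", "group2": "c", "z": 5, "p": 0.001},
            {"group1": "a", "group2": "c", "z": 0, "p": 0.9},
        ])
        letters = compact_letter_display(pw, ["a", "b", "c"])
        assert set(letters["a"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["b"])
        assert not set(letters["b"]) & set(letters["c"])


class TestExactContingency:
    def test_matches_fisher_exact_2x2(self):
        table = np.array([[8, 2], [1, 5]])
        mine = exact_contingency_2xk(table)
        _, p = stats.fisher_exact(table)
        assert mine.p_value == pytest.approx(p, rel=1e-9)

    def test_2x3_uniform_table_not_significant(self):
        res = exact_contingency_2xk(np.array([[5, 5, 5], [5, 5, 5]]))
        assert res.p_value > 0.5
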