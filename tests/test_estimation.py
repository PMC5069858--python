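import logging
import math

import numpy as np
import pytest

from irtscore import (
    MetricBank,
    Prior,
    estimate_eap_pattern,
    estimate_eap_sumscore,
    estimate_map,
    estimate_ml,
    estimate_prior_from_data,
    estimate_wle,
    make_grid,
    score_table,
    sumscore_table,
)
from irtscore.bank import MISSING, ResponseMatrix, ingest_responses
from irtscore.estimation import (
    ALL_MISSING,
    DIVERGED,
    INCOMPLETE_FOR_SUMSCORE,
)
from irtscore.synth import SimulationConfig, simulated_matrix

import _oracles
from conftest import grm_item, random_bank, random_pattern


def as_pairs(pattern, bank):
    return [(bank.item(c), k) for c, k in pattern.items()]


class TestQuadratureGrid:
    def test_standard_prior_weights_symmetric(self):
        grid = make_grid(Prior.standard(), 101, (-6, 6))
        assert np.abs(grid.weights - grid.weights[::-1]).max() < 1e-15
        assert grid.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_diffuse_prior_is_flatter(self):
        std = make_grid(Prior.standard(), 101, (-6, 6))
        dif = make_grid(Prior.diffuse(), 101, (-6, 6))
        assert (dif.weights.max() / dif.weights.min()
                < std.weights.max() / std.weights.min())

    def test_normal_density_ratio_between_adjacent_unit_nodes(self):
        # nodes at integers: w(0)/w(1) = phi(0)/phi(1) = exp(0.5)
        grid = make_grid(Prior.standard(), 13, (-6, 6))
        i0 = int(np.argmin(np.abs(grid.nodes - 0.0)))
        i1 = int(np.argmin(np.abs(grid.nodes - 1.0)))
        assert grid.weights[i0] / grid.weights[i1] \
            == pytest.approx(math.exp(0.5), rel=1e-12)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            make_grid(Prior.standard(), 5)


class TestPrior:
    def test_named_priors_pin_their_parameters(self):
        assert (Prior.standard().mean, Prior.standard().variance) == (0, 1)
        assert (Prior.diffuse().mean, Prior.diffuse().variance) == (0, 10)
        with pytest.raises(ValueError):
            Prior("standard", 1.0, 1.0)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            Prior.empirical(0.0, 0.0)


class TestEAP:
    def test_all_missing_returns_prior(self):
        bank = MetricBank(name="one", model="GRM", items=(grm_item("g1"),))
        est = estimate_eap_pattern({}, bank)
        assert est.theta_hat == 0.0
        assert est.se == pytest.approx(1.0, abs=1e-3)
        assert ALL_MISSING in est.flags

    def test_two_item_pattern_matches_fine_grid_integration(self):
        bank = MetricBank(
            name="toy", model="GRM",
            items=(grm_item("a1", a=1.5, thresholds=(-0.8, 0.5)),
                   grm_item("a2", a=0.9, thresholds=(0.2,))))
        pat = {"a1": 2, "a2": 0}
        est = estimate_eap_pattern(pat, bank, n_nodes=10_001)
        want_m, want_sd = _oracles.eap_dense(as_pairs(pat, bank))
        assert est.theta_hat == pytest.approx(want_m, abs=1e-4)
        assert est.se == pytest.approx(want_sd, abs=1e-4)

    def test_diffuse_prior_shrinks_less(self):
        bank = MetricBank(
            name="toy", model="GRM",
            items=(grm_item("a1", a=1.5, thresholds=(-0.8, 0.5)),
                   grm_item("a2", a=0.9, thresholds=(0.2,))))
        pat = {"a1": 2, "a2": 1}
        std = estimate_eap_pattern(pat, bank, Prior.standard())
        dif = estimate_eap_pattern(pat, bank, Prior.diffuse())
        assert abs(dif.theta_hat) >= abs(std.theta_hat)

    @pytest.mark.parametrize("seed", range(6))
    def test_eap_monotone_in_any_single_response(self, seed):
        rng = np.random.default_rng(300 + seed)
        model = "GRM" if seed % 2 == 0 else "GPCM"
        bank = random_bank(rng, model=model, n_items=4, max_k=4)
        pat = random_pattern(rng, bank)
        code = bank.items[int(rng.integers(4))].code
        item = bank.item(code)
        prev = None
        for k in range(item.n_categories):
            pat[code] = k
            est = estimate_eap_pattern(pat, bank)
            if prev is not None:
                assert est.theta_hat >= prev - 1e-9
            prev = est.theta_hat

    def test_missing_data_consistency(self, example_bank):
        # scoring a partial pattern == scoring against the partial bank
        pat = {c: 1 for c in example_bank.codes[:5]}
        sub = example_bank.subset(example_bank.codes[:5])
        full = estimate_eap_pattern(pat, example_bank)
        part = estimate_eap_pattern(pat, sub)
        assert full.theta_hat == part.theta_hat
        assert full.se == part.se


class TestSumScoreEAP:
    def test_single_item_set_equals_pattern_eap(self):
        bank = MetricBank(name="one", model="GRM",
                          items=(grm_item("g1", a=1.3,
                                          thresholds=(-1.0, 0.4, 1.2)),))
        for s in range(4):
            via_sum = estimate_eap_sumscore(s, ["g1"], bank)
            via_pat = estimate_eap_pattern({"g1": s}, bank)
            assert via_sum.theta_hat == pytest.approx(via_pat.theta_hat,
                                                      abs=1e-12)
            assert via_sum.se == pytest.approx(via_pat.se, abs=1e-12)

    @pytest.mark.parametrize("model", ["GRM", "GPCM"])
    def test_recursion_equals_pattern_enumeration(self, model):
        rng = np.random.default_rng(42)
        bank = random_bank(rng, model=model, n_items=3, max_k=4)
        table = sumscore_table(None, bank)
        want = _oracles.sumscore_eap_enumeration(list(bank.items))
        for s, (m, sd) in enumerate(want):
            assert table.theta[s] == pytest.approx(m, abs=1e-8)
            assert table.se[s] == pytest.approx(sd, abs=1e-8)

    def test_score_to_theta_table_is_nondecreasing(self, example_bank):
        table = sumscore_table("instrA", example_bank)
        assert np.all(np.diff(table.theta) >= 0)

    def test_out_of_range_score_rejected(self, example_bank):
        with pytest.raises(ValueError, match="outside"):
            estimate_eap_sumscore(999, "instrA", example_bank)


class TestMAP:
    def test_all_missing_returns_prior_mode(self):
        bank = MetricBank(name="one", model="GRM", items=(grm_item("g1"),))
        est = estimate_map({}, bank)
        assert est.theta_hat == 0.0
        assert ALL_MISSING in est.flags

    @pytest.mark.parametrize("seed", range(5))
    def test_mode_beats_every_grid_node(self, seed):
        rng = np.random.default_rng(500 + seed)
        model = "GRM" if seed % 2 == 0 else "GPCM"
        bank = random_bank(rng, model=model, n_items=5, max_k=4)
        pat = random_pattern(rng, bank)
        est = estimate_map(pat, bank)
        grid = np.linspace(-6, 6, 1201)
        obj = _oracles.pattern_loglik(as_pairs(pat, bank), grid) \
            - 0.5 * grid ** 2
        at_mode = _oracles.pattern_loglik(as_pairs(pat, bank),
                                          est.theta_hat)[0] \
            - 0.5 * est.theta_hat ** 2
        assert at_mode >= obj.max() - 1e-9

    def test_map_shrinks_toward_prior_mean(self):
        bank = MetricBank(name="one", model="GRM",
                          items=(grm_item("g1", a=1.0, thresholds=(0.0,)),
                                 grm_item("g2", a=1.0, thresholds=(0.5,))))
        pat = {"g1": 1, "g2": 0}
        ml = estimate_ml(pat, bank)
        mp = estimate_map(pat, bank)
        # MAP lies strictly between the prior mean (0) and the MLE
        lo, hi = sorted((0.0, ml.theta_hat))
        assert lo < mp.theta_hat < hi or math.isclose(ml.theta_hat, 0.0)


class TestML:
    def test_all_lowest_pattern_diverges(self, small_bank):
        pat = {c: 0 for c in small_bank.codes}
        est = estimate_ml(pat, small_bank)
        assert DIVERGED in est.flags
        assert math.isnan(est.theta_hat) and math.isnan(est.se)

    def test_all_highest_pattern_diverges(self, small_bank):
        pat = {c: small_bank.item(c).max_category for c in small_bank.codes}
        assert DIVERGED in estimate_ml(pat, small_bank).flags

    @pytest.mark.parametrize("seed", range(5))
    def test_interior_pattern_matches_grid_argmax(self, seed):
        rng = np.random.default_rng(700 + seed)
        model = "GRM" if seed % 2 == 0 else "GPCM"
        bank = random_bank(rng, model=model, n_items=6, max_k=4)
        pat = random_pattern(rng, bank, interior=True)
        est = estimate_ml(pat, bank)
        if DIVERGED in est.flags:
            pytest.skip("drew an all-extreme pattern")
        want = _oracles.ml_dense(as_pairs(pat, bank), n=1201)
        assert est.theta_hat == pytest.approx(want, abs=1e-3)

    def test_diffuse_prior_map_is_closer_to_ml(self, small_bank):
        pat = {"s1": 3, "s2": 2, "s3": 0}
        ml = estimate_ml(pat, small_bank).theta_hat
        map_std = estimate_map(pat, small_bank, Prior.standard()).theta_hat
        map_dif = estimate_map(pat, small_bank, Prior.diffuse()).theta_hat
        assert abs(map_dif - ml) <= abs(map_std - ml)

    def test_se_is_inverse_root_information(self, small_bank):
        from irtscore import test_information
        pat = {"s1": 2, "s2": 1, "s3": 1}
        est = estimate_ml(pat, small_bank)
        info = float(test_information(small_bank, est.theta_hat))
        assert est.se == pytest.approx(1 / math.sqrt(info), abs=1e-10)


class TestWLE:
    def test_extreme_patterns_stay_finite(self, small_bank):
        low = {c: 0 for c in small_bank.codes}
        high = {c: small_bank.item(c).max_category for c in small_bank.codes}
        for pat in (low, high):
            est = estimate_wle(pat, small_bank)
            assert np.isfinite(est.theta_hat)
            assert DIVERGED not in est.flags

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_score_vanishes_at_the_estimate(self, seed):
        rng = np.random.default_rng(900 + seed)
        model = "GRM" if seed % 2 == 0 else "GPCM"
        bank = random_bank(rng, model=model, n_items=6, max_k=4)
        pat = random_pattern(rng, bank, interior=True)
        est = estimate_wle(pat, bank)
        # rebuild the weighted score from finite differences of naive probs
        pairs = as_pairs(pat, bank)
        th = est.theta_hat
        g = info = comp = 0.0
        for item, cat in pairs:
            p, dp, d2p = _oracles._fd_prob_derivs(item, np.array([th]))
            psafe = np.clip(p, 1e-300, None)
            g += dp[0, cat] / psafe[0, cat]
            info += float(np.sum(dp * dp / psafe))
            comp += float(np.sum(dp * d2p / psafe))
        assert abs(g + comp / (2 * info)) < 1e-5

    def test_wle_matches_dense_grid_root(self):
        rng = np.random.default_rng(17)
        bank = random_bank(rng, model="GRM", n_items=5, max_k=4)
        pat = random_pattern(rng, bank, interior=True)
        est = estimate_wle(pat, bank)
        want = _oracles.wle_dense(as_pairs(pat, bank), n=10_001)
        assert est.theta_hat == pytest.approx(want, abs=1e-3)

    def test_wle_less_biased_than_ml(self, example_bank):
        """At true theta = 1 the Warm correction reduces the mean bias."""
        sub = example_bank.subset(example_bank.instruments["instrA"])
        rng = np.random.default_rng(2016)
        n_rep = 400
        theta_true = 1.0
        wle_vals, ml_vals = [], []
        cfg_bank = sub
        from irtscore.models import category_probs
        probs = {it.code: category_probs(it, theta_true, cfg_bank.scaling_D)
                 for it in cfg_bank.items}
        for _ in range(n_rep):
            pat = {}
            for it in cfg_bank.items:
                p = probs[it.code]
                pat[it.code] = int(rng.choice(it.n_categories, p=p / p.sum()))
            w = estimate_wle(pat, cfg_bank)
            m = estimate_ml(pat, cfg_bank)
            wle_vals.append(w.theta_hat)
            if DIVERGED not in m.flags:
                ml_vals.append(m.theta_hat)
        bias_wle = abs(np.mean(wle_vals) - theta_true)
        bias_ml = abs(np.mean(ml_vals) - theta_true)
        assert bias_wle <= bias_ml + 0.02


class TestEmpiricalPrior:
    def test_recovers_standard_population(self, example_bank):
        cfg = SimulationConfig(n_respondents=2000, seed=11)
        rm, _ = simulated_matrix(example_bank, cfg)
        prior = estimate_prior_from_data(rm, example_bank)
        assert prior.kind == "empirical"
        assert -0.1 < prior.mean < 0.1
        assert 0.85 < prior.variance < 1.15

    def test_recovers_shifted_population(self, example_bank):
        cfg = SimulationConfig(n_respondents=1000, theta_mean=1.0, seed=12)
        rm, _ = simulated_matrix(example_bank, cfg)
        prior = estimate_prior_from_data(rm, example_bank)
        assert prior.mean > 0.8

    def test_em_fixed_point(self, example_bank, simulated_data):
        rm, _ = simulated_data
        p1 = estimate_prior_from_data(rm, example_bank)
        p2 = estimate_prior_from_data(
            rm, example_bank, max_iter=1,
            init=(p1.mean, p1.variance))
        assert abs(p2.mean - p1.mean) < 1e-4
        assert abs(p2.variance - p1.variance) < 1e-4

    def test_small_samples_fall_back_to_standard(self, example_bank):
        cfg = SimulationConfig(n_respondents=20, seed=13)
        rm, _ = simulated_matrix(example_bank, cfg)
        with pytest.warns(UserWarning, match="falling back"):
            prior = estimate_prior_from_data(rm, example_bank)
        assert prior == Prior.standard()

    def test_all_empty_rows_is_an_error(self, example_bank):
        data = np.full((60, 16), MISSING)
        rm = ResponseMatrix(example_bank.codes, data)
        with pytest.raises(ValueError, match="all rows are empty"):
            estimate_prior_from_data(rm, example_bank)


class TestScoreTable:
    def test_row_count_order_and_flags(self, example_bank):
        import pandas as pd
        table = pd.DataFrame({
            "instrA_01": ["1", "", "2"],
            "instrA_02": ["0", "", "3"],
        })
        rm, _ = ingest_responses(table, example_bank)
        ests = score_table(rm, example_bank)
        assert len(ests) == 3
        assert ALL_MISSING in ests[1].flags
        assert ests[0].n_items_answered == 2

    def test_identical_patterns_get_identical_estimates(self, example_bank,
                                                        simulated_data):
        rm, _ = simulated_data
        twice = ResponseMatrix(rm.codes, np.vstack([rm.data[:1],
                                                    rm.data[:1]]))
        a, b = score_table(twice, example_bank)
        assert a == b

    def test_default_estimator_is_pattern_eap(self, example_bank,
                                              simulated_data):
        rm, _ = simulated_data
        ests = score_table(rm, example_bank)
        assert all(e.estimator == "EAP" for e in ests)
        direct = estimate_eap_pattern(rm.row_pattern(0), example_bank)
        assert ests[0].theta_hat == pytest.approx(direct.theta_hat,
                                                  abs=1e-12)

    @pytest.mark.parametrize("estimator", ["MAP", "WLE", "ML", "EAPsum"])
    def test_alternative_estimators_label_their_output(
            self, example_bank, simulated_data, estimator):
        rm, _ = simulated_data
        sub = ResponseMatrix(rm.codes, rm.data[:8])
        ests = score_table(sub, example_bank, estimator=estimator,
                           instrument="instrA")
        assert len(ests) == 8
        assert all(e.estimator == estimator for e in ests)

    def test_eapsum_flags_incomplete_instruments(self, example_bank):
        import pandas as pd
        table = pd.DataFrame({c: ["1"] for c in
                              example_bank.instruments["instrA"][:-1]})
        rm, _ = ingest_responses(table, example_bank)
        est = score_table(rm, example_bank, estimator="EAPsum",
                          instrument="instrA")[0]
        assert INCOMPLETE_FOR_SUMSCORE in est.flags
        assert math.isnan(est.theta_hat)

    def test_eapsum_without_instrument_on_multibank_errors(
            self, example_bank, simulated_data):
        rm, _ = simulated_data
        with pytest.raises(ValueError, match="instrument"):
            score_table(rm, example_bank, estimator="EAPsum")

    def test_prior_ignored_for_ml_with_notice(self, example_bank,
                                              simulated_data, caplog):
        rm, _ = simulated_data
        sub = ResponseMatrix(rm.codes, rm.data[:3])
        with caplog.at_level(logging.INFO, logger="irtscore.estimation"):
            score_table(sub, example_bank, estimator="ML",
                        prior=Prior.diffuse())
        assert any("ignored" in r.message for r in caplog.records)

    def test_subset_instrument_has_larger_se(self, example_bank):
        cfg = SimulationConfig(n_respondents=50, seed=3)
        rm, _ = simulated_matrix(example_bank, cfg)
        full = score_table(rm, example_bank)
        a_cols = [rm.codes.index(c)
                  for c in example_bank.instruments["instrA"]]
        masked = rm.data.copy()
        keep = np.zeros(masked.shape[1], dtype=bool)
        keep[a_cols] = True
        masked[:, ~keep] = MISSING
        partial = score_table(ResponseMatrix(rm.codes, masked), example_bank)
        assert np.mean([p.se - f.se for f, p in zip(full, partial)]) > 0
        assert all(f.se <= p.se + 1e-9 for f, p in zip(full, partial))

    def test_unknown_estimator_rejected(self, example_bank, simulated_data):
        rm, _ = simulated_data
        with pytest.raises(ValueError, match="unknown estimator"):
            score_table(rm, example_bank, estimator="bogus")
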