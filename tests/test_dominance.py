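"""Dominance GLM, subset scoring, and exact binomial intervals."""

import numpy as np
import pytest
from scipy.stats import binom

from rivalmix.choice import ChoiceScenario
from rivalmix.dominance import (
    LogisticFit,
    TrialRecord,
    best_subsets,
    clopper_pearson,
    dominance_curve,
    fit_dominance_glm,
    log_ratio_features,
    predict_and_score,
)
from rivalmix.synthetic import SyntheticChoiceSpec, make_choice_trials


def swap_trial(t: TrialRecord) -> TrialRecord:
    flipped = {"first": ChoiceScenario("second", winner="swap"),
               "second": ChoiceScenario("first", winner="swap")}[t.outcome.value]
    return TrialRecord(t.pair_id + "-swap", t.features2, t.features1,
                       flipped, 1 - t.y)


class TestLogRatio:
    def test_identical_features_zero(self):
        f = {"a": 2.0, "b": 5.0}
        np.testing.assert_array_equal(log_ratio_features(f, f, ["a", "b"]), 0.0)

    def test_antisymmetry(self, rng):
        f1 = {"a": 2.0, "b": 0.3}
        f2 = {"a": 1.0, "b": 0.9}
        x = log_ratio_features(f1, f2, ["a", "b"])
        np.testing.assert_array_equal(log_ratio_features(f2, f1, ["a", "b"]), -x)

    def test_ln2(self):
        x = log_ratio_features({"a": 2.0}, {"a": 1.0}, ["a"])
        assert x[0] == pytest.approx(np.log(2))

    def test_zero_feature_floored(self):
        x = log_ratio_features({"a": 0.0}, {"a": 1.0}, ["a"])
        assert np.isfinite(x[0]) and x[0] < 0
        both_zero = log_ratio_features({"a": 0.0}, {"a": 0.0}, ["a"])
        assert both_zero[0] == 0.0

    def test_negative_feature_rejected(self):
        with pytest.raises(ValueError):
            log_ratio_features({"a": -1.0}, {"a": 1.0}, ["a"])


class TestFit:
    def test_recovers_known_coefficient(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.4}, n_pairs=2000, seed=11)
        )
        fit = fit_dominance_glm(trials, ["f"], lambda_grid=[0.0])
        assert abs(fit.coef("f") - 1.4) < 3 * fit.se("f")
        assert fit.converged

    def test_null_features_give_small_coefficient(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 0.0}, n_pairs=2000, seed=12)
        )
        fit = fit_dominance_glm(trials, ["f"], lambda_grid=[0.0])
        assert abs(fit.coef("f")) < 3 * fit.se("f")

    def test_swap_duplication_leaves_estimate_unchanged(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.0}, n_pairs=200, seed=13)
        )
        doubled = trials + [swap_trial(t) for t in trials]
        a = fit_dominance_glm(trials, ["f"], lambda_grid=[0.0])
        b = fit_dominance_glm(doubled, ["f"], lambda_grid=[0.0])
        assert a.coef("f") == pytest.approx(b.coef("f"), abs=1e-5)

    def test_complete_separation_flagged(self):
        # perfectly separable: y = 1 iff log ratio > 0
        trials = []
        for i, x in enumerate(np.linspace(-2, 2, 40)):
            if x == 0:
                continue
            y = int(x > 0)
            out = (ChoiceScenario("first", winner="w") if y
                   else ChoiceScenario("second", winner="w"))
            trials.append(TrialRecord(f"t{i}", {"f": float(np.exp(x))},
                                      {"f": 1.0}, out, y))
        fit = fit_dominance_glm(trials, ["f"], lambda_grid=[0.0, 1e-2])
        if fit.lambda_ == 0.0:
            assert "complete-separation" not in fit.flags
        else:
            assert fit.lambda_ > 0

    def test_too_few_trials_rejected(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.0}, n_pairs=10, seed=1)
        )
        with pytest.raises(ValueError):
            fit_dominance_glm(trials, ["f"])


class TestPredictAndScore:
    def _fit(self, beta):
        return LogisticFit(("f",), np.array([beta]), np.array([0.1]),
                           10, 0.0, True)

    def _trial(self, x, y):
        out = (ChoiceScenario("first", winner="w") if y
               else ChoiceScenario("second", winner="w"))
        return TrialRecord(f"x{x}", {"f": float(np.exp(x))}, {"f": 1.0}, out, y)

    def test_perfect_agreement(self):
        trials = [self._trial(1.0, 1), self._trial(-1.0, 0)]
        _, agreement = predict_and_score(self._fit(2.0), trials)
        assert agreement == 1.0

    def test_total_disagreement(self):
        trials = [self._trial(1.0, 0), self._trial(-1.0, 1)]
        _, agreement = predict_and_score(self._fit(2.0), trials)
        assert agreement == 0.0

    def test_half_agreement(self):
        trials = [self._trial(1.0, 1), self._trial(1.0, 0),
                  self._trial(-1.0, 0), self._trial(-1.0, 1)]
        y_model, agreement = predict_and_score(self._fit(2.0), trials)
        assert list(y_model) == [1, 1, 0, 0]
        assert agreement == 0.5


class TestBestSubsets:
    def test_single_feature_single_row(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.0}, n_pairs=100, seed=3)
        )
        table = best_subsets(trials, ["f"], max_size=1, folds=5,
                             lambda_grid=[0.0], seed=0)
        assert len(table) == 1
        assert table.iloc[0].best_in_size

    def test_signal_feature_beats_noise(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"sig": 1.5, "noise": 0.0},
                                n_pairs=500, seed=4)
        )
        table = best_subsets(trials, ["sig", "noise"], max_size=1, folds=5,
                             lambda_grid=[0.0], seed=0)
        best = table[table.best_in_size].iloc[0]
        assert best.subset == "sig"


class TestClopperPearson:
    def test_closed_form_at_zero(self):
        lo, hi = clopper_pearson(0, 10, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_upper_is_one_at_n(self):
        lo, hi = clopper_pearson(10, 10, 0.95)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_against_tail_bisection_oracle(self):
        def oracle(k, n, level):
            a = (1 - level) / 2

            def bisect(f, lo, hi):
                for _ in range(80):
                    mid = (lo + hi) / 2
                    if f(mid):
                        lo = mid
                    else:
                        hi = mid
                return (lo + hi) / 2

            lower = 0.0 if k == 0 else bisect(
                lambda p: binom.sf(k - 1, n, p) < a, 0.0, 1.0)
            upper = 1.0 if k == n else bisect(
                lambda p: binom.cdf(k, n, p) > a, 0.0, 1.0)
            return lower, upper

        for n in (5, 10, 25):
            for k in range(n + 1):
                got = clopper_pearson(k, n, 0.95)
                want = oracle(k, n, 0.95)
                assert got == pytest.approx(want, abs=1e-6)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)


class TestDominanceCurve:
    def test_all_wins_give_probability_one(self):
        trials = []
        for i, x in enumerate(np.linspace(-1, 1, 30)):
            trials.append(TrialRecord(
                f"t{i}", {"f": float(np.exp(x))}, {"f": 1.0},
                ChoiceScenario("first", winner="w"), 1))
        curve = dominance_curve(trials, "f", n_bins=5)
        assert np.all(curve.p_choose_first == 1.0)
        assert np.all(curve.ci_upper == 1.0)
        assert np.all(curve.ci_lower <= curve.p_choose_first)

    def test_mirror_symmetry_of_symmetrized_trials(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.4}, n_pairs=300, seed=9)
        )
        doubled = trials + [swap_trial(t) for t in trials]
        curve = dominance_curve(doubled, "f", n_bins=6)
        np.testing.assert_allclose(
            curve.p_choose_first, 1.0 - curve.p_choose_first[::-1], atol=1e-12
        )
        np.testing.assert_allclose(
            curve.bin_centers, -curve.bin_centers[::-1], atol=1e-12
        )

    def test_counts_sum_to_trials(self):
        trials = make_choice_trials(
            SyntheticChoiceSpec(betas={"f": 1.0}, n_pairs=100, seed=2)
        )
        curve = dominance_curve(trials, "f")
        assert curve.counts.sum() == 100
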