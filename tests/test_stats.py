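"""Statistics tests: permutation inference, FDR, mixed models, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gammaswitch.datatypes import MixedModelResult, PermTestResult
from gammaswitch.stats import (
    PermConfig,
    classify_specificity,
    contingency_chi_square,
    extract_latencies,
    fdr_adjust,
    fit_roi_mixed_model,
    fit_rt_mixed_model,
    permutation_one_sample,
    permutation_two_sample,
)
from gammaswitch.synth import GeneratorConfig, RTModel, generate_cohort_trials
from gammaswitch.datatypes import trials_to_frame


def bh_oracle(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return np.minimum(adj, 1.0)


class TestFDR:
    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_adjust(np.ones(5)), np.ones(5))

    def test_hand_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.037])), [0.037])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_oracle_equivalence_and_monotonicity(self, ps):
        p = np.array(ps)
        adj = fdr_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)


TIMES = np.arange(40) * 10.0


class TestOneSamplePermutation:
    def test_all_zero_null(self):
        res = permutation_one_sample(np.zeros((5, 40)), TIMES)
        assert np.all(res.p_raw == 1.0)
        assert res.windows == []
        assert res.peak_value is None

    def test_exhaustive_sign_flip_oracle(self):
        """For n=8 units constant positive at one bin, the exhaustive
        sign-swap p is 2/2^8; Monte-Carlo agrees within binomial error."""
        n = 8
        values = np.zeros((n, 4))
        values[:, 2] = 1.0
        cfg = PermConfig(n_permutations=4000, seed=3)
        res = permutation_one_sample(values, np.arange(4) * 10.0, cfg)
        p_exact = 2.0 / 2**n
        se = np.sqrt(p_exact * (1 - p_exact) / cfg.n_permutations)
        assert abs(res.p_raw[2] - p_exact) < 3 * se + 2.0 / cfg.n_permutations

    def test_exhaustive_oracle_random_data(self, rng):
        """Monte-Carlo p matches full sign-flip enumeration for n <= 12."""
        n = 10
        values = rng.standard_normal((n, 6))
        cfg = PermConfig(n_permutations=3000, seed=7)
        res = permutation_one_sample(values, np.arange(6) * 10.0, cfg)

        def t_stat(x):
            return x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n))

        t_obs = t_stat(values)
        exceed = np.zeros(values.shape[1])
        for signs in itertools.product([-1.0, 1.0], repeat=n):
            exceed += np.abs(t_stat(np.array(signs)[:, None] * values)) >= np.abs(t_obs)
        p_exact = exceed / 2**n
        se = np.sqrt(p_exact * (1 - p_exact) / cfg.n_permutations)
        assert np.all(np.abs(res.p_raw - p_exact) < 3 * se + 2.0 / cfg.n_permutations)

    def test_needs_two_units(self):
        with pytest.raises(ValueError, match="2 units"):
            permutation_one_sample(np.zeros((1, 10)), np.arange(10.0))

    def test_type_one_error_controlled_under_null(self, rng):
        """Under a global null the raw permutation p-values are valid:
        P(p <= alpha) <= alpha plus Monte-Carlo error, and FDR windows
        are essentially absent (100 null datasets)."""
        n_datasets, n_units, n_bins = 100, 8, 20
        cfg = PermConfig(n_permutations=200, seed=0)
        hits = {0.01: 0, 0.05: 0, 0.1: 0}
        total = 0
        n_windows = 0
        for d in range(n_datasets):
            x = rng.standard_normal((n_units, n_bins))
            res = permutation_one_sample(
                x, np.arange(n_bins) * 10.0, PermConfig(n_permutations=200, seed=d)
            )
            total += n_bins
            for a in hits:
                hits[a] += int(np.sum(res.p_raw <= a))
            n_windows += len(res.windows)
        for a, h in hits.items():
            se = np.sqrt(a * (1 - a) / total)
            assert h / total <= a + 3 * se
        assert n_windows <= 2  # BH leaves almost nothing under the null


class TestTwoSamplePermutation:
    def test_label_swap_negates_statistic(self, rng):
        x = rng.standard_normal((30, 15))
        g = np.zeros(30, dtype=bool)
        g[:12] = True
        cfg = PermConfig(n_permutations=500, seed=1)
        a = permutation_two_sample(x, g, np.arange(15) * 10.0, cfg)
        b = permutation_two_sample(x, ~g, np.arange(15) * 10.0, cfg)
        np.testing.assert_allclose(a.observed_t, -b.observed_t, atol=1e-12)
        np.testing.assert_allclose(a.effect, -b.effect, atol=1e-12)
        np.testing.assert_allclose(a.p_raw, b.p_raw, atol=0.05)

    def test_small_group_rejected(self):
        g = np.zeros(10, dtype=bool)
        g[0] = True
        with pytest.raises(ValueError, match="2 trials"):
            permutation_two_sample(np.zeros((10, 5)), g, np.arange(5.0))

    def test_injected_difference_detected(self, rng):
        """A mean shift confined to bins 10-20 yields a significant
        window covering those bins and a peak inside it."""
        x = rng.standard_normal((120, 40))
        g = np.zeros(120, dtype=bool)
        g[:40] = True
        x[g, 10:20] += 1.2
        res = permutation_two_sample(x, g, TIMES, PermConfig(seed=2))
        assert res.windows
        onset, offset = res.windows[0]
        assert onset >= 60.0 and offset <= 230.0
        assert 100.0 <= res.peak_latency_ms <= 190.0


class TestLatencies:
    def perm_result(self, sig_bins, effect=None):
        n = 30
        p_adj = np.ones(n)
        p_adj[sig_bins] = 0.01
        eff = np.zeros(n) if effect is None else effect
        sig = p_adj < 0.05
        from gammaswitch.stats import _windows_from_mask

        times = np.arange(n) * 10.0
        windows = _windows_from_mask(sig, times)
        peak_v = peak_t = None
        if sig.any():
            idx = np.flatnonzero(sig)
            best = idx[np.argmax(np.abs(eff[idx]))]
            peak_v, peak_t = float(eff[best]), float(times[best])
        return PermTestResult(
            times_ms=times,
            observed_t=np.zeros(n),
            effect=eff,
            p_raw=p_adj,
            p_adj=p_adj,
            alpha=0.05,
            windows=windows,
            peak_value=peak_v,
            peak_latency_ms=peak_t,
        )

    def test_no_significance_gives_empty(self):
        lat = extract_latencies(self.perm_result([]))
        assert lat.onset_ms is None and lat.peak_value is None

    def test_two_disjoint_windows(self):
        eff = np.zeros(30)
        eff[20] = 5.0
        lat = extract_latencies(self.perm_result([3, 4, 5, 19, 20], effect=eff))
        assert lat.onset_ms == 30.0 and lat.offset_ms == 50.0
        assert len(lat.windows) == 2
        assert lat.peak_latency_ms == 200.0


def mm_result(p_fdr_by_predictor):
    rows = []
    for name, p in p_fdr_by_predictor.items():
        rows.append(
            {"predictor": name, "estimate": 1.0, "se": 1.0, "df": 10.0,
             "t": 1.0, "p": p, "ci_low": 0.0, "ci_high": 2.0, "p_fdr": p}
        )
    return MixedModelResult(
        table=pd.DataFrame(rows), random_intercept_var=1.0, residual_var=1.0,
        n_obs=100, n_groups=3, backend="test", converged=True,
    )


class TestSpecificity:
    def windows_result(self, has_window):
        n = 10
        return PermTestResult(
            times_ms=np.arange(n) * 10.0,
            observed_t=np.zeros(n),
            effect=np.zeros(n),
            p_raw=np.ones(n),
            p_adj=np.ones(n),
            alpha=0.05,
            windows=[(10.0, 30.0)] if has_window else [],
            peak_value=5.0 if has_window else None,
            peak_latency_ms=20.0 if has_window else None,
        )

    def test_both_significant(self):
        v = classify_specificity(
            self.windows_result(True), mm_result({"switch": 0.001}), "r", "switch"
        )
        assert v.specific

    def test_window_without_independent_effect(self):
        """A permutation window whose predictor fails the mixed-model FDR
        is not trial-type specific."""
        v = classify_specificity(
            self.windows_result(True), mm_result({"incongruent": 0.8}), "r", "congruency"
        )
        assert v.permutation_significant and not v.specific

    def test_neither(self):
        v = classify_specificity(
            self.windows_result(False), mm_result({"switch": 0.9}), "r", "switch"
        )
        assert not v.specific


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((243, 336, 1285, 1648), 5.0),
            ((673, 1000, 809, 917), 119.4),
            ((615, 933, 867, 984), 134.5),
            ((262, 450, 1279, 1542), 121.6),
        ],
    )
    def test_reference_contingencies(self, table, expected):
        stat, p = contingency_chi_square(*table)
        assert round(stat, 1) == expected
        assert p < 0.05

    def test_equal_proportions_zero(self):
        stat, _ = contingency_chi_square(50, 100, 500, 1000)
        assert stat == pytest.approx(0.0, abs=1e-12)


class TestMixedModels:
    def test_null_generator_recovers_zero_effects(self):
        """With all RT coefficients zero, every fitted fixed effect's CI
        covers zero."""
        cfg = GeneratorConfig(
            rt_model=RTModel(
                intercept=1000.0,
                coefs={k: 0.0 for k in ("switch", "moving", "incongruent",
                                        "prior_incorrect", "log10_trial", "session")},
                patient_sd=50.0,
                residual_sd=200.0,
            ),
            seed=2,
        )
        df = trials_to_frame(generate_cohort_trials(8, cfg, seed=2))
        mm = fit_rt_mixed_model(df)
        for pred in ("switch", "moving", "incongruent", "prior_incorrect", "session"):
            lo, hi = mm.ci(pred)
            assert lo <= 0.0 <= hi, pred

    def test_switch_effect_recovery(self):
        """The generating switch cost lies in the fitted 95% CI."""
        cfg = GeneratorConfig(seed=4)
        df = trials_to_frame(generate_cohort_trials(9, cfg, seed=4))
        mm = fit_rt_mixed_model(df)
        lo, hi = mm.ci("switch")
        assert lo <= 161.0 <= hi

    def test_missing_congruency_dropped(self):
        cfg = GeneratorConfig(seed=5)
        df = trials_to_frame(generate_cohort_trials(4, cfg, seed=5))
        df["is_incongruent"] = df["is_incongruent"].astype(object)
        df.loc[df.index[:50], "is_incongruent"] = None
        mm = fit_rt_mixed_model(df)
        assert mm.n_obs == len(df) - 50

    def test_roi_trend_sign_recovery(self, rng):
        """Opposite practice trends injected at two ROIs are recovered
        with the correct signs (repetition suppression vs enhancement),
        and the across-ROI FDR column is populated."""
        rows = []
        for pid in ("P01", "P02", "P03"):
            for sess in range(1, 6):
                for k in range(1, 45):
                    base = {
                        "patient_id": pid, "session": sess, "trial_index": k,
                        "switch": rng.integers(2), "moving": rng.integers(2),
                        "incongruent": rng.integers(2),
                        "prior_incorrect": rng.integers(2),
                        "log10_trial": np.log10(k),
                    }
                    for roi, slope in (("calcarine", -8.0), ("precuneus", 8.0)):
                        rows.append(
                            {**base, "roi": roi,
                             "hga": 20.0 + slope * np.log10(k) + rng.normal(0, 5)}
                        )
        res = fit_roi_mixed_model(pd.DataFrame(rows))
        cal = res["calcarine"].table.set_index("predictor")
        pre = res["precuneus"].table.set_index("predictor")
        assert cal.loc["log10_trial", "estimate"] < 0
        assert pre.loc["log10_trial", "estimate"] > 0
        assert cal.loc["log10_trial", "p_fdr"] >= cal.loc["log10_trial", "p"]
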