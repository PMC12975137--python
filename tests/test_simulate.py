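"""Tests for the virtual-cohort generator: parameter draws, signal models,
copula coupling, ground-truth labels and cohort assembly."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from wase.simulate import (
    SPORTS,
    ConfigurationError,
    SessionConfig,
    assign_ground_truth,
    generate_signals,
    induce_correlations,
    sample_profile,
    simulate_cohort,
    _truncated_normal,
)

UNIT_MODIFIERS = {s: 1.0 for s in SPORTS}


class TestSampleProfile:
    def test_seed_arithmetic(self):
        cfg = SessionConfig()
        rng = np.random.default_rng(cfg.master_seed + 7)
        p = sample_profile(rng, "running", 7, cfg)
        assert p.seed == 12352

    def test_truncated_normal_monte_carlo(self):
        rng = np.random.default_rng(42)
        draws = np.array([_truncated_normal(rng, 65, 15, 50, 80)
                          for _ in range(10_000)])
        assert draws.min() >= 50 and draws.max() <= 80
        assert abs(draws.mean() - 65) < 1.0

    def test_zero_variance_override(self):
        cfg = SessionConfig(e0_sd=0.0, sport_modifiers=UNIT_MODIFIERS)
        rng = np.random.default_rng(0)
        p = sample_profile(rng, "running", 1, cfg)
        assert p.E0 == 65.0

    def test_empty_truncation_region_rejected(self):
        cfg = SessionConfig(e0_sd=0.0, e0_mu=90.0, sport_modifiers=UNIT_MODIFIERS)
        with pytest.raises(ConfigurationError):
            sample_profile(np.random.default_rng(0), "running", 1, cfg)

    def test_parameters_within_stated_ranges(self):
        cfg = SessionConfig()
        for i in range(1, 30):
            p = sample_profile(np.random.default_rng(i), "swimming", i, cfg)
            assert 50 <= p.E0 <= 80
            assert 0.02 <= p.k <= 0.05
            assert 10 <= p.dI0 <= 50
            assert 0.5 <= p.a_couple <= 1.5
            assert 5 <= p.S_hours <= 9


class TestGenerateSignals:
    def _noise_free_cfg(self, **kw):
        sig = {k: 0.0 for k in ("E", "dI", "phi", "e_env", "C", "T")}
        return SessionConfig(noise_sigmas=sig, sport_modifiers=UNIT_MODIFIERS, **kw)

    def test_fatigue_curve_saturates_to_baseline(self):
        cfg = self._noise_free_cfg()
        p = sample_profile(np.random.default_rng(1), "running", 1, cfg)
        sigs = generate_signals(p, cfg)
        assert sigs["E_pct"].iloc[-1] == pytest.approx(p.E0, rel=1e-6)

    def test_cognition_starts_at_cmax(self):
        cfg = self._noise_free_cfg()
        p = sample_profile(np.random.default_rng(2), "running", 1, cfg)
        sigs = generate_signals(p, cfg)
        assert sigs["C_pct"].iloc[0] == pytest.approx(95.0)

    def test_asymmetry_formula_hand_evaluation(self):
        # dI(900 s) = 30 + 1.0*64 + 5*sin(2*pi*900/86400) ~= 94.327
        cfg = self._noise_free_cfg(n_steps=8, e0_sd=0.0, e0_mu=64.0,
                                   k_range=(0.05, 0.05),
                                   di0_sd=0.0, di0_mu=30.0,
                                   couple_range=(1.0, 1.0), circ_amp=5.0)
        p = sample_profile(np.random.default_rng(3), "running", 1, cfg)
        sigs = generate_signals(p, cfg)
        t = sigs["t_s"].to_numpy()
        i = int(np.where(t == 900.0)[0][0])
        e_at = 64.0 * (1.0 - math.exp(-0.05 * 900.0))
        expected = 30.0 + 1.0 * e_at + 5.0 * math.sin(2 * math.pi * 900 / 86400)
        assert expected == pytest.approx(94.327, abs=2e-3)
        assert sigs["dI_ms_clean"].iloc[i] == pytest.approx(expected, rel=1e-9)

    def test_noise_free_twin_equals_noisy_when_sigma_zero(self):
        cfg = self._noise_free_cfg(n_steps=50)
        p = sample_profile(np.random.default_rng(4), "running", 1, cfg)
        sigs = generate_signals(p, cfg)
        for ch in ("E_pct", "dI_ms", "phi", "e_env", "C_pct", "S_hours", "T"):
            np.testing.assert_allclose(sigs[ch], sigs[ch + "_clean"], atol=1e-12)

    def test_physical_ranges_respected(self):
        cfg = SessionConfig(n_steps=200)
        p = sample_profile(np.random.default_rng(5), "team", 1, cfg)
        sigs = generate_signals(p, cfg)
        assert sigs["E_pct"].between(0, 100).all()
        assert sigs["dI_ms"].between(0, 500).all()
        assert sigs["phi"].between(*cfg.phi_range).all()
        assert sigs["e_env"].between(0, 1).all()
        assert sigs["C_pct"].between(*cfg.c_clip).all()
        assert sigs["T"].between(0, 1).all()


class TestInduceCorrelations:
    def test_zero_targets_independent(self):
        rng = np.random.default_rng(11)
        z = induce_correlations(rng, 10_000, {})
        r = np.corrcoef(z.to_numpy().T)
        off = r[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_target_recovered(self):
        rng = np.random.default_rng(12)
        z = induce_correlations(rng, 10_000, {("E", "phi"): 0.45})
        r = np.corrcoef(z["E"], z["phi"])[0, 1]
        assert r == pytest.approx(0.45, abs=0.03)

    def test_marginals_standard_normal(self):
        rng = np.random.default_rng(13)
        z = induce_correlations(rng, 20_000, {("E", "phi"): 0.45,
                                              ("E", "dI"): 0.35,
                                              ("E", "C"): -0.28})
        assert np.allclose(z.mean(), 0, atol=0.03)
        assert np.allclose(z.std(), 1, atol=0.03)

    def test_perfect_correlation_comonotone(self):
        rng = np.random.default_rng(14)
        z = induce_correlations(rng, 1_000, {("E", "phi"): 1.0})
        np.testing.assert_allclose(z["E"], z["phi"], atol=1e-8)

    def test_non_psd_rejected_with_suggestion(self):
        rng = np.random.default_rng(15)
        targets = {("E", "phi"): 0.9, ("E", "dI"): 0.9, ("phi", "dI"): -0.9}
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            induce_correlations(rng, 10, targets)


class TestGroundTruth:
    def test_midpoint_probability_half(self):
        cfg = SessionConfig(label_softness=0.05)
        rng = np.random.default_rng(21)
        scores = np.full(20_000, cfg.label_threshold)
        labels = assign_ground_truth(scores, cfg, rng)
        # Bernoulli(0.5): 3 SE band
        assert abs(labels.mean() - 0.5) < 3 * 0.5 / math.sqrt(20_000)

    def test_hard_threshold_limit(self):
        cfg = SessionConfig(label_softness=1e-9)
        rng = np.random.default_rng(22)
        labels = assign_ground_truth(np.array([0.1, 0.2, 1.5, 1.9]), cfg, rng)
        np.testing.assert_array_equal(labels, [0, 0, 1, 1])

    def test_expected_positive_count_matches_enumeration(self):
        # exact Bernoulli expectation oracle on a fixed toy trace
        from scipy.special import expit
        cfg = SessionConfig(label_softness=0.05)
        trace = np.array([0.70, 0.75, 0.80, 0.85, 0.90, 1.00])
        expected = expit((trace - 0.8) / 0.05).sum()
        rng = np.random.default_rng(23)
        counts = [assign_ground_truth(trace, cfg, rng).sum()
                  for _ in range(10_000)]
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - expected) < 3 * se

    def test_non_positive_tau_rejected(self):
        cfg = SessionConfig(label_softness=0.0)
        with pytest.raises(ConfigurationError):
            assign_ground_truth(np.array([1.0]), cfg, np.random.default_rng(0))

    def test_prevalence_monotone_in_threshold(self):
        scores = np.linspace(0.2, 1.8, 5000)
        rng_lo = np.random.default_rng(24)
        rng_hi = np.random.default_rng(24)
        lo = assign_ground_truth(scores, SessionConfig(label_threshold=0.6), rng_lo)
        hi = assign_ground_truth(scores, SessionConfig(label_threshold=1.0), rng_hi)
        assert lo.sum() >= hi.sum()


class TestSimulateCohort:
    def test_row_count_arithmetic(self):
        ds = simulate_cohort(SessionConfig(n_athletes=4, n_steps=10))
        assert len(ds) == 40
        assert sorted(ds.frame["sport"].unique()) == sorted(SPORTS)

    def test_default_cohort_shape(self, tiny_default_cohort):
        ds = tiny_default_cohort
        counts = ds.frame.groupby("sport", observed=True)["athlete_id"].nunique()
        assert (counts == 1).all()  # 4 athletes, one per sport
        assert ds.frame["wase_score"].between(0, 2).all()
        assert set(np.unique(ds.labels)) <= {0, 1}

    def test_unbalanced_design_warns(self):
        with pytest.warns(UserWarning, match="not divisible"):
            simulate_cohort(SessionConfig(n_athletes=5, n_steps=5))

    def test_determinism_bitwise(self):
        cfg = SessionConfig(n_athletes=4, n_steps=30)
        a = simulate_cohort(cfg).frame
        b = simulate_cohort(cfg).frame
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = simulate_cohort(SessionConfig(n_athletes=2, n_steps=30)).frame
        b = simulate_cohort(SessionConfig(n_athletes=2, n_steps=30,
                                          master_seed=999)).frame
        assert not a["E_pct"].equals(b["E_pct"])

    def test_marginal_recovery_within_three_se(self):
        # cohort-level parameter draws recover their target means
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = simulate_cohort(SessionConfig(n_steps=2))
        prof = pd.DataFrame([p.__dict__ for p in ds.profiles])
        n = len(prof)
        for col, mu in (("E0", 65.0), ("dI0", 30.0), ("phi_mu_i", 0.80),
                        ("S_hours", 7.2)):
            se = prof[col].std(ddof=1) / math.sqrt(n)
            assert abs(prof[col].mean() - mu) < 3 * se, col

    def test_scores_recomputable_from_raw_columns(self, low_intensity_cohort):
        from wase.scoring import normalize_frame, score_factor_arrays
        frame = low_intensity_cohort.frame
        _, score, _ = score_factor_arrays(normalize_frame(frame))
        np.testing.assert_allclose(score, frame["wase_score"], atol=1e-12)
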