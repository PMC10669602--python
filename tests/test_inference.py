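"""Rate-constant estimation, site-count selection, transition detection."""

import warnings

import numpy as np
import pytest

from oxex import (
    ExchangeObservation,
    LabelDistribution,
    SimulationConfig,
    detect_transition,
    extent_from_kt,
    fit_michaelis_menten,
    fit_rate_constant,
    select_site_count,
    simulate_dataset,
)
from oxex.simulate import DEFAULT_INITIAL, simulate_population

K_TRUE = 10.5


def _uptake_obs(k, velocities, atp=None):
    obs = []
    for i, v in enumerate(velocities):
        x = extent_from_kt(k / v, 0.25)
        obs.append(
            ExchangeObservation(
                velocity=v,
                atp_conc=None if atp is None else atp[i],
                o18_per_p=x.o18_per_p,
                convention="uptake",
            )
        )
    return obs


class TestObservationValidation:
    def test_needs_some_observable(self):
        with pytest.raises(ValueError):
            ExchangeObservation(velocity=10.0)

    def test_washout_consistency_enforced(self):
        with pytest.raises(ValueError):
            ExchangeObservation(
                velocity=10.0,
                o18_per_p=0.5,
                distribution=LabelDistribution(57, 17, 2, 24),  # mean 2.07
                convention="washout",
            )

    def test_mixed_convention_skips_consistency(self):
        obs = ExchangeObservation(
            velocity=10.0,
            o18_per_p=3.9,
            distribution=LabelDistribution(0, 0, 0, 100),
            convention="mixed",
        )
        assert obs.o18_per_p == 3.9


class TestFitRateConstant:
    def test_noiseless_exact_recovery(self):
        velocities = np.geomspace(3.5, 650, 15)
        fit = fit_rate_constant(_uptake_obs(K_TRUE, velocities))
        assert fit.estimates["k"] == pytest.approx(K_TRUE, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert len(fit.residuals) == 15

    def test_two_point_slope(self):
        obs = _uptake_obs(K_TRUE, [10.0, 5.0])  # t = 0.1, 0.2
        fit = fit_rate_constant(obs)
        assert fit.estimates["k"] == pytest.approx(K_TRUE, rel=1e-12)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(1)
        n_mol = 10_000
        obs = []
        for v in np.geomspace(3.5, 650, 15):
            kt = K_TRUE / v
            p = 1 - np.exp(-kt)
            labels = 1 + rng.binomial(3, p, size=n_mol)
            obs.append(
                ExchangeObservation(
                    velocity=float(v),
                    o18_per_p=float(labels.mean()),
                    convention="uptake",
                )
            )
        fit = fit_rate_constant(obs)
        assert fit.estimates["k"] == pytest.approx(K_TRUE, rel=0.05)

    def test_extent_below_floor_names_record(self):
        good = _uptake_obs(K_TRUE, [10.0, 5.0])
        bad = ExchangeObservation(velocity=600.0, o18_per_p=0.9,
                                  convention="uptake")
        with pytest.raises(ValueError, match="18O/P must be >= 1"):
            fit_rate_constant(good + [bad])

    def test_saturated_points_excluded_with_warning(self):
        obs = _uptake_obs(K_TRUE, [10.0, 5.0]) + [
            ExchangeObservation(velocity=0.5, o18_per_p=4.0, convention="uptake")
        ]
        with pytest.warns(UserWarning, match="saturated"):
            fit = fit_rate_constant(obs, max_extent=1 - 1e-6)
        assert fit.estimates["k"] == pytest.approx(K_TRUE, rel=1e-9)

    def test_singular_design_with_intercept(self):
        obs = _uptake_obs(K_TRUE, [10.0, 10.0])
        with pytest.raises(ValueError, match="singular"):
            fit_rate_constant(obs, fit_intercept=True)

    def test_free_intercept_mode_near_zero_intercept(self):
        obs = _uptake_obs(K_TRUE, np.geomspace(3.5, 650, 15))
        fit = fit_rate_constant(obs, fit_intercept=True)
        assert fit.estimates["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert fit.estimates["k"] == pytest.approx(K_TRUE, abs=1e-9)


class TestSelectSiteCount:
    @pytest.mark.parametrize("v,n_true", [(4.0, 2), (200.0, 3)])
    def test_recovers_generating_site_count(self, v, n_true):
        rng = np.random.default_rng(1)
        dist, _ = simulate_population(
            DEFAULT_INITIAL, K_TRUE * n_true / v, 10_000, rng
        )
        obs = ExchangeObservation(velocity=v, distribution=dist)
        sel = select_site_count(obs, K_TRUE, DEFAULT_INITIAL, (1, 2, 3))
        assert sel.n == n_true
        assert not sel.tie
        assert min(sel.sse, key=sel.sse.get) == n_true

    def test_degenerate_no_exchange_ties_to_smallest(self):
        # distribution equal to the initial: all candidates identical fits
        obs = ExchangeObservation(
            velocity=1e9, distribution=DEFAULT_INITIAL
        )
        sel = select_site_count(obs, 1e-9, DEFAULT_INITIAL, (1, 2, 3))
        assert sel.tie
        assert sel.n == 1

    def test_requires_distribution(self):
        obs = ExchangeObservation(velocity=4.0, o18_per_p=2.0,
                                  convention="uptake")
        with pytest.raises(ValueError, match="distribution"):
            select_site_count(obs, K_TRUE, DEFAULT_INITIAL)

    def test_empty_candidates_rejected(self):
        obs = ExchangeObservation(velocity=4.0, distribution=DEFAULT_INITIAL)
        with pytest.raises(ValueError, match="empty"):
            select_site_count(obs, K_TRUE, DEFAULT_INITIAL, ())

    def test_chi2_criterion_agrees_on_clear_cases(self):
        rng = np.random.default_rng(2)
        dist, _ = simulate_population(DEFAULT_INITIAL, K_TRUE * 2 / 4.0, 10_000, rng)
        obs = ExchangeObservation(velocity=4.0, distribution=dist)
        sse_sel = select_site_count(obs, K_TRUE, DEFAULT_INITIAL)
        chi_sel = select_site_count(
            obs, K_TRUE, DEFAULT_INITIAL, criterion="chi2", molecules=10_000
        )
        assert sse_sel.n == chi_sel.n == 2

    def test_selection_accuracy_increases_with_molecule_count(self):
        accuracies = []
        for n_mol in (100, 1_000, 10_000):
            hits = 0
            for seed in range(100):
                rng = np.random.default_rng(seed)
                for v, n_true in ((4.0, 2), (200.0, 3)):
                    dist, _ = simulate_population(
                        DEFAULT_INITIAL, K_TRUE * n_true / v, n_mol, rng
                    )
                    obs = ExchangeObservation(velocity=v, distribution=dist)
                    hits += (
                        select_site_count(obs, K_TRUE, DEFAULT_INITIAL).n
                        == n_true
                    )
            accuracies.append(hits / 200)
        assert accuracies[0] <= accuracies[1] <= accuracies[2]
        assert accuracies[-1] >= 0.95


class TestDetectTransition:
    def _obs_at(self, v, n, n_mol=10_000, seed=0, atp=None):
        rng = np.random.default_rng(seed)
        dist, _ = simulate_population(DEFAULT_INITIAL, K_TRUE * n / v, n_mol, rng)
        return ExchangeObservation(velocity=v, atp_conc=atp, distribution=dist)

    def test_bracket_contains_switch_time(self):
        # series crossing the 33 ms regime boundary; enough molecules that
        # the small kt gaps at the highest ATP concentrations resolve
        ds = simulate_dataset(
            SimulationConfig(seed=5, molecules_per_condition=100_000)
        )
        with_dist = [r.observation for r in ds.records]
        res = detect_transition(with_dist, K_TRUE, DEFAULT_INITIAL)
        assert res.found
        lo, hi = res.bracket_times
        assert lo < 0.033 < hi
        assert lo < res.transition_time < hi

    def test_all_one_regime_reports_no_transition(self):
        obs = [self._obs_at(v, 2, seed=i) for i, v in enumerate((2.0, 4.0, 8.0))]
        res = detect_transition(obs, K_TRUE, DEFAULT_INITIAL)
        assert not res.found
        assert res.transition_time is None

    def test_two_point_midpoint(self):
        obs = [
            self._obs_at(1 / 0.005, 3, n_mol=200_000, seed=1, atp=200.0),
            self._obs_at(1 / 0.250, 2, n_mol=200_000, seed=2, atp=1.0),
        ]
        res = detect_transition(obs, K_TRUE, DEFAULT_INITIAL)
        assert res.found
        assert res.transition_time == pytest.approx(0.1275, rel=1e-12)
        assert res.bracket_times == (pytest.approx(0.005), pytest.approx(0.250))
        assert res.bracket_atp == (200.0, 1.0)

    def test_non_monotone_sequence_warns_not_raises(self):
        obs = [
            self._obs_at(200.0, 2, n_mol=200_000, seed=3),  # short time but n=2
            self._obs_at(4.0, 3, n_mol=200_000, seed=4),    # long time but n=3
        ]
        with pytest.warns(UserWarning, match="not monotone"):
            res = detect_transition(obs, K_TRUE, DEFAULT_INITIAL)
        assert res.labels == (2, 3)


class TestMichaelisMenten:
    def test_noiseless_recovery(self):
        S = np.geomspace(0.11, 5000, 12)
        v = 640 * S / (99 + S)
        fit = fit_michaelis_menten(S, v)
        assert fit.estimates["vmax"] == pytest.approx(640, rel=1e-6)
        assert fit.estimates["km"] == pytest.approx(99, rel=1e-6)

    def test_half_saturation_defines_km(self):
        S = np.array([9.9, 99.0, 990.0])
        v = 640 * S / (99 + S)
        fit = fit_michaelis_menten(S, v)
        assert 640 * 99 / (99 + 99) == pytest.approx(320.0)
        assert fit.estimates["km"] == pytest.approx(99, rel=1e-6)

    def test_saturated_design_flags_km_uncertainty(self):
        rng = np.random.default_rng(0)
        S = np.array([5e4, 1e5, 5e5, 1e6])  # all far above Km
        v = 640 * S / (99 + S) * (1 + 0.01 * rng.standard_normal(4))
        fit = fit_michaelis_menten(S, v)
        relative_se = fit.standard_errors["km"] / abs(fit.estimates["km"])
        assert relative_se > 0.5, "saturated design should leave Km unidentifiable"

    def test_scale_equivariance(self):
        S = np.geomspace(1, 1000, 8)
        v = 640 * S / (99 + S)
        base = fit_michaelis_menten(S, v)
        scaled = fit_michaelis_menten(S, 3.0 * v)
        assert scaled.estimates["vmax"] == pytest.approx(
            3.0 * base.estimates["vmax"], rel=1e-8
        )
        assert scaled.estimates["km"] == pytest.approx(
            base.estimates["km"], rel=1e-8
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            fit_michaelis_menten([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestEndToEndRecovery:
    def test_pipeline_recovers_rate_and_site_counts(self):
        errors, label_hits, label_total = [], 0, 0
        for seed in range(100):
            ds = simulate_dataset(SimulationConfig(seed=seed))
            n_mol = ds.config.molecules_per_condition
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                fit = fit_rate_constant(
                    ds.observations, max_extent=1 - 10 / (4 * n_mol)
                )
            errors.append(abs(fit.estimates["k"] - K_TRUE) / K_TRUE)
            for rec in ds.records:
                sel = select_site_count(
                    rec.observation, K_TRUE, DEFAULT_INITIAL
                )
                label_hits += sel.n == rec.n_true
                label_total += 1
        errors = np.asarray(errors)
        assert np.median(errors) < 0.05
        assert (errors < 0.05).mean() >= 0.95
        assert label_hits / label_total >= 0.95
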