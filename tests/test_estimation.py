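"""Objective function, bounded local fits and the multi-start ensemble."""

from dataclasses import replace

import numpy as np
import pytest

from isrfit import (
    EstimationError,
    FitConfig,
    ModelParams,
    ParamBounds,
    SecretionParams,
    fit_ensemble,
    fit_single_start,
    fit_subject,
    interpolate_glucose,
    objective,
    simulate,
)
from isrfit.models import steady_state_init
from isrfit.synthetic import CPEPTIDE_VALIDATION_BOUNDS, VALIDATION_BOUNDS

TRUTH = {"tau_p": 15.0, "km": 0.6, "c0": 1000.0, "alpha": 0.01}


class TestObjective:
    def test_matches_brute_force_sum(self, noiseless_subject):
        """J equals an explicit per-point residual loop on a random parameter set."""
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        rng = np.random.default_rng(7)
        theta = ModelParams(
            kind="single",
            secretion=SecretionParams(
                km=rng.uniform(0.2, 2.0), c0=rng.uniform(800, 1200), alpha=rng.uniform(0.005, 0.03)
            ),
            tau_p=rng.uniform(10, 60),
        )
        cost = objective(theta, rec, ginput, "insulin")
        x0 = steady_state_init(theta, float(ginput(rec.times[0])))
        traj = simulate(theta, ginput, x0=x0, out_times=rec.times)
        brute = 0.0
        for z, y in zip(rec.insulin, traj.values):
            brute += (z - y) ** 2
        assert cost == pytest.approx(brute, rel=1e-12)

    def test_self_consistency_on_generating_parameters(self, noiseless_subject):
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta = noiseless_subject.spec.theta_insulin
        cost = objective(theta, rec, ginput, "insulin")
        assert cost < 1e-12 * float(np.sum(rec.insulin**2))

    def test_invariant_under_row_permutation(self, noiseless_subject):
        """J sums over measurement times, so shuffling rows cannot change it."""
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta = replace(noiseless_subject.spec.theta_insulin, tau_p=22.0)
        perm = np.random.default_rng(0).permutation(rec.times.size)
        # rebuild the record sorted back from permuted rows: same content
        order = np.argsort(rec.times[perm])
        rec2 = replace(
            rec,
            times=rec.times[perm][order],
            glucose=rec.glucose[perm][order],
            insulin=rec.insulin[perm][order],
            cpeptide=rec.cpeptide[perm][order],
        )
        assert objective(theta, rec2, ginput, "insulin") == pytest.approx(
            objective(theta, rec, ginput, "insulin"), rel=1e-14
        )


class TestSingleStart:
    def test_descent_from_generating_parameters(self, noiseless_subject):
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta0 = noiseless_subject.spec.theta_insulin
        res = fit_single_start(rec, ginput, "insulin", theta0, bounds=VALIDATION_BOUNDS)
        assert res.cost <= objective(theta0, rec, ginput, "insulin") + 1e-15

    def test_descent_from_perturbed_start(self, noiseless_subject):
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta0 = replace(noiseless_subject.spec.theta_insulin, tau_p=40.0)
        start_cost = objective(theta0, rec, ginput, "insulin")
        res = fit_single_start(rec, ginput, "insulin", theta0, bounds=VALIDATION_BOUNDS)
        assert res.cost <= start_cost
        assert res.converged

    def test_noiseless_recovery_within_half_percent(self, noiseless_subject):
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta0 = ModelParams(
            kind="single", secretion=SecretionParams(km=2.0, c0=700.0, alpha=0.02), tau_p=60.0
        )
        res = fit_single_start(rec, ginput, "insulin", theta0, bounds=VALIDATION_BOUNDS)
        est = {
            "tau_p": res.theta.tau_p,
            "km": res.theta.secretion.km,
            "c0": res.theta.secretion.c0,
            "alpha": res.theta.secretion.alpha,
        }
        for name, true_value in TRUTH.items():
            assert abs(est[name] - true_value) / true_value < 0.005

    def test_start_outside_bounds_rejected(self, noiseless_subject):
        rec = noiseless_subject.record
        ginput = interpolate_glucose(rec)
        theta0 = ModelParams(
            kind="single", secretion=SecretionParams(km=500.0, c0=1000.0, alpha=0.02), tau_p=15.0
        )
        with pytest.raises(ValueError):
            fit_single_start(rec, ginput, "insulin", theta0, bounds=VALIDATION_BOUNDS)


class TestEnsemble:
    def test_seed_determinism(self, noiseless_subject):
        config = FitConfig(n_starts=8, seed=42, bounds=VALIDATION_BOUNDS)
        a = fit_ensemble(noiseless_subject.record, "insulin", config=config)
        b = fit_ensemble(noiseless_subject.record, "insulin", config=config)
        np.testing.assert_array_equal(a.params, b.params)
        assert [r.start_index for r in a.accepted] == [r.start_index for r in b.accepted]

    def test_noiseless_ensemble_is_degenerate(self, noiseless_ensemble):
        """All starts reach the same optimum: coefficient of variation < 1%."""
        cv = noiseless_ensemble.param_sd / noiseless_ensemble.param_mean
        assert noiseless_ensemble.n_accepted == noiseless_ensemble.n_starts
        assert np.all(cv < 0.01)

    def test_noiseless_ensemble_recovers_truth(self, noiseless_ensemble):
        est = dict(zip(noiseless_ensemble.param_names, noiseless_ensemble.param_mean))
        for name, true_value in TRUTH.items():
            assert abs(est[name] - true_value) / true_value < 0.005

    def test_boundary_exclusion_when_truth_outside_bounds(self, noiseless_subject):
        """Narrowing tau_p's range to exclude 15 min pushes fits onto the bound."""
        narrow = replace(VALIDATION_BOUNDS, tau_p=(30.0, 180.0))
        config = FitConfig(n_starts=6, seed=1, bounds=narrow)
        with pytest.raises(EstimationError):
            fit_ensemble(noiseless_subject.record, "insulin", config=config)

    def test_ensemble_mean_trajectory_matches_truth(self, noiseless_subject, noiseless_ensemble):
        truth = noiseless_subject.truth["insulin"]
        idx = np.clip(
            np.rint((noiseless_ensemble.grid_times - truth.times[0]) / 0.1).astype(int),
            0,
            truth.times.size - 1,
        )
        ref = truth.values[idx]
        assert np.max(np.abs(noiseless_ensemble.output_mean - ref)) < 1e-3 * np.max(ref)


class TestFitSubject:
    def test_both_species_recovered_with_molar_coupling(self, noiseless_subject):
        config = FitConfig(
            n_starts=10, seed=9, bounds=VALIDATION_BOUNDS, cpeptide_bounds=CPEPTIDE_VALIDATION_BOUNDS
        )
        ens_i, ens_c = fit_subject(noiseless_subject.record, config)
        km_i = dict(zip(ens_i.param_names, ens_i.param_mean))["km"]
        km_c = dict(zip(ens_c.param_names, ens_c.param_mean))["km"]
        assert km_i == pytest.approx(0.6, rel=0.01)
        assert km_c == pytest.approx(0.6 * 0.056, rel=0.01)

    def test_only_available_species_fitted(self, noiseless_subject):
        rec = replace(noiseless_subject.record, cpeptide=None)
        config = FitConfig(n_starts=5, seed=2, bounds=VALIDATION_BOUNDS)
        ens_i, ens_c = fit_subject(rec, config)
        assert ens_i is not None and ens_c is None

    def test_independent_of_other_species_values(self, noiseless_subject):
        """Permuting the c-peptide column cannot change the insulin ensemble."""
        rec = noiseless_subject.record
        scrambled = replace(
            rec, cpeptide=np.random.default_rng(1).permutation(rec.cpeptide)
        )
        config = FitConfig(n_starts=5, seed=3, bounds=VALIDATION_BOUNDS)
        a = fit_ensemble(rec, "insulin", config=config)
        b = fit_ensemble(scrambled, "insulin", config=config)
        np.testing.assert_array_equal(a.params, b.params)

    def test_record_without_any_species_raises(self, noiseless_subject):
        rec = replace(noiseless_subject.record, insulin=None, cpeptide=None)
        with pytest.raises(ValueError):
            fit_subject(rec, FitConfig(n_starts=3))


class TestTwoCompartmentFit:
    def test_noiseless_closure_recovers_all_five_parameters(self):
        theta = ModelParams(
            kind="two_compartment",
            secretion=SecretionParams(km=0.6, c0=1000.0, alpha=0.01),
            tau_p=15.0,
            tau_i=30.0,
        )
        from isrfit import generate_subject, validation_spec

        spec = replace(validation_spec(15.0, noise_fraction=0.0, seed=4), theta_insulin=theta)
        subject = generate_subject(spec)
        config = FitConfig(
            model_kind="two_compartment", n_starts=12, seed=5, bounds=VALIDATION_BOUNDS
        )
        ens = fit_ensemble(subject.record, "insulin", config=config)
        est = dict(zip(ens.param_names, ens.param_mean))
        truth = {"tau_p": 15.0, "tau_i": 30.0, "km": 0.6, "c0": 1000.0, "alpha": 0.01}
        for name, value in truth.items():
            assert abs(est[name] - value) / value < 0.005, name


class TestParamBounds:
    def test_unit_rescaling(self):
        b = ParamBounds().for_unit("mg/dl")
        assert b.c0 == (20.0, 150.0)
        assert b.alpha == pytest.approx((0.15, 0.45))
        assert b.tau_p == (10.0, 180.0)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            ParamBounds(tau_p=(100.0, 10.0))

    def test_config_file_roundtrip(self, tmp_path):
        config = FitConfig(
            model_kind="single",
            n_starts=25,
            seed=7,
            bounds=VALIDATION_BOUNDS,
            cpeptide_bounds=CPEPTIDE_VALIDATION_BOUNDS,
        )
        path = tmp_path / "fit.cfg"
        config.to_file(path)
        back = FitConfig.from_file(path)
        assert back.n_starts == 25 and back.seed == 7
        assert back.bounds.km == VALIDATION_BOUNDS.km
        assert back.cpeptide_bounds.km == CPEPTIDE_VALIDATION_BOUNDS.km
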