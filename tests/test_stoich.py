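import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smstoich.stoich import (
    CalibrationError,
    MonomerCalibration,
    MonomerCalibrator,
    StoichiometryModel,
    build_pdf,
    calibrate_monomer,
    correct_labeling,
    fit_mixture,
    forward_labeling,
    particle_density,
)


class TestCalibrateMonomer:
    def test_gaussian_sample_recovered(self, rng):
        x = rng.normal(1000.0, 150.0, 5000)
        cal = calibrate_monomer(x)
        assert cal.mu1 == pytest.approx(1000.0, rel=0.02)
        assert cal.sigma1 == pytest.approx(150.0, rel=0.05)

    def test_degenerate_zero_variance_is_error(self):
        with pytest.raises(CalibrationError, match="5"):
            calibrate_monomer(np.full(100, 5.0))

    def test_too_few_particles_rejected(self, rng):
        with pytest.raises(CalibrationError, match="particles"):
            calibrate_monomer(rng.normal(1000, 100, 20))

    def test_bimodal_sample_tracks_lower_mode(self, rng):
        # 80% monomer / 20% dimer contamination at twice the mean
        x = np.concatenate(
            [rng.normal(1000.0, 150.0, 4000), rng.normal(2000.0, 212.0, 1000)]
        )
        cal = calibrate_monomer(x)
        assert cal.mu1 == pytest.approx(1000.0, rel=0.03)

    def test_estimator_wrapper_exposes_fitted_attributes(self, rng):
        est = MonomerCalibrator().fit(rng.normal(500.0, 60.0, 1000))
        assert est.mu1_ == pytest.approx(500.0, rel=0.03)
        cal = est.to_calibration()
        assert cal.n_particles == 1000


class TestBuildPdf:
    def test_density_integrates_to_one(self, rng):
        pdf = build_pdf(rng.exponential(200.0, 500))
        assert np.trapezoid(pdf.density, pdf.grid) == pytest.approx(1.0, abs=1e-3)

    def test_kde_consistent_with_closed_form(self, rng):
        from scipy.stats import norm

        x = rng.standard_normal(20000)
        pdf = build_pdf(x)
        assert np.max(np.abs(pdf.density - norm.pdf(pdf.grid))) < 0.02

    def test_two_identical_values_single_peak_at_value(self):
        pdf = build_pdf([42.0, 42.0])
        assert pdf.grid[np.argmax(pdf.density)] == pytest.approx(42.0, rel=1e-2)

    def test_singleton_input_rejected(self):
        with pytest.raises(ValueError):
            build_pdf([5.0])


class TestFitMixture:
    CAL = MonomerCalibration(mu1=250.0, sigma1=62.0, n_particles=1000)

    def test_pure_monomer_sample_is_one_component(self, rng):
        b = rng.normal(250.0, 62.0, 2000)
        frac, _ = fit_mixture(build_pdf(b), self.CAL)
        assert frac[1] >= 0.95

    def test_dimer_trimer_mixture_recovered(self, rng):
        ks = rng.choice([2, 3], 2000)
        b = rng.normal(ks * 250.0, np.sqrt(ks) * 62.0)
        frac, residual = fit_mixture(build_pdf(b), self.CAL)
        assert frac[2] == pytest.approx(0.5, abs=0.05)
        assert frac[3] == pytest.approx(0.5, abs=0.05)
        assert frac[1] <= 0.05
        assert residual < 1e-3

    def test_no_mass_below_dimer_means_no_monomer_weight(self, rng):
        ks = rng.choice([2, 3], 2000)
        b = rng.normal(ks * 250.0, np.sqrt(ks) * 62.0)
        frac, _ = fit_mixture(build_pdf(b), self.CAL)
        assert frac[1] <= 0.02

    def test_weights_invariant_under_common_rescaling(self, rng):
        ks = rng.choice([1, 2, 3], 1500, p=[0.2, 0.5, 0.3])
        b = rng.normal(ks * 250.0, np.sqrt(ks) * 62.0)
        f1, _ = fit_mixture(build_pdf(b), self.CAL)
        c = 3.7
        cal2 = MonomerCalibration(250.0 * c, 62.0 * c, 1000)
        f2, _ = fit_mixture(build_pdf(b * c), cal2)
        assert max(abs(f1[n] - f2[n]) for n in f1) < 1e-9

    def test_fractions_sum_to_one_and_nonnegative(self, rng):
        b = rng.normal(500.0, 90.0, 800)
        frac, _ = fit_mixture(build_pdf(b), self.CAL)
        assert sum(frac.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(v >= 0 for v in frac.values())

    def test_max_n_above_30_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_mixture(build_pdf(rng.normal(250, 60, 100)), self.CAL, max_n=31)

    def test_mle_objective_agrees_with_nnls(self, rng):
        ks = rng.choice([2, 3], 3000)
        b = rng.normal(ks * 250.0, np.sqrt(ks) * 62.0)
        nnls = StoichiometryModel(
            calibration=self.CAL, labeling_p=1.0, objective="nnls"
        ).fit(b)
        mle = StoichiometryModel(
            calibration=self.CAL, labeling_p=1.0, objective="mle"
        ).fit(b)
        for n in (2, 3):
            assert nnls.observed_fractions_[n] == pytest.approx(
                mle.observed_fractions_[n], abs=0.05
            )


class TestLabelingModel:
    def test_full_labeling_is_identity(self):
        f = {1: 0.2, 2: 0.5, 3: 0.3}
        out = forward_labeling(f, p=1.0, max_n=6)
        for n, v in f.items():
            assert out[n] == pytest.approx(v, abs=1e-12)
        back = correct_labeling(out, p=1.0, max_n=6)
        for n, v in f.items():
            assert back[n] == pytest.approx(v, abs=1e-9)

    def test_pure_trimers_give_enumerated_k_fractions(self):
        # binomial enumeration: (0.189, 0.441, 0.343) / (1 - 0.3^3)
        out = forward_labeling({3: 1.0}, p=0.7, max_n=6)
        assert out[1] == pytest.approx(0.1943, abs=1e-4)
        assert out[2] == pytest.approx(0.4533, abs=1e-4)
        assert out[3] == pytest.approx(0.3525, abs=1e-4)

    def test_pure_monomers_put_all_mass_at_one_label(self):
        out = forward_labeling({1: 1.0}, p=0.4, max_n=6)
        assert out[1] == pytest.approx(1.0)

    def test_inversion_of_trimer_fractions(self):
        obs = {1: 0.1943, 2: 0.4533, 3: 0.3525}
        back = correct_labeling(obs, p=0.7, max_n=6)
        assert back[3] >= 0.98

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_forward_then_invert_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(6))
        true = {n + 1: float(f[n]) for n in range(6)}
        obs = forward_labeling(true, p=0.7, max_n=6)
        back = correct_labeling(obs, p=0.7, max_n=6)
        assert max(abs(back[n] - true[n]) for n in true) < 1e-6

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_invalid_labeling_probability_rejected(self, p):
        with pytest.raises(ValueError):
            forward_labeling({2: 1.0}, p=p, max_n=4)
        with pytest.raises(ValueError):
            correct_labeling({2: 1.0}, p=p, max_n=4)

    def test_uncorrected_fractions_biased_toward_lower_n(self):
        # without correction, observed label counts stochastically
        # under-represent the true subunit counts
        true = {2: 0.5, 3: 0.5}
        obs = forward_labeling(true, p=0.7, max_n=6)
        cum_obs = np.cumsum([obs[n] for n in range(1, 7)])
        cum_true = np.cumsum([true.get(n, 0.0) for n in range(1, 7)])
        assert (cum_obs >= cum_true - 1e-12).all()
        assert cum_obs[0] > cum_true[0]


class TestParticleDensity:
    def test_zero_particles_zero_density(self):
        assert particle_density(0, 100.0) == 0.0

    def test_500_particles_in_50um_square_field(self):
        assert particle_density(500, 50.0 * 50.0) == pytest.approx(0.2)

    def test_dilution_factor_scales_density(self):
        base = particle_density(500, 2500.0)
        assert particle_density(500, 2500.0, dilution_factor=10) == pytest.approx(
            10 * base
        )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            particle_density(10, 0.0)


class TestStoichiometryModel:
    def test_corrected_fractions_recover_truth_from_sampled_brightness(self, rng):
        ns = rng.choice([2, 3], 3000)
        kk = rng.binomial(ns, 0.7)
        kk = kk[kk > 0]
        b = rng.normal(kk * 250.0, np.sqrt(kk) * 62.0)
        m = StoichiometryModel(mu1=250.0, sigma1=62.0, labeling_p=0.7).fit(b)
        assert m.corrected_fractions_[2] == pytest.approx(0.5, abs=0.05)
        assert m.corrected_fractions_[3] == pytest.approx(0.5, abs=0.05)
        assert sum(m.corrected_fractions_.values()) == pytest.approx(1.0, abs=1e-6)

    def test_sklearn_params_round_trip(self):
        m = StoichiometryModel(mu1=100.0, sigma1=20.0, labeling_p=0.6)
        params = m.get_params()
        m2 = StoichiometryModel(**params)
        assert m2.get_params() == params

    def test_missing_calibration_is_an_error(self, rng):
        with pytest.raises(ValueError, match="calibration"):
            StoichiometryModel().fit(rng.normal(250, 60, 100))
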