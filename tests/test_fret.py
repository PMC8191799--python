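import numpy as np
import pytest
from scipy.optimize import curve_fit

from kturn.fret import (
    AbsorbanceRatios,
    EmissionSpectrum,
    FretError,
    TitrationPoint,
    bootstrap_kd,
    deconvolute_spectrum,
    efret_acceptor_ratio,
    fit_two_state,
    model_efret,
    read_titration_csv,
    simulate_titration,
    write_titration_csv,
)

KT7 = dict(e0=0.25, de=0.31, kd=70e-6)  # wild-type background parameters


class TestIsotherm:
    def test_zero_concentration_returns_e0(self):
        assert model_efret(0.25, 0.31, 1 / 70e-6, 0.0) == pytest.approx(0.25)

    def test_half_saturation(self):
        # at [Mg2+] = Kd the rise is half complete
        assert model_efret(0.25, 0.31, 1 / 70e-6, 70e-6) == pytest.approx(0.405)

    def test_saturation_limit(self):
        kd = 70e-6
        val = model_efret(0.25, 0.31, 1 / kd, 1e4 * kd)
        assert val == pytest.approx(0.25 + 0.31, abs=1e-4)
        assert abs(model_efret(0.1, 0.5, 1 / kd, 1e7 * kd) - 0.6) < 1e-6

    def test_negative_concentration_rejected(self):
        with pytest.raises(FretError):
            model_efret(0.25, 0.31, 1 / 70e-6, -1e-6)

    def test_monotone_increasing_when_de_positive(self):
        mg = np.geomspace(1e-8, 1e-1, 200)
        vals = model_efret(0.2, 0.4, 1 / 50e-6, mg)
        assert np.all(np.diff(vals) > 0)


def _gaussian_spectrum(center, width, wl=None, label="donor-only", scale=1.0):
    wl = np.linspace(480, 700, 221) if wl is None else wl
    return EmissionSpectrum(wl, scale * np.exp(-(((wl - center) / width) ** 2)), 470, label)


class TestDeconvolution:
    def test_exact_linear_recovery(self):
        donor = _gaussian_spectrum(520, 20)
        acceptor = _gaussian_spectrum(565, 24, label="acceptor-only")
        doubly = EmissionSpectrum(
            donor.wavelength_nm, 2.0 * donor.intensity + 0.5 * acceptor.intensity, 470
        )
        a_d, a_a, resid = deconvolute_spectrum(doubly, donor, acceptor)
        assert a_d == pytest.approx(2.0, abs=1e-9)
        assert a_a == pytest.approx(0.5, abs=1e-9)
        assert resid < 1e-9

    def test_donor_only_input_gives_zero_acceptor(self):
        donor = _gaussian_spectrum(520, 20)
        acceptor = _gaussian_spectrum(565, 24, label="acceptor-only")
        doubly = EmissionSpectrum(donor.wavelength_nm, donor.intensity.copy(), 470)
        _, a_a, _ = deconvolute_spectrum(doubly, donor, acceptor)
        assert a_a == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_propagated_bounds(self):
        """Monte-Carlo: 1% peak noise; amplitude errors within 3 sigma bounds."""
        donor = _gaussian_spectrum(520, 20)
        acceptor = _gaussian_spectrum(565, 24, label="acceptor-only")
        clean = 1.4 * donor.intensity + 0.6 * acceptor.intensity
        basis = np.column_stack([donor.intensity, acceptor.intensity])
        sigma = 0.01 * clean.max()
        # linear-model error propagation: cov = sigma^2 (B^T B)^-1
        cov = sigma**2 * np.linalg.inv(basis.T @ basis)
        sd_d, sd_a = np.sqrt(np.diag(cov))
        rng = np.random.default_rng(7)
        errs_d, errs_a = [], []
        for _ in range(100):
            noisy = EmissionSpectrum(donor.wavelength_nm, clean + rng.normal(0, sigma, clean.size), 470)
            a_d, a_a, _ = deconvolute_spectrum(noisy, donor, acceptor)
            errs_d.append(a_d - 1.4)
            errs_a.append(a_a - 0.6)
        # sample mean of the recovery error stays within 3 sigma / sqrt(n)
        assert abs(np.mean(errs_d)) < 3 * sd_d / 10
        assert abs(np.mean(errs_a)) < 3 * sd_a / 10
        assert np.std(errs_d) < 3 * sd_d

    def test_collinear_references_rejected(self):
        donor = _gaussian_spectrum(520, 20)
        clone = _gaussian_spectrum(520, 20, label="acceptor-only", scale=2.0)
        doubly = EmissionSpectrum(donor.wavelength_nm, donor.intensity.copy(), 470)
        with pytest.raises(FretError, match="collinear"):
            deconvolute_spectrum(doubly, donor, clone)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(FretError):
            EmissionSpectrum(np.array([600.0, 500.0]), np.array([1.0, 1.0]), 470)


class TestAcceptorRatio:
    RATIOS = AbsorbanceRatios(eps_A_at_donor_ex=0.05, eps_A_at_acceptor_ex=1.0,
                              eps_D_at_donor_ex=0.9)

    def test_direct_excitation_only_gives_zero(self):
        # (ratio)A equal to the extinction ratio means no transfer component
        e = efret_acceptor_ratio(0.05, 1.0, self.RATIOS)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_forward_inverse_round_trip(self):
        # forward-compute the acceptor signal for E = 0.5, then invert
        e_true = 0.5
        ratio_a = 0.05 / 1.0 + e_true * 0.9 / 1.0
        assert efret_acceptor_ratio(ratio_a, 1.0, self.RATIOS) == pytest.approx(e_true)

    def test_linear_in_inverse_donor_extinction(self):
        r2 = AbsorbanceRatios(0.05, 1.0, 1.8)
        e1 = efret_acceptor_ratio(0.5, 1.0, self.RATIOS)
        e2 = efret_acceptor_ratio(0.5, 1.0, r2)
        assert e2 == pytest.approx(e1 / 2)

    def test_scale_invariance_of_fluorescence_inputs(self):
        e1 = efret_acceptor_ratio(0.5, 1.0, self.RATIOS)
        e2 = efret_acceptor_ratio(0.5 * 37.2, 1.0 * 37.2, self.RATIOS)
        assert e2 == pytest.approx(e1, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(FretError):
            efret_acceptor_ratio(0.0, 1.0, self.RATIOS)


class TestTwoStateFit:
    def test_noise_free_recovery_to_4_sig_figs(self, standard_grid):
        pts = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.0)
        fit = fit_two_state(pts)
        assert fit.e0 == pytest.approx(KT7["e0"], rel=1e-4)
        assert fit.de == pytest.approx(KT7["de"], rel=1e-4)
        assert fit.kd == pytest.approx(KT7["kd"], rel=1e-4)
        assert fit.converged and fit.identifiable
        assert fit.kd == pytest.approx(1.0 / fit.ka, rel=1e-12)

    def test_agrees_with_independent_curve_fit(self, standard_grid):
        """Cross-check against scipy.optimize.curve_fit on a noisy replicate."""
        pts = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.02, seed=11)
        ours = fit_two_state(pts)
        x = np.array([p.mg_conc for p in pts])
        y = np.array([p.efret for p in pts])
        popt, _ = curve_fit(
            lambda m, e0, de, ka: e0 + de * ka * m / (1 + ka * m),
            x, y, p0=[y.min(), y.max() - y.min(), 1.0 / 70e-6], maxfev=20000,
        )
        assert ours.e0 == pytest.approx(popt[0], rel=1e-3)
        assert ours.de == pytest.approx(popt[1], rel=1e-3)
        assert ours.ka == pytest.approx(popt[2], rel=1e-2)

    def test_constant_curve_flags_unidentifiable(self, standard_grid):
        pts = [TitrationPoint(float(c), 0.4) for c in standard_grid]
        fit = fit_two_state(pts)
        assert abs(fit.de) < 1e-6
        assert not fit.identifiable
        assert fit.warnings

    def test_too_few_points_rejected(self):
        pts = [TitrationPoint(0.0, 0.2), TitrationPoint(1e-4, 0.3), TitrationPoint(1e-3, 0.4)]
        with pytest.raises(FretError, match=">= 4"):
            fit_two_state(pts)

    def test_single_concentration_rejected(self):
        pts = [TitrationPoint(1e-4, 0.3)] * 5
        with pytest.raises(FretError, match="distinct"):
            fit_two_state(pts)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random_parameters(self, seed, standard_grid):
        """fit(simulate(theta, sigma=0)) == theta over random parameter draws."""
        rng = np.random.default_rng(seed)
        e0 = rng.uniform(0.05, 0.45)
        de = rng.uniform(0.05, 0.5)
        kd = 10 ** rng.uniform(-5.3, -3.3)
        pts = simulate_titration(e0, de, kd, standard_grid, noise_sd=0.0)
        fit = fit_two_state(pts)
        assert fit.e0 == pytest.approx(e0, rel=1e-4)
        assert fit.de == pytest.approx(de, rel=1e-4)
        assert fit.kd == pytest.approx(kd, rel=1e-4)

    def test_kd_bias_shrinks_with_noise(self, standard_grid):
        """Median recovered Kd approaches truth as the noise level drops."""
        biases = []
        for sd in (0.05, 0.02, 0.005):
            kds = [
                fit_two_state(
                    simulate_titration(**KT7, concentrations=standard_grid,
                                       noise_sd=sd, seed=s)
                ).kd
                for s in range(40)
            ]
            biases.append(abs(np.median(kds) - KT7["kd"]) / KT7["kd"])
        assert biases[-1] < 0.02
        assert biases[-1] <= biases[0] + 1e-9

    def test_deterministic_given_identical_input(self, standard_grid):
        pts = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.02, seed=3)
        f1, f2 = fit_two_state(pts), fit_two_state(pts)
        assert (f1.e0, f1.de, f1.ka) == (f2.e0, f2.de, f2.ka)


class TestSimulate:
    def test_zero_noise_lies_on_model(self, standard_grid):
        pts = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.0)
        for p in pts:
            assert p.efret == pytest.approx(
                model_efret(KT7["e0"], KT7["de"], 1 / KT7["kd"], p.mg_conc)
            )

    def test_same_seed_reproduces(self, standard_grid):
        a = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.02, seed=5)
        b = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.02, seed=5)
        assert a == b

    def test_residual_mean_near_zero(self):
        """CLT check on 10^4 points: mean residual ~ 0 within 3 sd / sqrt(n)."""
        conc = np.full(10_000, 1e-4)
        sd = 0.02
        pts = simulate_titration(0.25, 0.31, 70e-6, conc, noise_sd=sd, seed=1)
        clean = model_efret(0.25, 0.31, 1 / 70e-6, 1e-4)
        resid = np.array([p.efret for p in pts]) - clean
        assert abs(resid.mean()) < 3 * sd / 100

    def test_empty_concentrations_rejected(self):
        with pytest.raises(FretError, match="empty"):
            simulate_titration(0.25, 0.31, 70e-6, [], 0.0)


def test_bootstrap_kd_interval_covers_truth(standard_grid):
    pts = simulate_titration(**KT7, concentrations=standard_grid, noise_sd=0.02, seed=2)
    boot = bootstrap_kd(pts, n_boot=100, seed=9)
    assert boot["kd_ci_low"] < KT7["kd"] < boot["kd_ci_high"]
    assert boot["n_successful"] > 80


def test_titration_csv_round_trip_with_units(tmp_path):
    pts = [TitrationPoint(70e-6, 0.4), TitrationPoint(1e-3, 0.52)]
    path = tmp_path / "t.csv"
    write_titration_csv(pts, path, units="uM")
    assert "mg_conc_uM" in path.read_text().splitlines()[0]
    back = read_titration_csv(path)
    assert back[0].mg_conc == pytest.approx(70e-6)
    assert back[1].efret == pytest.approx(0.52)
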