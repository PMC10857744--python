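"""Compartmental necrosis model: forcing, geometry, integration, fitting."""

import numpy as np
import pytest

from necrosim import compartmental as comp
from necrosim.compartmental import (
    CompartmentParams,
    ConversionConstants,
    VolumeSeries,
    estimate_rho,
    fit_lesion,
    healthy_death_forcing,
    k_from_initial_volume,
    simulate,
)


class TestHealthyDeathForcing:
    def test_midpoint_and_saturation(self):
        assert healthy_death_forcing(60.0, 1e5, 60.0) == pytest.approx(5e4)
        assert healthy_death_forcing(0.0, 1e5, 60.0) == pytest.approx(1e5, rel=1e-9)
        assert healthy_death_forcing(200.0, 1e5, 60.0) == pytest.approx(0.0, abs=1e-40)

    def test_bounded_in_zero_k(self):
        t = np.linspace(0, 300, 1000)
        H = healthy_death_forcing(t, 2.5e5, 60.0)
        assert np.all(H >= 0) and np.all(H <= 2.5e5)

    def test_total_mass_matches_k_tN(self):
        """Integrated forcing equals ~k * t_N: the shell dies over the window."""
        k, t_N = 3.1e5, 60.0
        t = np.linspace(0, 2 * t_N, 20001)
        mass = np.trapezoid(healthy_death_forcing(t, k, t_N), t)
        assert 0.95 * k * t_N <= mass <= 1.0 * k * t_N

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            healthy_death_forcing(1.0, -1.0, 60.0)
        with pytest.raises(ValueError):
            healthy_death_forcing(1.0, 1.0, -60.0)


class TestKFromInitialVolume:
    def test_reference_lesions_within_5pct(self):
        """One global cell density maps every anchor V0 to its k."""
        conv = ConversionConstants()
        for v0, k_ref in comp.RN_LESION_ANCHORS:
            k = k_from_initial_volume(v0, conv)
            assert abs(k - k_ref) / k_ref < 0.05

    def test_vanishing_margin(self):
        conv = ConversionConstants(margin_width=1e-9)
        assert k_from_initial_volume(1.0, conv) == pytest.approx(0.0, abs=1.0)

    def test_positive_volume_required(self):
        with pytest.raises(ValueError):
            k_from_initial_volume(0.0)


class TestSimulate:
    def test_pure_exponential_limit(self):
        """With no forcing and empty N, I pools the model is T0 e^{rho t}."""
        conv = ConversionConstants()
        p = CompartmentParams(rho=0.01, lambda_N=0, gamma=0, theta=0, k=0, T0=1e7)
        traj = simulate(p, 200.0, conv)
        expected = 1e7 * np.exp(0.01 * traj.times) / (1000 * conv.cell_density)
        np.testing.assert_allclose(traj.total_volume, expected, rtol=1e-6)

    def test_immune_closed_form(self):
        p = CompartmentParams(
            rho=0.001, lambda_N=0, gamma=0, theta=0.17, lambda_I=0.07,
            k=0, T0=1.0, I0=1e7,
        )
        traj = simulate(p, 100.0, ConversionConstants())
        np.testing.assert_allclose(
            traj.I, 1e7 * np.exp(0.1 * traj.times), rtol=1e-6
        )

    def test_non_negativity(self):
        conv = ConversionConstants()
        p = CompartmentParams(
            rho=0.005, lambda_N=2.4e-11, gamma=2.1e-7, theta=0.25,
            k=k_from_initial_volume(1.0, conv), T0=conv.cells_from_cm3(1.0),
        )
        traj = simulate(p, 400.0, conv)
        for pop in (traj.T, traj.N, traj.I):
            assert np.all(pop >= 0)
        assert np.all(traj.total_volume > 0)
        assert np.all(np.diff(traj.times) > 0)

    def test_immune_dominates_late(self):
        """Necrosis-like parameters: the immune pool outgrows the tumor."""
        conv = ConversionConstants()
        p = CompartmentParams(
            rho=0.07, lambda_N=2.3e-11, gamma=1.9e-7, theta=0.17,
            k=k_from_initial_volume(1.0, conv), T0=5e7,
        )
        traj = simulate(p, 600.0, conv)
        assert traj.I[-1] > traj.T[-1]


class TestEstimateRho:
    def test_direct_formula(self):
        s = VolumeSeries("x", [0.0, 1.0], [1.0, np.e])
        assert estimate_rho(s) == pytest.approx(1.0)
        s2 = VolumeSeries("y", [0.0, 30.0], [0.5, 0.6])
        assert estimate_rho(s2) == pytest.approx(np.log(1.2) / 30.0)

    def test_no_growth_rejected(self):
        with pytest.raises(ValueError):
            estimate_rho(VolumeSeries("z", [0.0, 10.0], [2.0, 2.0]))


class TestFitLesion:
    def test_recovers_generating_parameters(self):
        """Noiseless self-consistency: the fitter finds the true rates."""
        conv = ConversionConstants()
        true = CompartmentParams(
            rho=0.005, lambda_N=2.1e-11, gamma=1.95e-7, theta=0.18,
            k=k_from_initial_volume(1.2, conv), T0=conv.cells_from_cm3(1.2),
        )
        times = np.linspace(0.0, 270.0, 7)
        traj = simulate(true, 270.0, conv, times=times)
        series = VolumeSeries("syn", times, traj.total_volume)
        fit = fit_lesion(series, rho=true.rho, k=true.k, conv=conv)
        # relative residual: volumes span six orders of magnitude
        assert fit.residual_norm / series.volumes.max() < 1e-6
        # theta and gamma control the immune blow-up and are identifiable;
        # lambda_N barely affects the total volume and is not asserted
        assert fit.params.theta == pytest.approx(true.theta, rel=0.01)
        assert fit.params.gamma == pytest.approx(true.gamma, rel=0.01)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            fit_lesion(VolumeSeries("a", [0.0, 30.0], [1.0, 1.1]))


class TestBetaDistributionExperiment:
    def test_determinism_and_schema(self):
        a = comp.beta_distribution_experiment(
            n_events=5, V0_grid=np.array([1.0]), seed=42
        )
        b = comp.beta_distribution_experiment(
            n_events=5, V0_grid=np.array([1.0]), seed=42
        )
        assert a.equals(b)
        assert {"V0", "beta", "converged"} <= set(a.columns)

    def test_betas_superlinear_at_small_n(self):
        df = comp.beta_distribution_experiment(
            n_events=40, V0_grid=np.array([1.0, 2.0]), seed=3
        )
        d = df[df.converged]
        assert d.groupby("V0").beta.median().min() > 1.2
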