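"""Swelling percentage, pseudo-second-order kinetics and gel characterisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnswell.exceptions import DegenerateFitError, InsufficientDataError, ValidationError
from mnswell.swelling import (
    GelMasses,
    MassSeries,
    PsoParams,
    convert_ks,
    ewc,
    gel_fraction,
    mass_at_equilibrium,
    porosity,
    pso_fit,
    pso_fit_nls,
    pso_predict,
    swelling_percent_series,
)


def _params(S_inf, k_s):
    return PsoParams(S_inf=S_inf, k_s=k_s, r2=1.0,
                     intercept=1.0 / (k_s * S_inf**2), slope=1.0 / S_inf)


class TestSwellingPercent:
    @pytest.mark.parametrize("m0,mt,expected", [
        (100.0, 456.0, 356.0),
        (100.0, 100.0, 0.0),
        (200.0, 774.0, 287.0),
    ])
    def test_examples(self, m0, mt, expected):
        series = MassSeries(t=np.array([0.0, 10.0]), m=np.array([m0, mt]), m0=m0)
        _, S = swelling_percent_series(series)
        assert S[-1] == pytest.approx(expected)

    def test_mass_below_dry_mass_rejected(self):
        series = MassSeries(t=np.array([0.0, 10.0]), m=np.array([100.0, 90.0]), m0=100.0)
        with pytest.raises(ValidationError, match="below m0"):
            swelling_percent_series(series)

    def test_nonpositive_m0_rejected(self):
        with pytest.raises(ValidationError):
            MassSeries(t=np.array([0.0]), m=np.array([1.0]), m0=0.0)


class TestPsoFit:
    def test_noise_free_round_trip(self):
        t = np.arange(10.0, 181.0, 10.0)
        S = pso_predict(_params(500.0, 2e-4), t)
        fit = pso_fit(t, S)
        assert fit.S_inf == pytest.approx(500.0, rel=1e-6)
        assert fit.k_s == pytest.approx(2e-4, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_linearized_agrees_with_nonlinear_oracle(self):
        t = np.arange(10.0, 181.0, 10.0)
        S = pso_predict(_params(714.0, 5.35e-5), t)
        lin, nls = pso_fit(t, S), pso_fit_nls(t, S)
        assert lin.S_inf == pytest.approx(nls.S_inf, rel=1e-6)
        assert lin.k_s == pytest.approx(nls.k_s, rel=1e-6)

    @given(S_inf=st.floats(50.0, 2000.0), log_ks=st.floats(-6.0, -2.0))
    @settings(max_examples=50, deadline=None)
    def test_forward_backward_consistency(self, S_inf, log_ks):
        k_s = 10.0**log_ks
        t = np.arange(10.0, 181.0, 10.0)
        fit = pso_fit(t, pso_predict(_params(S_inf, k_s), t))
        assert fit.S_inf == pytest.approx(S_inf, rel=1e-6)
        assert fit.k_s == pytest.approx(k_s, rel=1e-6)

    def test_constant_series_is_degenerate(self):
        t = np.arange(10.0, 181.0, 10.0)
        with pytest.raises(DegenerateFitError):
            pso_fit(t, np.full_like(t, 400.0))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pso_fit(np.array([10.0, 20.0]), np.array([50.0, 80.0]))

    def test_t_zero_excluded_before_linearization(self):
        t = np.arange(0.0, 181.0, 10.0)
        S = pso_predict(_params(500.0, 2e-4), t)
        fit = pso_fit(t, S)  # the t=0, S=0 point must not break the fit
        assert fit.S_inf == pytest.approx(500.0, rel=1e-6)


class TestPsoPredict:
    def test_boundary_values(self):
        p = _params(714.0, 5.35e-5)
        assert pso_predict(p, 0.0) == 0.0
        assert pso_predict(p, 1e9) == pytest.approx(714.0, rel=1e-3)
        t_half = 1.0 / (p.k_s * p.S_inf)
        assert pso_predict(p, t_half) == pytest.approx(714.0 / 2.0)

    def test_monotone_and_bounded(self):
        p = _params(500.0, 2e-4)
        t = np.linspace(0.0, 1e4, 500)
        S = pso_predict(p, t)
        assert np.all(np.diff(S) > 0)
        assert np.all(S < 500.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            pso_predict(_params(500.0, 2e-4), -1.0)


class TestGelCharacterisation:
    def test_ewc_worked_example(self):
        masses = GelMasses(m0=100.0, m_inf=683.0, m_x=100.0, m_EtOH=100.0, V_T=1.0)
        assert ewc(masses) == pytest.approx(583.0)

    @pytest.mark.parametrize("m_inf,m_x,expected", [(200.0, 100.0, 100.0),
                                                    (100.0, 100.0, 0.0)])
    def test_ewc_trivial(self, m_inf, m_x, expected):
        masses = GelMasses(m0=100.0, m_inf=m_inf, m_x=m_x, m_EtOH=100.0, V_T=1.0)
        assert ewc(masses) == pytest.approx(expected)

    @pytest.mark.parametrize("m0,m_x,expected", [(100.0, 97.0, 97.0),
                                                 (100.0, 100.0, 100.0),
                                                 (100.0, 50.0, 50.0)])
    def test_gel_fraction(self, m0, m_x, expected):
        masses = GelMasses(m0=m0, m_inf=500.0, m_x=m_x, m_EtOH=m0, V_T=1.0)
        assert gel_fraction(masses) == pytest.approx(expected)

    def test_porosity_worked_example(self):
        # Delta m of 0.11835 g (118.35 mg) in a 1 cm^3 gel -> phi = 0.15
        masses = GelMasses(m0=100.0, m_inf=500.0, m_x=97.0,
                           m_EtOH=218.35, V_T=1.0, rho_EtOH=0.789)
        assert porosity(masses) == pytest.approx(0.15)

    def test_porosity_boundaries(self):
        full = GelMasses(m0=100.0, m_inf=500.0, m_x=97.0,
                         m_EtOH=100.0 + 789.0, V_T=1.0)
        assert porosity(full) == pytest.approx(1.0)
        # m_EtOH == m0 -> 0; equality is a degenerate but legal record
        zero = GelMasses(m0=100.0, m_inf=500.0, m_x=97.0, m_EtOH=100.0 + 1e-12, V_T=1.0)
        assert porosity(zero) == pytest.approx(0.0, abs=1e-12)

    def test_porosity_warns_outside_unit_interval(self):
        masses = GelMasses(m0=100.0, m_inf=500.0, m_x=97.0, m_EtOH=2000.0, V_T=1.0)
        with pytest.warns(UserWarning):
            assert porosity(masses) > 1.0

    def test_validation(self):
        with pytest.raises(ValidationError):
            GelMasses(m0=0.0, m_inf=500.0, m_x=97.0, m_EtOH=100.0, V_T=1.0)


class TestConsistencyAndUnits:
    def test_m_inf_links_fit_and_gel_masses(self):
        """m_inf = m0 (1 + S_inf/100): EWC computed from the fitted plateau
        matches EWC computed from the implied equilibrium mass."""
        m0, S_inf = 260.0, 714.0
        m_inf = mass_at_equilibrium(m0, S_inf)
        assert m_inf == pytest.approx(m0 * (1 + 714.0 / 100.0))
        masses = GelMasses(m0=m0, m_inf=m_inf, m_x=m0 * 0.97, m_EtOH=m0, V_T=1.0)
        expected_ewc = (m_inf - m0 * 0.97) / (m0 * 0.97) * 100.0
        assert ewc(masses) == pytest.approx(expected_ewc)

    def test_ks_unit_conversion_round_trip(self):
        """Percent-scale and mass-fraction-scale rate constants differ by
        exactly 100: refitting the same kinetics with S as a mg/mg fraction
        recovers convert_ks of the percent-scale constant."""
        t = np.arange(10.0, 181.0, 10.0)
        S_pct = pso_predict(_params(500.0, 2e-4), t)
        fit_frac = pso_fit(t, S_pct / 100.0)  # same data on the fraction scale
        assert fit_frac.k_s == pytest.approx(convert_ks(2e-4, "fraction"), rel=1e-6)
        assert convert_ks(convert_ks(2e-4, "fraction"), "percent") == pytest.approx(2e-4)
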