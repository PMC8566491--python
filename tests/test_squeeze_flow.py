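import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oralflow import (
    InvalidInputError,
    NumericalError,
    OralParameters,
    PowerLawFluid,
    approximation_ratio,
    gap_at_time,
    integrate_gap_ode,
    pressure_field,
    stress_at_rate,
    tongue_stress,
    velocity_profile,
)
from oralflow.squeeze_flow import GapTrace, closing_rate


def reference_gap(fluid, params, t, const):
    """Independent transcription of the closed form, arranged differently."""
    n = fluid.n
    B = (
        (n + 1.0)
        * params.F_N
        * params.h0 ** (n + 1.0)
        * params.V ** (1.0 - n)
        / (const * math.pi * n * fluid.kappa * params.R**4)
    )
    return params.h0 / (1.0 + B * t) ** (1.0 / (n + 1.0))


fluid_strategy = st.builds(
    PowerLawFluid,
    kappa=st.floats(0.01, 40.0),
    n=st.floats(0.15, 1.0),
)


class TestGapAtTime:
    def test_t0_is_h0_exactly(self, defaults, sample1_fluid):
        for variant in ("main_text", "derivation"):
            assert gap_at_time(sample1_fluid, defaults, 0.0, variant) == defaults.h0

    def test_newtonian_independent_of_speed(self, defaults):
        fluid = PowerLawFluid(0.05, 1.0)
        slow = defaults.with_overrides(V=0.05)
        fast = defaults.with_overrides(V=0.30)
        for variant in ("main_text", "derivation"):
            h_slow = gap_at_time(fluid, slow, 0.7, variant)
            h_fast = gap_at_time(fluid, fast, 0.7, variant)
            assert h_slow == h_fast  # bitwise

    def test_sample1_derivation_value(self, defaults, sample1_fluid):
        h = gap_at_time(sample1_fluid, defaults, 1.2, "derivation")
        assert h == pytest.approx(3.7e-5, rel=0.02)
        trace = integrate_gap_ode(sample1_fluid, defaults, np.array([0.0, 1.2]))
        assert abs(h / trace.gap[-1] - 1.0) <= 1e-6

    def test_negative_time_rejected(self, defaults, sample1_fluid):
        with pytest.raises(InvalidInputError):
            gap_at_time(sample1_fluid, defaults, -0.1)

    def test_unknown_variant(self, defaults, sample1_fluid):
        with pytest.raises(InvalidInputError):
            gap_at_time(sample1_fluid, defaults, 1.0, "typo")

    def test_matches_independent_transcription(self, defaults, rng):
        for _ in range(50):
            fluid = PowerLawFluid(rng.uniform(0.01, 40), rng.uniform(0.15, 1.0))
            t = rng.uniform(0, 5)
            for variant, const in (("main_text", 2.0), ("derivation", 3.0)):
                assert gap_at_time(fluid, defaults, t, variant) == pytest.approx(
                    reference_gap(fluid, defaults, t, const), rel=1e-12
                )

    @settings(max_examples=60, deadline=None)
    @given(fluid=fluid_strategy, t=st.floats(0.0, 5.0))
    def test_variant_ordering(self, defaults, fluid, t):
        h_main = gap_at_time(fluid, defaults, t, "main_text")
        h_deriv = gap_at_time(fluid, defaults, t, "derivation")
        assert h_main <= h_deriv
        assert tongue_stress(fluid, defaults, t, "main_text") >= tongue_stress(
            fluid, defaults, t, "derivation"
        )

    @settings(max_examples=60, deadline=None)
    @given(fluid=fluid_strategy, t=st.floats(0.0, 5.0), dt=st.floats(0.01, 2.0))
    def test_gap_non_increasing(self, defaults, fluid, t, dt):
        assert gap_at_time(fluid, defaults, t + dt) <= gap_at_time(fluid, defaults, t)


class TestTongueStress:
    def test_t0_equals_stress_at_rate(self, defaults, sample1_fluid):
        sigma = tongue_stress(sample1_fluid, defaults, 0.0)
        expected = stress_at_rate(sample1_fluid, defaults.V / defaults.h0)
        assert sigma == pytest.approx(expected, rel=1e-12)
        assert sigma == pytest.approx(0.28, abs=0.01)

    def test_envelope_all_samples(self, defaults, table1):
        for variant in ("main_text", "derivation"):
            sigmas = [
                tongue_stress(s.fluid, defaults, 1.2, variant) for s in table1
            ]
            assert min(sigmas) >= 1.0
            assert max(sigmas) <= 110.0

    def test_closed_form_identity_with_published_stress_expression(
        self, defaults, rng
    ):
        # sigma(t) computed from h(t) must equal the explicit closed form
        # kappa V^n h0^-n (1 + B t)^{n/(n+1)}
        for _ in range(30):
            fluid = PowerLawFluid(rng.uniform(0.01, 40), rng.uniform(0.15, 1.0))
            t = rng.uniform(0, 3)
            for variant, const in (("main_text", 2.0), ("derivation", 3.0)):
                n = fluid.n
                B = (
                    (n + 1.0)
                    * defaults.F_N
                    * defaults.h0 ** (n + 1.0)
                    * defaults.V ** (1.0 - n)
                    / (const * math.pi * n * fluid.kappa * defaults.R**4)
                )
                explicit = (
                    fluid.kappa
                    * defaults.V**n
                    * defaults.h0**-n
                    * (1.0 + B * t) ** (n / (n + 1.0))
                )
                assert tongue_stress(fluid, defaults, t, variant) == pytest.approx(
                    explicit, rel=1e-12
                )

    @settings(max_examples=40, deadline=None)
    @given(fluid=fluid_strategy, t=st.floats(0.0, 4.0), dt=st.floats(0.01, 2.0))
    def test_non_decreasing_in_time(self, defaults, fluid, t, dt):
        assert tongue_stress(fluid, defaults, t + dt) >= tongue_stress(
            fluid, defaults, t
        )

    @settings(max_examples=40, deadline=None)
    @given(fluid=fluid_strategy, t=st.floats(0.0, 4.0), up=st.floats(1.01, 4.0))
    def test_non_decreasing_in_force(self, defaults, fluid, t, up):
        hi = defaults.with_overrides(F_N=defaults.F_N * up)
        assert tongue_stress(fluid, hi, t) >= tongue_stress(fluid, defaults, t)

    @settings(max_examples=40, deadline=None)
    @given(
        kappa=st.floats(0.01, 10.0),
        n=st.floats(0.15, 1.0),
        t=st.floats(0.0, 4.0),
        up=st.floats(1.01, 4.0),
    )
    def test_non_decreasing_in_kappa(self, defaults, kappa, n, t, up):
        lo = tongue_stress(PowerLawFluid(kappa, n), defaults, t)
        hi = tongue_stress(PowerLawFluid(kappa * up, n), defaults, t)
        assert hi >= lo

    def test_dimensional_scaling(self, sample1_fluid):
        """Scaling all lengths and V by lambda transforms the stress exactly
        as the closed form predicts (checked against the independent
        transcription, not the implementation)."""
        lam = 2.7
        base = OralParameters()
        scaled = OralParameters(
            V=base.V * lam,
            V0=base.V0 * lam**3,  # keeps h0 = V0/(pi R^2) scaled by lam
            R=base.R * lam,
        )
        assert scaled.h0 == pytest.approx(base.h0 * lam, rel=1e-12)
        for t in (0.0, 0.5, 1.2):
            got = tongue_stress(sample1_fluid, scaled, t, "derivation")
            n = sample1_fluid.n
            h = reference_gap(sample1_fluid, scaled, t, 3.0)
            expected = sample1_fluid.kappa * (scaled.V / h) ** n
            assert got == pytest.approx(expected, rel=1e-12)


class TestIntegrateGapOde:
    def test_newtonian_closed_form(self, defaults):
        mu = 0.05
        fluid = PowerLawFluid(mu, 1.0)
        t_grid = np.linspace(0.0, 2.0, 21)
        trace = integrate_gap_ode(fluid, defaults, t_grid)
        h0 = defaults.h0
        expected = h0 * (
            1.0
            + 2.0 * defaults.F_N * h0**2 * t_grid / (3.0 * math.pi * mu * defaults.R**4)
        ) ** (-0.5)
        np.testing.assert_allclose(trace.gap, expected, rtol=1e-6)

    def test_agrees_with_closed_form_random_suite(self, defaults, rng):
        for _ in range(10):
            fluid = PowerLawFluid(rng.uniform(0.01, 40), rng.uniform(0.15, 1.0))
            t_end = rng.uniform(0.1, 5.0)
            t_grid = np.array([0.0, t_end / 2, t_end])
            trace = integrate_gap_ode(fluid, defaults, t_grid)
            closed = gap_at_time(fluid, defaults, t_grid, "derivation")
            np.testing.assert_allclose(trace.gap, closed, rtol=1e-6)

    def test_zero_force_constant_gap(self, defaults):
        params = defaults.with_overrides(F_N=0.0)
        fluid = PowerLawFluid(0.1, 0.5)
        trace = integrate_gap_ode(fluid, params, np.linspace(0.0, 2.0, 11))
        np.testing.assert_allclose(trace.gap, params.h0, rtol=1e-12)

    def test_invalid_grids(self, defaults, sample1_fluid):
        with pytest.raises(InvalidInputError):
            integrate_gap_ode(sample1_fluid, defaults, np.array([0.5, 1.0]))
        with pytest.raises(InvalidInputError):
            integrate_gap_ode(sample1_fluid, defaults, np.array([0.0, 1.0, 0.5]))

    def test_trace_invariants(self, defaults, sample1_fluid):
        trace = integrate_gap_ode(sample1_fluid, defaults, np.linspace(0.0, 1.2, 13))
        assert trace.gap[0] == defaults.h0
        assert np.all(trace.gap > 0)
        assert np.all(np.diff(trace.gap) <= 0)
        assert np.all(trace.stress >= 0)
        assert np.all(np.diff(trace.stress) >= 0)
        assert trace.variant == "derivation"

    def test_trace_csv_round_trip(self, tmp_path, defaults, sample1_fluid):
        import pandas as pd

        trace = integrate_gap_ode(sample1_fluid, defaults, np.linspace(0.0, 1.2, 5))
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path, comment="#")
        assert list(df.columns) == ["time_s", "gap_m", "stress_pa"]
        np.testing.assert_allclose(df["gap_m"].to_numpy(), trace.gap)


class TestVelocityProfile:
    def test_no_slip_boundaries_randomized(self, rng):
        for _ in range(30):
            fluid = PowerLawFluid(rng.uniform(0.05, 5.0), rng.uniform(0.2, 1.0))
            h = rng.uniform(1e-5, 2e-3)
            V = rng.uniform(0.05, 0.5)
            # choose dPdx so that alpha/V is a controlled small number
            eps = rng.uniform(0.01, 0.3)
            n = fluid.n
            mag = (fluid.kappa / h) * ((n + 1.0) * eps * V / (n * h)) ** n
            dPdx = rng.choice([-1.0, 1.0]) * mag
            field = velocity_profile(fluid, h, V, dPdx)
            assert field.alpha == pytest.approx(eps * V, rel=1e-9)
            assert abs(field.u_x[0] - V) <= 1e-9 * V
            assert abs(field.u_x[-1]) <= 1e-9 * V

    def test_newtonian_matches_couette_poiseuille(self):
        mu, h, V = 0.05, 1e-3, 0.15
        dPdx = 0.05 * mu * V / h**2  # alpha/V = 2.5e-2 approx
        field = velocity_profile(PowerLawFluid(mu, 1.0), h, V, dPdx)
        z = field.z_grid
        classical = V * (1 - z / h) - (dPdx / (2 * mu)) * z * (h - z)
        np.testing.assert_allclose(field.u_x, classical, atol=1e-12 * V)
        # and the favourable-gradient branch
        field2 = velocity_profile(PowerLawFluid(mu, 1.0), h, V, -dPdx)
        classical2 = V * (1 - z / h) + (dPdx / (2 * mu)) * z * (h - z)
        np.testing.assert_allclose(field2.u_x, classical2, atol=1e-12 * V)

    def test_zero_gradient_is_couette(self):
        field = velocity_profile(PowerLawFluid(0.1, 0.5), 1e-3, 0.15, 0.0)
        z = field.z_grid
        np.testing.assert_allclose(field.u_x, 0.15 * (1 - z / 1e-3), rtol=1e-12)

    def test_small_gradient_converges_to_couette(self):
        fluid = PowerLawFluid(0.1, 0.4)
        h, V = 1e-3, 0.15
        couette = None
        prev_err = None
        for scale in (1e-2, 1e-4, 1e-6):
            dPdx = scale * fluid.kappa * (V / h) ** fluid.n / h
            field = velocity_profile(fluid, h, V, dPdx)
            if couette is None:
                couette = V * (1 - field.z_grid / h)
            err = np.max(np.abs(field.u_x - couette))
            if prev_err is not None:
                assert err < prev_err
            prev_err = err
        assert prev_err < 1e-6 * V

    def test_taylor_c1_close_to_exact_when_valid(self):
        fluid = PowerLawFluid(0.1, 0.4)
        h, V = 1e-3, 0.15
        dPdx = 1e-3 * fluid.kappa * (V / h) ** fluid.n / h
        field = velocity_profile(fluid, h, V, dPdx)
        assert field.c1 == pytest.approx(field.c1_taylor, rel=1e-2)

    def test_out_of_regime_raises(self):
        fluid = PowerLawFluid(0.01, 0.3)
        with pytest.raises(NumericalError):
            velocity_profile(fluid, 1e-3, 1e-4, 1e6)

    def test_invalid_inputs(self):
        fluid = PowerLawFluid(0.1, 0.5)
        with pytest.raises(InvalidInputError):
            velocity_profile(fluid, 0.0, 0.1, 1.0)
        with pytest.raises(InvalidInputError):
            velocity_profile(fluid, 1e-3, -0.1, 1.0)


class TestPressureField:
    def test_rim_pressure_zero(self, defaults, sample1_fluid):
        h = 1e-4
        hdot = closing_rate(sample1_fluid, defaults, h)
        field = pressure_field(sample1_fluid, defaults, h, hdot, n_grid=101)
        X, Y = np.meshgrid(field.x_grid, field.y_grid)
        rim = np.isclose(X**2 + Y**2, defaults.R**2, rtol=1e-12)
        assert np.all(field.pressure[~(X**2 + Y**2 <= defaults.R**2)] == 0.0)
        if rim.any():
            assert np.all(field.pressure[rim] <= 1e-12)

    def test_peak_pressure_at_center(self, defaults, sample1_fluid):
        h = 1e-4
        n, kappa = sample1_fluid.n, sample1_fluid.kappa
        hdot = closing_rate(sample1_fluid, defaults, h)
        field = pressure_field(sample1_fluid, defaults, h, hdot, n_grid=101)
        expected_peak = (
            6.0 * kappa * n * hdot * defaults.R**2
            / (h ** (n + 2.0) * defaults.V ** (1.0 - n))
        )
        assert field.pressure.max() == pytest.approx(expected_peak, rel=1e-12)
        center = np.argmin(np.abs(field.x_grid))
        assert field.pressure[center, center] == field.pressure.max()

    def test_load_matches_analytic(self, defaults, sample1_fluid):
        # independent oracle: integral of (R^2 - r^2) over the disk is pi R^4 / 2
        h = 1e-4
        n, kappa = sample1_fluid.n, sample1_fluid.kappa
        hdot = closing_rate(sample1_fluid, defaults, h)
        field = pressure_field(sample1_fluid, defaults, h, hdot, n_grid=201)
        analytic = (
            3.0 * math.pi * kappa * n * hdot * defaults.R**4
            / (h ** (n + 2.0) * defaults.V ** (1.0 - n))
        )
        assert abs(field.load / analytic - 1.0) <= 1e-4

    def test_load_is_imposed_force(self, defaults, sample1_fluid):
        # with hdot from the load balance, the integrated load is F_N itself
        h = 5e-5
        hdot = closing_rate(sample1_fluid, defaults, h)
        field = pressure_field(sample1_fluid, defaults, h, hdot, n_grid=201)
        assert field.load == pytest.approx(defaults.F_N, rel=1e-4)

    def test_invalid_inputs(self, defaults, sample1_fluid):
        with pytest.raises(InvalidInputError):
            pressure_field(sample1_fluid, defaults, -1e-4, 1e-3)
        with pytest.raises(InvalidInputError):
            pressure_field(sample1_fluid, defaults, 1e-4, -1e-3)


class TestApproximationRatio:
    def test_zero_squeeze_zero_ratio(self, sample1_fluid):
        params = OralParameters(F_N=0.0)
        assert approximation_ratio(sample1_fluid, params, 0.5) == 0.0

    def test_all_samples_valid_at_assessment_time(self, defaults, table1):
        for s in table1:
            assert approximation_ratio(s.fluid, defaults, 1.2) < 1.0

    def test_increasing_in_force(self, defaults, sample1_fluid):
        forces = [0.1, 0.3, 0.5, 1.0, 2.0]
        ratios = [
            approximation_ratio(
                sample1_fluid, defaults.with_overrides(F_N=F), 1.2
            )
            for F in forces
        ]
        assert all(r2 > r1 for r1, r2 in zip(ratios, ratios[1:]))

    def test_decreasing_in_time(self, defaults, sample1_fluid):
        # squeezing slows as the gap closes, so the ratio relaxes
        r_early = approximation_ratio(sample1_fluid, defaults, 0.05)
        r_late = approximation_ratio(sample1_fluid, defaults, 1.2)
        assert r_late < r_early


class TestGapTraceValidation:
    def test_length_mismatch(self, defaults, sample1_fluid):
        with pytest.raises(InvalidInputError):
            GapTrace(
                times=np.array([0.0, 1.0]),
                gap=np.array([1e-3]),
                stress=np.array([1.0, 2.0]),
                variant="main_text",
                fluid=sample1_fluid,
                params=defaults,
            )
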