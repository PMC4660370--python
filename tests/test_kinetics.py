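"""Rate laws, initial velocities, Michaelis–Menten and global inhibition
fits, mechanism selection and Hanes–Woolf diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokin import kinetics as K
from allokin import synth
from allokin.exceptions import (
    EstimationError,
    InvalidParameterError,
    ValidationError,
)

GDP = synth.KINETICS_TRUTHS["GDP"]
GTP = synth.KINETICS_TRUTHS["GTP"]
GMP = synth.KINETICS_TRUTHS["GMP"]

# independent symbolic evaluation of the mixed rate law at S=Km=51,
# I=Ki=210 with the GDP parameter set (exact rational 6533/20500)
MIXED_ORACLE_V = 6533.0 / 20500.0


class TestRateLaws:
    def test_half_saturation_all_mechanisms(self):
        for mech, params in [
            ("none", {"vmax": 2.0, "km": 51.0}),
            ("competitive", {"vmax": 2.0, "km": 51.0, "ki": 600.0}),
            ("mixed", {"vmax": 2.0, "km": 51.0, "ki": 210.0,
                       "alpha": 6.5, "beta": 0.033}),
        ]:
            assert K.predict_velocity(51.0, 0.0, params, mech) \
                == pytest.approx(1.0)

    def test_competitive_km_doubles_at_I_equal_ki(self):
        p = {"vmax": 1.0, "km": 51.0, "ki": 600.0}
        # Km_app = 2 Km at I = Ki, so v(S=Km) = Vmax/3
        assert K.predict_velocity(51.0, 600.0, p, "competitive") \
            == pytest.approx(1.0 / 3.0)

    def test_mixed_rate_matches_symbolic_oracle(self):
        v = K.predict_velocity(51.0, 210.0, GDP, "mixed")
        assert v == pytest.approx(MIXED_ORACLE_V, rel=1e-12)

    def test_mixed_high_I_limit(self):
        # v -> beta*Vmax*S/(alpha*Km + S) as I -> inf
        S_val = 100.0
        v = K.predict_velocity(S_val, 1e12, GDP, "mixed")
        expected = GDP["beta"] * GDP["vmax"] * S_val \
            / (GDP["alpha"] * GDP["km"] + S_val)
        assert v == pytest.approx(expected, rel=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            K.predict_velocity(1.0, 0.0, {"vmax": -1.0, "km": 51.0}, "none")
        with pytest.raises(InvalidParameterError):
            K.predict_velocity(1.0, 1.0, {"vmax": 1.0, "km": np.nan,
                                          "ki": 1.0}, "competitive")
        with pytest.raises(InvalidParameterError):
            K.predict_velocity(-1.0, 0.0, {"vmax": 1.0, "km": 51.0}, "none")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 1e4), st.floats(0.1, 1e4),
        st.floats(1.0, 1e4), st.floats(1.5, 100.0), st.floats(0.0, 0.9),
    )
    def test_monotonicity(self, km, ki, vmax, alpha, beta):
        """v nondecreasing in S; nonincreasing in I for alpha>1, beta<1."""
        p = {"vmax": vmax, "km": km, "ki": ki, "alpha": alpha, "beta": beta}
        S_grid = np.geomspace(0.01, 1e5, 30)
        I_grid = np.geomspace(0.01, 1e5, 30)
        v_S = K.predict_velocity(S_grid, np.full_like(S_grid, ki), p, "mixed")
        assert np.all(np.diff(v_S) >= -1e-12 * vmax)
        v_I = K.predict_velocity(np.full_like(I_grid, km), I_grid, p, "mixed")
        assert np.all(np.diff(v_I) <= 1e-12 * vmax)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1.0, 1e3), st.floats(1.0, 1e3), st.floats(0.1, 50.0),
           st.floats(0.0, 5.0), st.floats(0.0, 5e3), st.floats(0.1, 5e3))
    def test_apparent_params_consistent_with_rate_law(self, km, ki, alpha,
                                                      beta, I, S_val):
        p = {"vmax": 1.7, "km": km, "ki": ki, "alpha": alpha, "beta": beta}
        va, ka = K.apparent_parameters(I, p, "mixed")
        v_direct = K.predict_velocity(S_val, I, p, "mixed")
        assert v_direct == pytest.approx(va * S_val / (ka + S_val), rel=1e-12)

    def test_alpha_beta_unity_means_no_inhibition(self):
        p = {"vmax": 1.0, "km": 51.0, "ki": 210.0, "alpha": 1.0, "beta": 1.0}
        S_grid = np.geomspace(1, 5000, 20)
        v0 = K.predict_velocity(S_grid, 0.0, p, "mixed")
        v1 = K.predict_velocity(S_grid, 5000.0, p, "mixed")
        np.testing.assert_allclose(v0, v1, rtol=1e-12)

    def test_mixed_approaches_competitive_as_alpha_grows(self):
        pc = {"vmax": 1.0, "km": 51.0, "ki": 210.0}
        S_grid = np.geomspace(10, 5000, 10)
        prev = np.inf
        for alpha in (1e2, 1e4, 1e6):
            pm = dict(pc, alpha=alpha, beta=0.0)
            vm = K.predict_velocity(S_grid, 210.0, pm, "mixed")
            vc = K.predict_velocity(S_grid, 210.0, pc, "competitive")
            dev = float(np.max(np.abs(vm - vc) / vc))
            assert dev < prev
            prev = dev
        assert prev < 1e-3


class TestApparentParameters:
    def test_identity_at_zero_inhibitor(self):
        fitlike = {"vmax": 3.0, "km": 40.0, "ki": 100.0,
                   "alpha": 2.0, "beta": 0.1}
        assert K.apparent_parameters(0.0, fitlike, "mixed") \
            == pytest.approx((3.0, 40.0))

    def test_competitive_at_ki(self):
        p = {"vmax": 3.0, "km": 40.0, "ki": 100.0}
        va, ka = K.apparent_parameters(100.0, p, "competitive")
        assert (va, ka) == pytest.approx((3.0, 80.0))

    def test_mixed_large_I_limits(self):
        p = {"vmax": 2.0, "km": 51.0, "ki": 210.0, "alpha": 6.5,
             "beta": 0.033}
        va, ka = K.apparent_parameters(1e6 * 210.0, p, "mixed")
        assert va == pytest.approx(0.033 * 2.0, rel=1e-3)
        assert ka == pytest.approx(6.5 * 51.0, rel=1e-3)

    def test_mechanism_none_ignores_inhibitor(self):
        assert K.apparent_parameters(500.0, {"vmax": 1.0, "km": 51.0},
                                     "none") == (1.0, 51.0)


class TestInitialVelocity:
    def test_unit_conversion_linear_trace(self):
        # slope 0.00622 A/min with eps=6220, l=1 -> exactly 1 μM/min
        t = np.arange(0, 300, 5.0)
        A = 0.00622 / 60.0 * t
        tc = K.TimeCourse(times=t, absorbance=A)
        assert K.estimate_initial_velocity(tc) == pytest.approx(1.0, rel=1e-9)

    def test_flat_trace_gives_zero(self):
        tc = K.TimeCourse(times=np.arange(10.0), absorbance=np.zeros(10))
        assert K.estimate_initial_velocity(tc) == pytest.approx(0.0, abs=1e-12)

    def test_saturating_curve_with_noise_within_5pct(self):
        tc = synth.gen_progress_curve(
            2.0, noise=synth.NoiseSpec(proportional_sd=0.005, seed=7))
        v0 = K.estimate_initial_velocity(tc)
        assert v0 == pytest.approx(2.0, rel=0.05)

    def test_too_few_points_raises(self):
        tc = K.TimeCourse(times=np.arange(4.0), absorbance=np.zeros(4))
        with pytest.raises(EstimationError):
            K.estimate_initial_velocity(tc)


class TestMichaelisMentenFit:
    S_GRID = np.array(synth.DEFAULT_S_GRID)

    def test_noiseless_exact_recovery(self):
        v = K.predict_velocity(self.S_GRID, 0.0,
                               {"vmax": 1.0, "km": 51.0}, "none")
        mm = K.fit_michaelis_menten((self.S_GRID, v))
        assert abs(mm.vmax - 1.0) < 1e-6
        assert abs(mm.km - 51.0) / 51.0 < 1e-6

    def test_scale_equivariance(self):
        v = K.predict_velocity(self.S_GRID, 0.0,
                               {"vmax": 1.0, "km": 51.0}, "none")
        mm10 = K.fit_michaelis_menten((self.S_GRID, 10.0 * v))
        assert mm10.vmax == pytest.approx(10.0, rel=1e-6)
        assert mm10.km == pytest.approx(51.0, rel=1e-6)

    def test_noisy_recovery_within_3se(self):
        data = synth.gen_kinetics_dataset(
            {"mechanism": "none", "vmax": 1.0, "km": 51.0},
            synth.NoiseSpec(proportional_sd=0.03, seed=11),
            i_levels=(0.0,), replicates=3)
        mm = K.fit_michaelis_menten(data)
        assert abs(mm.km - 51.0) < 3.0 * mm.km_se


class TestGlobalFit:
    def test_noiseless_roundtrip_mixed(self):
        data = synth.gen_kinetics_dataset(
            GDP, synth.NoiseSpec(proportional_sd=0.0, seed=0), replicates=1)
        fit = K.fit_inhibition_global(data)
        assert fit.mechanism is K.Mechanism.MIXED
        for name, truth in [("ki", 210.0), ("alpha", 6.5), ("beta", 0.033),
                            ("km", 51.0), ("vmax", 1.0)]:
            assert abs(getattr(fit, name) - truth) / truth < 1e-4

    def test_mixed_recovery_within_3se(self):
        data = synth.gen_kinetics_dataset(GDP, synth.NoiseSpec(seed=3))
        fit = K.fit_inhibition_global(data)
        assert fit.mechanism is K.Mechanism.MIXED
        for name, truth in [("ki", 210.0), ("alpha", 6.5), ("beta", 0.033)]:
            se = fit.standard_errors[name]
            assert abs(getattr(fit, name) - truth) < 3.0 * se

    def test_competitive_recovery(self):
        data = synth.gen_kinetics_dataset(GMP, synth.NoiseSpec(seed=5))
        fit = K.fit_inhibition_global(data)
        assert fit.mechanism is K.Mechanism.COMPETITIVE
        assert abs(fit.ki - 600.0) < 3.0 * fit.standard_errors["ki"]

    def test_inert_inhibitor_classified_none(self):
        data = synth.gen_kinetics_dataset(
            {"mechanism": "mixed", "vmax": 1.0, "km": 51.0, "ki": 210.0,
             "alpha": 1.0, "beta": 1.0},  # velocities independent of I
            synth.NoiseSpec(seed=4))
        fit = K.fit_inhibition_global(data)
        assert fit.mechanism is K.Mechanism.NONE

    def test_apparent_params_at_zero_equal_global(self):
        data = synth.gen_kinetics_dataset(GDP, synth.NoiseSpec(seed=3))
        fit = K.fit_inhibition_global(data)
        va, ka = fit.apparent_params[0.0]
        assert (va, ka) == pytest.approx((fit.vmax, fit.km))

    def test_requires_two_nonzero_levels(self):
        data = synth.gen_kinetics_dataset(
            GDP, synth.NoiseSpec(seed=0), i_levels=(0.0, 210.0))
        with pytest.raises(ValidationError):
            K.fit_inhibition_global(data)


class TestClassifyMechanism:
    def test_prefers_simpler_within_indifference(self):
        crit = {"none": 10.0, "competitive": 0.0, "mixed": -1.0}
        mech, ambiguous = K.classify_mechanism(crit)
        assert mech is K.Mechanism.COMPETITIVE
        assert ambiguous

    def test_clear_winner_not_ambiguous(self):
        crit = {"none": 10.0, "competitive": 5.0, "mixed": 0.0}
        mech, ambiguous = K.classify_mechanism(crit)
        assert mech is K.Mechanism.MIXED
        assert not ambiguous

    def test_empty_criteria_rejected(self):
        with pytest.raises(ValidationError):
            K.classify_mechanism({})


class TestHanesWoolf:
    S_GRID = np.array(synth.DEFAULT_S_GRID)

    @staticmethod
    def _dataset(truth, i_levels):
        return synth.gen_kinetics_dataset(
            truth, synth.NoiseSpec(proportional_sd=0.0, seed=0),
            i_levels=i_levels, replicates=1)

    def test_slope_is_inverse_vmax_noiseless(self):
        data = self._dataset({"mechanism": "none", "vmax": 2.0, "km": 51.0},
                             (0.0,) * 1 + (1.0, 2.0))
        hw = K.hanes_woolf(data)
        for lev in hw.levels:
            assert lev.slope == pytest.approx(0.5, rel=1e-10)

    def test_competitive_parallel_lines_intercept_ratio_2(self):
        data = self._dataset(GMP, (0.0, 600.0))  # I = Ki
        hw = K.hanes_woolf(data)
        s0, s1 = hw.levels[0], hw.levels[1]
        assert s0.slope == pytest.approx(s1.slope, rel=1e-10)
        assert s1.intercept / s0.intercept == pytest.approx(2.0, rel=1e-10)

    def test_mixed_slope_factor_matches_formula(self):
        # slope ratio (1 + I/(alpha Ki)) / (1 + beta I/(alpha Ki)),
        # evaluated symbolically beforehand for the GTP parameters at I=Ki
        data = self._dataset(GTP, (0.0, 160.0))
        hw = K.hanes_woolf(data)
        ratio = hw.levels[1].slope / hw.levels[0].slope
        assert ratio == pytest.approx(1.1751152073732718, rel=1e-10)

    def test_sparse_level_skipped(self):
        obs = [K.KineticObservation(s, 0.0, "none", v)
               for s, v in zip([10, 20, 40, 80, 160],
                               [0.1, 0.2, 0.3, 0.4, 0.5])]
        obs += [K.KineticObservation(10.0, 50.0, "X", 0.05),
                K.KineticObservation(20.0, 50.0, "X", -0.01)]
        hw = K.hanes_woolf(K.KineticDataset("e", obs))
        assert hw.skipped_levels == [50.0]
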