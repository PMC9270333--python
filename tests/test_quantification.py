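"""Enhancement, polarization, back-extrapolation, reproducibility statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dnpq.calibration import AcquisitionScheme
from dnpq.quantification import (
    SpectrumMeasurement,
    back_extrapolate,
    enhancement,
    polarization_from_enhancement,
    quantify_dissolution,
    solid_state_polarization,
    summarize_runs,
)
from dnpq.relaxometry import fit_liquid_decay
from dnpq.spin_physics import FieldState, get_nucleus, thermal_polarization
from dnpq.synthetic_data import simulate_dissolution_run


def measurement(integral, alpha, ns=1, rg=1.0, role="hyperpolarized"):
    return SpectrumMeasurement(
        integral, AcquisitionScheme(flip_angle=alpha, ns=ns, rg=rg), role
    )


# Worked examples of the high-field / low-field cross-calibration
HP_94T = measurement(7.59e5, 5.0, ns=1, rg=0.25)
TP_94T = measurement(1.41e5, 90.0, ns=1, rg=101.0, role="thermal")
HP_1T = measurement(32.38, 5.0, ns=1, rg=31.0)
TP_1T = measurement(4.18e-4, 20.0, ns=3600, rg=31.0, role="thermal")


class TestEnhancement:
    def test_high_field_worked_example(self):
        assert enhancement(HP_94T, TP_94T) == pytest.approx(2.5e4, rel=0.02)

    def test_low_field_worked_example_summed_convention(self):
        assert enhancement(HP_1T, TP_1T) == pytest.approx(1.09e9, rel=0.02)

    def test_averaged_convention_drops_ns_ratio(self):
        summed = enhancement(HP_1T, TP_1T, "summed")
        averaged = enhancement(HP_1T, TP_1T, "averaged")
        assert summed / averaged == pytest.approx(3600.0, rel=1e-12)

    def test_identical_measurements_give_unity(self):
        m = measurement(5.0, 10.0, ns=4, rg=2.0)
        assert enhancement(m, m) == pytest.approx(1.0)

    def test_zero_thermal_integral_rejected(self):
        with pytest.raises(ValueError, match="thermal"):
            enhancement(HP_1T, measurement(0.0, 20.0, role="thermal"))

    def test_zero_flip_angle_rejected(self):
        with pytest.raises(ValueError, match="sine"):
            enhancement(measurement(1.0, 0.0), TP_1T)

    @given(factor=st.floats(0.01, 100.0))
    def test_invariances_under_common_rescaling(self, factor):
        """Scaling both integrals (or both RGs) by one factor changes nothing;
        epsilon is linear in the hyperpolarized integral."""
        base = enhancement(HP_94T, TP_94T)
        hp2 = measurement(HP_94T.integral * factor, 5.0, rg=0.25)
        tp2 = measurement(TP_94T.integral * factor, 90.0, rg=101.0, role="thermal")
        assert enhancement(hp2, tp2) == pytest.approx(base, rel=1e-9)
        hp3 = measurement(HP_94T.integral, 5.0, rg=0.25 * factor)
        tp3 = measurement(TP_94T.integral, 90.0, rg=101.0 * factor, role="thermal")
        assert enhancement(hp3, tp3) == pytest.approx(base, rel=1e-9)
        hp4 = measurement(HP_94T.integral * factor, 5.0, rg=0.25)
        assert enhancement(hp4, TP_94T) == pytest.approx(base * factor, rel=1e-9)


class TestPolarization:
    def test_high_field_example_reaches_20_percent(self):
        eps = enhancement(HP_94T, TP_94T)
        p_tp = thermal_polarization(get_nucleus("13C"), FieldState(9.4, 295.0))
        assert polarization_from_enhancement(eps, p_tp) * 100 == pytest.approx(20.0, abs=0.5)

    def test_unit_enhancement_returns_thermal(self):
        assert polarization_from_enhancement(1.0, 8.2e-6) == pytest.approx(8.2e-6)

    def test_zero_enhancement_returns_zero(self):
        assert polarization_from_enhancement(0.0, 8.2e-6) == 0.0


class TestBackExtrapolate:
    def test_table_row_example(self):
        assert back_extrapolate(0.34, 19.0, 88.0) * 100 == pytest.approx(42.2, abs=0.1)

    def test_zero_transfer_time_is_identity(self):
        assert back_extrapolate(0.34, 0.0, 88.0) == pytest.approx(0.34)

    def test_monotone_in_transfer_time(self):
        p = [back_extrapolate(0.3, t, 80.0) for t in (0.0, 5.0, 10.0, 30.0)]
        assert all(b > a for a, b in zip(p, p[1:]))

    @given(t1=st.floats(1.0, 50.0), t2=st.floats(1.0, 50.0))
    def test_semigroup_property(self, t1, t2):
        """Extrapolating t1+t2 at once equals two sequential steps."""
        one = back_extrapolate(0.2, t1 + t2, 70.0)
        two = back_extrapolate(back_extrapolate(0.2, t1, 70.0), t2, 70.0)
        assert one == pytest.approx(two, rel=1e-12)


class TestSolidStatePolarization:
    def test_dnp_vs_thermal_equilibrium_signal(self):
        p = solid_state_polarization(2.0e7, 4.07e4, 1220e-6)
        assert p * 100 == pytest.approx(60.0, abs=1.0)

    def test_equal_signals_return_thermal(self):
        assert solid_state_polarization(5.0, 5.0, 1.2e-3) == pytest.approx(1.2e-3)

    def test_zero_signal_returns_zero(self):
        assert solid_state_polarization(0.0, 5.0, 1.2e-3) == 0.0

    def test_zero_equilibrium_rejected(self):
        with pytest.raises(ValueError):
            solid_state_polarization(1.0, 0.0, 1.2e-3)


# Five repeated dissolutions of the standard protocol (printed run table)
RUNS = pd.DataFrame(
    {
        "conc_mM": [61.19, 59.51, 58.39, 59.23, 56.14],
        "tdnp_s": [1000.0, 1047.0, 1018.0, 1048.0, 1045.0],
        "ttrans_s": [19.0, 19.0, 20.0, 20.0, 17.0],
        "p_meas_pct": [34.0, 33.0, 36.0, 46.0, 43.0],
        "p0_pct": [42.3, 39.6, 44.8, 57.5, 51.9],
        "t1_s": [88.0, 101.0, 89.0, 94.0, 87.0],
        "ph": [8.40, 8.32, 8.90, 8.77, 8.65],
    }
)


class TestSummarizeRuns:
    def test_buildup_constant_statistics(self):
        s = summarize_runs(RUNS)["tdnp_s"]
        assert s.mean == pytest.approx(1032.0, abs=1.0)
        assert s.sample_sd == pytest.approx(21.7, abs=0.2)
        assert s.cv_percent == pytest.approx(2.1, abs=0.1)

    def test_concentration_statistics(self):
        s = summarize_runs(RUNS)["conc_mM"]
        assert s.mean == pytest.approx(58.89, abs=0.01)
        assert s.cv_percent == pytest.approx(3.1, abs=0.1)

    def test_back_extrapolated_polarization_mean(self):
        assert summarize_runs(RUNS)["p0_pct"].mean == pytest.approx(47.2, abs=0.1)

    def test_identical_values_have_zero_cv(self):
        s = summarize_runs(pd.DataFrame({"x": [3.0, 3.0, 3.0]}))["x"]
        assert s.sample_sd == 0.0
        assert s.cv_percent == 0.0

    def test_single_run_has_no_spread(self):
        s = summarize_runs(pd.DataFrame({"x": [3.0]}))["x"]
        assert s.mean == 3.0
        assert s.sample_sd is None and s.cv_percent is None

    @given(factor=st.floats(0.01, 1000.0))
    def test_cv_scale_invariant(self, factor):
        base = summarize_runs(RUNS)["tdnp_s"].cv_percent
        scaled = summarize_runs(RUNS.assign(tdnp_s=RUNS["tdnp_s"] * factor))
        assert scaled["tdnp_s"].cv_percent == pytest.approx(base, rel=1e-9)


class TestEndToEndDissolution:
    HP_SCHEME = AcquisitionScheme(flip_angle=5.0, ns=1, rg=31.0, tr=3.0)
    TP_SCHEME = AcquisitionScheme(flip_angle=20.0, ns=3600, rg=31.0, tr=2.0)

    def quantify_run(self, run):
        fit = fit_liquid_decay(run.decay, self.HP_SCHEME)
        return quantify_dissolution(
            run.hyper,
            run.thermal,
            run.truth["thermal_pol"],
            run.truth["t_trans"],
            fit.time_constant_corrected,
        )

    def test_noiseless_pipeline_recovers_p0_within_1pct(self):
        run = simulate_dissolution_run(
            true_p0=0.47,
            liquid_t1=88.0,
            t_trans=19.0,
            hyper_scheme=self.HP_SCHEME,
            thermal_scheme=self.TP_SCHEME,
            thermal_pol=0.8711e-6,
            seed=11,
        )
        q = self.quantify_run(run)
        assert q.polarization_at_dissolution == pytest.approx(0.47, rel=1e-2)

    def test_snr50_pipeline_recovers_p0_within_5pct(self):
        recovered = []
        for seed in range(100):
            run = simulate_dissolution_run(
                true_p0=0.47,
                liquid_t1=88.0,
                t_trans=19.0,
                hyper_scheme=self.HP_SCHEME,
                thermal_scheme=self.TP_SCHEME,
                thermal_pol=0.8711e-6,
                seed=seed,
                snr=50.0,
            )
            recovered.append(self.quantify_run(run).polarization_at_dissolution)
        assert abs(np.mean(recovered) - 0.47) / 0.47 < 0.05

    def test_ns_convention_mismatch_off_by_ns_ratio(self):
        """Quantifying NS-averaged data as summed shifts P by exactly NS_TP/NS_HP."""
        run = simulate_dissolution_run(
            true_p0=0.47,
            liquid_t1=88.0,
            t_trans=19.0,
            hyper_scheme=self.HP_SCHEME,
            thermal_scheme=self.TP_SCHEME,
            thermal_pol=0.8711e-6,
            seed=11,
            ns_convention="averaged",
        )
        eps_right = enhancement(run.hyper, run.thermal, "averaged")
        eps_wrong = enhancement(run.hyper, run.thermal, "summed")
        assert eps_wrong / eps_right == pytest.approx(3600.0, rel=1e-12)
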