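"""Indo-1 calibration and force/calcium summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kinfiber import (
    CalibrationParams,
    FiberScenario,
    FiberTrace,
    StimulationProtocol,
    caffeine_probe,
    calcium_to_ratio,
    fatigue_summary,
    fit_hill,
    frequency_curves,
    generate_fiber_recording,
    hill_force,
    ratio_to_calcium,
    specific_force,
    tetanic_peaks,
)


class TestCalibration:
    def test_ratio_at_rmin_gives_zero(self, params):
        assert calcium_to_ratio(0.0, params) == pytest.approx(params.r_min)
        assert ratio_to_calcium(params.r_min + 1e-12, params) == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_ratio_gives_kd_beta(self, params):
        mid = (params.r_min + params.r_max) / 2.0
        kdb = params.kd_um * params.beta
        assert ratio_to_calcium(mid, params) == pytest.approx(kdb, rel=1e-12)
        assert calcium_to_ratio(kdb, params) == pytest.approx(mid, rel=1e-12)

    def test_direct_substitution(self, params):
        # K_D=0.25, beta=3, R_min=0.2, R_max=1.0, R=0.6 -> 0.75 uM
        assert ratio_to_calcium(0.6, params) == pytest.approx(0.75)

    def test_saturating_limit(self, params):
        r = calcium_to_ratio(np.array([0.0, 1e3, 1e6]), params)
        assert np.all(np.diff(r) > 0)
        assert r[-1] < params.r_max
        assert r[-1] == pytest.approx(params.r_max, rel=1e-5)

    def test_roundtrip_identity_on_grid(self, params):
        ca = np.geomspace(1e-4, 50.0, 1000)
        back = ratio_to_calcium(calcium_to_ratio(ca, params), params)
        assert np.max(np.abs(back / ca - 1.0)) < 1e-9

    @given(r=st.floats(0.21, 0.99))
    def test_strictly_increasing(self, params, r):
        h = 1e-6
        assert ratio_to_calcium(r + h, params) > ratio_to_calcium(r, params)

    def test_out_of_range_raises_unless_clipped(self, params):
        with pytest.raises(ValueError):
            ratio_to_calcium(params.r_max, params)
        with pytest.raises(ValueError):
            ratio_to_calcium(np.array([0.5, 0.1]), params)
        assert ratio_to_calcium(1.5, params, clip=True) > 1e6
        with pytest.raises(ValueError):
            calcium_to_ratio(-1.0, params)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CalibrationParams(kd_um=-1, beta=3, r_min=0.2, r_max=1.0)
        with pytest.raises(ValueError):
            CalibrationParams(kd_um=0.25, beta=3, r_min=1.0, r_max=0.2)


class TestSpecificForce:
    def test_unit_conversion(self):
        assert specific_force(0.3, 1500.0) == pytest.approx(200.0)

    def test_zero_force_and_csa_scaling(self):
        assert specific_force(0.0, 1000.0) == 0.0
        assert specific_force(0.4, 2000.0) == pytest.approx(specific_force(0.4, 1000.0) / 2)

    def test_nonpositive_csa(self):
        with pytest.raises(ValueError):
            specific_force(0.3, 0.0)


def square_trace(peaks, duration=0.35, interval=2.0, fs=200.0, fiber_id="f1"):
    """Force trace with rectangular tetani of the given peak forces."""
    n = len(peaks)
    t = np.arange(0.0, 0.5 + n * interval, 1.0 / fs)
    force = np.zeros_like(t)
    rows = []
    for i, p in enumerate(peaks):
        s, e = 0.5 + i * interval, 0.5 + i * interval + duration
        force[(t >= s) & (t <= e)] = p
        rows.append({"start_s": s, "end_s": e, "frequency_hz": 70.0})
    return FiberTrace(fiber_id=fiber_id, time_s=t, force_mn=force,
                      csa_um2=1500.0, windows=pd.DataFrame(rows))


class TestTetanicPeaks:
    def test_constant_force_window_peak(self):
        out = tetanic_peaks(square_trace([0.4]))
        assert out["peak_force_mn"].iloc[0] == pytest.approx(0.4)

    def test_second_window_scaled_by_half(self):
        out = tetanic_peaks(square_trace([0.4, 0.2]))
        assert out["peak_force_mn"].iloc[1] == pytest.approx(
            0.5 * out["peak_force_mn"].iloc[0]
        )

    def test_plateau_estimate_recovers_generator_truth(self, params):
        scenario = FiberScenario(
            protocol=StimulationProtocol.frequency_sweep((15, 50, 150), interval_s=2.0),
            params=params, noise_cv=0.0, rng_seed=0,
        )
        rec = generate_fiber_recording(scenario)
        out = tetanic_peaks(rec.trace, params)
        assert np.allclose(
            out["tetanic_ca_um"], rec.truth["true_ca_amplitude_um"], rtol=0.01
        )

    def test_window_without_samples_raises(self):
        tr = square_trace([0.4])
        tr.windows.loc[0, ["start_s", "end_s"]] = [90.0, 90.3]
        with pytest.raises(ValueError):
            tetanic_peaks(tr)


class TestFrequencyCurves:
    def sweep(self, params, seed=0, noise=0.0):
        scenario = FiberScenario(
            protocol=StimulationProtocol.frequency_sweep(interval_s=2.0),
            params=params, noise_cv=noise, rng_seed=seed,
        )
        return generate_fiber_recording(scenario), scenario

    def test_single_fiber_mean_equals_fiber_values(self, params):
        rec, _ = self.sweep(params)
        per_fiber, summary = frequency_curves([rec.trace], params)
        merged = summary.merge(per_fiber, on="frequency_hz")
        assert np.allclose(merged["specific_force_kn_m2_mean"],
                           merged["specific_force_kn_m2"])
        assert np.allclose(merged["tetanic_ca_um_mean"], merged["tetanic_ca_um"])

    def test_hill_half_activation_recovered_within_5pct(self, params):
        rec, scenario = self.sweep(params, noise=0.005, seed=4)
        per_fiber, _ = frequency_curves([rec.trace], params)
        fit = fit_hill(per_fiber["tetanic_ca_um"], per_fiber["specific_force_kn_m2"])
        assert fit["ca50_um"] == pytest.approx(scenario.ca50_um, rel=0.05)

    def test_all_zero_force_gives_zero_curve(self, params):
        tr = square_trace([0.0, 0.0])
        tr.windows["frequency_hz"] = [15.0, 70.0]
        per_fiber, summary = frequency_curves([tr])
        assert (per_fiber["peak_force_mn"] == 0).all()
        assert (summary["specific_force_kn_m2_mean"] == 0).all()

    def test_duplicate_frequency_rejected(self):
        tr = square_trace([0.4, 0.3])
        with pytest.raises(ValueError):
            frequency_curves([tr])


class TestFatigueSummary:
    protocol = StimulationProtocol.fatigue(n_contractions=10)

    def test_no_decline_all_100(self):
        tr = square_trace([0.4] * 10)
        out = fatigue_summary(tr, self.protocol)
        assert np.allclose(out["pct_force"], 100.0)

    def test_geometric_decline_closed_form(self):
        peaks = [0.4 * 0.99**i for i in range(10)]
        out = fatigue_summary(square_trace(peaks), self.protocol)
        assert out["pct_force"].iloc[-1] == pytest.approx(100 * 0.99**9, rel=1e-9)

    @given(scale=st.floats(0.01, 50.0))
    def test_invariant_to_positive_scaling(self, scale):
        peaks = [0.4 * 0.98**i for i in range(10)]
        a = fatigue_summary(square_trace(peaks), self.protocol)
        b = fatigue_summary(square_trace([p * scale for p in peaks]), self.protocol)
        assert np.allclose(a["pct_force"], b["pct_force"])

    def test_missing_window_is_an_error(self):
        with pytest.raises(ValueError):
            fatigue_summary(square_trace([0.4] * 9), self.protocol)

    def test_zero_first_peak_is_an_error(self):
        with pytest.raises(ValueError):
            fatigue_summary(square_trace([0.0] * 10), self.protocol)


class TestCaffeineProbe:
    def probe_traces(self, params, scale=1.0, seed=0):
        base = dict(
            protocol=StimulationProtocol.frequency_sweep((150,), interval_s=2.0),
            params=params, noise_cv=0.0,
        )
        pre = generate_fiber_recording(FiberScenario(rng_seed=seed, **base))
        amp = pre.scenario.resolved_ca_amplitudes()
        post = generate_fiber_recording(
            FiberScenario(
                rng_seed=seed,
                ca_amplitudes_um={150.0: amp[150.0] * scale},
                **base,
            )
        )
        return pre.trace, post.trace

    def test_identical_traces_zero_difference(self, params):
        pre, post = self.probe_traces(params, scale=1.0)
        out = caffeine_probe(pre, post, params)
        assert len(out) == 1
        assert out["delta_ca_um"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_20pct_larger_store_gives_20pct_difference(self, params):
        pre, post = self.probe_traces(params, scale=1.2)
        out = caffeine_probe(pre, post, params)
        assert out["delta_ca_um"].iloc[0] == pytest.approx(
            0.2 * out["pre_ca_um"].iloc[0], rel=0.02
        )

    def test_mismatched_fiber_ids_rejected(self, params):
        pre, post = self.probe_traces(params)
        post.fiber_id = "other"
        with pytest.raises(ValueError):
            caffeine_probe(pre, post, params)


class TestProtocol:
    def test_interval_must_exceed_duration(self):
        with pytest.raises(ValueError):
            StimulationProtocol.fatigue(interval_s=0.3)

    def test_hill_is_saturating(self):
        ca = np.linspace(0.01, 10, 100)
        f = hill_force(ca, 1.0, 0.6, 3.0)
        assert np.all(np.diff(f) > 0) and f[-1] < 1.0
        assert hill_force(np.array(0.6), 1.0, 0.6, 3.0) == pytest.approx(0.5)
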