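"""Ventilation, metabolic, AUC, burst, and timing metrics."""

import numpy as np
import pytest

from respicycle import metrics as met
from respicycle.cycles import PhaseSegmentation

FS = 1000.0


def _seg(N=100, insp=40, postI=20, lateE=15):
    return PhaseSegmentation(
        lateE=(N - lateE, N), insp=(0, insp), postI=(insp, insp + postI),
        rest=(insp + postI, N - lateE), mode="last-quarter", N=N,
    )


class TestCalibration:
    def test_exact_line_recovered(self):
        cal = met.fit_calibration([(x, 2 * x) for x in (0.1, 0.5, 1.0, 2.0, 2.5)])
        assert cal.slope == pytest.approx(2.0, abs=1e-12)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.residual == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_perturbation_stays_within_delta(self):
        delta = 0.05
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        pert = delta * np.array([1, -1, 1, -1, 0])
        cal = met.fit_calibration(list(zip(x, 3 * x + pert)))
        fitted = cal.to_ml(x)
        assert np.max(np.abs(fitted - 3 * x)) <= delta + 1e-12

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="need >= 2 calibration points"):
            met.fit_calibration([(1.0, 2.0)])

    def test_duplicate_x_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            met.fit_calibration([(1.0, 2.0), (1.0, 3.0)])


class TestTidalVolume:
    def _cal(self, slope=2.0):
        return met.fit_calibration([(0.0, 0.0), (1.0, slope)])

    def test_rectangular_pulse(self):
        """Height h over width w with ml = 2x gives VT = 2hw/mass."""
        h, w, mass = 0.4, 0.25, 0.5
        x = np.zeros(1000)
        x[: int(w * FS)] = h
        x[int(w * FS) : int(w * FS) + 100] = -0.2  # expiratory deflection
        vt = met.tidal_volume(x, FS, self._cal(), mass, insp_end=int(w * FS))
        assert vt == pytest.approx(2 * h * w / mass, rel=1e-9)
        # auto-detected inspiratory end lands within a smoothing window
        vt_auto = met.tidal_volume(x, FS, self._cal(), mass)
        assert vt_auto == pytest.approx(2 * h * w / mass, rel=0.01)

    def test_zero_airflow_gives_intercept_over_mass(self):
        cal = met.fit_calibration([(0.0, 1.0), (1.0, 3.0)])  # intercept 1
        assert met.tidal_volume(np.zeros(500), FS, cal, 0.5) == pytest.approx(2.0)
        assert met.tidal_volume(np.zeros(500), FS, self._cal(), 0.5) == 0.0

    def test_linearity_with_zero_intercept(self):
        x = np.zeros(800)
        x[:300] = np.sin(np.pi * np.arange(300) / 300)
        x[300:400] = -0.1
        v1 = met.tidal_volume(x, FS, self._cal(), 1.0)
        v2 = met.tidal_volume(2 * x, FS, self._cal(), 1.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-6)

    def test_negative_fitted_volume_clipped(self):
        cal = met.fit_calibration([(0.0, -1.0), (1.0, 0.0)])
        assert met.tidal_volume(np.zeros(500), FS, cal, 1.0) == 0.0


class TestRateAndTimes:
    def test_uniform_cycles(self):
        rr, ti, te = met.rate_and_times(np.full(10, 1.5), _seg())
        assert rr == pytest.approx(40.0)
        assert rr * (ti + te) == pytest.approx(60.0)

    def test_ti_te_split_follows_segmentation(self):
        seg = _seg(N=100, insp=25)
        rr, ti, te = met.rate_and_times(np.full(5, 1.2), seg)
        assert ti == pytest.approx(0.3)
        assert te == pytest.approx(0.9)


class TestOxygenConsumption:
    def test_formula_value(self):
        assert met.oxygen_consumption(300.0, 0.30, 0.28) == pytest.approx(
            8.5714, abs=1e-4
        )

    def test_equal_fractions_give_zero(self):
        assert met.oxygen_consumption(250.0, 0.30, 0.30) == 0.0

    def test_monotone_in_extraction(self):
        v = [met.oxygen_consumption(300.0, 0.30, f) for f in (0.29, 0.27, 0.25)]
        assert v[0] < v[1] < v[2]

    def test_expired_above_inspired_rejected(self):
        with pytest.raises(ValueError, match="expired O2 exceeds inspired"):
            met.oxygen_consumption(300.0, 0.28, 0.30)


class TestPhaseAuc:
    def test_identical_cycles_give_zero_everywhere(self, rng):
        a = rng.standard_normal(100)
        seg = _seg()
        aucs = met.phase_auc(a, a, seg, seg)
        assert all(v == 0.0 for v in aucs.values())

    def test_constant_offset_over_inspiration(self):
        seg = _seg(N=100, insp=40)
        base = np.zeros(100)
        resp = base.copy()
        resp[:40] += 0.5
        aucs = met.phase_auc(resp, base, seg, seg)
        assert aucs["insp"] == pytest.approx(0.5 * 40)
        assert aucs["postI"] == 0.0

    def test_negative_deflection_gives_negative_auc(self):
        seg = _seg()
        base = np.zeros(100)
        resp = base.copy()
        resp[seg.lateE[0]:] = -0.3
        aucs = met.phase_auc(resp, base, seg, seg)
        assert aucs["lateE"] < 0

    def test_phase_additivity(self, rng):
        """Sum of per-phase AUCs equals the whole-cycle AUC exactly."""
        resp, base = rng.standard_normal((2, 100))
        seg = _seg()
        aucs = met.phase_auc(resp, base, seg, seg)
        assert sum(aucs.values()) == pytest.approx(resp.sum() - base.sum(),
                                                   abs=1e-9)


class TestLateEPeak:
    def test_no_subzero_flow_has_zero_area(self):
        a = np.full(100, 0.2)
        a[:40] = 1.0
        amp, area = met.late_e_peak(a, _seg(), mean_duration_s=1.0)
        assert area == 0.0
        assert amp == pytest.approx(0.2)

    def test_triangular_deflection(self):
        N, lateE = 200, 50
        seg = PhaseSegmentation(
            lateE=(N - lateE, N), insp=(0, 80), postI=(80, 100),
            rest=(100, N - lateE), mode="last-quarter", N=N,
        )
        d, dur = 0.6, 2.0
        a = np.zeros(N)
        a[N - lateE : N] = -d * (1 - np.abs(np.linspace(-1, 1, lateE)))
        amp, area = met.late_e_peak(a, seg, mean_duration_s=dur)
        w = lateE / N * dur  # deflection base in seconds
        assert amp == pytest.approx(-d, rel=0.05)
        assert area == pytest.approx(-d * w / 2, rel=0.05)

    def test_deeper_deflection_lowers_amplitude(self):
        seg = _seg()
        a = np.zeros(100)
        amps = []
        for d in (0.1, 0.4, 0.9):
            a[seg.lateE[0]:] = -d
            amps.append(met.late_e_peak(a, seg, 1.0)[0])
        assert amps[0] > amps[1] > amps[2]


class TestBurstDetection:
    def test_flat_trace_has_no_bursts(self):
        assert met.detect_bursts(np.zeros(1000), FS) == []

    def test_injected_bursts_recovered_at_injected_times(self):
        x = np.zeros(60000)
        times = [5.0, 12.0, 20.0, 33.0, 50.0]
        for t in times:
            i = int(t * FS)
            x[i : i + 100] = 6.0 * np.sin(np.pi * np.arange(100) / 100)
        events = met.detect_bursts(x, FS, k_sd=3.0)
        assert len(events) == len(times)
        for ev, t in zip(events, times):
            assert abs(ev.t_start - t) < 0.05
            assert ev.peak == pytest.approx(6.0, rel=0.01)

    def test_close_runs_merged(self):
        x = np.zeros(2000)
        x[100:200] = 5.0
        x[250:350] = 5.0  # 50 ms gap < 150 ms merge window
        x[1000:1100] = 5.0
        events = met.detect_bursts(x, FS, k_sd=3.0, min_gap_s=0.15)
        assert len(events) == 2
        assert events[0].t_end - events[0].t_start == pytest.approx(0.25, abs=0.01)


def _burst(channel, t):
    return met.BurstEvent(channel=channel, t_start=t, t_end=t + 0.05, peak=5.0)


class TestCouplingAndTiming:
    def test_three_abd_per_five_dia_gives_point_six(self):
        dia = [_burst("DIA", 10.0 + k * 1.5) for k in range(5)]
        abd = [_burst("ABD", 10.0 + k * 1.5 + 1.2) for k in (0, 2, 4)]
        assert met.abd_dia_coupling(abd, dia, 0.0) == pytest.approx(0.6)

    def test_fully_coupled_is_one(self):
        dia = [_burst("DIA", k * 1.5) for k in range(20)]
        abd = [_burst("ABD", k * 1.5 + 1.2) for k in range(20)]
        assert met.abd_dia_coupling(abd, dia, 0.0) == pytest.approx(1.0)

    def test_double_abd_bursts_in_one_breath_count_once(self):
        dia = [_burst("DIA", k * 1.5) for k in range(10)]
        abd = [_burst("ABD", k * 1.5 + 0.5) for k in range(10)]
        abd += [_burst("ABD", k * 1.5 + 1.2) for k in range(10)]
        assert met.abd_dia_coupling(sorted(abd, key=lambda b: b.t_start),
                                    dia, 0.0) == pytest.approx(1.0)

    def test_sustained_tonic_event_credits_spanned_breaths(self):
        """One long merged ABD event over many breaths couples all of them."""
        dia = [_burst("DIA", k * 1.5) for k in range(10)]
        tonic = met.BurstEvent(channel="ABD", t_start=0.5, t_end=13.6, peak=20.0)
        assert met.abd_dia_coupling([tonic], dia, 0.0) == pytest.approx(1.0)

    def test_no_abd_bursts_is_zero(self):
        dia = [_burst("DIA", k * 1.5) for k in range(5)]
        assert met.abd_dia_coupling([], dia, 0.0) == 0.0

    def test_no_dia_bursts_rejected(self):
        with pytest.raises(ValueError, match="no inspiratory bursts"):
            met.abd_dia_coupling([_burst("ABD", 1.0)], [], 0.0)

    def test_delay_sign_and_duration(self):
        abd = [_burst("ABD", 390.0), _burst("ABD", 450.0)]
        s = met.abd_delay_duration(abd, t_inj2_end=370.0)
        assert s.delay_s == pytest.approx(20.0)
        assert s.duration_min == pytest.approx(1.0)
        early = met.abd_delay_duration([_burst("ABD", 281.3)], t_inj2_end=370.0)
        assert early.delay_s == pytest.approx(-88.7)
        assert early.duration_min == 0.0

    def test_no_bursts_summary(self):
        s = met.abd_delay_duration([], 370.0)
        assert s.delay_s is None and s.duration_min == 0.0


class TestPeakResponseBin:
    def test_flat_series_returns_first_bin_zero_change(self):
        label, change = met.peak_response_bin(
            {"R1": 2.0, "R2": 2.0, "R3": 2.0}, 2.0
        )
        assert label == "R1" and change == 0.0

    def test_single_elevated_bin(self):
        label, change = met.peak_response_bin(
            {"R1": 1.0, "R2": 1.29, "R3": 1.0}, 1.0
        )
        assert label == "R2"
        assert change == pytest.approx(29.0)

    def test_monotone_series_peaks_last(self):
        series = {f"R{k}": 1.0 + 0.1 * k for k in range(1, 6)}
        assert met.peak_response_bin(series, 1.0)[0] == "R5"

    def test_zero_baseline_falls_back_to_absolute(self):
        label, change = met.peak_response_bin({"R1": 0.2, "R2": -0.5}, 0.0)
        assert label == "R2" and change == pytest.approx(-0.5)


class TestInjectionSiteDistance:
    def test_pythagorean_quadruple(self):
        assert met.injection_site_distance((0.3, 0.4, 1.2), (0, 0, 0)) == \
            pytest.approx(1.3)
        assert met.injection_site_distance((1, 2, 3), (1, 2, 3)) == 0.0

    def test_axis_permutation_symmetry(self):
        d1 = met.injection_site_distance((0.3, 0.4, 1.2), (0.1, 0.0, 0.2))
        d2 = met.injection_site_distance((1.2, 0.3, 0.4), (0.2, 0.1, 0.0))
        assert d1 == pytest.approx(d2)
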