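"""Onset detection, cycle alignment, mean-cycles, and phase segmentation."""

import numpy as np
import pytest

from respicycle import cycles as cyc
from respicycle import synth
from respicycle.pipeline import PipelineConfig, _smooth

FS = 1000.0


class TestOnsetDetection:
    def test_sine_onsets_at_period_multiples(self):
        T = 1.0
        t = np.arange(int(5 * T * FS)) / FS + 1e-4
        x = np.sin(2 * np.pi * t / T)
        onsets = cyc.detect_inspiratory_onsets(x, FS, eps=0.05, min_dur_s=0.3)
        # the t=0 onset has no preceding arming excursion; interior ones remain
        expected = np.array([1, 2, 3, 4]) * T * FS
        assert onsets.size == expected.size
        assert np.max(np.abs(onsets - expected)) <= 1

    def test_strictly_positive_trace_has_no_cycles(self):
        with pytest.raises(ValueError, match="no cycles detected"):
            cyc.detect_inspiratory_onsets(np.ones(5000) * 0.3, FS)

    def test_hysteresis_rejects_dither_but_keeps_excursion(self, rng):
        eps = 0.1
        x = eps / 2 * np.sign(np.sin(np.arange(4000) * 0.7))  # +-eps/2 dither
        x[1000:1200] = -3 * eps  # arming excursion
        x[1200:1400] = +3 * eps  # full upward excursion
        onsets = cyc.detect_inspiratory_onsets(x, FS, eps=eps, min_dur_s=0.1)
        assert onsets.size == 1
        assert 1195 <= onsets[0] <= 1205

    def test_min_duration_suppresses_fast_recrossings(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * t / 0.2)  # 0.2 s cycles, below min_dur 0.3 s
        onsets = cyc.detect_inspiratory_onsets(x, FS, eps=0.05, min_dur_s=0.3)
        assert np.all(np.diff(onsets) >= 0.3 * FS)

    def test_recall_on_noise_free_generator_output(self):
        """Every true inspiratory onset recovered, no false positives."""
        tpl = synth.BreathTemplate(timing_jitter_cv=0.0, amplitude_cv=0.0)
        noise = synth.NoiseModel(emg_floor_sd=0.0, airflow_noise_sd=0.0, seed=0)
        rec = synth.generate_baseline(tpl, noise, 60.0)
        true_onsets = np.array([int(round(b.t0 * rec.fs)) for b in rec.plan])
        onsets = cyc.detect_inspiratory_onsets(
            rec.airflow, rec.fs, eps=0.05 * rec.airflow.std(), min_dur_s=0.3
        )
        # the first true onset at t=0 cannot be armed; all others must match
        assert onsets.size == true_onsets.size - 1
        assert np.max(np.abs(onsets - true_onsets[1:])) <= 1


class TestBuildCycles:
    def test_k_onsets_give_k_minus_1_cycles(self, rng):
        x = rng.standard_normal(5000)
        onsets = np.array([0, 900, 2000, 3100, 4500])
        cs = cyc.build_cycles(x, x, x, onsets, FS, N=50)
        assert cs.n_cycles == 4

    def test_linear_ramp_resamples_exactly(self):
        x = np.arange(2000, dtype=float)  # ramp in sample index
        onsets = np.array([100, 600, 1500])
        cs = cyc.build_cycles(x, x, x, onsets, FS, N=40)
        for ci, (a, b) in enumerate(zip(onsets[:-1], onsets[1:])):
            L = b - a
            expected = a + np.arange(40) / 40 * L
            np.testing.assert_allclose(cs.cycles[ci, :, 0], expected, rtol=1e-12)

    def test_first_grid_point_is_onset_value(self, rng):
        x = rng.standard_normal(3000)
        onsets = np.array([10, 800, 2500])
        cs = cyc.build_cycles(x, x, x, onsets, FS, N=200)
        np.testing.assert_array_equal(cs.cycles[:, 0, 0], x[onsets[:-1]])

    def test_single_cycle_mean_is_the_cycle(self, rng):
        x = rng.standard_normal(1200)
        cs = cyc.build_cycles(x, x, x, np.array([0, 1000]), FS, N=64)
        mc = cyc.mean_cycle(cs)
        np.testing.assert_array_equal(mc.mu, cs.cycles[0])
        assert mc.sigma is None

    def test_short_spans_dropped(self, rng):
        x = rng.standard_normal(1000)
        cs = cyc.build_cycles(x, x, x, np.array([0, 2, 500, 900]), FS, N=20)
        assert cs.n_cycles == 2  # the 2-sample span is dropped


class TestMeanCycle:
    def test_identical_cycles_have_zero_covariance(self, rng):
        one = rng.standard_normal((30, 3))
        cs = cyc.CycleSet(
            onsets=np.arange(5) * 100,
            cycles=np.repeat(one[None], 5, axis=0),
            durations=np.ones(5),
        )
        mc = cyc.mean_cycle(cs)
        np.testing.assert_allclose(mc.mu, one, atol=1e-15)
        np.testing.assert_allclose(mc.sigma, np.zeros((30, 3, 3)), atol=1e-30)

    def test_two_cycle_hand_covariance(self):
        """Two cycles differing by +-d in ABD at one grid point: var = 2d^2."""
        d = 0.7
        base = np.zeros((10, 3))
        c1, c2 = base.copy(), base.copy()
        c1[4, 2] += d
        c2[4, 2] -= d
        cs = cyc.CycleSet(
            onsets=np.array([0, 100]),
            cycles=np.stack([c1, c2]),
            durations=np.ones(2),
        )
        mc = cyc.mean_cycle(cs)
        np.testing.assert_array_equal(mc.mu, base)
        assert mc.sigma[4, 2, 2] == pytest.approx(2 * d * d)
        assert mc.sigma[4, 0, 0] == 0.0 and mc.sigma[4, 0, 2] == 0.0

    def test_matches_bruteforce_loop(self, rng):
        """Vectorized mean/covariance equals an explicit per-point loop."""
        cycles = rng.standard_normal((20, 15, 3))
        cs = cyc.CycleSet(
            onsets=np.arange(20) * 50, cycles=cycles, durations=np.ones(20)
        )
        mc = cyc.mean_cycle(cs)
        for t in range(15):
            pts = cycles[:, t, :]
            np.testing.assert_allclose(mc.mu[t], pts.mean(axis=0), atol=1e-12)
            np.testing.assert_allclose(
                mc.sigma[t], np.cov(pts.T, ddof=1), atol=1e-12
            )

    def test_unit_noise_gives_unit_diagonal(self, rng):
        n = 400
        cycles = rng.standard_normal((n, 8, 3))
        cs = cyc.CycleSet(
            onsets=np.arange(n) * 10, cycles=cycles, durations=np.ones(n)
        )
        mc = cyc.mean_cycle(cs)
        diag = np.einsum("nii->ni", mc.sigma)
        assert np.all(np.abs(diag - 1.0) < 3 / np.sqrt(n))


def _bump_cycle(N=200, with_deflection=False):
    a = np.zeros(N)
    k = np.arange(N, dtype=float)
    insp = slice(0, int(0.4 * N))
    a[insp] = np.sin(np.pi * (k[insp] + 0.5) / (0.4 * N))
    postI = slice(int(0.4 * N), int(0.6 * N))
    a[postI] = -0.3 * np.sin(np.pi * (k[: int(0.2 * N)] + 0.5) / (0.2 * N))
    if with_deflection:
        tail = slice(int(0.9 * N), N)
        a[tail] = -0.8 * np.sin(np.pi * (k[: N - int(0.9 * N)] + 0.5) / (0.1 * N))
    return a


class TestSegmentPhases:
    def test_last_quarter_fallback_partition(self):
        """40% bump + 20% deflection + flat: late-E = last quarter of expiration."""
        a = _bump_cycle(200)
        seg = cyc.segment_phases(a)
        assert seg.insp == (0, 80)
        assert seg.postI == (80, 120)
        assert seg.lateE == (170, 200)  # last 15% of the cycle
        assert seg.rest == (120, 170)
        assert seg.mode == "last-quarter"

    def test_terminal_excursion_triggers_negative_deflection_mode(self):
        a = _bump_cycle(200, with_deflection=True)
        seg = cyc.segment_phases(a, deflection_thresh=0.5)
        assert seg.mode == "negative-deflection"
        assert seg.lateE == (180, 200)

    def test_insignificant_excursion_falls_back_to_last_quarter(self):
        a = _bump_cycle(200, with_deflection=True)
        seg = cyc.segment_phases(a, deflection_thresh=0.9)
        assert seg.mode == "last-quarter"

    def test_not_inspiratory_aligned_raises(self):
        with pytest.raises(ValueError, match="not an inspiratory-aligned"):
            cyc.segment_phases(-_bump_cycle(100))

    def test_merged_postI_lateE_split_at_max_between_troughs(self):
        N = 200
        a = np.zeros(N)
        k = np.arange(N, dtype=float)
        a[:60] = np.sin(np.pi * (k[:60] + 0.5) / 60)
        # two troughs with an intermediate maximum, never returning to zero
        u = (k[: N - 60]) / (N - 60)
        a[60:] = -0.2 - 0.6 * np.abs(np.sin(2 * np.pi * u))
        seg = cyc.segment_phases(a)
        assert seg.mode == "negative-deflection"
        assert seg.rest[1] == seg.rest[0]  # empty rest
        assert seg.postI[1] == seg.lateE[0]

    def test_partition_invariant_on_random_cycles(self, rng):
        """Phases always partition [0, N) and are scale invariant."""
        for _ in range(200):
            N = int(rng.integers(40, 300))
            a = _random_mean_cycle(rng, N)
            seg = cyc.segment_phases(a)
            counts = np.zeros(N, int)
            for ph in ("lateE", "insp", "postI", "rest"):
                lo, hi = seg.range(ph)
                counts[lo:hi] += 1
            assert np.all(counts == 1)
            seg2 = cyc.segment_phases(3.7 * a, deflection_thresh=3.7 * 0.5)
            assert seg2.range("lateE") == seg.range("lateE")
            assert seg2.mode == seg.mode


def _random_mean_cycle(rng, N):
    """Random plausible mean-cycle airflow: positive insp, negative post-I."""
    a = np.zeros(N)
    k = np.arange(N, dtype=float)
    insp_frac = rng.uniform(0.15, 0.45)
    pi_frac = rng.uniform(0.1, 0.3)
    ie = max(2, int(insp_frac * N))
    pe = min(N - 1, ie + max(2, int(pi_frac * N)))
    a[:ie] = rng.uniform(0.5, 2.0) * np.sin(np.pi * (k[:ie] + 0.5) / ie)
    a[ie:pe] = -rng.uniform(0.2, 1.0) * np.sin(
        np.pi * (k[: pe - ie] + 0.5) / (pe - ie)
    )
    if rng.random() < 0.5 and pe < N - 4:
        nle = max(2, int(rng.uniform(0.05, 0.2) * N))
        s = N - nle
        if s > pe:
            a[s:] = -rng.uniform(0.1, 1.5) * np.sin(
                np.pi * (k[:nle] + 0.5) / nle
            )
    return a
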