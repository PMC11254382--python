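"""End-to-end per-recording analysis.

Order of operations, mirroring the analysis the recordings are designed
for:

1. EMG envelopes by rectification + leaky integration (tau = 0.08 s).
2. A bootstrap airflow-only pass over the baseline bin finds the quiescent
   rest periods between breaths; each channel is then standardized to
   baseline SD units (zeroed on rest, divided by the SD of the
   time-collapsed baseline amplitude distribution).
3. Time bins: one 5-min baseline bin ending at the start of the first
   injection, then ten 2-min response bins clocked from the end of the
   second injection (trailing partial bins computed but flagged).
4. Per bin: inspiratory onsets (hysteresis zero-crossing detector on a
   lightly smoothed airflow copy), cycles time-normalized onto an N = 200
   grid, mean-cycle with per-timepoint covariance, phase segmentation on
   the mean airflow.
5. Per-bin metrics (RR, Ti, Te, V_T, V_E, V_O2, V_E/V_O2, late-E peak
   amplitude/area, per-phase AUC vs baseline) and 3D trajectory distances
   (mean Euclidean and Mahalanobis per phase vs the baseline mean-cycle).
6. Burst detection on the standardized envelopes for the ABD response
   delay, duration, and ABD:DIA coupling ratio.

Onset detection runs on a 25 ms moving-average copy of the standardized
airflow: at 1 kHz the raw sensor noise crosses a 0.05 SD hysteresis band
freely, while the smoothed copy keeps sub-0.01 SD noise and shifts onsets
by at most half the window. The airflow cycles are built from the same
smoothed trace so every cycle starts at a positive sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import metrics as met
from . import preprocess as pre
from . import trajectory as traj
from .synth import Recording

logger = logging.getLogger(__name__)

RELATIVE_METRICS = ("RR", "VT", "VE", "VO2", "VE_over_VO2", "lateE_amp",
                    "lateE_area")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the analysis, with the defaults the study design fixes."""

    tau: float = 0.08
    grid_n: int = 200
    eps_sd: float = 0.05
    min_cycle_s: float = 0.3
    smooth_s: float = 0.025
    deflection_thresh: float = 0.5
    deflection_min_frac: float = 0.02
    dia_burst_k: float = 2.0
    abd_burst_k: float = 10.0
    burst_merge_gap_s: float = 0.15
    coupling_window_min: float = 10.0
    baseline_gap_s: float = 10.0
    mahalanobis_squared: bool = False
    min_cycles_per_bin: int = 5


@dataclass
class BinAnalysis:
    bin: pre.TimeBin
    cycle_set: cyc.CycleSet | None
    mean: cyc.MeanCycle | None
    seg: cyc.PhaseSegmentation | None


@dataclass
class RecordingAnalysis:
    """All per-recording results: tidy tables plus the underlying objects."""

    metrics: pd.DataFrame
    distances: pd.DataFrame
    abd: met.AbdResponseSummary
    bins: list[BinAnalysis]
    standardization: dict[str, pre.StandardizationStats]
    dia_bursts: list[met.BurstEvent]
    abd_bursts: list[met.BurstEvent]

    @property
    def baseline(self) -> BinAnalysis:
        return self.bins[0]


def _smooth(x: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    w = max(1, int(round(smooth_s * fs)))
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def baseline_rest_mask(
    airflow_V: np.ndarray, fs: float, cfg: PipelineConfig
) -> np.ndarray:
    """Boolean mask of rest-period samples within the baseline bin.

    Airflow-only bootstrap: breaths are detected on the smoothed raw
    airflow with a hysteresis threshold scaled to that trace's SD; within
    each cycle the rest period runs from the end of the post-I deflection
    (plus a small guard) to the start of the last quarter of expiration,
    so neither deflections nor late-E territory leak into the mask.
    """
    x = _smooth(np.asarray(airflow_V, dtype=float), fs, cfg.smooth_s)
    eps = cfg.eps_sd * float(np.std(x))
    onsets = cyc.detect_inspiratory_onsets(x, fs, eps=eps,
                                           min_dur_s=cfg.min_cycle_s)
    mask = np.zeros(x.size, dtype=bool)
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = x[a:b]
        L = b - a
        insp_end = met.inspiratory_end_index(seg, fs, smooth_s=0.0)
        if insp_end >= L:
            continue
        back_pos = np.flatnonzero(seg[insp_end:] >= 0)
        if back_pos.size == 0:
            continue
        postI_end = insp_end + int(back_pos[0])
        lo = postI_end + max(1, int(0.05 * L))
        hi = b - a - max(1, int(0.25 * (L - insp_end)))
        if hi > lo:
            mask[a + lo : a + hi] = True
    return mask


def _feo2_for_bin(feo2, tbin: pre.TimeBin) -> float:
    """Scalar FeO2, or the per-segment [[t_start, value], ...] lookup."""
    if isinstance(feo2, (int, float)):
        return float(feo2)
    value = float(feo2[0][1])
    for t_start, v in feo2:
        if tbin.start_s >= t_start:
            value = float(v)
    return value


def analyze_recording(
    rec: Recording, cfg: PipelineConfig | None = None
) -> RecordingAnalysis:
    """Run the full cycle-by-cycle analysis of one recording."""
    cfg = cfg or PipelineConfig()
    fs = rec.fs
    env_params = pre.EnvelopeParams(tau=cfg.tau)
    dia_env = pre.rectify_integrate(rec.dia_raw, fs, env_params)
    abd_env = pre.rectify_integrate(rec.abd_raw, fs, env_params)

    baseline_start = rec.t_inj1_end - cfg.baseline_gap_s - pre.BASELINE_BIN_S
    if baseline_start < 0:
        raise ValueError("recording too short for a 5-min baseline bin")
    bins = pre.make_time_bins(rec.t_inj2_end, rec.duration_s, baseline_start)
    base_bin = bins[0]
    bsl = base_bin.slice_for(fs)

    rest_mask = baseline_rest_mask(rec.airflow[bsl], fs, cfg)
    stats = {
        "airflow": pre.fit_standardization(np.asarray(rec.airflow[bsl], float),
                                           rest_mask),
        "dia": pre.fit_standardization(dia_env[bsl], rest_mask),
        "abd": pre.fit_standardization(abd_env[bsl], rest_mask),
    }
    air_sd = pre.standardize(rec.airflow, stats["airflow"])
    dia_sd = pre.standardize(dia_env, stats["dia"])
    abd_sd = pre.standardize(abd_env, stats["abd"])
    air_smooth = _smooth(air_sd, fs, cfg.smooth_s)

    cal = met.fit_calibration(rec.calibration)

    analyses: list[BinAnalysis] = []
    rows: list[dict] = []
    for tbin in bins:
        sl = tbin.slice_for(fs)
        try:
            onsets = cyc.detect_inspiratory_onsets(
                air_smooth[sl], fs, eps=cfg.eps_sd, min_dur_s=cfg.min_cycle_s
            )
        except ValueError:
            logger.warning("bin %s: no cycles detected", tbin.label)
            analyses.append(BinAnalysis(tbin, None, None, None))
            continue
        if onsets.size < cfg.min_cycles_per_bin + 1:
            logger.warning("bin %s: only %d onsets", tbin.label, onsets.size)
            analyses.append(BinAnalysis(tbin, None, None, None))
            continue
        cs = cyc.build_cycles(
            air_smooth[sl], dia_sd[sl], abd_sd[sl], onsets, fs, N=cfg.grid_n
        )
        mc = cyc.mean_cycle(cs)
        seg = cyc.segment_phases(
            mc.mu[:, 0],
            deflection_thresh=cfg.deflection_thresh,
            deflection_min_frac=cfg.deflection_min_frac,
        )
        analyses.append(BinAnalysis(tbin, cs, mc, seg))

        rr, ti, te = met.rate_and_times(cs.durations, seg)
        raw_air = np.asarray(rec.airflow, dtype=float)
        start = sl.start
        vts = [
            met.tidal_volume(raw_air[start + a : start + b], fs, cal,
                             rec.body_mass_kg)
            for a, b in zip(onsets[:-1], onsets[1:])
            if b - a >= 4
        ]
        vt = float(np.mean(vts)) if vts else np.nan
        ve = vt * rr
        feo2 = _feo2_for_bin(rec.feo2, tbin)
        vo2 = met.oxygen_consumption(ve, rec.fio2, feo2)
        air_volts = (mc.mu[:, 0] * stats["airflow"].pooled_sd
                     + stats["airflow"].rest_mean)
        le_amp, le_area = met.late_e_peak(air_volts, seg, mc.mean_duration_s)
        rows.append(
            {
                "bin": tbin.label, "partial": tbin.partial,
                "n_cycles": cs.n_cycles, "RR": rr, "Ti": ti, "Te": te,
                "VT": vt, "VE": ve, "VO2": vo2,
                "VE_over_VO2": ve / vo2 if vo2 > 0 else np.nan,
                "lateE_amp": le_amp, "lateE_area": le_area,
                "seg_mode": seg.mode,
            }
        )

    base_ba = analyses[0]
    if base_ba.mean is None:
        raise ValueError("baseline bin yielded no cycles")

    # per-phase AUC differences vs baseline, per channel
    auc_cols: dict[str, list] = {}
    for row, ba in zip(rows, analyses):
        if ba.mean is None:
            continue
        for ci, chan in enumerate(cyc.CHANNELS):
            aucs = met.phase_auc(
                ba.mean.mu[:, ci], base_ba.mean.mu[:, ci], ba.seg, base_ba.seg
            )
            for phase, val in aucs.items():
                row[f"auc_{chan}_{phase}"] = val
    metrics_df = pd.DataFrame(rows)

    # relative (% of baseline) metrics; the baseline row is exactly 0%
    base_row = metrics_df[metrics_df["bin"] == "baseline"].iloc[0]
    for col in RELATIVE_METRICS:
        b = base_row[col]
        if b != 0:
            metrics_df[f"rel_{col}"] = (metrics_df[col] - b) / abs(b) * 100.0
        else:
            metrics_df[f"rel_{col}"] = metrics_df[col] - b
            logger.warning("baseline %s is 0; relative change is absolute", col)

    # trajectory distances vs the baseline mean-cycle
    dist_rows = []
    for ba in analyses[1:]:
        if ba.mean is None:
            continue
        dists = traj.phase_distances(
            ba.mean, base_ba.mean, ba.seg, base_ba.seg,
            squared=cfg.mahalanobis_squared,
        )
        for phase, d in dists.items():
            dist_rows.append(
                {
                    "bin": ba.bin.label, "partial": ba.bin.partial,
                    "phase": phase, "n_points": d.n_points,
                    "mean_euclidean": d.mean_euclidean,
                    "mean_mahalanobis": d.mean_mahalanobis,
                    "flagged": d.flagged,
                }
            )
    distances_df = pd.DataFrame(dist_rows)

    # burst trains: DIA over the whole recording, ABD after the baseline bin
    dia_bursts = met.detect_bursts(
        dia_sd, fs, k_sd=cfg.dia_burst_k, min_gap_s=cfg.burst_merge_gap_s,
        channel="DIA",
    )
    post_base = int(round(base_bin.end_s * fs))
    abd_bursts = met.detect_bursts(
        abd_sd[post_base:], fs, k_sd=cfg.abd_burst_k,
        min_gap_s=cfg.burst_merge_gap_s, channel="ABD",
        t0=base_bin.end_s,
    )
    abd = met.abd_delay_duration(abd_bursts, rec.t_inj2_end)
    if abd_bursts and dia_bursts:
        abd.coupling = met.abd_dia_coupling(
            abd_bursts, dia_bursts, rec.t_inj2_end,
            window_min=cfg.coupling_window_min,
        )
    elif dia_bursts:
        abd.coupling = 0.0

    return RecordingAnalysis(
        metrics=metrics_df,
        distances=distances_df,
        abd=abd,
        bins=analyses,
        standardization=stats,
        dia_bursts=dia_bursts,
        abd_bursts=abd_bursts,
    )
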