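"""Ventilation, metabolic, AUC, burst and abdominal-timing metrics.

Quantities per time bin:

* RR (breaths/min), Ti, Te from cycle durations and the inspiratory phase;
* V_T (ml/kg) by integrating inspiratory airflow and converting through a
  least-squares linear calibration of airflow integral to milliliters;
* V_E = V_T * RR (ml/min/kg);
* V_O2 by the open-circuit formula with only O2 measured,
  VO2 = VE * (FiO2 - FeO2) / (1 - FiO2);
* normalized per-phase AUC (response minus baseline, signed grid sums);
* late-E expiratory peak amplitude (V) and area (V*s);
* EMG burst events, the ABD:DIA coupling ratio over the first 10 min of the
  response, and the ABD response delay/duration relative to the end of the
  second injection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cycles import MeanCycle, PhaseSegmentation

logger = logging.getLogger(__name__)

BURST_K_SD_DEFAULT = 3.0
BURST_MERGE_GAP_S_DEFAULT = 0.15
COUPLING_WINDOW_MIN_DEFAULT = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear airflow-integral -> milliliters map fitted by least squares."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    residual: float

    def to_ml(self, integral: float | np.ndarray):
        return self.slope * integral + self.intercept


@dataclass(frozen=True)
class BurstEvent:
    """One supra-threshold EMG envelope burst."""

    channel: str
    t_start: float
    t_end: float
    peak: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")


@dataclass
class AbdResponseSummary:
    """Timing of the abdominal response relative to the second injection.

    delay_s is negative when the first ABD burst precedes the end of the
    second injection; delay_s is None when no burst occurred.
    """

    delay_s: float | None
    duration_min: float
    coupling: float | None = None


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (airflow integral, ml) points."""
    pts = [(float(x), float(v)) for x, v in points]
    if len(pts) < 2:
        raise ValueError("need >= 2 calibration points")
    x = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    if np.unique(x).size < len(pts):
        raise ValueError("duplicate calibration x values")
    A = np.stack([x, np.ones_like(x)], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, v, rcond=None)
    residual = float(np.sqrt(res[0] / len(pts))) if res.size else 0.0
    return CalibrationCurve(
        points=tuple(pts), slope=float(coef[0]), intercept=float(coef[1]),
        residual=residual,
    )


def inspiratory_end_index(cycle_airflow: np.ndarray, fs: float,
                          smooth_s: float = 0.005) -> int:
    """First downward zero crossing after the inspiratory peak.

    The crossing is searched on a lightly smoothed copy (moving average of
    ``smooth_s``) and only after the airflow maximum, so sensor noise around
    the onset cannot truncate the inspiratory phase.
    """
    x = np.asarray(cycle_airflow, dtype=float)
    w = max(1, int(round(smooth_s * fs)))
    if w > 1:
        kernel = np.ones(w) / w
        xs = np.convolve(x, kernel, mode="same")
    else:
        xs = x
    peak = int(np.argmax(xs))
    neg = np.flatnonzero(xs[peak:] < 0)
    if neg.size == 0:
        return x.size
    return peak + int(neg[0])


def tidal_volume(
    cycle_airflow: np.ndarray,
    fs: float,
    cal: CalibrationCurve,
    mass_kg: float,
    insp_end: int | None = None,
) -> float:
    """Tidal volume (ml/kg) of one cycle from the inspiratory airflow integral."""
    x = np.asarray(cycle_airflow, dtype=float)
    if insp_end is None:
        insp_end = inspiratory_end_index(x, fs)
    integral = float(np.sum(x[:insp_end])) / fs
    ml = float(cal.to_ml(integral))
    if ml < 0:
        logger.warning("negative fitted volume %.4g ml clipped to 0", ml)
        ml = 0.0
    return ml / mass_kg


def rate_and_times(
    durations: np.ndarray, seg: PhaseSegmentation
) -> tuple[float, float, float]:
    """RR (breaths/min), Ti and Te (s) from cycle durations and segmentation."""
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("no cycles")
    mean_dur = float(durations.mean())
    rr = 60.0 / mean_dur
    ti = seg.length("insp") / seg.N * mean_dur
    te = mean_dur - ti
    return rr, ti, te


def oxygen_consumption(ve: float, fio2: float, feo2: float) -> float:
    """Open-circuit VO2 (same units as VE) with only O2 fractions measured."""
    if not (0 < fio2 < 1) or not (0 < feo2 < 1):
        raise ValueError("gas fractions must lie in (0, 1)")
    if feo2 > fio2:
        raise ValueError("expired O2 exceeds inspired")
    return ve * (fio2 - feo2) / (1.0 - fio2)


def phase_auc(
    resp: np.ndarray,
    base: np.ndarray,
    seg_resp: PhaseSegmentation,
    seg_base: PhaseSegmentation,
) -> dict[str, float]:
    """Normalized per-phase AUC: signed grid sum of response minus baseline.

    AUC in each phase is the plain sum of the signal over that phase's grid
    points (all channels share the sampling grid), so sub-zero signal
    contributes negatively; the baseline phase AUC is subtracted from the
    response phase AUC.
    """
    resp = np.asarray(resp, dtype=float)
    base = np.asarray(base, dtype=float)
    out = {}
    for phase in ("lateE", "insp", "postI", "rest"):
        r_lo, r_hi = seg_resp.range(phase)
        b_lo, b_hi = seg_base.range(phase)
        out[phase] = float(resp[r_lo:r_hi].sum() - base[b_lo:b_hi].sum())
    return out


def late_e_peak(
    mean_airflow_volts: np.ndarray,
    seg: PhaseSegmentation,
    mean_duration_s: float,
) -> tuple[float, float]:
    """Expiratory (late-E) peak amplitude (V) and sub-zero area (V*s).

    Amplitude is the minimum airflow within the late-E phase in original
    volts; area integrates only the below-zero portion (0 when airflow never
    drops below zero in late-E).
    """
    a = np.asarray(mean_airflow_volts, dtype=float)
    lo, hi = seg.range("lateE")
    if hi <= lo:
        return 0.0, 0.0
    phase = a[lo:hi]
    dt = mean_duration_s / seg.N
    amplitude = float(phase.min())
    area = float(np.minimum(phase, 0.0).sum() * dt)
    return amplitude, area


def detect_bursts(
    env: np.ndarray,
    fs: float,
    k_sd: float = BURST_K_SD_DEFAULT,
    min_gap_s: float = BURST_MERGE_GAP_S_DEFAULT,
    channel: str = "EMG",
    t0: float = 0.0,
) -> list[BurstEvent]:
    """Maximal supra-threshold runs of a standardized envelope, gap-merged.

    Runs where env > k_sd separated by less than ``min_gap_s`` are merged
    into one event. ``t0`` offsets the reported times (seconds) when ``env``
    is a slice of a longer recording.
    """
    x = np.asarray(env, dtype=float)
    above = x > k_sd
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, x.size]
    min_gap = int(round(min_gap_s * fs))
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < min_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [
        BurstEvent(
            channel=channel,
            t_start=t0 + s / fs,
            t_end=t0 + e / fs,
            peak=float(x[s:e].max()),
        )
        for s, e in merged
    ]


def abd_dia_coupling(
    abd_bursts: list[BurstEvent],
    dia_bursts: list[BurstEvent],
    t_inj2_end: float,
    window_min: float = COUPLING_WINDOW_MIN_DEFAULT,
) -> float:
    """ABD:DIA burst count ratio over the first 10 min of the response.

    The window opens at the first ABD burst (the response onset) and closes
    at ``window_min`` minutes later or at the last ABD burst, whichever is
    earlier — trailing response-free time is excluded, mirroring the
    exclusion of fading end-of-response bins.

    The ratio compares breaths-with-expiratory-ABD-activity to inspiratory
    bursts: each inter-DIA interval (one breath) counts as coupled when any
    ABD burst overlaps it, so multiple ABD components of one breath (post-I
    plus late-E) count once, and a tonically sustained ABD event credits
    every breath it spans. The result lives in [0, 1].
    """
    if not dia_bursts:
        raise ValueError("no inspiratory bursts")
    if not abd_bursts:
        return 0.0
    onset = min(b.t_start for b in abd_bursts)
    last = max(b.t_start for b in abd_bursts)
    close = min(onset + window_min * 60.0, last)
    dia_all = np.sort([b.t_start for b in dia_bursts])
    # the breath containing the first ABD burst starts at the preceding DIA
    # burst; open the window there so that breath's DIA is counted too
    preceding = dia_all[dia_all <= onset]
    window_start = preceding[-1] if preceding.size else onset
    dia_t = dia_all[(dia_all >= window_start) & (dia_all <= close)]
    if dia_t.size == 0:
        raise ValueError("no inspiratory bursts")
    edges = np.r_[dia_t, close + 1e-9]
    coupled = np.zeros(dia_t.size, dtype=bool)
    for b in abd_bursts:
        if b.t_end < edges[0] or b.t_start > close or b.t_start < onset:
            continue
        # the breath in which the burst starts is coupled; further breaths
        # count only when the event covers most of their interval (a
        # sustained tonic event), so that the envelope's decay tail beyond
        # a burst cannot credit the following breath
        lo = max(0, int(np.searchsorted(edges, b.t_start, side="right")) - 1)
        coupled[lo] = True
        for i in range(lo + 1, dia_t.size):
            if edges[i] >= b.t_end:
                break
            overlap = min(b.t_end, edges[i + 1]) - edges[i]
            if overlap >= 0.5 * (edges[i + 1] - edges[i]):
                coupled[i] = True
    return float(coupled.sum()) / dia_t.size


def abd_delay_duration(
    abd_bursts: list[BurstEvent], t_inj2_end: float
) -> AbdResponseSummary:
    """ABD response delay and duration from the burst train.

    Delay = first ABD burst onset minus the end of the second injection
    (negative when the response begins earlier); duration = minutes between
    the first and last ABD burst. No bursts -> duration 0, delay absent.
    """
    if not abd_bursts:
        return AbdResponseSummary(delay_s=None, duration_min=0.0)
    t_first = min(b.t_start for b in abd_bursts)
    t_last = max(b.t_start for b in abd_bursts)
    return AbdResponseSummary(
        delay_s=t_first - t_inj2_end,
        duration_min=(t_last - t_first) / 60.0,
    )


def peak_response_bin(
    series: dict[str, float], baseline: float
) -> tuple[str, float]:
    """Bin with the strongest relative change from baseline.

    Returns (bin label, relative change in %). Relative change is
    (x - baseline)/baseline * 100; ties are broken by the earliest bin. A
    zero baseline falls back to absolute change (logged), with the change
    reported as the absolute difference.
    """
    if not series:
        raise ValueError("no response bins")
    labels = list(series)
    if baseline == 0:
        logger.warning("baseline is 0; using absolute change for peak bin")
        changes = {k: v - baseline for k, v in series.items()}
    else:
        changes = {k: (v - baseline) / baseline * 100.0 for k, v in series.items()}
    best = max(labels, key=lambda k: (abs(changes[k]), -labels.index(k)))
    # max() keeps the first maximal element only when later ones are not
    # strictly greater; the tuple key above makes earliest-bin ties explicit
    return best, changes[best]


def injection_site_distance(site, ref) -> float:
    """Euclidean distance (mm) between an injection site and the VIIc reference."""
    site = np.asarray(site, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not (np.isfinite(site).all() and np.isfinite(ref).all()):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(site - ref))
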