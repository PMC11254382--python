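"""Raw-channel conditioning: EMG envelopes, SD-unit standardization, time bins.

EMG envelopes follow the classic "rectify and integrate" scheme: the absolute
value of the raw signal is passed through a first-order leaky integrator with
a decay time constant of 0.08 s. The discretization is the exponential
smoother

    y[n] = a * y[n-1] + (1 - a) * |x[n]|,   a = exp(-1 / (fs * tau)),

which has unity DC gain, so a sustained burst of amplitude c converges to an
envelope of c * E|noise|-scale rather than an arbitrary multiple.

Standardization converts every channel into baseline SD units: the channel is
zeroed on the quiescent rest periods between breaths of the baseline bin, and
divided by the standard deviation of the time-collapsed amplitude
distribution over the whole baseline bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

logger = logging.getLogger(__name__)

BASELINE_BIN_S = 300.0
RESPONSE_BIN_S = 120.0
N_RESPONSE_BINS = 10


@dataclass(frozen=True)
class EnvelopeParams:
    """Leaky-integrator settings for EMG envelope extraction.

    tau is the decay time constant in seconds (default 0.08 s).
    """

    tau: float = 0.08

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class StandardizationStats:
    """Per-channel rest mean and pooled baseline SD (the standardization map)."""

    rest_mean: float
    pooled_sd: float


@dataclass(frozen=True)
class TimeBin:
    """Half-open analysis window [start_s, end_s).

    label is "baseline" or "R1".."R10"; partial marks a trailing response bin
    truncated by the end of the recording (computed but excluded from group
    statistics).
    """

    label: str
    start_s: float
    end_s: float
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def slice_for(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)), int(round(self.end_s * fs)))


def rectify_integrate(
    x: np.ndarray, fs: float, params: EnvelopeParams | None = None
) -> np.ndarray:
    """Rectify a raw EMG trace and integrate it with a leaky integrator.

    Implements y[n] = a*y[n-1] + (1-a)*|x[n]| with a = exp(-1/(fs*tau)) and
    y[0] = (1-a)*|x[0]| (zero initial state). Unity DC gain: a constant input
    c converges to c.
    """
    if params is None:
        params = EnvelopeParams()
    if not fs > 0:
        raise ValueError("fs must be > 0")
    x = np.asarray(x, dtype=float)
    bad = ~np.isfinite(x)
    if bad.any():
        raise ValueError(
            f"non-finite sample at index {int(np.flatnonzero(bad)[0])}"
        )
    a = np.exp(-1.0 / (fs * params.tau))
    return lfilter([1.0 - a], [1.0, -a], np.abs(x))


def fit_standardization(
    x: np.ndarray, baseline_rest_mask: np.ndarray, min_rest_samples: int = 100
) -> StandardizationStats:
    """Fit the rest mean and pooled baseline SD of one channel.

    ``x`` must be the baseline-bin samples of the channel and
    ``baseline_rest_mask`` a boolean trace of the same length marking the
    quiescent rest periods between breaths. The rest mean is taken over the
    masked samples only; the pooled SD is the SD of (x - rest_mean) over ALL
    baseline samples — the time-collapsed amplitude distribution.
    """
    x = np.asarray(x, dtype=float)
    mask = np.asarray(baseline_rest_mask, dtype=bool)
    if x.shape != mask.shape:
        raise ValueError("trace and mask lengths differ")
    n_rest = int(mask.sum())
    if n_rest == 0:
        raise ValueError("no rest samples")
    if n_rest < min_rest_samples:
        raise ValueError(
            f"only {n_rest} rest samples; need >= {min_rest_samples}"
        )
    rest_mean = float(x[mask].mean())
    pooled_sd = float(np.sqrt(np.mean((x - rest_mean) ** 2)))
    if pooled_sd == 0.0:
        raise ValueError("degenerate signal")
    return StandardizationStats(rest_mean=rest_mean, pooled_sd=pooled_sd)


def standardize(x: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """Map a trace into baseline SD units: (x - rest_mean) / pooled_sd."""
    if not stats.pooled_sd > 0:
        raise ValueError("degenerate signal")
    return (np.asarray(x, dtype=float) - stats.rest_mean) / stats.pooled_sd


def make_time_bins(
    t_inj2_end: float, recording_end: float, baseline_start: float
) -> list[TimeBin]:
    """Build the baseline bin and the ten 2-min response bins.

    The baseline bin is the 300 s window starting at ``baseline_start`` (the
    last 5 min preceding the first injection). The response clock starts at
    the END of the second injection; bins are contiguous half-open 120 s
    windows [t_inj2_end + 120*(k-1), t_inj2_end + 120*k) for k = 1..10.
    Bins truncated by ``recording_end`` are flagged partial; bins that would
    start at or past the end are dropped.
    """
    if baseline_start + BASELINE_BIN_S > t_inj2_end:
        raise ValueError("baseline bin must precede the injections")
    if recording_end < t_inj2_end + RESPONSE_BIN_S:
        raise ValueError("recording ends before the first response bin completes")
    bins = [TimeBin("baseline", baseline_start, baseline_start + BASELINE_BIN_S)]
    for k in range(1, N_RESPONSE_BINS + 1):
        start = t_inj2_end + RESPONSE_BIN_S * (k - 1)
        end = t_inj2_end + RESPONSE_BIN_S * k
        if start >= recording_end:
            break
        if end > recording_end:
            logger.warning("response bin R%d truncated at recording end", k)
            bins.append(TimeBin(f"R{k}", start, recording_end, partial=True))
            break
        bins.append(TimeBin(f"R{k}", start, end))
    return bins
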