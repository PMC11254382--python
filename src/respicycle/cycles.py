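"""Breath detection, aligned cycle matrices, mean-cycles, phase segmentation.

A breath starts at the inspiratory onset, the upward zero crossing where
airflow turns positive. Cycles of variable duration are aligned by linear
time-normalization onto a fixed N-point grid (default 200) from onset to the
next onset, which makes per-timepoint means and covariances — and hence the
Mahalanobis trajectory distance — well defined.

The mean-cycle airflow is segmented into four phases using its zero
crossings: inspiration = [onset, first downward crossing); post-I = the
negative deflection until airflow returns to zero; late-E = either the
terminal below-zero excursion preceding the next onset (when that deflection
is significant — the active-expiration signature) or, by fallback, the last
quarter of the expiratory period; rest = the remaining quiescent expiration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_GRID_N = 200
DEFAULT_EPS_SD = 0.05
DEFAULT_MIN_CYCLE_S = 0.3
DEFAULT_DEFLECTION_THRESH = 0.5
DEFAULT_DEFLECTION_MIN_FRAC = 0.02

CHANNELS = ("airflow", "dia", "abd")
PHASES = ("lateE", "insp", "postI", "rest")


@dataclass
class CycleSet:
    """Aligned per-cycle matrices for one time bin.

    cycles has shape (n_cycles, N, 3) with channels (airflow, ∫DIA, ∫ABD) in
    SD units; onsets are sample indices of inspiratory onsets; durations are
    seconds per cycle.
    """

    onsets: np.ndarray
    cycles: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def N(self) -> int:
        return self.cycles.shape[1]


@dataclass
class MeanCycle:
    """Per-timepoint mean breath with SD and 3x3 covariance.

    mu and sd have shape (N, 3); sigma has shape (N, 3, 3) and is the
    unbiased sample covariance across cycles at each grid point (None when
    only one cycle is available). mean_duration_s carries the average cycle
    length so grid indices can be mapped back to seconds.
    """

    mu: np.ndarray
    sd: np.ndarray
    sigma: np.ndarray | None
    n_cycles: int
    mean_duration_s: float

    @property
    def N(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class PhaseSegmentation:
    """Disjoint half-open index ranges partitioning the [0, N) mean-cycle grid.

    mode records how late-E was determined: "negative-deflection" when a
    significant terminal below-zero airflow excursion was found, otherwise
    "last-quarter".
    """

    lateE: tuple[int, int]
    insp: tuple[int, int]
    postI: tuple[int, int]
    rest: tuple[int, int]
    mode: str
    N: int

    def __post_init__(self) -> None:
        counts = np.zeros(self.N, dtype=int)
        for lo, hi in (self.lateE, self.insp, self.postI, self.rest):
            counts[lo:hi] += 1
        if not np.all(counts == 1):
            raise ValueError("phase ranges must partition [0, N)")

    def range(self, phase: str) -> tuple[int, int]:
        return getattr(self, phase)

    def indices(self, phase: str) -> np.ndarray:
        lo, hi = self.range(phase)
        return np.arange(lo, hi)

    def length(self, phase: str) -> int:
        lo, hi = self.range(phase)
        return hi - lo


def detect_inspiratory_onsets(
    airflow: np.ndarray,
    fs: float,
    eps: float = DEFAULT_EPS_SD,
    min_dur_s: float = DEFAULT_MIN_CYCLE_S,
) -> np.ndarray:
    """Detect inspiratory onsets as armed upward zero crossings of airflow.

    A hysteresis pair rejects noise chatter around zero: a crossing only
    counts once the trace has been below -eps (arming) and subsequently
    rises above +eps; the onset is placed at the upward zero crossing
    between the two events. Onsets closer than ``min_dur_s`` to the previous
    accepted onset are discarded.
    """
    x = np.asarray(airflow, dtype=float)
    below = x < -eps
    above_idx = np.flatnonzero((x[1:] >= eps) & (x[:-1] < eps)) + 1
    if above_idx.size == 0 or not below.any():
        raise ValueError("no cycles detected")

    # cumulative count of below-(-eps) samples: armed iff some below sample
    # lies strictly between the previous onset's +eps event and this one
    below_cum = np.cumsum(below)
    min_sep = int(round(min_dur_s * fs))
    nonpos_idx = np.flatnonzero(x <= 0.0)

    onsets: list[int] = []
    last_event = -1
    last_onset = None
    for c in above_idx:
        armed = below_cum[c] - (below_cum[last_event] if last_event >= 0 else 0) > 0
        if not armed:
            continue
        # upward zero crossing: first sample > 0 after the last <= 0 sample
        j = np.searchsorted(nonpos_idx, c) - 1
        onset = int(nonpos_idx[j]) + 1 if j >= 0 else 0
        if last_onset is not None and onset - last_onset < min_sep:
            continue
        onsets.append(onset)
        last_onset = onset
        last_event = c
    if not onsets:
        raise ValueError("no cycles detected")
    return np.asarray(onsets, dtype=int)


def build_cycles(
    airflow: np.ndarray,
    dia_env: np.ndarray,
    abd_env: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    N: int = DEFAULT_GRID_N,
) -> CycleSet:
    """Resample each inter-onset span onto an N-point grid per channel.

    Grid position k (k = 0..N-1) maps to sample offset k*L/N within a span
    of L samples, so the first grid point is exactly the value at the onset
    and the grid stops just short of the next onset. Channels are linearly
    interpolated (exact for ramps). Spans shorter than 4 samples are dropped
    with a warning.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        raise ValueError("need at least 2 onsets")
    chans = [np.asarray(c, dtype=float) for c in (airflow, dia_env, abd_env)]
    kept_onsets: list[int] = []
    rows: list[np.ndarray] = []
    durations: list[float] = []
    grid_frac = np.arange(N) / N
    for a, b in zip(onsets[:-1], onsets[1:]):
        L = b - a
        if L < 4:
            logger.warning("cycle at sample %d only %d samples long; dropped", a, L)
            continue
        pos = grid_frac * L
        knots = np.arange(L + 1, dtype=float)
        cyc = np.stack(
            [np.interp(pos, knots, ch[a : b + 1]) for ch in chans], axis=1
        )
        rows.append(cyc)
        kept_onsets.append(int(a))
        durations.append(L / fs)
    if not rows:
        raise ValueError("no usable cycles")
    return CycleSet(
        onsets=np.asarray(kept_onsets, dtype=int),
        cycles=np.stack(rows, axis=0),
        durations=np.asarray(durations, dtype=float),
    )


def mean_cycle(cs: CycleSet) -> MeanCycle:
    """Per-grid-point mean, SD, and unbiased 3x3 covariance across cycles."""
    c = cs.cycles
    n = cs.n_cycles
    mu = c.mean(axis=0)
    if n >= 2:
        dev = c - mu  # (n, N, 3)
        sigma = np.einsum("cni,cnj->nij", dev, dev) / (n - 1)
        sd = np.sqrt(np.einsum("nii->ni", sigma))
    else:
        sigma = None
        sd = np.zeros_like(mu)
    return MeanCycle(
        mu=mu,
        sd=sd,
        sigma=sigma,
        n_cycles=n,
        mean_duration_s=float(cs.durations.mean()),
    )


def _first_index(cond: np.ndarray, start: int) -> int | None:
    idx = np.flatnonzero(cond[start:])
    return int(idx[0]) + start if idx.size else None


def segment_phases(
    mean_airflow: np.ndarray,
    deflection_thresh: float = DEFAULT_DEFLECTION_THRESH,
    deflection_min_frac: float = DEFAULT_DEFLECTION_MIN_FRAC,
) -> PhaseSegmentation:
    """Partition an inspiratory-aligned mean-cycle into the four phases.

    Rules, applied to the zero crossings of the mean airflow:

    * inspiration = [0, first downward zero crossing);
    * post-I = from the end of inspiration until airflow first returns to
      >= 0;
    * late-E = the terminal below-zero excursion preceding the next onset if
      it is significant (below ``-deflection_thresh`` for at least
      ``deflection_min_frac * N`` grid points), else the last quarter of the
      expiratory period;
    * rest = the remaining expiration between post-I and late-E.

    When post-I and the terminal excursion merge into one unbroken
    below-zero stretch, the boundary is placed at the sample closest to zero
    between the two troughs (logged).
    """
    a = np.asarray(mean_airflow, dtype=float)
    N = a.size
    if not a[0] > 0:
        raise ValueError("not an inspiratory-aligned cycle")

    insp_end = _first_index(a < 0, 1)
    if insp_end is None:
        raise ValueError("airflow never crosses below zero; cannot segment")
    postI_end = _first_index(a >= 0, insp_end)
    exp_len = N - insp_end
    mode = "last-quarter"

    if postI_end is None:
        # merged post-I / late-E: one unbroken below-zero excursion to N
        seg = a[insp_end:]
        half = max(1, exp_len // 2)
        t1 = insp_end + int(np.argmin(seg[:half]))
        t2 = insp_end + half + int(np.argmin(seg[half:]))
        if t2 > t1 + 1:
            boundary = t1 + int(np.argmax(a[t1 : t2 + 1]))
        else:
            boundary = N - max(1, exp_len // 4)
        boundary = max(insp_end + 1, min(boundary, N - 1))
        logger.warning(
            "post-I and late-E merged below zero; boundary at grid %d", boundary
        )
        return PhaseSegmentation(
            lateE=(boundary, N),
            insp=(0, insp_end),
            postI=(insp_end, boundary),
            rest=(boundary, boundary),
            mode="negative-deflection",
            N=N,
        )

    # terminal below-zero excursion: samples [j+1, N) all < 0 with j = last >= 0
    nonneg = np.flatnonzero(a >= 0)
    j = int(nonneg[-1])
    lateE_start = None
    if j + 1 < N and j + 1 >= postI_end:
        excursion = a[j + 1 :]
        min_pts = max(1, int(np.ceil(deflection_min_frac * N)))
        if int((excursion < -deflection_thresh).sum()) >= min_pts:
            lateE_start = j + 1
            mode = "negative-deflection"
    if lateE_start is None:
        lateE_start = N - max(1, exp_len // 4)
        mode = "last-quarter"
    lateE_start = max(lateE_start, postI_end)

    return PhaseSegmentation(
        lateE=(lateE_start, N),
        insp=(0, insp_end),
        postI=(insp_end, postI_end),
        rest=(postI_end, lateE_start),
        mode=mode,
        N=N,
    )
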