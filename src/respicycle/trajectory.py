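"""3D respiratory-loop distances between response and baseline mean-cycles.

Each mean-cycle timepoint is a point in the 3D space (airflow, ∫DIA, ∫ABD),
all in baseline SD units, so a breath traces a closed loop. Response loops
deform relative to baseline: a late-E "tail", an inspiratory "bulb", a
post-I "foot". Two per-phase distances quantify the deformation:

* Euclidean: d_t = sqrt(air_diff² + dia_diff² + abd_diff²), averaged over
  the phase's timepoints;
* Mahalanobis: d_t = sqrt((R_t - μ_t) Σ_t⁻¹ (R_t - μ_t)ᵀ) with Σ_t the
  covariance of the baseline cycles at timepoint t, i.e. the deformation
  measured in units of baseline cycle-to-cycle variability.

The response phase is linearly resampled to the baseline phase's point
count before comparison so both loops contribute the same number of
comparison points. The square-root (distance-unit) Mahalanobis form is the
default; the squared form is available via ``squared=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cycles import MeanCycle, PhaseSegmentation

logger = logging.getLogger(__name__)

REPORTED_PHASES = ("lateE", "insp", "postI")
FEATURE_NAMES = {"lateE": "lateE_tail", "insp": "insp_bulb", "postI": "postI_foot"}

RIDGE_SCALE = 1e-8
MAX_SKIP_FRAC = 0.2


@dataclass
class DistanceResult:
    """Mean per-phase trajectory distance between response and baseline."""

    phase: str
    mean_euclidean: float | None
    mean_mahalanobis: float | None
    n_points: int
    n_skipped: int = 0
    flagged: bool = False


def resample_phase(segment: np.ndarray, n_target: int) -> np.ndarray:
    """Linearly resample an (M, 3) phase segment to n_target points.

    Positions are uniform over [0, M-1], so the first and last rows are
    preserved exactly and a per-channel linear ramp stays exactly linear.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim == 1:
        seg = seg[:, None]
    M = seg.shape[0]
    if M < 2:
        raise ValueError("need >= 2 points to resample")
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    if M == n_target:
        return seg.copy()
    pos = np.linspace(0.0, M - 1.0, n_target)
    knots = np.arange(M, dtype=float)
    return np.stack([np.interp(pos, knots, seg[:, j]) for j in range(seg.shape[1])],
                    axis=1)


def _phase_points(mc: MeanCycle, seg: PhaseSegmentation, phase: str) -> np.ndarray:
    lo, hi = seg.range(phase)
    return mc.mu[lo:hi]


def _match_points(r: np.ndarray, n: int) -> np.ndarray:
    """Resample response phase points to the baseline phase's count."""
    if r.shape[0] == n:
        return r
    if r.shape[0] == 1:
        return np.repeat(r, n, axis=0)
    if n == 1:
        return r[:1]
    return resample_phase(r, n)


def euclidean_phase_distance(
    resp: MeanCycle,
    base: MeanCycle,
    seg_resp: PhaseSegmentation,
    seg_base: PhaseSegmentation,
    phase: str,
) -> DistanceResult:
    """Mean Euclidean distance between the two loops within one phase."""
    b = _phase_points(base, seg_base, phase)
    r = _phase_points(resp, seg_resp, phase)
    if b.shape[0] == 0 or r.shape[0] == 0:
        return DistanceResult(phase, None, None, n_points=0)
    r = _match_points(r, b.shape[0])
    diff = r - b
    d_t = np.sqrt((diff**2).sum(axis=1))
    return DistanceResult(phase, float(d_t.mean()), None, n_points=b.shape[0])


def mahalanobis_phase_distance(
    resp: MeanCycle,
    base: MeanCycle,
    seg_resp: PhaseSegmentation,
    seg_base: PhaseSegmentation,
    phase: str,
    squared: bool = False,
) -> DistanceResult:
    """Mean Mahalanobis distance within one phase.

    The baseline per-timepoint covariance Σ_t is inverted by symmetric
    positive-definite solve; on failure a ridge λI with
    λ = 1e-8 * trace(Σ_t)/3 is added once, and still-singular points are
    skipped and counted (result flagged when more than 20% are skipped).
    """
    if base.sigma is None:
        raise ValueError("baseline covariance unavailable (need >= 2 cycles)")
    lo, hi = seg_base.range(phase)
    b = base.mu[lo:hi]
    sig = base.sigma[lo:hi]
    r = _phase_points(resp, seg_resp, phase)
    if b.shape[0] == 0 or r.shape[0] == 0:
        return DistanceResult(phase, None, None, n_points=0)
    r = _match_points(r, b.shape[0])
    diff = r - b
    vals: list[float] = []
    skipped = 0
    for t in range(b.shape[0]):
        d2 = _mahalanobis_sq(diff[t], sig[t])
        if d2 is None:
            skipped += 1
        else:
            vals.append(d2 if squared else np.sqrt(d2))
    if not vals:
        return DistanceResult(phase, None, None, n_points=0,
                              n_skipped=skipped, flagged=True)
    flagged = skipped > MAX_SKIP_FRAC * b.shape[0]
    if flagged:
        logger.warning("%s: %d/%d covariance points singular", phase, skipped,
                       b.shape[0])
    return DistanceResult(
        phase,
        mean_euclidean=None,
        mean_mahalanobis=float(np.mean(vals)),
        n_points=len(vals),
        n_skipped=skipped,
        flagged=flagged,
    )


def _mahalanobis_sq(diff: np.ndarray, sigma: np.ndarray) -> float | None:
    for mat in (sigma, sigma + RIDGE_SCALE * (np.trace(sigma) / 3.0) * np.eye(3)):
        try:
            L = np.linalg.cholesky(mat)
        except np.linalg.LinAlgError:
            continue
        y = np.linalg.solve(L, diff)
        return float(y @ y)
    return None


def phase_distances(
    resp: MeanCycle,
    base: MeanCycle,
    seg_resp: PhaseSegmentation,
    seg_base: PhaseSegmentation,
    squared: bool = False,
) -> dict[str, DistanceResult]:
    """Both distances for the three reported phases (late-E, insp, post-I)."""
    out: dict[str, DistanceResult] = {}
    for phase in REPORTED_PHASES:
        eu = euclidean_phase_distance(resp, base, seg_resp, seg_base, phase)
        if base.sigma is not None and eu.n_points > 0:
            ma = mahalanobis_phase_distance(
                resp, base, seg_resp, seg_base, phase, squared=squared
            )
            eu.mean_mahalanobis = ma.mean_mahalanobis
            eu.n_skipped = ma.n_skipped
            eu.flagged = ma.flagged
        out[phase] = eu
    return out


def loop_features(distances: dict[str, DistanceResult],
                  which: str = "euclidean") -> dict[str, float | None]:
    """Map per-phase distances to the named loop deformations.

    Returns {"lateE_tail", "insp_bulb", "postI_foot"} from either the
    Euclidean ("euclidean") or Mahalanobis ("mahalanobis") means.
    """
    attr = "mean_euclidean" if which == "euclidean" else "mean_mahalanobis"
    return {
        FEATURE_NAMES[phase]: getattr(distances[phase], attr)
        for phase in REPORTED_PHASES
        if phase in distances
    }
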