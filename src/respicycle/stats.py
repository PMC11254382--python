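"""Group-level nonparametric comparisons across injection locations.

Per-bin comparisons across location groups use the Kruskal-Wallis H test
(ranks pooled over all groups, tie-corrected, chi-square approximation with
k-1 degrees of freedom) followed by Dunn's post hoc z-tests on mean ranks
with Sidak adjustment, p_adj = 1 - (1 - p)^m over the m tested pairs.
Effect size is eta squared, ss_effect / ss_total.

Kruskal-Wallis and Dunn are implemented here directly (the statistic layer
is the point of this module); scipy supplies only ranking and the reference
distributions. Parametric screens and alternatives (Shapiro-Wilk for the
normality gate, one-way ANOVA) are delegated to scipy pass-through.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSample:
    """Per-group metric values (one value per animal or replicate)."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p: float
    p_adj: float


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    effect: float | None = None


def _pooled_ranks(groups: list[GroupSample]):
    values = np.concatenate([g.values for g in groups])
    ranks = sps.rankdata(values)
    out = []
    i = 0
    for g in groups:
        out.append(ranks[i : i + g.values.size])
        i += g.values.size
    return values, ranks, out


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: list[GroupSample]) -> TestResult:
    """Kruskal-Wallis H on pooled ranks with tie correction.

    H = 12/(N(N+1)) * sum(n_i * Rbar_i^2) - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); df = k - 1; p from the
    chi-square approximation. All-identical data gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if g.values.size < 2:
            raise ValueError(f"group {g.group} has < 2 values")
    values, _, group_ranks = _pooled_ranks(groups)
    N = values.size
    df = len(groups) - 1
    tie = _tie_term(values)
    correction = 1.0 - tie / (N**3 - N)
    if correction == 0.0:  # every observation identical
        return TestResult(statistic=0.0, df=df, p=1.0)
    h = 12.0 / (N * (N + 1)) * sum(
        r.size * r.mean() ** 2 for r in group_ranks
    ) - 3.0 * (N + 1)
    h /= correction
    h = max(h, 0.0)
    return TestResult(statistic=float(h), df=df, p=float(sps.chi2.sf(h, df)))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment: p_adj = 1 - (1 - p)^m, clipped to 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def dunn_posthoc_sidak(
    groups: list[GroupSample],
    pairs: list[tuple[str, str]] | None = None,
) -> list[PairwiseResult]:
    """Dunn's z-tests on mean ranks, Sidak-adjusted over the tested pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12(N-1)); two-sided normal p-values.
    """
    values, _, group_ranks = _pooled_ranks(groups)
    N = values.size
    labels = [g.group for g in groups]
    mean_rank = {lab: r.mean() for lab, r in zip(labels, group_ranks)}
    n = {lab: r.size for lab, r in zip(labels, group_ranks)}
    if pairs is None:
        pairs = list(combinations(labels, 2))
    if not pairs:
        return []
    tie_T = _tie_term(values) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_T
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        out.append(PairwiseResult(pair=(a, b), z=float(z), p=p,
                                  p_adj=sidak_adjust(p, m)))
    return out


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """Effect size eta squared = ss_effect / ss_total."""
    if not ss_total > 0:
        raise ValueError("ss_total must be > 0")
    if ss_effect < 0 or ss_effect > ss_total:
        raise ValueError("ss_effect must lie in [0, ss_total]")
    return ss_effect / ss_total


def compare_groups(
    groups: list[GroupSample], alpha: float = 0.05
) -> TestResult:
    """Kruskal-Wallis followed by Dunn/Sidak when the omnibus is significant."""
    res = kruskal_wallis(groups)
    if res.p < alpha:
        res.pairwise = dunn_posthoc_sidak(groups)
    return res


def normality_rejected(groups: list[GroupSample], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk screen (delegated to scipy) on each group's values.

    Returns True when any group rejects normality at ``alpha`` (the cue to
    use the rank-based path). Groups with fewer than 3 values cannot be
    screened and count as rejecting.
    """
    for g in groups:
        if g.values.size < 3:
            return True
        if np.ptp(g.values) == 0:
            return True
        if sps.shapiro(g.values).pvalue < alpha:
            return True
    return False


def build_report(
    metrics: pd.DataFrame,
    distances: pd.DataFrame,
    tests: dict[str, TestResult] | None = None,
) -> tuple[dict, str]:
    """Assemble a machine-readable summary plus a human-readable text digest.

    ``metrics`` is the tidy per-(recording, bin) metric table; ``distances``
    the per-(recording, bin, phase) distance table; ``tests`` optional
    per-metric omnibus results. Regeneration from the same inputs is
    byte-identical (keys sorted, floats serialized by repr).
    """
    for name, df, needed in (
        ("metrics", metrics, {"group", "bin"}),
        ("distances", distances, {"group", "bin", "phase"}),
    ):
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing field {sorted(missing)[0]}")

    summary: dict = {"groups": {}, "tests": {}, "flags": []}
    value_cols = [
        c for c in metrics.columns
        if c not in ("group", "bin", "recording", "seed", "partial")
        and pd.api.types.is_numeric_dtype(metrics[c])
    ]
    complete = metrics[~metrics.get("partial", False).astype(bool)] \
        if "partial" in metrics.columns else metrics
    response = complete[complete["bin"] != "baseline"]
    if response.empty:
        summary["flags"].append("no response bins")
    for (group, bin_label), sub in sorted(complete.groupby(["group", "bin"])):
        entry = summary["groups"].setdefault(str(group), {})
        entry[str(bin_label)] = {
            c: {
                "median": float(sub[c].median()),
                "iqr": float(sub[c].quantile(0.75) - sub[c].quantile(0.25)),
                "n": int(sub[c].notna().sum()),
            }
            for c in value_cols
        }
    if tests:
        for name, res in sorted(tests.items()):
            summary["tests"][name] = {
                "H": res.statistic,
                "df": res.df,
                "p": res.p,
                "eta_sq": res.effect,
                "pairwise": [
                    {"pair": list(pr.pair), "z": pr.z, "p": pr.p,
                     "p_adj": pr.p_adj}
                    for pr in res.pairwise
                ],
            }

    lines = ["respicycle group report", "======================="]
    for flag in summary["flags"]:
        lines.append(f"note: {flag}")
    for group in sorted(summary["groups"]):
        lines.append(f"group {group}: {len(summary['groups'][group])} bins")
    for name in sorted(summary["tests"]):
        t = summary["tests"][name]
        lines.append(
            f"{name}: H({t['df']}) = {t['H']:.3f}, p = {t['p']:.4f}"
        )
        for pr in t["pairwise"]:
            if pr["p_adj"] < 0.05:
                lines.append(
                    f"  {pr['pair'][0]} vs {pr['pair'][1]}: "
                    f"z = {pr['z']:.2f}, p_adj = {pr['p_adj']:.4f}"
                )
    text = "\n".join(lines) + "\n"
    # canonical serialization keeps regeneration byte-identical
    summary = json.loads(json.dumps(summary, sort_keys=True))
    return summary, text
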