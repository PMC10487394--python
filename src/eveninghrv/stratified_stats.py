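"""Time-stratified statistics over the observation table.

The analysis design: bin each observation's KSS and SSS score into
low / medium / high sleepiness (medium excluded from group comparisons),
then for each HRV metric

* pooled low-vs-high independent t-test across all time points,
* per-time-point low-vs-high Mann-Whitney U test (exact null for small
  tie-free samples, tie-corrected normal approximation otherwise),
* per-time-point Pearson correlation of the metric with the raw score
  (all observations, no sleepiness exclusion).

p-values are two-sided and reported raw; a Benjamini-Hochberg option exists
but is off by default. Significance tiers: significant p < 0.05, trend
0.05 <= p < 0.10, else ns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .hrv_metrics import ALL_METRICS, METRIC_DOMAIN

__all__ = [
    "BinningRule",
    "KSS_RULE",
    "SSS_RULE",
    "ComparisonResult",
    "CorrelationResult",
    "bin_scores",
    "compare_pooled",
    "compare_by_timepoint",
    "correlate_by_timepoint",
    "build_report",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class BinningRule:
    """Score thresholds for one sleepiness scale: <= low_max is 'low',
    >= high_min is 'high', anything between is 'medium' (excluded)."""

    scale: str
    low_max: int
    high_min: int
    score_min: int
    score_max: int

    def __post_init__(self) -> None:
        if self.low_max >= self.high_min:
            raise ValueError("low_max must be < high_min")

    def label(self, score: int) -> str:
        if not (self.score_min <= score <= self.score_max):
            raise ValueError(f"{self.scale} score {score} out of range")
        if score <= self.low_max:
            return "low"
        if score >= self.high_min:
            return "high"
        return "medium"


KSS_RULE = BinningRule("KSS", low_max=4, high_min=7, score_min=1, score_max=9)
SSS_RULE = BinningRule("SSS", low_max=2, high_min=4, score_min=1, score_max=7)
_RULES = {"KSS": KSS_RULE, "SSS": SSS_RULE}


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    scale: str
    time_point: Optional[str]  # None => pooled over the evening
    n_low: int
    n_high: int
    mean_low: float
    mean_high: float
    statistic: float  # t (pooled) or U (per time point)
    p: float
    tier: str


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    scale: str
    time_point: str
    r: float
    p: float
    n: int


def _tier(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "trend"
    return "ns"


def bin_scores(obs: pd.DataFrame, rules: Optional[dict] = None,
               *, warn=None) -> pd.DataFrame:
    """Attach kss_label / sss_label columns; out-of-range rows are dropped.

    Every in-range score maps to exactly one of low/medium/high.
    """
    rules = rules or _RULES
    out = obs.copy()
    ok = np.ones(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        try:
            rules["KSS"].label(int(row["kss"]))
            rules["SSS"].label(int(row["sss"]))
        except ValueError as e:
            ok[i] = False
            if warn:
                warn(str(e))
    out = out.loc[ok].copy()
    out["kss_label"] = [rules["KSS"].label(int(v)) for v in out["kss"]]
    out["sss_label"] = [rules["SSS"].label(int(v)) for v in out["sss"]]
    return out


def _groups(obs: pd.DataFrame, metric: str, scale: str,
            time_point: Optional[str]) -> tuple[np.ndarray, np.ndarray]:
    col = "kss_label" if scale.upper() == "KSS" else "sss_label"
    df = obs if time_point is None else obs[obs["time_point"] == time_point]
    lo = df.loc[df[col] == "low", metric].dropna().to_numpy(dtype=float)
    hi = df.loc[df[col] == "high", metric].dropna().to_numpy(dtype=float)
    return lo, hi


def compare_pooled(obs: pd.DataFrame, metric: str, scale: str,
                   *, equal_var: bool = True) -> Optional[ComparisonResult]:
    """Low-vs-high independent two-sample t-test pooled across time points.

    Classic pooled-variance form by default (equal_var=False gives Welch).
    Returns None when a group has < 2 usable values; degenerate variance in
    both groups yields a NaN p.
    """
    lo, hi = _groups(obs, metric, scale, None)
    if len(lo) < 2 or len(hi) < 2:
        return None
    if np.var(lo) == 0 and np.var(hi) == 0:
        # no within-group variance: identical groups are a clean null,
        # anything else has no defined t
        t, p = (0.0, 1.0) if np.mean(lo) == np.mean(hi) else (math.nan, math.nan)
    else:
        t, p = stats.ttest_ind(lo, hi, equal_var=equal_var)
        t, p = float(t), float(p)
    return ComparisonResult(metric, scale.upper(), None, len(lo), len(hi),
                            float(np.mean(lo)), float(np.mean(hi)), t, p, _tier(p))


def mann_whitney(lo: np.ndarray, hi: np.ndarray,
                 exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U_min, p).

    Exact null distribution when the combined sample is <= exact_max_n and
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction. U is reported min-oriented (min of the two
    one-sided U statistics), matching common small-sample reporting.
    """
    n1, n2 = len(lo), len(hi)
    ties = len(np.unique(np.concatenate([lo, hi]))) < n1 + n2
    method = "exact" if (n1 + n2 <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(lo, hi, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return u, float(res.pvalue)


def compare_by_timepoint(obs: pd.DataFrame, metric: str, scale: str,
                         time_point: str) -> Optional[ComparisonResult]:
    """Low-vs-high Mann-Whitney U at one time point; None if a group is empty."""
    lo, hi = _groups(obs, metric, scale, time_point)
    if len(lo) < 1 or len(hi) < 1:
        return None
    u, p = mann_whitney(lo, hi)
    return ComparisonResult(metric, scale.upper(), time_point, len(lo), len(hi),
                            float(np.mean(lo)), float(np.mean(hi)), u, p, _tier(p))


def correlate_by_timepoint(obs: pd.DataFrame, metric: str, scale: str,
                           time_point: str) -> Optional[CorrelationResult]:
    """Pearson r of metric vs raw score at one time point (all observations).

    Two-sided p from the t transform; None for n < 3 or zero variance.
    """
    col = "kss" if scale.upper() == "KSS" else "sss"
    df = obs[obs["time_point"] == time_point][[metric, col]].dropna()
    x = df[metric].to_numpy(dtype=float)
    y = df[col].to_numpy(dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(metric, scale.upper(), time_point,
                             float(r), float(p), len(x))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default report uses raw p)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def _sort_key(metric: str) -> tuple:
    domain_order = {"time": 0, "frequency": 1, "non-linear": 2}
    return (domain_order[METRIC_DOMAIN[metric]], metric)


def build_report(obs: pd.DataFrame, *, metrics=ALL_METRICS,
                 scales=("KSS", "SSS"), only_notable: bool = False,
                 adjust: bool = False) -> dict[str, pd.DataFrame]:
    """Assemble the full analysis tables from a labelled observation table.

    Returns a dict of tidy DataFrames: pooled_kss, pooled_sss,
    timepoint_kss, timepoint_sss, correlations. Rows are ordered
    deterministically by (domain, metric name, time point). With
    only_notable=True only significant/trend rows (p < 0.10) are kept,
    mirroring compact study-style reporting.
    """
    metrics = sorted(metrics, key=_sort_key)
    time_points = sorted(obs["time_point"].unique()) if len(obs) else []
    tables: dict[str, pd.DataFrame] = {}

    for scale in scales:
        rows = []
        for m in metrics:
            r = compare_pooled(obs, m, scale) if len(obs) else None
            if r is not None:
                rows.append({"domain": METRIC_DOMAIN[m], "metric": m,
                             "n_low": r.n_low, "n_high": r.n_high,
                             "mean_low": r.mean_low, "mean_high": r.mean_high,
                             "t": r.statistic, "p": r.p, "tier": r.tier})
        tables[f"pooled_{scale.lower()}"] = pd.DataFrame(
            rows, columns=["domain", "metric", "n_low", "n_high",
                           "mean_low", "mean_high", "t", "p", "tier"])

        rows = []
        for tp in time_points:
            for m in metrics:
                r = compare_by_timepoint(obs, m, scale, tp)
                if r is not None:
                    rows.append({"time_point": tp, "domain": METRIC_DOMAIN[m],
                                 "metric": m, "n_low": r.n_low, "n_high": r.n_high,
                                 "mean_low": r.mean_low, "mean_high": r.mean_high,
                                 "U": r.statistic, "p": r.p, "tier": r.tier})
        tables[f"timepoint_{scale.lower()}"] = pd.DataFrame(
            rows, columns=["time_point", "domain", "metric", "n_low", "n_high",
                           "mean_low", "mean_high", "U", "p", "tier"])

    rows = []
    for tp in time_points:
        for m in metrics:
            for scale in scales:
                r = correlate_by_timepoint(obs, m, scale, tp)
                if r is not None:
                    rows.append({"time_point": tp, "domain": METRIC_DOMAIN[m],
                                 "metric": m, "scale": scale.upper(),
                                 "r": r.r, "p": r.p, "n": r.n,
                                 "tier": _tier(r.p)})
    tables["correlations"] = pd.DataFrame(
        rows, columns=["time_point", "domain", "metric", "scale",
                       "r", "p", "n", "tier"])

    if adjust:
        for name, df in tables.items():
            if len(df):
                df["p_adj"] = benjamini_hochberg(df["p"].to_numpy())
    if only_notable:
        for name, df in tables.items():
            tables[name] = df[df["tier"] != "ns"].reset_index(drop=True) if len(df) else df
    return tables
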