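"""Inter-variant agreement statistics.

Measurements of the same lesions by different software variants are compared
with (i) Pearson correlation, labelled with the conventional strength bands
(|r| in 0.7–1 very strong, 0.5–0.7 strong, 0.3–0.5 moderate, 0–0.3 low;
boundaries assigned upward), (ii) paired difference tests gated on
Shapiro–Wilk normality of the paired differences (paired t-test if normal,
Wilcoxon signed-rank otherwise), and (iii) per-variant mean ± SD summaries.
No multiple-testing correction is applied by default; Holm adjustment is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .delineation import LesionMetrics
from .errors import DegenerateTestError, InvalidArgumentError

__all__ = [
    "CORRELATION_BANDS",
    "ComparisonReport",
    "pearson_r",
    "classify_correlation",
    "shapiro_wilk",
    "paired_compare",
    "summarize",
    "build_comparison_report",
]

#: (lower bound on |r|, band label), boundaries inclusive upward.
CORRELATION_BANDS: tuple[tuple[float, str], ...] = (
    (0.7, "very strong"),
    (0.5, "strong"),
    (0.3, "moderate"),
    (0.0, "low"),
)

#: metric-table columns compared across variants; LBM columns are skipped for
#: variants whose conventions do not provide LBM normalization.
_PARAMETER_COLUMNS = (
    "suv_max_bw", "suv_max_raw", "suv_max_lbm",
    "suv_mean_bw", "suv_mean_raw", "suv_mean_lbm",
    "tlg_bw", "tlg_raw", "tlg_lbm",
    "mtv_cm3",
)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise InvalidArgumentError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


def classify_correlation(r: float) -> str:
    """Strength band of a correlation coefficient, judged on |r|."""
    if abs(r) > 1:
        raise InvalidArgumentError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    for lower, label in CORRELATION_BANDS:
        if a >= lower:
            return label
    return "low"  # pragma: no cover — the 0.0 bound always matches


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value for normality."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InvalidArgumentError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("Shapiro–Wilk undefined for a constant sample")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def paired_compare(a: Sequence[float], b: Sequence[float],
                   normality_alpha: float = 0.05) -> tuple[str, float]:
    """Paired difference test with normality-gated test choice.

    Shapiro–Wilk is run on the paired differences: if its p-value is at
    least ``normality_alpha`` a paired t-test is used, otherwise the
    Wilcoxon signed-rank test.  Returns ``(test name, p-value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("paired vectors must have equal length")
    if a.size < 3:
        raise InvalidArgumentError("need at least 3 pairs")
    diff = a - b
    if np.all(diff == 0):
        raise DegenerateTestError("all paired differences are zero")
    if np.ptp(diff) == 0:
        # constant nonzero shift: normality is vacuous, the t-test is exact
        return "paired t-test", float(sps.ttest_rel(a, b).pvalue)
    _, p_norm = shapiro_wilk(diff)
    if p_norm >= normality_alpha:
        return "paired t-test", float(sps.ttest_rel(a, b).pvalue)
    return "wilcoxon signed-rank", float(sps.wilcoxon(a, b).pvalue)


def summarize(values: Sequence[float], population_sd: bool = False) -> tuple[float, float]:
    """Arithmetic mean and SD (sample, n−1 denominator, by default)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidArgumentError("need at least 2 observations")
    return float(values.mean()), float(values.std(ddof=0 if population_sd else 1))


@dataclass
class ComparisonReport:
    """Agreement report across measurement variants.

    ``correlations``: one row per (parameter, variant pair) with r and its
    strength band.  ``summaries``: per-variant mean ± SD per parameter.
    ``difference_tests``: pairwise paired-test p-values with the test used
    and a significance flag.
    """

    correlations: pd.DataFrame
    summaries: pd.DataFrame
    difference_tests: pd.DataFrame
    alpha: float = 0.05

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"correlations": self.correlations, "summaries": self.summaries,
                "difference_tests": self.difference_tests}


def metrics_to_frame(metrics: Sequence[LesionMetrics]) -> pd.DataFrame:
    """Tabulate per-lesion metrics, one row per lesion."""
    return pd.DataFrame([m.as_dict() for m in metrics], columns=_PARAMETER_COLUMNS)


def build_comparison_report(per_variant_metrics: Mapping[str, Sequence[LesionMetrics]],
                            alpha: float = 0.05,
                            holm: bool = False,
                            population_sd: bool = False) -> ComparisonReport:
    """Assemble the full agreement report from per-variant lesion metrics.

    All variants must have measured the same lesions in the same order.
    Parameters a variant does not provide (LBM columns) are skipped for
    pairs involving that variant, and its summary cells are left absent.
    Values may be given as :class:`LesionMetrics` sequences or as already
    tabulated DataFrames with the same columns.
    """
    names = list(per_variant_metrics)
    if len(names) < 2:
        raise InvalidArgumentError("need at least two variants to compare")
    frames = {
        name: (ms.reindex(columns=_PARAMETER_COLUMNS) if isinstance(ms, pd.DataFrame)
               else metrics_to_frame(ms))
        for name, ms in per_variant_metrics.items()
    }
    n_rows = {name: len(f) for name, f in frames.items()}
    if len(set(n_rows.values())) != 1:
        raise InvalidArgumentError(f"variant cohorts differ in size: {n_rows}")

    corr_rows, test_rows, summary_rows = [], [], []
    for param in _PARAMETER_COLUMNS:
        for name in names:
            col = frames[name][param]
            if col.isna().all():
                continue
            mean, sd = summarize(col.to_numpy(), population_sd=population_sd)
            summary_rows.append({"parameter": param, "variant": name,
                                 "mean": mean, "sd": sd})
        for na, nb in combinations(names, 2):
            xa, xb = frames[na][param], frames[nb][param]
            if xa.isna().all() or xb.isna().all():
                continue
            r = pearson_r(xa.to_numpy(), xb.to_numpy())
            corr_rows.append({"parameter": param, "pair": f"{na} vs {nb}",
                              "r": r, "band": classify_correlation(r)})
            try:
                test, p = paired_compare(xa.to_numpy(), xb.to_numpy())
            except DegenerateTestError:
                test, p = "degenerate (identical)", float("nan")
            test_rows.append({"parameter": param, "pair": f"{na} vs {nb}",
                              "test": test, "p_value": p})

    tests = pd.DataFrame(test_rows)
    if holm and len(tests):
        p = tests["p_value"].to_numpy(copy=True)
        valid = np.flatnonzero(~np.isnan(p))
        order = valid[np.argsort(p[valid])]
        m = len(valid)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            p[i] = min(1.0, running)
        tests["p_value"] = p
    tests["significant"] = tests["p_value"] < alpha

    return ComparisonReport(correlations=pd.DataFrame(corr_rows),
                            summaries=pd.DataFrame(summary_rows),
                            difference_tests=tests, alpha=alpha)
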