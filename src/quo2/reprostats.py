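"""Test-retest reproducibility statistics.

For each metric x ROI cell with paired measurements (Test A, Test B) across
subjects: the standard deviation of differences (dSD), within-subject SD
(wsSD = dSD/sqrt(2) for two measurements), within-subject CV, coefficient
of repeatability (CR = 1.96 dSD, the half-width of the 95% limits of
agreement), and between-subject CV on the pooled values.  A decision tree
checks the preconditions of the analysis — normality of the differences
(Shapiro-Wilk) and independence of |difference| from the mean (Kendall's
tau) — and moves to the log10 scale when either fails, falling back to the
original scale (with annotation) when the log data still deviate from
normality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05
SIGNIFICANCE_BINS = ((0.0005, "<0.0005"), (0.005, "<0.005"), (0.05, "<0.05"))


@dataclass
class PairedSample:
    """Paired test-retest values of one metric in one ROI."""

    subjects: Sequence[str]
    test_a: np.ndarray
    test_b: np.ndarray

    def __post_init__(self) -> None:
        self.test_a = np.asarray(self.test_a, dtype=float)
        self.test_b = np.asarray(self.test_b, dtype=float)
        if len(self.subjects) != self.test_a.size or self.test_a.size != self.test_b.size:
            raise ValueError("subjects, test_a and test_b must have equal length")
        if self.test_a.size < 3:
            raise ValueError("need at least 3 paired observations")
        if not (np.all(np.isfinite(self.test_a)) and np.all(np.isfinite(self.test_b))):
            raise ValueError("non-finite values in paired sample")

    @property
    def diffs(self) -> np.ndarray:
        return self.test_b - self.test_a

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.test_a + self.test_b)

    def log10(self) -> "PairedSample":
        if np.any(self.test_a <= 0) or np.any(self.test_b <= 0):
            raise ValueError("log transform requires positive values")
        return PairedSample(self.subjects, np.log10(self.test_a), np.log10(self.test_b))


@dataclass(frozen=True)
class ReproMetrics:
    """Reproducibility summary of one metric x ROI cell."""

    dsd: float
    wssd: float
    wscv_pct: float
    cr: float
    bscv_pct: float
    scale: str  # original | log10 | log10_failed
    p_shapiro: float
    p_kendall: float
    p_paired_t: float


def difference_stats(sample: PairedSample) -> Tuple[float, float]:
    """(dSD, wsSD): SD of the paired differences and dSD/sqrt(2)."""
    dsd = float(np.std(sample.diffs, ddof=1))
    return dsd, dsd / np.sqrt(2.0)


def ws_cv(sample: PairedSample, scale: str = "original") -> float:
    """Within-subject coefficient of variation, percent.

    Original scale: sqrt of the mean over subjects of (wsSD_i / mean_i)^2
    with wsSD_i = |B_i - A_i|/sqrt(2) and mean_i the subject mean.  Log10
    scale: 100 * (10^wsSD_log - 1) with wsSD_log from the log10 data.
    """
    if scale in ("original", "log10_failed"):
        means = sample.means
        if np.any(means == 0):
            raise ValueError("zero subject mean")
        ws_i = np.abs(sample.diffs) / np.sqrt(2.0)
        return 100.0 * float(np.sqrt(np.mean((ws_i / means) ** 2)))
    if scale == "log10":
        _, wssd_log = difference_stats(sample.log10())
        return 100.0 * (10.0**wssd_log - 1.0)
    raise ValueError(f"unknown scale {scale!r}")


def repeatability_coefficient(dsd: float) -> float:
    """CR = 1.96 * dSD: 95% of repeated differences fall within mean +/- CR."""
    if dsd < 0:
        raise ValueError("dSD must be non-negative")
    return 1.96 * dsd


def bs_cv(pooled: np.ndarray) -> float:
    """Between-subject CV: 100 * SD / mean of the pooled A and B values."""
    pooled = np.asarray(pooled, dtype=float)
    mean = pooled.mean()
    if mean == 0:
        raise ValueError("zero pooled mean")
    return 100.0 * float(np.std(pooled, ddof=1) / mean)


def transform_decision(
    sample: PairedSample, alpha: float = ALPHA_DEFAULT
) -> Tuple[str, float, float]:
    """Choose the analysis scale; returns (scale flag, p_shapiro, p_kendall).

    The differences must look normal (Shapiro-Wilk) and their magnitude
    must not grow with the mean (Kendall's tau between |diff| and mean).
    Either failure triggers a retry on log10 data; if the log data pass,
    the cell is analysed on the log scale; if they still deviate from
    normality the original scale is kept with the ``log10_failed`` flag.
    """
    p_sw = float(stats.shapiro(sample.diffs).pvalue)
    p_kt = float(stats.kendalltau(np.abs(sample.diffs), sample.means).pvalue)
    if p_sw > alpha and p_kt > alpha:
        return "original", p_sw, p_kt
    logged = sample.log10()  # raises on non-positive values
    p_sw_log = float(stats.shapiro(logged.diffs).pvalue)
    p_kt_log = float(stats.kendalltau(np.abs(logged.diffs), logged.means).pvalue)
    if p_sw_log > alpha and p_kt_log > alpha:
        return "log10", p_sw_log, p_kt_log
    return "log10_failed", p_sw_log, p_kt_log


def paired_t(sample: PairedSample) -> float:
    """Two-tailed paired t-test p-value (order effect between tests)."""
    if np.std(sample.diffs, ddof=1) == 0:
        raise ValueError("zero-variance differences")
    return float(stats.ttest_rel(sample.test_b, sample.test_a).pvalue)


def bland_altman(
    sample: PairedSample, cr: Optional[float] = None
) -> Tuple[float, Tuple[float, float], float]:
    """Mean difference, limits of agreement (mean +/- CR), fraction within."""
    if cr is None:
        cr = repeatability_coefficient(difference_stats(sample)[0])
    md = float(np.mean(sample.diffs))
    limits = (md - cr, md + cr)
    within = float(np.mean((sample.diffs >= limits[0]) & (sample.diffs <= limits[1])))
    return md, limits, within


def compute_repro_metrics(sample: PairedSample, alpha: float = ALPHA_DEFAULT) -> ReproMetrics:
    """Full reproducibility cell: scale decision, then all metrics.

    Degenerate zero-variance differences (a session copied verbatim) yield
    zero dSD/wsSD/wsCV/CR with undefined test p-values rather than an error.
    """
    if float(np.std(sample.diffs, ddof=1)) == 0.0:
        return ReproMetrics(
            dsd=0.0, wssd=0.0, wscv_pct=0.0, cr=0.0,
            bscv_pct=bs_cv(np.concatenate([sample.test_a, sample.test_b])),
            scale="original", p_shapiro=np.nan, p_kendall=np.nan, p_paired_t=np.nan,
        )
    try:
        scale, p_sw, p_kt = transform_decision(sample, alpha)
    except ValueError:
        # non-positive values: the log branch is unavailable, stay original
        scale = "original"
        p_sw = float(stats.shapiro(sample.diffs).pvalue)
        p_kt = float(stats.kendalltau(np.abs(sample.diffs), sample.means).pvalue)
    work = sample.log10() if scale == "log10" else sample
    dsd, wssd = difference_stats(work)
    return ReproMetrics(
        dsd=dsd,
        wssd=wssd,
        wscv_pct=ws_cv(sample, scale),
        cr=repeatability_coefficient(dsd),
        bscv_pct=bs_cv(np.concatenate([sample.test_a, sample.test_b])),
        scale=scale,
        p_shapiro=p_sw,
        p_kendall=p_kt,
        p_paired_t=paired_t(sample),
    )


def compare_rois(
    values_by_roi: Dict[str, np.ndarray],
    alpha: float = ALPHA_DEFAULT,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise ROI comparisons with multiplicity correction.

    Welch two-sample t-tests on the pooled values of each ROI pair;
    corrected p-values are binned into {ns, <0.05, <0.005, <0.0005}.
    """
    rois = list(values_by_roi)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    pairs = list(itertools.combinations(rois, 2))
    raw = []
    for a, b in pairs:
        va = np.asarray(values_by_roi[a], dtype=float)
        vb = np.asarray(values_by_roi[b], dtype=float)
        if va.size < 2 or vb.size < 2:
            raise ValueError(f"insufficient data in ROI pair ({a}, {b})")
        raw.append(float(stats.ttest_ind(va, vb, equal_var=False).pvalue))
    raw = np.asarray(raw)
    if method == "bonferroni":
        adj = np.minimum(raw * len(pairs), 1.0)
    elif method == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, raw[i] * (len(pairs) - rank))
            adj[i] = min(running, 1.0)
    else:
        raise ValueError("method must be 'bonferroni' or 'holm'")

    def binof(p: float) -> str:
        if p >= alpha:
            return "ns"
        for cut, label in SIGNIFICANCE_BINS:
            if p < cut:
                return label
        return "<0.05"

    return pd.DataFrame(
        {
            "roi_a": [a for a, _ in pairs],
            "roi_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": adj,
            "category": [binof(p) for p in adj],
        }
    )


def repro_table(
    long_df: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Reproducibility metrics for every metric x ROI cell of a long table.

    Expects columns (subject, test, roi, metric, value) with test in
    {"A", "B"}; subjects must be matched across tests within each cell.
    """
    required = {"subject", "test", "roi", "metric", "value"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (metric, roi), cell in long_df.groupby(["metric", "roi"], sort=True):
        wide = cell.pivot_table(index="subject", columns="test", values="value")
        if not {"A", "B"}.issubset(wide.columns):
            raise ValueError(f"cell {metric}/{roi} lacks one of tests A/B")
        wide = wide.dropna(subset=["A", "B"])
        sample = PairedSample(list(wide.index), wide["A"].to_numpy(), wide["B"].to_numpy())
        r = compute_repro_metrics(sample, alpha)
        rows.append(
            {
                "metric": metric,
                "roi": roi,
                "n": len(wide),
                "scale": r.scale,
                "dsd": r.dsd,
                "wssd": r.wssd,
                "wscv_pct": r.wscv_pct,
                "cr": r.cr,
                "bscv_pct": r.bscv_pct,
                "p_shapiro": r.p_shapiro,
                "p_kendall": r.p_kendall,
                "p_paired_t": r.p_paired_t,
            }
        )
    return pd.DataFrame(rows)
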