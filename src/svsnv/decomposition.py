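"""Windowed SV/SNV counting and the SNV-load decomposition regression.

SVs and SNVs are counted in non-overlapping windows tiling each chromosome
(window sizes of 15, 30 and 60 Mb by default elsewhere in the pipeline).
Ordinary least squares of SNV count on SV count across windows decomposes
the SNV load into an SV-dependent component (the slope, in SNVs per SV) and
an SV-independent component (the intercept, converted to SNVs per Mb by
dividing by the window size).  Two fitted conditions are compared via ratio
estimates with delta-method confidence intervals, and per-chromosome SV
accumulation rates are correlated between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import GenomeDef
from .variant_io import SnvRecord, SvBreakend

DEFAULT_WINDOW_SIZES_BP = (15_000_000, 30_000_000, 60_000_000)


@dataclass
class WindowCountTable:
    """Per-window SV and SNV counts for one sample/condition."""

    window_bp: int
    table: pd.DataFrame  # chrom, start, end, length, partial, sv_count, snv_count
    sample: str = "sample"
    condition: str = "condition"


@dataclass
class DecompositionResult:
    """OLS decomposition of window SNV counts into SV-dependent/-independent parts."""

    window_bp: int
    slope: float                 # SNVs per SV
    slope_se: float
    intercept: float             # SNVs per window
    intercept_se: float
    r_squared: float
    n_windows: int
    condition: str = "condition"
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)

    @property
    def intercept_rate(self) -> float:
        """SV-independent SNVs per Mb: intercept / (w / 1e6)."""
        return self.intercept / (self.window_bp / 1e6)

    @property
    def intercept_rate_se(self) -> float:
        return self.intercept_se / (self.window_bp / 1e6)


@dataclass
class RatioEstimate:
    ratio: float | None
    ci_low: float | None
    ci_high: float | None


@dataclass
class ConditionComparison:
    """Between-condition summary: component ratios and chromosome-level SV stats."""

    slope_ratio: RatioEstimate | None = None
    intercept_rate_ratio: RatioEstimate | None = None
    student_t: tuple[float, float] | None = None   # (statistic, p) on residuals
    welch_t: tuple[float, float] | None = None
    chromosome_rates: pd.DataFrame | None = None   # per-chrom SVs per Mb per condition
    pearson_r: float | None = None
    pearson_p: float | None = None
    normalized_sv_totals: dict[str, float] | None = None


def count_in_windows(snvs: Iterable[SnvRecord], breakends: Iterable[SvBreakend],
                     genome: GenomeDef, w: int,
                     sample: str = "sample",
                     condition: str = "condition") -> WindowCountTable:
    """Count SNVs and SV breakends in windows of ``w`` bp tiling each chromosome.

    Windows start at position 1; the final partial window of each chromosome
    is kept and flagged with its true length.  Every record lands in exactly
    one window.
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    rows = []
    index: dict[str, int] = {}
    for chrom in genome.names:
        L = genome.lengths[chrom]
        n_win = -(-L // w)  # ceil
        for i in range(n_win):
            start = i * w + 1
            end = min((i + 1) * w, L)
            if chrom not in index:
                index[chrom] = len(rows)
            rows.append([chrom, start, end, end - start + 1, end - start + 1 < w, 0, 0])
    for snv in snvs:
        genome.validate_position(snv.chrom, snv.pos)
        rows[index[snv.chrom] + (snv.pos - 1) // w][6] += 1
    for b in breakends:
        genome.validate_position(b.chrom, b.pos)
        rows[index[b.chrom] + (b.pos - 1) // w][5] += 1
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                        "partial", "sv_count", "snv_count"])
    return WindowCountTable(w, table, sample=sample, condition=condition)


def fit_decomposition(table: WindowCountTable,
                      drop_partial: bool = True,
                      poisson: bool = False) -> DecompositionResult:
    """Regress window SNV counts on SV counts.

    OLS by default (a Poisson GLM with identity link is available via
    ``poisson=True``).  Partial end-of-chromosome windows are dropped by
    default; with ``drop_partial=False`` their counts are rescaled to
    full-window equivalents (length weighting).
    """
    df = table.table
    if drop_partial:
        df = df[~df["partial"]]
    x = df["sv_count"].to_numpy(dtype=float)
    y = df["snv_count"].to_numpy(dtype=float)
    if not drop_partial:
        scale = table.window_bp / df["length"].to_numpy(dtype=float)
        x, y = x * scale, y * scale
    if len(x) < 3:
        raise ValueError("need at least 3 usable windows")
    if np.all(x == x[0]):
        raise ValueError("degenerate design: all window SV counts identical")
    X = sm.add_constant(x)
    if poisson:
        model = sm.GLM(y, X, family=sm.families.Poisson(sm.families.links.Identity()))
        fit = model.fit()
        r2 = 1.0 - np.sum((y - fit.fittedvalues) ** 2) / np.sum((y - y.mean()) ** 2)
    else:
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
    return DecompositionResult(
        window_bp=table.window_bp,
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        r_squared=r2, n_windows=len(x),
        condition=table.condition,
        residuals=np.asarray(y - fit.fittedvalues),
    )


def _ratio_with_ci(num: float, num_se: float, den: float, den_se: float,
                   z: float = 1.959963984540054) -> RatioEstimate:
    """Delta-method CI for a ratio of two independent estimates."""
    if den <= 0:
        return RatioEstimate(None, None, None)
    if num <= 0:
        return RatioEstimate(num / den, None, None)  # degenerate numerator: flagged via missing CI
    r = num / den
    se = r * np.sqrt((num_se / num) ** 2 + (den_se / den) ** 2)
    return RatioEstimate(r, r - z * se, r + z * se)


def compare_conditions(res_a: DecompositionResult,
                       res_b: DecompositionResult) -> ConditionComparison:
    """Ratios (B/A) of slope and intercept rate with delta-method CIs.

    Also reports two-sample Student and Welch t-tests on the window-level
    regression residuals of the two fits.
    """
    if res_a.window_bp != res_b.window_bp:
        raise ValueError("window sizes differ between conditions")
    slope_ratio = _ratio_with_ci(res_b.slope, res_b.slope_se,
                                 res_a.slope, res_a.slope_se)
    intercept_ratio = _ratio_with_ci(res_b.intercept_rate, res_b.intercept_rate_se,
                                     res_a.intercept_rate, res_a.intercept_rate_se)
    student = welch = None
    if len(res_a.residuals) >= 2 and len(res_b.residuals) >= 2:
        s = stats.ttest_ind(res_b.residuals, res_a.residuals, equal_var=True)
        w = stats.ttest_ind(res_b.residuals, res_a.residuals, equal_var=False)
        student = (float(s.statistic), float(s.pvalue))
        welch = (float(w.statistic), float(w.pvalue))
    return ConditionComparison(slope_ratio=slope_ratio,
                               intercept_rate_ratio=intercept_ratio,
                               student_t=student, welch_t=welch)


def chromosome_sv_stats(breakends_a: Sequence[SvBreakend],
                        breakends_b: Sequence[SvBreakend],
                        genome: GenomeDef) -> ConditionComparison:
    """Per-chromosome SV accumulation rates and their between-condition correlation.

    Rates are breakend counts per Mb of chromosome.  When the genome carries
    per-chromosome copy numbers, SV totals divided by copy number are also
    reported (chromosome-number normalization).
    """
    if len(genome.names) < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    rows = []
    for chrom in genome.names:
        mb = genome.lengths[chrom] / 1e6
        ca = sum(1 for b in breakends_a if b.chrom == chrom)
        cb = sum(1 for b in breakends_b if b.chrom == chrom)
        rows.append([chrom, ca, cb, ca / mb, cb / mb])
    df = pd.DataFrame(rows, columns=["chrom", "count_a", "count_b",
                                     "rate_a_per_mb", "rate_b_per_mb"])
    if df["rate_a_per_mb"].nunique() > 1 and df["rate_b_per_mb"].nunique() > 1:
        r, p = stats.pearsonr(df["rate_a_per_mb"], df["rate_b_per_mb"])
    else:
        r, p = (1.0, 0.0) if (df["rate_a_per_mb"] == df["rate_b_per_mb"]).all() else (np.nan, np.nan)
    normalized = None
    if genome.copy_numbers is not None:
        total_cn = sum(genome.copy_numbers[c] for c in genome.names)
        normalized = {"a": len(breakends_a) / total_cn,
                      "b": len(breakends_b) / total_cn}
    return ConditionComparison(chromosome_rates=df, pearson_r=float(r),
                               pearson_p=float(p),
                               normalized_sv_totals=normalized)
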