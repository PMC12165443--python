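"""Device-agreement and ISO 81060-2 validation statistics.

Everything a cuffless blood-pressure validation study reports on paired
(predicted, reference) readings: MAPE, paired-difference summaries,
Bland-Altman bias and limits of agreement, the two ISO 81060-2 acceptance
criteria, Shapiro-Wilk normality and Wilcoxon signed-rank tests, ESH blood
pressure grading, and cohort composition against the ISO sampling minimums.

ISO 81060-2 criterion 1 operates on per-measurement device-minus-reference
errors (|mean| <= 5 mm Hg, SD <= 8 mm Hg). Criterion 2 operates on
per-subject averaged errors: the permissible SD depends on the observed
mean error m so that, under normality, at least 85% of per-subject errors
fall within +/-10 mm Hg — i.e. the largest s with
Phi((10 - m)/s) - Phi((-10 - m)/s) >= 0.85.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedReadings",
    "AgreementReport",
    "ISOConstants",
    "ISOValidationReport",
    "BPCategory",
    "mape",
    "paired_difference_summary",
    "bland_altman",
    "agreement_report",
    "iso_criterion1",
    "per_subject_errors",
    "iso_criterion2_threshold",
    "iso_criterion2",
    "iso_validation_report",
    "criterion1_verdict",
    "criterion2_verdict",
    "normality_test",
    "wilcoxon_signed_rank",
    "classify_bp",
    "cohort_composition",
]

Z95 = 1.96  # normal 95% multiplier, fixed by the Bland-Altman convention


@dataclass(frozen=True)
class PairedReadings:
    """Paired device/reference readings, one row per measurement."""

    subject_id: np.ndarray
    predicted: np.ndarray
    reference: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "subject_id", np.asarray(self.subject_id))
        object.__setattr__(self, "predicted", np.asarray(self.predicted, dtype=float))
        object.__setattr__(self, "reference", np.asarray(self.reference, dtype=float))
        if not (len(self.subject_id) == len(self.predicted) == len(self.reference)):
            raise ValueError("columns must have equal length")
        if not (np.isfinite(self.predicted).all() and np.isfinite(self.reference).all()):
            raise ValueError("readings must be finite")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedReadings":
        return cls(df["subject_id"].to_numpy(), df["predicted"].to_numpy(),
                   df["reference"].to_numpy())

    @property
    def differences(self) -> np.ndarray:
        return self.predicted - self.reference

    def __len__(self) -> int:
        return len(self.predicted)


@dataclass(frozen=True)
class AgreementReport:
    mape: float
    mean_pred: float
    mean_ref: float
    sd_pred: float
    sd_ref: float
    mean_diff: float
    sd_diff: float
    ci95_halfwidth: float
    ba_bias: float
    ba_loa_low: float
    ba_loa_high: float
    n: int


@dataclass(frozen=True)
class ISOConstants:
    c1_mean_max: float = 5.0  # mm Hg
    c1_sd_max: float = 8.0  # mm Hg
    c2_coverage: float = 0.85
    c2_limit: float = 10.0  # mm Hg


@dataclass(frozen=True)
class ISOValidationReport:
    c1_mean: float
    c1_sd: float
    c1_pass: bool
    c1_mean_pass: bool
    c1_sd_pass: bool
    c2_mean: float
    c2_sd: float
    c2_sd_max: float
    c2_pass: bool
    n_measurements: int
    n_subjects: int


class BPCategory(Enum):
    hypotension = "hypotension"
    optimal = "optimal"
    normal = "normal"
    grade1 = "grade1"
    grade2_3 = "grade2_3"


# --------------------------------------------------------------------------
# agreement statistics
# --------------------------------------------------------------------------

def mape(pairs: PairedReadings) -> float:
    """Mean absolute percentage error, 100 * mean(|pred - ref| / |ref|)."""
    if (pairs.reference == 0).any():
        raise ValueError("reference readings must be nonzero for MAPE")
    return float(100.0 * np.mean(np.abs(pairs.differences) / np.abs(pairs.reference)))


def paired_difference_summary(pairs: PairedReadings, signed: bool = True):
    """(mean_diff, sd_diff, ci95_halfwidth) of predicted - reference.

    SD uses the n-1 denominator; the CI half-width is 1.96 * sd / sqrt(n).
    With ``signed=False`` the absolute mean difference is reported (the
    convention some studies print for summary tables).
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.differences
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    ci = Z95 * sd_d / math.sqrt(n)
    return (mean_d if signed else abs(mean_d)), sd_d, ci


def bland_altman(pairs: PairedReadings, plot_path=None):
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD).

    If ``plot_path`` is given, writes a difference-vs-mean scatter with the
    bias and limit lines.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - Z95 * sd, bias + Z95 * sd
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        means = (pairs.predicted + pairs.reference) / 2.0
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(means, d, s=8, alpha=0.6)
        for y, style in ((bias, "-"), (loa_low, "--"), (loa_high, "--")):
            ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
        ax.set_xlabel("mean of predicted and reference")
        ax.set_ylabel("predicted - reference")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return bias, loa_low, loa_high


def agreement_report(pairs: PairedReadings, signed: bool = True) -> AgreementReport:
    """Full agreement summary for one vital sign."""
    mean_diff, sd_diff, ci = paired_difference_summary(pairs, signed=signed)
    bias, lo, hi = bland_altman(pairs)
    return AgreementReport(
        mape=mape(pairs),
        mean_pred=float(pairs.predicted.mean()),
        mean_ref=float(pairs.reference.mean()),
        sd_pred=float(pairs.predicted.std(ddof=1)),
        sd_ref=float(pairs.reference.std(ddof=1)),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        ci95_halfwidth=ci,
        ba_bias=bias,
        ba_loa_low=lo,
        ba_loa_high=hi,
        n=len(pairs),
    )


# --------------------------------------------------------------------------
# ISO 81060-2
# --------------------------------------------------------------------------

def criterion1_verdict(mean: float, sd: float, constants: ISOConstants = ISOConstants()):
    """(mean_pass, sd_pass, overall) for per-measurement errors."""
    mean_pass = abs(mean) <= constants.c1_mean_max
    sd_pass = sd <= constants.c1_sd_max
    return mean_pass, sd_pass, mean_pass and sd_pass


def iso_criterion1(pairs: PairedReadings, constants: ISOConstants = ISOConstants()):
    """Mean and SD of all per-measurement differences, with the pass verdict.

    Passes iff |mean| <= 5 mm Hg and SD <= 8 mm Hg. Both clauses are also
    reported separately (some published tables show only the SD clause).
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 measurements")
    d = pairs.differences
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    mean_pass, sd_pass, overall = criterion1_verdict(mean, sd, constants)
    return mean, sd, overall


def per_subject_errors(pairs: PairedReadings) -> np.ndarray:
    """Average each subject's differences; subjects in order of first appearance."""
    if len(pairs) == 0:
        raise ValueError("no readings")
    df = pd.DataFrame({"subject_id": pairs.subject_id, "d": pairs.differences})
    if df["subject_id"].isna().any():
        raise ValueError("missing subject ids")
    # sort=False preserves first-appearance order
    return df.groupby("subject_id", sort=False)["d"].mean().to_numpy()


def iso_criterion2_threshold(mean_error: float,
                             constants: ISOConstants = ISOConstants()) -> float:
    """Largest permissible SD of per-subject errors given their mean.

    Solves Phi((L - m)/s) - Phi((-L - m)/s) = coverage for s by bisection
    (absolute tolerance 1e-4), with L = 10 mm Hg and coverage 0.85;
    the probability is decreasing in s, so this is the largest s meeting
    the coverage requirement. Returned at full precision; round to 2
    decimals for table display.
    """
    m = float(mean_error)
    L = constants.c2_limit
    if abs(m) >= L:
        raise ValueError(f"|mean error| {abs(m)} >= {L}: no feasible SD")

    def coverage(s: float) -> float:
        return stats.norm.cdf((L - m) / s) - stats.norm.cdf((-L - m) / s)

    lo, hi = 1e-9, 1.0
    while coverage(hi) >= constants.c2_coverage:
        hi *= 2.0
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if coverage(mid) >= constants.c2_coverage:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def criterion2_verdict(mean: float, sd: float, constants: ISOConstants = ISOConstants()):
    """(sd_max, passes) for per-subject averaged errors with given mean/SD.

    The observed mean is rounded to 1 decimal before solving for the
    threshold, matching how validation tables print it.
    """
    sd_max = iso_criterion2_threshold(round(float(mean), 1), constants)
    return sd_max, sd < sd_max


def iso_criterion2(pairs: PairedReadings, constants: ISOConstants = ISOConstants(),
                   per_subject: bool = True):
    """Criterion-2 mean, SD, threshold and verdict.

    ``per_subject=True`` (the standard's definition) averages errors within
    subject first; ``False`` evaluates the same rule on raw per-measurement
    errors for comparison.
    """
    errors = per_subject_errors(pairs) if per_subject else pairs.differences
    if len(errors) < 2:
        raise ValueError("need at least 2 subjects")
    mean, sd = float(errors.mean()), float(errors.std(ddof=1))
    sd_max, ok = criterion2_verdict(mean, sd, constants)
    return mean, sd, sd_max, ok


def iso_validation_report(pairs: PairedReadings,
                          constants: ISOConstants = ISOConstants()) -> ISOValidationReport:
    c1_mean, c1_sd, _ = iso_criterion1(pairs, constants)
    c1_mean_pass, c1_sd_pass, c1_pass = criterion1_verdict(c1_mean, c1_sd, constants)
    c2_mean, c2_sd, c2_sd_max, c2_pass = iso_criterion2(pairs, constants)
    return ISOValidationReport(
        c1_mean=c1_mean, c1_sd=c1_sd, c1_pass=c1_pass,
        c1_mean_pass=c1_mean_pass, c1_sd_pass=c1_sd_pass,
        c2_mean=c2_mean, c2_sd=c2_sd, c2_sd_max=c2_sd_max, c2_pass=c2_pass,
        n_measurements=len(pairs),
        n_subjects=len(np.unique(pairs.subject_id)),
    )


# --------------------------------------------------------------------------
# hypothesis tests
# --------------------------------------------------------------------------

def normality_test(values) -> tuple:
    """Shapiro-Wilk W and p; p <= .05 is read as a departure from normality."""
    values = np.asarray(values, dtype=float)
    if not 3 <= len(values) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("degenerate (constant) input")
    w, p = stats.shapiro(values)
    return float(w), float(p)


def _signed_rank_enumeration(d: np.ndarray) -> tuple:
    """Exact two-sided signed-rank p by enumeration over all 2^n sign vectors.

    Valid with ties (midranks are used); feasible for small n only.
    """
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = ranks.sum()
    w_min = min(w_pos, total - w_pos)
    count = 0
    for mask in range(2 ** n):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if w <= w_min + 1e-9 or w >= total - w_min - 1e-9:
            count += 1
    return w_min, count / 2 ** n


def wilcoxon_signed_rank(pairs: PairedReadings, exact_max_n: int = 12) -> tuple:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original convention). For
    n <= ``exact_max_n`` the p-value is computed by exhaustive enumeration
    over all sign assignments (valid under ties); larger samples use the
    normal approximation with tie and continuity corrections. Returns
    (statistic, p); all-zero differences yield (0, 1) flagged degenerate
    via p = 1 and statistic 0.
    """
    d = pairs.differences
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    if n <= exact_max_n:
        return _signed_rank_enumeration(d)
    stat, p = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method="approx")
    return float(stat), float(p)


# --------------------------------------------------------------------------
# blood pressure categories and cohort composition
# --------------------------------------------------------------------------

def classify_bp(sbp: float, dbp: float) -> BPCategory:
    """ESH office-BP grade with grades 2 and 3 merged; hypotension first.

    Hypotension (SBP <= 100 and/or DBP <= 60) takes precedence; otherwise
    the higher grade triggered by either vital applies.
    """
    if sbp <= 0 or dbp <= 0:
        raise ValueError("vitals must be positive")
    if sbp <= 100 or dbp <= 60:
        return BPCategory.hypotension
    if sbp >= 160 or dbp >= 100:
        return BPCategory.grade2_3
    if sbp >= 140 or dbp >= 90:
        return BPCategory.grade1
    if sbp >= 120 or dbp >= 80:
        return BPCategory.normal
    return BPCategory.optimal


#: (label, vital, predicate threshold, direction, ISO minimum percent)
_ISO_RANGES = (
    ("sbp_le_100", "sbp", 100.0, "le", 5.0),
    ("sbp_ge_140", "sbp", 140.0, "ge", 20.0),
    ("sbp_ge_160", "sbp", 160.0, "ge", 5.0),
    ("dbp_le_60", "dbp", 60.0, "le", 5.0),
    ("dbp_ge_85", "dbp", 85.0, "ge", 20.0),
    ("dbp_ge_100", "dbp", 100.0, "ge", 5.0),
)


def cohort_composition(labels: pd.DataFrame, n_total: int | None = None) -> pd.DataFrame:
    """Percentage of the cohort in each ISO sampling range, with verdicts.

    ``labels`` needs ``sbp`` and ``dbp`` columns (one row per patient).
    Returns a frame with columns range, percent, iso_minimum, meets_minimum.
    """
    if n_total is None:
        n_total = len(labels)
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    rows = []
    for name, vital, thr, direction, minimum in _ISO_RANGES:
        v = labels[vital].to_numpy(dtype=float)
        count = int((v <= thr).sum() if direction == "le" else (v >= thr).sum())
        pct = 100.0 * count / n_total
        rows.append({
            "range": name,
            "count": count,
            "percent": pct,
            "iso_minimum": minimum,
            "meets_minimum": pct >= minimum,
        })
    return pd.DataFrame(rows)
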