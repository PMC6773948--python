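"""Rater/method agreement statistics for cellularity scores.

Two-way intraclass correlation (ICC) from the classical ANOVA
decomposition of an n-subjects x k-raters score matrix, with F-based 95%
confidence intervals; range-stratified score counts; and binary
healthy-vs-cancer accuracy (healthy iff score == 0).

Two ICC variants are provided, in Shrout–Fleiss notation:

``agreement``  ICC(2,1): two-way random effects, single rater, absolute
               agreement — the default, appropriate when methods should
               reproduce each other's values, not merely rank subjects.
``consistency`` ICC(3,1): two-way mixed effects, single rater, consistency
               — invariant to adding a constant to one rater's scores.

Confidence intervals follow McGraw & Wong: an exact F interval for the
consistency form and the Satterthwaite approximation for the agreement
form.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

#: Stratification bins: exactly-zero, then half-open real intervals
#: generalising the integer ranges 1-30, 31-70, >70.
STRATA_LABELS = ("0%", "1-30%", "31-70%", ">70%")


class ICCResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    variant: str
    n_subjects: int
    n_raters: int


@dataclass
class AgreementReport:
    """Pairwise agreement between two score tables."""

    method_a: str
    method_b: str
    icc: ICCResult
    slope: float
    intercept: float
    n: int
    binary_accuracy: float
    strata_counts: dict = field(default_factory=dict)


def _two_way_anova(matrix: np.ndarray):
    """Mean squares of the two-way, single-observation ANOVA."""
    n, k = matrix.shape
    grand = matrix.mean()
    subject_means = matrix.mean(axis=1)
    rater_means = matrix.mean(axis=0)
    ss_subjects = k * np.sum((subject_means - grand) ** 2)
    ss_raters = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((matrix - grand) ** 2)
    ss_error = ss_total - ss_subjects - ss_raters
    msb = ss_subjects / (n - 1)  # between subjects
    msj = ss_raters / (k - 1)  # between raters
    mse = max(ss_error / ((n - 1) * (k - 1)), 0.0)  # residual
    return msb, msj, mse


def icc_two_way(
    matrix,
    variant: str = "agreement",
    confidence_level: float = 0.95,
) -> ICCResult:
    """Two-way ICC with an F-based confidence interval.

    ``matrix`` is an (n_subjects, k_raters) array or DataFrame; rows with
    any missing value are dropped (listwise deletion, logged via warning).
    Requires >= 5 complete subjects and >= 2 raters.

    Degenerate conventions: an all-identical matrix is perfect agreement
    (ICC = 1); zero between-subject variance with rater noise is no
    agreement (ICC = 0); both emit a warning.
    """
    X = np.asarray(
        matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix, float
    )
    if X.ndim != 2:
        raise ValueError("score matrix must be 2-dimensional (subjects x raters)")
    complete = ~np.isnan(X).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"listwise deletion removed {dropped} subject(s)", stacklevel=2)
    X = X[complete]
    n, k = X.shape
    if k < 2:
        raise ValueError("ICC needs at least 2 raters")
    if n < 5:
        raise ValueError("ICC needs at least 5 complete subjects")
    if variant not in ("agreement", "consistency"):
        raise ValueError("variant must be 'agreement' or 'consistency'")

    msb, msj, mse = _two_way_anova(X)
    alpha = 1.0 - confidence_level

    if np.ptp(X) < 1e-12:
        warnings.warn(
            "all scores identical: ICC set to 1 by the perfect-agreement limit",
            stacklevel=2,
        )
        return ICCResult(1.0, 1.0, 1.0, variant, n, k)

    if variant == "consistency":
        denom = msb + (k - 1) * mse
        if denom <= 0:
            warnings.warn("degenerate variance: ICC set to 0", stacklevel=2)
            return ICCResult(0.0, 0.0, 0.0, variant, n, k)
        est = (msb - mse) / denom
        df1, df2 = n - 1, (n - 1) * (k - 1)
        if mse == 0.0:
            lo, hi = 1.0, 1.0
        else:
            fobs = msb / mse
            fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:  # absolute agreement, ICC(2,1)
        denom = msb + (k - 1) * mse + (k / n) * (msj - mse)
        if denom <= 0:
            warnings.warn("degenerate variance: ICC set to 0", stacklevel=2)
            return ICCResult(0.0, 0.0, 0.0, variant, n, k)
        est = (msb - mse) / denom
        if mse == 0.0 and msj == 0.0:
            lo, hi = 1.0, 1.0
        else:
            # Satterthwaite df for the agreement-form interval
            a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
            b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
            if not np.isfinite(a) or not np.isfinite(b):
                lo, hi = 1.0, 1.0
            else:
                num = (a * msj + b * mse) ** 2
                den = (a * msj) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else 1.0
                f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = (
                    n * (msb - f1 * mse)
                    / (f1 * (k * msj + (k * n - k - n) * mse) + n * msb)
                )
                hi = (
                    n * (f2 * msb - mse)
                    / (k * msj + (k * n - k - n) * mse + n * f2 * msb)
                )

    est = float(np.clip(est, -1.0 + 1e-15, 1.0))
    lo = float(min(np.clip(lo, -1.0, 1.0), est))
    hi = float(max(np.clip(hi, -1.0, 1.0), est))
    return ICCResult(est, lo, hi, variant, n, k)


def stratify_scores(scores, bins=None) -> np.ndarray:
    """Counts per cellularity range: [0,0], (0,30], (30,70], (70,100].

    The exact-zero bin is "no tumour cells"; interior bins are
    upper-inclusive. Scores outside [0, 100] raise. Returns a length-4
    integer array aligned with :data:`STRATA_LABELS`.
    """
    s = np.asarray(scores, float)
    if s.size and (s.min() < 0.0 or s.max() > 100.0):
        raise ValueError("scores must lie in [0, 100]")
    edges = bins if bins is not None else (0.0, 30.0, 70.0, 100.0)
    zero, e1, e2, e3 = edges
    counts = np.array(
        [
            int(np.sum(s == zero)),
            int(np.sum((s > zero) & (s <= e1))),
            int(np.sum((s > e1) & (s <= e2))),
            int(np.sum((s > e2) & (s <= e3))),
        ]
    )
    return counts


def binary_accuracy(predicted, reference) -> float:
    """Healthy-vs-cancer accuracy: both vectors binarised as healthy iff
    the score equals 0; returns the fraction of agreements."""
    p = np.asarray(predicted, float)
    r = np.asarray(reference, float)
    if p.shape != r.shape:
        raise ValueError("predicted and reference lengths differ")
    if p.size == 0:
        raise ValueError("empty score vectors")
    return float(np.mean((p == 0.0) == (r == 0.0)))


def evaluate_methods(
    score_tables: dict[str, pd.DataFrame],
    variant: str = "agreement",
    confidence_level: float = 0.95,
) -> tuple[pd.DataFrame, list[AgreementReport]]:
    """Pairwise agreement across >= 2 raters/methods.

    Each table needs columns ``patch_id`` and ``score``; pairs are aligned
    on shared patch ids (an empty intersection raises). Returns a tidy
    pairwise summary (ICC + CI, least-squares slope/intercept, binary
    accuracy, n) and the full per-pair reports with stratified counts.
    """
    if len(score_tables) < 2:
        raise ValueError("need at least two score tables")
    series = {}
    for name, tbl in score_tables.items():
        if not {"patch_id", "score"} <= set(tbl.columns):
            raise ValueError(f"table {name!r} must have patch_id and score columns")
        series[name] = tbl.set_index("patch_id")["score"].astype(float)

    rows = []
    reports = []
    for a, b in itertools.combinations(series, 2):
        joined = pd.concat(
            {"a": series[a], "b": series[b]}, axis=1, join="inner"
        ).dropna()
        if len(joined) == 0:
            raise ValueError(f"no shared patch ids between {a!r} and {b!r}")
        xs = joined["a"].to_numpy()
        ys = joined["b"].to_numpy()
        icc = icc_two_way(joined.to_numpy(), variant, confidence_level)
        if np.ptp(xs) < 1e-12:
            slope, intercept = 0.0, float(ys.mean())
        else:
            slope, intercept = (float(v) for v in np.polyfit(xs, ys, 1))
        report = AgreementReport(
            method_a=a,
            method_b=b,
            icc=icc,
            slope=slope,
            intercept=intercept,
            n=len(joined),
            binary_accuracy=binary_accuracy(xs, ys),
            strata_counts={
                a: stratify_scores(xs).tolist(),
                b: stratify_scores(ys).tolist(),
            },
        )
        reports.append(report)
        rows.append(
            {
                "method_a": a,
                "method_b": b,
                "icc": icc.estimate,
                "ci_low": icc.ci_low,
                "ci_high": icc.ci_high,
                "slope": slope,
                "intercept": intercept,
                "binary_accuracy": report.binary_accuracy,
                "n": len(joined),
            }
        )
    return pd.DataFrame(rows), reports
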