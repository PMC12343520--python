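"""Time-to-onset extraction and Weibull summarisation.

TTO is the interval in days from therapy start (START_DT) to event onset
(EVENT_DT) for reports matching the case definition and exposed to the drug.
Records with the event before therapy start, missing dates, or partial date
precision are excluded (tallied by reason, never raised).  Summaries are the
median and interquartile range (linear-interpolation quantiles) plus a
two-parameter Weibull fit of the onset hazard: a shape below 1 indicates an
early, front-loaded hazard; near 1 a memoryless (random) one; above 1 a
late, wear-out-type onset.

The Weibull maximum-likelihood estimate uses the classic profile reduction:
for data x_1..x_n and shape k the scale has the closed form
lam(k) = (mean(x^k))^(1/k), and k solves

    sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x) = 0,

a monotone one-dimensional root found by bracketed root-finding.  The Wald
CI on log-shape comes from the observed information (numeric Hessian of the
log-likelihood in (log shape, log scale)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from faersig.contingency import CaseDefinition, is_case
from faersig.io import ReportCase

Z95 = 1.96

EXCLUSION_REASONS = (
    "missing_event_dt", "missing_start_dt", "partial_date", "negative_interval"
)


@dataclass(frozen=True)
class TTORecord:
    drug: str
    caseid: str
    onset_days: int


@dataclass
class WeibullFit:
    shape: float
    scale: float
    shape_ci_low: float
    shape_ci_high: float
    converged: bool
    n: int
    zeros_shifted: int = 0


@dataclass
class TTOSummary:
    """Per-drug onset-interval distribution summary."""

    drug: str
    n_used: int
    n_excluded: dict[str, int]
    median_days: float | None = None
    iqr_low: float | None = None
    iqr_high: float | None = None
    weibull_shape: float | None = None
    weibull_scale: float | None = None
    shape_ci_low: float | None = None
    shape_ci_high: float | None = None
    onset_pattern: str | None = None
    fit_failed: bool = False


def extract_tto(
    cases: Sequence[ReportCase], drug: str, definition: CaseDefinition
) -> tuple[list[TTORecord], dict[str, int]]:
    """One record per eligible case exposed to ``drug`` with the event.

    Uses the earliest parseable START_DT among the drug's therapy rows
    (first exposure).  Failures never raise; they are tallied by reason.
    """
    records: list[TTORecord] = []
    excluded = {reason: 0 for reason in EXCLUSION_REASONS}
    for case in cases:
        mentions = [m for m in case.drugs if m.raw_name == drug]
        if not mentions or not is_case(case, definition):
            continue
        if case.event_dt is None:
            raw = case.event_dt_raw
            if raw.isdigit() and len(raw) in (4, 6):
                excluded["partial_date"] += 1
            else:
                excluded["missing_event_dt"] += 1
            continue
        starts = [m.start_dt for m in mentions if m.start_dt is not None]
        if not starts:
            raws = [m.start_dt_raw for m in mentions]
            if any(r.isdigit() and len(r) in (4, 6) for r in raws):
                excluded["partial_date"] += 1
            else:
                excluded["missing_start_dt"] += 1
            continue
        onset = (case.event_dt - min(starts)).days
        if onset < 0:
            excluded["negative_interval"] += 1
            continue
        records.append(TTORecord(drug=drug, caseid=case.caseid, onset_days=onset))
    return records, excluded


def summarize_tto(
    records: Sequence[TTORecord] | Sequence[float],
) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile) by linear interpolation."""
    values = np.asarray(
        [r.onset_days if isinstance(r, TTORecord) else r for r in records], dtype=float
    )
    if values.size == 0:
        raise ValueError("no records to summarize")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return float(q50), float(q25), float(q75)


def _profile_score(k: float, x: np.ndarray, mean_log: float) -> float:
    xk = np.power(x, k)
    return float(np.sum(xk * np.log(x)) / np.sum(xk) - 1.0 / k - mean_log)


def _loglik(logk: float, loglam: float, x: np.ndarray) -> float:
    k, lam = math.exp(logk), math.exp(loglam)
    z = np.power(x / lam, k)
    return float(
        x.size * (math.log(k) - k * math.log(lam))
        + (k - 1.0) * np.sum(np.log(x))
        - np.sum(z)
    )


def weibull_fit(
    values: Sequence[float] | np.ndarray,
    min_n: int = 10,
    shift_zeros: bool = True,
) -> WeibullFit:
    """Two-parameter Weibull MLE by profile likelihood on the shape.

    Zeros (same-day onsets) are shifted to 0.5 day since the Weibull support
    is the positive reals; identical values make the likelihood degenerate
    (shape diverges) and are reported as non-converged.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if np.any(x < 0):
        raise ValueError("negative onset values")
    zeros = int(np.sum(x == 0))
    if zeros:
        if not shift_zeros:
            raise ValueError("zero onset values and shift_zeros disabled")
        x = np.where(x == 0, 0.5, x)
    n = x.size
    if np.allclose(x, x[0]):
        return WeibullFit(math.nan, math.nan, math.nan, math.nan, False, n, zeros)
    mean_log = float(np.mean(np.log(x)))
    lo, hi = 1e-3, 1.0
    while _profile_score(hi, x, mean_log) < 0 and hi < 1e4:
        hi *= 2.0
    try:
        shape = optimize.brentq(_profile_score, lo, hi, args=(x, mean_log), xtol=1e-10)
    except ValueError:
        return WeibullFit(math.nan, math.nan, math.nan, math.nan, False, n, zeros)
    scale = float(np.mean(np.power(x, shape)) ** (1.0 / shape))

    # Wald CI on log-shape from the numeric observed information.
    logk, loglam = math.log(shape), math.log(scale)
    h = 1e-5
    hess = np.zeros((2, 2))
    pts = [(logk, loglam)]

    def f(u: float, v: float) -> float:
        return _loglik(u, v, x)

    hess[0, 0] = (f(logk + h, loglam) - 2 * f(*pts[0]) + f(logk - h, loglam)) / h**2
    hess[1, 1] = (f(logk, loglam + h) - 2 * f(*pts[0]) + f(logk, loglam - h)) / h**2
    hess[0, 1] = hess[1, 0] = (
        f(logk + h, loglam + h) - f(logk + h, loglam - h)
        - f(logk - h, loglam + h) + f(logk - h, loglam - h)
    ) / (4 * h**2)
    try:
        cov = np.linalg.inv(-hess)
        se_logk = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        se_logk = math.nan
    if not math.isfinite(se_logk) or se_logk <= 0:
        return WeibullFit(shape, scale, math.nan, math.nan, False, n, zeros)
    ci_low = shape * math.exp(-Z95 * se_logk)
    ci_high = shape * math.exp(Z95 * se_logk)
    return WeibullFit(shape, scale, ci_low, ci_high, True, n, zeros)


def classify_onset_pattern(fit: WeibullFit) -> str:
    """early / random / late by where the shape CI sits relative to 1."""
    if fit.shape_ci_high < 1.0:
        return "early"
    if fit.shape_ci_low > 1.0:
        return "late"
    return "random"


def summarize_drug_tto(
    cases: Sequence[ReportCase],
    drug: str,
    definition: CaseDefinition,
    min_fit_n: int = 10,
) -> TTOSummary:
    """Full TTO summary for one drug: extraction, quantiles, Weibull fit."""
    records, excluded = extract_tto(cases, drug, definition)
    summary = TTOSummary(drug=drug, n_used=len(records), n_excluded=excluded)
    if not records:
        return summary
    summary.median_days, summary.iqr_low, summary.iqr_high = summarize_tto(records)
    if len(records) >= min_fit_n:
        fit = weibull_fit([r.onset_days for r in records], min_n=min_fit_n)
        if fit.converged:
            summary.weibull_shape = fit.shape
            summary.weibull_scale = fit.scale
            summary.shape_ci_low = fit.shape_ci_low
            summary.shape_ci_high = fit.shape_ci_high
            summary.onset_pattern = classify_onset_pattern(fit)
        else:
            summary.fit_failed = True
    return summary
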