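"""The four disproportionality statistics and the joint signal rule.

All four operate on the 2x2 report counts (a, b, c, d), N = a+b+c+d:

* ROR = ad/bc with Wald CI on the log scale,
  SE(lnROR) = sqrt(1/a + 1/b + 1/c + 1/d).
* PRR = (a/(a+b)) / (c/(c+d)),
  SE(lnPRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
* BCPNN information component IC = log2(aN / ((a+b)(a+c))) with the
  prior-smoothed E(IC), V(IC) closed forms and lower bound
  IC025 = E(IC) - 2*sqrt(V(IC)).
* EBGM here denotes the observed/expected reporting ratio
  aN / ((a+b)(a+c)) — identical to 2^IC — with the same Wald SE as the ROR
  and EBGM05 its lower 95% bound.  This is deliberately not the shrunken
  gamma-Poisson (MGPS) estimator; see docs/methods.md.

Signal thresholds (defaults): ROR positive iff a>=3, ROR>=3 and CI lower
bound > 1; PRR positive iff a>=3, PRR>=2 and CI lower bound > 1; BCPNN
positive iff IC025 > 0; EBGM positive iff EBGM05 > 2.  The joint call is
positive only when all four are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from faersig.config import SignalThresholds
from faersig.contingency import ContingencyTable
from faersig.errors import EvaluationError, UndefinedStatisticError

Z95 = 1.96
Z90_ONESIDED = 1.645


@dataclass(frozen=True)
class BCPNNPriors:
    """Dirichlet prior hyperparameters of the BCPNN closed forms.

    Defaults alpha=beta=2, alpha1=beta1=1, gamma11=1; gamma is derived:
    gamma = gamma11 (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)).
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alpha1", "beta1", "gamma11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BCPNN prior {name} must be strictly positive")


@dataclass
class SignalStatistics:
    """Point estimates and interval bounds for one 2x2 table."""

    drug: str = ""
    a: int = 0
    ror: float | None = None
    ror_ci_low: float | None = None
    ror_ci_high: float | None = None
    prr: float | None = None
    prr_ci_low: float | None = None
    prr_ci_high: float | None = None
    chi2: float | None = None
    ic: float | None = None
    eic: float | None = None
    vic: float | None = None
    ic025: float | None = None
    ebgm: float | None = None
    ebgm05: float | None = None
    ebgm95: float | None = None
    continuity_corrected: bool = False


@dataclass
class SignalDecision:
    """Per-algorithm threshold verdicts plus the joint all-four call."""

    ror_positive: bool
    prr_positive: bool
    bcpnn_positive: bool
    ebgm_positive: bool
    joint_positive: bool
    reasons: dict[str, str]


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding used for reported tables."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _corrected_cells(
    t: ContingencyTable, continuity: bool
) -> tuple[float, float, float, float, bool]:
    """Haldane-Anscombe +0.5 on all cells when b or c is zero (if enabled)."""
    a, b, c, d = t.cells()
    if b == 0 or c == 0:
        if not continuity:
            cell = "b" if b == 0 else "c"
            raise UndefinedStatisticError(
                f"{t.drug or 'table'}: cell {cell} is zero and continuity correction is disabled"
            )
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return float(a), float(b), float(c), float(d), False


def ror_stat(
    t: ContingencyTable, continuity: bool = True
) -> tuple[float, float, float]:
    """Reporting odds ratio ad/bc with its 95% Wald CI."""
    a, b, c, d, _ = _corrected_cells(t, continuity)
    if min(a, b, c, d) <= 0:
        raise UndefinedStatisticError(f"{t.drug or 'table'}: zero cell, ROR undefined")
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se)


def prr_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Proportional reporting ratio with its 95% Wald CI.

    Undefined when a = 0 or c = 0 (no continuity variant is applied to the
    PRR; the correction convention covers only the odds-ratio-form
    statistics).
    """
    a, b, c, d = (float(x) for x in t.cells())
    if a < 1 or c < 1:
        cell = "a" if a < 1 else "c"
        raise UndefinedStatisticError(f"{t.drug or 'table'}: cell {cell} is zero, PRR undefined")
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se)


def bcpnn_stat(
    t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors()
) -> tuple[float, float, float, float]:
    """BCPNN information component: (IC, E(IC), V(IC), IC025).

    IC = log2(aN/((a+b)(a+c))); the expectation and variance use the
    Dirichlet-smoothed closed forms with the derived gamma, and
    IC025 = E(IC) - 2*sqrt(V(IC)).
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    if a < 1 or n < 1:
        raise UndefinedStatisticError(f"{t.drug or 'table'}: a = 0, IC undefined")
    p = priors
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((a + b + p.alpha1) * (a + c + p.beta1))
    ic = math.log2(a * n / ((a + b) * (a + c)))
    eic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + gamma) * (a + b + p.alpha1) * (a + c + p.beta1))
    )
    vic = (1.0 / math.log(2) ** 2) * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - a - b + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
        + (n - a - c + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
    )
    if vic <= 0:
        raise UndefinedStatisticError(f"{t.drug or 'table'}: non-positive V(IC)")
    return ic, eic, vic, eic - 2.0 * math.sqrt(vic)


def ebgm_stat(
    t: ContingencyTable, continuity: bool = True, onesided_05: bool = False
) -> tuple[float, float, float]:
    """Observed/expected ratio aN/((a+b)(a+c)) with Wald bounds.

    ``onesided_05`` switches the lower bound from the two-sided 1.96
    multiplier to the conventional one-sided 1.645 fifth percentile.
    """
    a, b, c, d, _ = _corrected_cells(t, continuity)
    if min(a, b, c, d) <= 0:
        raise UndefinedStatisticError(f"{t.drug or 'table'}: zero cell, EBGM undefined")
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z90_ONESIDED if onesided_05 else Z95
    return ebgm, ebgm * math.exp(-z * se), ebgm * math.exp(Z95 * se)


def chi2_stat(t: ContingencyTable, yates: bool = True, continuity: bool = True) -> float:
    """Pearson chi-square, by default with the Yates continuity correction
    (clamped at zero).  Reported alongside the PRR; never part of the joint
    signal rule."""
    a, b, c, d, _ = _corrected_cells(t, continuity)
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) <= 0:
        raise UndefinedStatisticError(f"{t.drug or 'table'}: degenerate margin, chi2 undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    return n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])


def compute_statistics(
    t: ContingencyTable,
    priors: BCPNNPriors = BCPNNPriors(),
    continuity: bool = True,
    ebgm05_onesided: bool = False,
) -> SignalStatistics:
    """Evaluate all four algorithms (plus chi2) on one table.

    Statistics that are undefined for the table (e.g. PRR with c = 0 and no
    continuity variant) are left as None rather than raising.
    """
    s = SignalStatistics(drug=t.drug, a=t.a)
    s.continuity_corrected = (t.b == 0 or t.c == 0) and continuity
    try:
        s.ror, s.ror_ci_low, s.ror_ci_high = ror_stat(t, continuity)
    except UndefinedStatisticError:
        pass
    try:
        s.prr, s.prr_ci_low, s.prr_ci_high = prr_stat(t)
    except UndefinedStatisticError:
        pass
    try:
        s.chi2 = chi2_stat(t, continuity=continuity)
    except UndefinedStatisticError:
        pass
    try:
        s.ic, s.eic, s.vic, s.ic025 = bcpnn_stat(t, priors)
    except UndefinedStatisticError:
        pass
    try:
        s.ebgm, s.ebgm05, s.ebgm95 = ebgm_stat(t, continuity, ebgm05_onesided)
    except UndefinedStatisticError:
        pass
    return s


def evaluate_signal(
    s: SignalStatistics, thresholds: SignalThresholds = SignalThresholds()
) -> SignalDecision:
    """Apply the per-algorithm thresholds and the joint all-four rule."""
    missing = [
        name for name, value in (
            ("ror", s.ror), ("ror_ci_low", s.ror_ci_low),
            ("prr", s.prr), ("prr_ci_low", s.prr_ci_low),
            ("ic025", s.ic025), ("ebgm05", s.ebgm05),
        ) if value is None
    ]
    if missing:
        raise EvaluationError(f"cannot evaluate signal, missing statistics: {missing}")
    th = thresholds
    reasons: dict[str, str] = {}
    ror_pos = s.a >= th.min_a and s.ror >= th.ror_min and s.ror_ci_low > th.ror_ci_low_min
    reasons["ror"] = (
        f"a={s.a}>={th.min_a}, ROR={s.ror:.2f}>={th.ror_min}, "
        f"CI low={s.ror_ci_low:.2f}>{th.ror_ci_low_min}" if ror_pos else
        f"fails a>={th.min_a} & ROR>={th.ror_min} & CI low>{th.ror_ci_low_min}"
    )
    prr_pos = s.a >= th.min_a and s.prr >= th.prr_min and s.prr_ci_low > th.prr_ci_low_min
    reasons["prr"] = (
        f"a={s.a}>={th.min_a}, PRR={s.prr:.2f}>={th.prr_min}, "
        f"CI low={s.prr_ci_low:.2f}>{th.prr_ci_low_min}" if prr_pos else
        f"fails a>={th.min_a} & PRR>={th.prr_min} & CI low>{th.prr_ci_low_min}"
    )
    bcpnn_pos = s.ic025 > th.ic025_min
    reasons["bcpnn"] = f"IC025={s.ic025:.2f}" + (">" if bcpnn_pos else "<=") + f"{th.ic025_min}"
    ebgm_pos = s.ebgm05 > th.ebgm05_min
    reasons["ebgm"] = f"EBGM05={s.ebgm05:.2f}" + (">" if ebgm_pos else "<=") + f"{th.ebgm05_min}"
    joint = ror_pos and prr_pos and bcpnn_pos and ebgm_pos
    return SignalDecision(ror_pos, prr_pos, bcpnn_pos, ebgm_pos, joint, reasons)


def signal_frame(
    tables: Sequence[ContingencyTable],
    priors: BCPNNPriors = BCPNNPriors(),
    thresholds: SignalThresholds = SignalThresholds(),
    continuity: bool = True,
    ebgm05_onesided: bool = False,
) -> pd.DataFrame:
    """One row per drug: n, the four statistics with bounds, per-criterion
    flags and the joint flag."""
    rows = []
    for t in tables:
        s = compute_statistics(t, priors, continuity, ebgm05_onesided)
        try:
            decision = evaluate_signal(s, thresholds)
        except EvaluationError:
            decision = SignalDecision(False, False, False, False, False,
                                      {"error": "undefined statistics"})
        rows.append({
            "drug": t.drug, "n": t.a,
            "ror": s.ror, "ror_ci_low": s.ror_ci_low, "ror_ci_high": s.ror_ci_high,
            "prr": s.prr, "chi2": s.chi2,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "ic": s.ic, "ic025": s.ic025,
            "ror_positive": decision.ror_positive,
            "prr_positive": decision.prr_positive,
            "bcpnn_positive": decision.bcpnn_positive,
            "ebgm_positive": decision.ebgm_positive,
            "joint_positive": decision.joint_positive,
            "continuity_corrected": s.continuity_corrected,
        })
    return pd.DataFrame(rows)
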