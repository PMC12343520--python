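"""Descriptive outputs: strata, yearly trend, top drugs, signal ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from faersig.contingency import CaseDefinition, is_case
from faersig.io import ReportCase
from faersig.stats import round_half_up
from faersig.tto import TTOSummary

AGE_BIN_LABELS = ("<=18", "19-40", "41-64", ">=65", "Unknown")
OUTCOME_LABELS = {
    "DE": "Death",
    "DS": "Disability",
    "LT": "Life-threatening",
    "HO": "Hospitalization",
}


@dataclass(frozen=True)
class StratumSummary:
    dimension: str  # sex | age_group | indication | outcome | country
    label: str
    count: int
    percent: float


@dataclass(frozen=True)
class RankedDrugRow:
    rank: int
    drug: str
    n: int
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float | None
    ebgm05: float
    ic025: float
    joint_positive: bool
    tto: str
    annotation: str = ""


def age_bin(age_years: float | None) -> str:
    """Bin integer years with inclusive boundaries 18/40/64."""
    if age_years is None:
        return "Unknown"
    years = int(age_years)
    if years <= 18:
        return "<=18"
    if years <= 40:
        return "19-40"
    if years <= 64:
        return "41-64"
    return ">=65"


def _select(cases: Sequence[ReportCase], definition: CaseDefinition | None) -> list[ReportCase]:
    if definition is None:
        return list(cases)
    return [c for c in cases if is_case(c, definition)]


def describe(
    cases: Sequence[ReportCase],
    definition: CaseDefinition | None = None,
    top_k: int = 5,
) -> list[StratumSummary]:
    """Stratum counts and percents over the (case-restricted) report set.

    Sex and age-group strata include Unknown and sum to N; indication,
    outcome and country are top-k lists.  All percents use the total N as
    denominator, rounded half-up to two decimals.
    """
    selected = _select(cases, definition)
    if not selected:
        raise ValueError("empty case set")
    n = len(selected)

    def pct(count: int) -> float:
        return round_half_up(100.0 * count / n, 2)

    rows: list[StratumSummary] = []
    sex_counts = {"female": 0, "male": 0, "unknown": 0}
    age_counts = {label: 0 for label in AGE_BIN_LABELS}
    indi: dict[str, int] = {}
    outc: dict[str, int] = {}
    ctry: dict[str, int] = {}
    for case in selected:
        sex_counts[case.sex] += 1
        age_counts[age_bin(case.age_years)] += 1
        for term in set(case.indications):
            indi[term] = indi.get(term, 0) + 1
        for code in set(case.outcomes):
            label = OUTCOME_LABELS.get(code.upper(), code.upper())
            outc[label] = outc.get(label, 0) + 1
        if case.country:
            ctry[case.country] = ctry.get(case.country, 0) + 1
    for label, nice in (("female", "Female"), ("male", "Male"), ("unknown", "Unknown")):
        rows.append(StratumSummary("sex", nice, sex_counts[label], pct(sex_counts[label])))
    for label in AGE_BIN_LABELS:
        rows.append(StratumSummary("age_group", label, age_counts[label], pct(age_counts[label])))
    for dimension, counts in (("indication", indi), ("outcome", outc), ("country", ctry)):
        top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        rows.extend(
            StratumSummary(dimension, label, count, pct(count)) for label, count in top
        )
    return rows


def yearly_trend(
    cases: Sequence[ReportCase],
    definition: CaseDefinition | None = None,
    year_range: tuple[int, int] | None = None,
) -> tuple[list[tuple[int, int]], int]:
    """Report counts per FDA receipt year, zero-filled within the range.

    Returns (trend, excluded count of reports outside the range or without a
    parseable receipt date).
    """
    selected = _select(cases, definition)
    counts: dict[int, int] = {}
    excluded = 0
    for case in selected:
        year = case.fda_dt.year if case.fda_dt is not None else None
        if year is None or (year_range and not year_range[0] <= year <= year_range[1]):
            excluded += 1
            continue
        counts[year] = counts.get(year, 0) + 1
    if year_range:
        years = range(year_range[0], year_range[1] + 1)
    elif counts:
        years = range(min(counts), max(counts) + 1)
    else:
        years = range(0)
    return [(y, counts.get(y, 0)) for y in years], excluded


def top_drugs(
    cases: Sequence[ReportCase],
    definition: CaseDefinition,
    k: int,
) -> list[tuple[str, int, float, float]]:
    """Drugs ranked by case-report count, descending (ties by name).

    Returns (drug, count, percent of all case reports, percent of the top-k
    sum) — both denominator conventions are emitted and labelled because
    neither is universal.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    selected = _select(cases, definition)
    counts: dict[str, int] = {}
    for case in selected:
        for drug in case.drug_names():
            counts[drug] = counts.get(drug, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    total = len(selected)
    topk_sum = sum(c for _, c in ranked)
    return [
        (
            drug,
            count,
            round_half_up(100.0 * count / total, 2) if total else 0.0,
            round_half_up(100.0 * count / topk_sum, 2) if topk_sum else 0.0,
        )
        for drug, count in ranked
    ]


def format_tto(summary: TTOSummary | None) -> str:
    """Table-style 'median (q1-q3)' rendering; '-' when no usable records."""
    if summary is None or summary.n_used == 0 or summary.median_days is None:
        return "-"
    return f"{summary.median_days:g} ({summary.iqr_low:g}-{summary.iqr_high:g})"


def rank_signals(
    stats: pd.DataFrame,
    tto_summaries: Mapping[str, TTOSummary] | None = None,
    k: int = 30,
    annotations: Mapping[str, str] | None = None,
) -> list[RankedDrugRow]:
    """Joint-positive drugs sorted by descending ROR, top k, with TTO merged."""
    tto_summaries = tto_summaries or {}
    annotations = annotations or {}
    positives = stats[stats["joint_positive"]].sort_values(
        ["ror", "drug"], ascending=[False, True], kind="mergesort"
    )
    rows = []
    for rank, rec in enumerate(positives.head(k).itertuples(index=False), start=1):
        rows.append(RankedDrugRow(
            rank=rank,
            drug=rec.drug,
            n=int(rec.n),
            ror=rec.ror,
            ror_ci_low=rec.ror_ci_low,
            ror_ci_high=rec.ror_ci_high,
            prr=rec.prr,
            chi2=rec.chi2,
            ebgm05=rec.ebgm05,
            ic025=rec.ic025,
            joint_positive=bool(rec.joint_positive),
            tto=format_tto(tto_summaries.get(rec.drug)),
            annotation=annotations.get(rec.drug, ""),
        ))
    return rows


def ranked_frame(rows: Sequence[RankedDrugRow]) -> pd.DataFrame:
    """Ranked rows as a report table, point estimates rounded to 2 decimals."""
    return pd.DataFrame([
        {
            "rank": r.rank,
            "drug": r.drug,
            "n": r.n,
            "ror": round_half_up(r.ror, 2),
            "ror_95ci": f"{round_half_up(r.ror_ci_low, 2):.2f}-{round_half_up(r.ror_ci_high, 2):.2f}",
            "prr": round_half_up(r.prr, 2),
            "chi2": round_half_up(r.chi2, 2) if r.chi2 is not None else "",
            "ebgm05": round_half_up(r.ebgm05, 2),
            "ic025": round_half_up(r.ic025, 2),
            "tto_days": r.tto,
            "annotation": r.annotation,
        }
        for r in rows
    ])


def plot_yearly_trend(trend: Sequence[tuple[int, int]], path: str) -> None:
    """Simple bar plot of the yearly report counts (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    years = [y for y, _ in trend]
    counts = [c for _, c in trend]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(years, counts, color="#4878a8")
    ax.set_xlabel("Year (FDA receipt)")
    ax.set_ylabel("Reports")
    ax.set_title("Reported cases per year")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
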