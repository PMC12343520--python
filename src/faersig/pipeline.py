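"""End-to-end orchestration: raw quarterly files to ranked signal table."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from faersig.config import SignalThresholds
from faersig.contingency import NEURALGIA, CaseDefinition, all_tables
from faersig.io import CleaningLog, ReportCase, clean_and_join, find_quarters
from faersig.mapping import DrugDictionary, MappingResult, map_to_generic
from faersig.reporting import (
    RankedDrugRow,
    StratumSummary,
    describe,
    rank_signals,
    top_drugs,
    yearly_trend,
)
from faersig.stats import BCPNNPriors, signal_frame
from faersig.tto import TTOSummary, summarize_drug_tto


@dataclass
class PipelineResult:
    cases: list[ReportCase]
    cleaning_log: CleaningLog
    mapping_excluded: int
    mapping_audit: list[MappingResult]
    tables: list
    stats: pd.DataFrame
    tto: dict[str, TTOSummary]
    ranked: list[RankedDrugRow]
    strata: list[StratumSummary]
    trend: list[tuple[int, int]]
    trend_excluded: int
    top_drugs: list[tuple[str, int, float, float]]

    @property
    def joint_positive_drugs(self) -> list[str]:
        if self.stats.empty:
            return []
        return list(self.stats.loc[self.stats["joint_positive"], "drug"])


def run_pipeline(
    data_dir: str | Path,
    dictionary: DrugDictionary | str | Path,
    definition: CaseDefinition = NEURALGIA,
    min_a: int = 3,
    priors: BCPNNPriors = BCPNNPriors(),
    thresholds: SignalThresholds = SignalThresholds(),
    mapping_policy: str = "exclude-report",
    roles: Sequence[str] | None = None,
    tto_min_fit: int = 10,
    top_k: int = 30,
    year_range: tuple[int, int] | None = None,
) -> PipelineResult:
    """Ingest, deduplicate, clean, map, screen and rank in one call.

    TTO summaries are computed for every jointly positive drug, matching the
    practice of reserving onset analysis for drugs with valid signals.
    """
    if not isinstance(dictionary, DrugDictionary):
        dictionary = DrugDictionary.from_tsv(dictionary)
    quarters = find_quarters(data_dir)
    if not quarters:
        raise FileNotFoundError(f"no DEMO*.txt quarterly files under {data_dir}")
    cases, log = clean_and_join(quarters)
    mapped, excluded, audit = map_to_generic(cases, dictionary, policy=mapping_policy)
    tables = all_tables(mapped, definition, min_a=min_a, roles=roles)
    stats = signal_frame(tables, priors=priors, thresholds=thresholds)
    tto: dict[str, TTOSummary] = {}
    if not stats.empty:
        for drug in stats.loc[stats["joint_positive"], "drug"]:
            tto[drug] = summarize_drug_tto(mapped, drug, definition, min_fit_n=tto_min_fit)
    ranked = rank_signals(stats, tto, k=top_k)
    try:
        strata = describe(mapped, definition)
    except ValueError:  # no report matches the case definition
        strata = []
    trend, trend_excluded = yearly_trend(mapped, definition, year_range)
    top = top_drugs(mapped, definition, k=top_k)
    return PipelineResult(
        cases=mapped,
        cleaning_log=log,
        mapping_excluded=excluded,
        mapping_audit=audit,
        tables=tables,
        stats=stats,
        tto=tto,
        ranked=ranked,
        strata=strata,
        trend=trend,
        trend_excluded=trend_excluded,
        top_drugs=top,
    )
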