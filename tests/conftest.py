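"""Shared fixtures: a small synthetic dataset and case-construction helpers."""

from __future__ import annotations

import datetime as dt

import pytest

from faersig.config import SignalDrug, SyntheticConfig
from faersig.io import DrugMention, ReportCase
from faersig.pipeline import run_pipeline
from faersig.synthetic import generate_dataset


def make_case(
    caseid: str = "c1",
    drugs: list[str] | None = None,
    reactions: list[str] | None = None,
    sex: str = "unknown",
    age_years: float | None = None,
    country: str | None = None,
    event_dt: dt.date | None = None,
    fda_dt: dt.date | None = dt.date(2021, 6, 1),
    starts: dict[str, dt.date] | None = None,
    outcomes: list[str] | None = None,
    indications: list[str] | None = None,
) -> ReportCase:
    """Terse ReportCase builder for toy examples."""
    starts = starts or {}
    mentions = [
        DrugMention(name, "PS", i + 1, starts.get(name))
        for i, name in enumerate(drugs or ["somedrug"])
    ]
    return ReportCase(
        caseid=caseid,
        primaryid=caseid + "1",
        fda_dt=fda_dt,
        sex=sex,
        age_years=age_years,
        country=country,
        event_dt=event_dt,
        drugs=mentions,
        reactions=reactions or ["Headache"],
        outcomes=outcomes or [],
        indications=indications or [],
    )


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    base = dict(
        n_reports=2000,
        n_background_drugs=10,
        signal_drugs=[
            SignalDrug("signalfast", 6.0, tto_shape=1.0, tto_scale_days=10.0,
                       exposure_prob=0.05),
            SignalDrug("signalslow", 10.0, tto_shape=2.0, tto_scale_days=40.0,
                       exposure_prob=0.03),
        ],
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 2000-report synthetic dataset with two planted signals."""
    out = tmp_path_factory.mktemp("synth_small")
    config = small_config()
    paths, truth = generate_dataset(config, out)
    return {"dir": out, "paths": paths, "truth": truth, "config": config}


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Full pipeline result over the small synthetic dataset."""
    out = small_dataset["dir"]
    return run_pipeline(out, out / "drug_dictionary.tsv")
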