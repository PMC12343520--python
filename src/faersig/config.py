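"""Configuration objects for the synthetic generator and the analysis.

The synthetic generator is parameterised by :class:`SyntheticConfig`; its
defaults define the simulated reporting conditions used throughout the test
suite (a background of null-rate drugs plus planted signal drugs whose
target-event probability is ``rate_ratio * baseline_event_prob``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from faersig.errors import ConfigurationError

#: Fields of ``missing_field_rates`` that trigger report exclusion downstream.
EXCLUSION_FIELDS = ("drugname", "reaction", "demo")
#: Fields whose missingness is benign (retained with an unknown stratum).
BENIGN_FIELDS = ("age", "sex", "event_dt", "start_dt", "event_dt_partial")

DEFAULT_MISSING_RATES: dict[str, float] = {
    "drugname": 0.01,
    "reaction": 0.01,
    "demo": 0.005,
    "age": 0.30,
    "sex": 0.08,
    "event_dt": 0.15,
    "start_dt": 0.10,
    "event_dt_partial": 0.05,
}


@dataclass(frozen=True)
class SignalDrug:
    """A planted signal drug with its true reporting-rate ratio and onset law.

    The target preferred term occurs on a report exposed to this drug with
    probability ``rate_ratio * baseline_event_prob``; true time-to-onset is
    Weibull(``tto_shape``, ``tto_scale_days``), rounded up to whole days.
    Each report is exposed to the drug independently with probability
    ``exposure_prob`` (on top of its background-drug mentions).
    """

    name: str
    rate_ratio: float
    tto_shape: float = 1.0
    tto_scale_days: float = 30.0
    exposure_prob: float = 0.01


@dataclass
class SyntheticConfig:
    n_reports: int = 10_000
    n_background_drugs: int = 50
    signal_drugs: list[SignalDrug] = field(default_factory=list)
    baseline_event_prob: float = 0.08
    duplicate_rate: float = 0.05
    missing_field_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    date_error_rate: float = 0.02
    brand_alias_fraction: float = 0.30
    unmappable_fraction: float = 0.02
    seed: int = 0
    quarter_range: tuple[str, str] = ("2020Q1", "2021Q4")
    # Secondary knobs (held fixed across the study conditions).
    target_pt: str = "Neuralgia"
    concomitant_mean: float = 0.4
    background_tto_shape: float = 1.0
    background_tto_scale_days: float = 30.0
    duplicate_fda_dt_ties: bool = False

    def __post_init__(self) -> None:
        self.signal_drugs = [
            SignalDrug(**d) if isinstance(d, dict) else d for d in self.signal_drugs
        ]
        self.quarter_range = tuple(self.quarter_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be a positive integer")
        if self.n_background_drugs < 1:
            raise ConfigurationError("n_background_drugs must be a positive integer")
        if not 0.0 < self.baseline_event_prob < 1.0:
            raise ConfigurationError("baseline_event_prob must lie in (0, 1)")
        for name, value in (
            ("duplicate_rate", self.duplicate_rate),
            ("date_error_rate", self.date_error_rate),
        ):
            if not 0.0 <= value < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        for name, value in (
            ("brand_alias_fraction", self.brand_alias_fraction),
            ("unmappable_fraction", self.unmappable_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for fname, rate in self.missing_field_rates.items():
            if fname not in EXCLUSION_FIELDS + BENIGN_FIELDS:
                raise ConfigurationError(f"missing_field_rates: unknown field {fname!r}")
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"missing_field_rates[{fname!r}] must lie in [0, 1)")
        for drug in self.signal_drugs:
            if drug.rate_ratio <= 0:
                raise ConfigurationError(f"signal drug {drug.name!r}: rate_ratio must be positive")
            if drug.rate_ratio * self.baseline_event_prob > 1.0:
                raise ConfigurationError(
                    f"signal drug {drug.name!r}: rate_ratio * baseline_event_prob exceeds 1"
                )
            if drug.tto_shape <= 0 or drug.tto_scale_days <= 0:
                raise ConfigurationError(
                    f"signal drug {drug.name!r}: Weibull parameters must be positive"
                )
            if not 0.0 < drug.exposure_prob < 1.0:
                raise ConfigurationError(
                    f"signal drug {drug.name!r}: exposure_prob must lie in (0, 1)"
                )
        # The per-report error categories are drawn disjointly, so the
        # exclusion-type rates must leave room for error-free reports.
        total = (
            self.date_error_rate
            + self.unmappable_fraction
            + sum(self.missing_field_rates.get(f, 0.0) for f in EXCLUSION_FIELDS)
        )
        if total >= 1.0:
            raise ConfigurationError(
                "date_error_rate + unmappable_fraction + exclusion-type missing rates "
                "must sum to less than 1"
            )
        start, end = self.quarter_range
        for label in (start, end):
            if not _valid_quarter(label):
                raise ConfigurationError(f"quarter_range: bad quarter label {label!r}")
        if start > end:
            raise ConfigurationError("quarter_range: start quarter after end quarter")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _valid_quarter(label: str) -> bool:
    if len(label) != 6 or label[4] != "Q":
        return False
    return label[:4].isdigit() and label[5] in "1234"


@dataclass
class SignalThresholds:
    """Signal-positivity thresholds for the four algorithms.

    Defaults: ROR requires a>=3, ROR>=3 and CI lower bound > 1; PRR requires
    a>=3, PRR>=2 and CI lower bound > 1; BCPNN requires IC025 > 0; EBGM
    requires EBGM05 > 2.  A signal is jointly positive only when all four
    criteria hold.
    """

    min_a: int = 3
    ror_min: float = 3.0
    ror_ci_low_min: float = 1.0
    prr_min: float = 2.0
    prr_ci_low_min: float = 1.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML analysis configuration into a plain dictionary."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return data


def synthetic_config_from_dict(data: dict[str, Any]) -> SyntheticConfig:
    known = set(SyntheticConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown synthetic config fields: {sorted(unknown)}")
    merged_rates = dict(DEFAULT_MISSING_RATES)
    merged_rates.update(data.get("missing_field_rates", {}))
    data = {**data, "missing_field_rates": merged_rates}
    return SyntheticConfig(**data)
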