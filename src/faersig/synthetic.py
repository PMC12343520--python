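"""Synthetic FAERS-like report generator with known ground truth.

Emits quarterly ``DEMO``/``DRUG``/``REAC``/``OUTC``/``THER``/``INDI`` tables
in the FAERS ASCII dialect ($-delimited, one header row) for a simulated
reporting system, and records every planted feature in a
:class:`GroundTruth` sidecar so downstream cleaning, mapping, contingency
and time-to-onset stages can be audited exactly.

Sampling model
--------------
Every report carries one background drug drawn uniformly from the background
pool (plus a Poisson number of concomitant background mentions).  Each
planted signal drug is added to a report independently with its configured
``exposure_prob``.  The target preferred term then occurs with probability
``baseline_event_prob`` times the largest rate ratio among the report's
signal exposures (1 for unexposed reports), so background drugs report the
event at exactly the null rate while signal drugs report it at their planted
ratio.  Onset intervals for event reports follow the exposing drug's
Weibull law, rounded up to whole days, and therapy start dates are placed at
``EVENT_DT - onset`` so extraction can recover them.

Injected pathologies mirror real spontaneous data: multi-version cases
sharing a CASEID with later FDA_DT, reports missing drug/reaction/
demographic fields, implausible date orderings (event before every therapy
start), brand names requiring dictionary mapping, and unmappable drug names.
Error categories are drawn disjointly per report so every cleaning tally can
be compared to the ground truth exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from faersig.config import SignalDrug, SyntheticConfig

TABLES = ("demo", "drug", "reac", "outc", "ther", "indi")

BACKGROUND_PTS = [
    "Headache", "Nausea", "Dizziness", "Fatigue", "Rash", "Pyrexia",
    "Vomiting", "Arthralgia", "Dyspnoea", "Pruritus", "Diarrhoea",
    "Insomnia", "Anxiety", "Hypertension", "Cough",
]
INDICATIONS = [
    "Plasma cell myeloma", "Multiple sclerosis", "Depression",
    "Urinary tract infection", "Breast cancer", "Hypertension",
    "Rheumatoid arthritis", "Product used for unknown indication",
]
INDICATION_P = [0.14, 0.11, 0.09, 0.08, 0.08, 0.20, 0.10, 0.20]
COUNTRIES = ["US", "GB", "CA", "FR", "DE", "JP", "IT"]
COUNTRY_P = [0.70, 0.06, 0.04, 0.04, 0.04, 0.06, 0.06]
OUTCOME_CODES = ["HO", "OT", "DS", "DE", "LT"]
OUTCOME_P = [0.50, 0.25, 0.12, 0.08, 0.05]

ERROR_CATEGORIES = ("date_error", "missing_drug", "missing_reaction", "missing_demo", "unmappable")


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream audits."""

    n_reports: int
    baseline_event_prob: float
    #: P(target event | exposed to this drug and nothing stronger)
    drug_event_prob: dict[str, float]
    drug_tto_params: dict[str, tuple[float, float]]
    signal_drugs: list[str]
    signal_rate_ratio: dict[str, float] = field(default_factory=dict)
    signal_exposure_prob: dict[str, float] = field(default_factory=dict)
    duplicate_caseids: list[str] = field(default_factory=list)
    error_caseids: dict[str, list[str]] = field(default_factory=dict)
    #: drug -> {caseid: planted onset interval in days} for signal-driven events
    planted_tto: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def duplicate_count(self) -> int:
        return len(self.duplicate_caseids)

    def error_count(self, category: str) -> int:
        return len(self.error_caseids.get(category, []))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_reports": self.n_reports,
            "baseline_event_prob": self.baseline_event_prob,
            "drug_event_prob": self.drug_event_prob,
            "drug_tto_params": {k: list(v) for k, v in self.drug_tto_params.items()},
            "signal_drugs": self.signal_drugs,
            "signal_rate_ratio": self.signal_rate_ratio,
            "signal_exposure_prob": self.signal_exposure_prob,
            "duplicate_caseids": self.duplicate_caseids,
            "error_caseids": self.error_caseids,
            "planted_tto": self.planted_tto,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["drug_tto_params"] = {
            k: tuple(v) for k, v in payload["drug_tto_params"].items()
        }
        return cls(**payload)


def background_drug_names(n: int) -> list[str]:
    return [f"backdrug{i:03d}" for i in range(n)]


def signal_study_config(seed: int, n_reports: int = 50_000) -> SyntheticConfig:
    """The planted-signal study: 50 null background drugs plus signal drugs
    at rate ratios 3, 5 and 10.

    Exposure probabilities are set by power analysis: the weakest signal
    (ratio 3) gets a common-drug exposure (4% of reports) so its 2x2 cells
    carry enough information at this scale, while the strong signals are
    kept rare (as extreme-disproportionality drugs are in practice), which
    also limits their contamination of every other drug's comparator.
    """
    return SyntheticConfig(
        n_reports=n_reports,
        n_background_drugs=50,
        signal_drugs=[
            SignalDrug("signalmild", 3.0, tto_shape=1.0, tto_scale_days=10.0,
                       exposure_prob=0.04),
            SignalDrug("signalmoderate", 5.0, tto_shape=0.5, tto_scale_days=30.0,
                       exposure_prob=0.008),
            SignalDrug("signalstrong", 10.0, tto_shape=2.0, tto_scale_days=45.0,
                       exposure_prob=0.004),
        ],
        seed=seed,
    )


def _quarter_periods(config: SyntheticConfig) -> pd.PeriodIndex:
    start, end = config.quarter_range
    return pd.period_range(pd.Period(start, freq="Q"), pd.Period(end, freq="Q"), freq="Q")


def _fmt_dates(days: np.ndarray, blank: np.ndarray | None = None,
               partial: np.ndarray | None = None) -> pd.Series:
    """Render int epoch-day arrays as YYYYMMDD strings ('' when blank)."""
    stamps = pd.Series(pd.to_datetime(days, unit="D"))
    out = stamps.dt.strftime("%Y%m%d")
    if partial is not None:
        out = out.where(~pd.Series(partial), stamps.dt.strftime("%Y%m"))
    if blank is not None:
        out = out.mask(pd.Series(blank), "")
    return out.reset_index(drop=True)


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[dict[str, dict[str, Path]], GroundTruth]:
    """Generate quarterly FAERS-style files plus the ground-truth sidecar.

    Returns a mapping ``{quarter_label: {table: path}}`` and the
    :class:`GroundTruth`.  Also writes ``drug_dictionary.tsv`` (the local
    brand-to-generic lookup covering every mappable alias emitted) and
    ``ground_truth.json`` into ``out_dir``.  Identical config (including
    seed) yields byte-identical files.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    bg = background_drug_names(config.n_background_drugs)
    signals = list(config.signal_drugs)
    drug_names = bg + [s.name for s in signals]
    n_bg = len(bg)

    caseid = 100_000_000 + np.arange(n, dtype=np.int64)
    pid1 = caseid * 10 + 1

    periods = _quarter_periods(config)
    q_idx = rng.integers(0, len(periods), n)
    q_start = periods.start_time.asi8 // 86_400_000_000_000  # epoch days
    q_days = (periods.end_time.normalize() - periods.start_time).days.to_numpy() + 1
    fda = q_start[q_idx] + rng.integers(0, q_days[q_idx])
    event_dt = fda - rng.integers(0, 91, n)

    # --- exposure and event model
    primary = rng.integers(0, n_bg, n)
    sig_mask = [rng.random(n) < s.exposure_prob for s in signals]
    ratio = np.ones(n)
    driver = np.full(n, -1)  # index of the strongest signal exposure
    for j, s in enumerate(signals):
        upd = sig_mask[j] & (s.rate_ratio > ratio)
        ratio[upd] = s.rate_ratio
        driver[upd] = j
    has_event = rng.random(n) < config.baseline_event_prob * ratio

    shape_r = np.full(n, config.background_tto_shape)
    scale_r = np.full(n, config.background_tto_scale_days)
    for j, s in enumerate(signals):
        shape_r[driver == j] = s.tto_shape
        scale_r[driver == j] = s.tto_scale_days
    onset_w = np.maximum(1, np.ceil(scale_r * rng.weibull(shape_r)).astype(np.int64))
    onset = np.where(has_event, onset_w, rng.integers(1, 366, n))

    k_conc = rng.poisson(config.concomitant_mean, n)
    conc_report = np.repeat(np.arange(n), k_conc)
    m_conc = conc_report.size
    conc_drug = rng.integers(0, n_bg, m_conc)

    # Disjoint per-report error categories: 0 none, then ERROR_CATEGORIES order.
    rates = config.missing_field_rates
    edges = np.cumsum([
        config.date_error_rate,
        rates.get("drugname", 0.0),
        rates.get("reaction", 0.0),
        rates.get("demo", 0.0),
        config.unmappable_fraction,
    ])
    idx = np.searchsorted(edges, rng.random(n), side="right")
    category = np.where(idx < len(edges), idx + 1, 0)
    is_date_err = category == 1

    # --- drug mention assembly (primary, signal exposures, concomitants)
    mention_report = np.concatenate(
        [np.arange(n)] + [np.flatnonzero(m) for m in sig_mask] + [conc_report]
    )
    mention_drug = np.concatenate(
        [primary]
        + [np.full(int(m.sum()), n_bg + j) for j, m in enumerate(sig_mask)]
        + [conc_drug]
    )
    seg_prio = np.concatenate(
        [np.zeros(n, dtype=np.int64)]
        + [np.full(int(m.sum()), 1 + j) for j, m in enumerate(sig_mask)]
        + [np.full(m_conc, 1 + len(signals))]
    )
    mention_role = np.where(seg_prio <= len(signals), "PS", "C")
    m = mention_report.size
    # Therapy start: the event-driving mention starts onset days before the
    # event; all other mentions start at an unrelated earlier date.
    drives = np.zeros(m, dtype=bool)
    drives[:n] = has_event & (driver == -1)  # background-driven events
    offset = n
    for j, s in enumerate(signals):
        rows = np.flatnonzero(sig_mask[j])
        drives[offset:offset + rows.size] = (driver[rows] == j) & has_event[rows]
        offset += rows.size
    mention_start = np.where(
        drives,
        event_dt[mention_report] - onset[mention_report],
        event_dt[mention_report] - rng.integers(1, 366, m),
    )
    order = np.lexsort((seg_prio, mention_report))
    mention_report = mention_report[order]
    mention_drug = mention_drug[order]
    mention_role = mention_role[order]
    mention_start = mention_start[order]
    counts = np.bincount(mention_report, minlength=n)
    mention_seq = np.arange(m) - np.repeat(np.cumsum(counts) - counts, counts) + 1

    # Implausible ordering: event strictly before every therapy start.
    min_start = np.full(n, np.iinfo(np.int64).max)
    np.minimum.at(min_start, mention_report, mention_start)
    event_dt = np.where(is_date_err, min_start - rng.integers(1, 101, n), event_dt)

    miss_age = rng.random(n) < rates.get("age", 0.0)
    miss_sex = rng.random(n) < rates.get("sex", 0.0)
    miss_event = (rng.random(n) < rates.get("event_dt", 0.0)) & ~is_date_err
    partial_event = (
        (rng.random(n) < rates.get("event_dt_partial", 0.0)) & ~is_date_err & ~miss_event
    )
    mention_start_blank = (
        (rng.random(m) < rates.get("start_dt", 0.0)) & ~is_date_err[mention_report]
    )

    sex = np.where(rng.random(n) < 0.58, "F", "M")
    sex = np.where(miss_sex, "", sex)
    age_years = rng.integers(1, 96, n)
    age_in_months = rng.random(n) < 0.03
    age_val = np.where(age_in_months, age_years * 12, age_years).astype(str)
    age_cod = np.where(age_in_months, "MON", "YR")
    age_val = np.where(miss_age, "", age_val)
    age_cod = np.where(miss_age, "", age_cod)
    country = rng.choice(COUNTRIES, n, p=COUNTRY_P)

    # Drug-name rendering: brand aliases, mixed case, occasional form/dose suffix.
    generic = pd.Series(np.array(drug_names, dtype=object)[mention_drug])
    use_brand = rng.random(m) < config.brand_alias_fraction
    names = generic.str.upper().where(~use_brand, "BR-" + generic.str.upper())
    style = rng.integers(0, 3, m)
    names = names.where(style != 0, names.str.lower())
    names = names.where(style != 1, names.str.title())
    suffix_u = rng.random(m)
    names = names.where(suffix_u >= 0.05, names + " 10MG")
    names = names.where((suffix_u < 0.05) | (suffix_u >= 0.10), names + " TABLET")
    # Unmappable injection replaces the first mention's name outright.
    unmappable_rows = np.flatnonzero((category[mention_report] == 5) & (mention_seq == 1))
    names.iloc[unmappable_rows] = [
        f"XC-{caseid[mention_report[i]]}" for i in unmappable_rows
    ]
    names = names.where(pd.Series(category[mention_report] != 2), "")

    # REAC rows: the target PT for event reports plus 1-3 background PTs.
    n_extra = 1 + (rng.random(n) < 0.6).astype(int) + (rng.random(n) < 0.3).astype(int)
    extra_report = np.repeat(np.arange(n), n_extra)
    extra_pt = rng.choice(BACKGROUND_PTS, extra_report.size)
    reac_report = np.concatenate([np.flatnonzero(has_event), extra_report])
    reac_pt = np.concatenate(
        [np.repeat(config.target_pt, int(has_event.sum())), extra_pt]
    )
    keep_reac = category[reac_report] != 3
    reac_report, reac_pt = reac_report[keep_reac], reac_pt[keep_reac]

    has_outc1 = rng.random(n) < 0.25
    outc1 = rng.choice(OUTCOME_CODES, n, p=OUTCOME_P)
    has_outc2 = has_outc1 & (rng.random(n) < 0.20)
    outc2 = rng.choice(OUTCOME_CODES, n, p=OUTCOME_P)
    outc_report = np.concatenate([np.flatnonzero(has_outc1), np.flatnonzero(has_outc2)])
    outc_code = np.concatenate([outc1[has_outc1], outc2[has_outc2]])

    has_indi = rng.random(n) < 0.6
    indi_report = np.flatnonzero(has_indi)
    indi_pt = rng.choice(INDICATIONS, indi_report.size, p=INDICATION_P)

    ther_end = mention_start + rng.integers(1, 201, m)
    ther_end_blank = rng.random(m) < 0.5

    # Duplicate versions: re-emit a full copy of the case under a later
    # (or, with the tie flag, equal) FDA_DT and a new primaryid.
    dup_eligible = category != 4  # a case absent from DEMO cannot be versioned
    dup_mask = (rng.random(n) < config.duplicate_rate) & dup_eligible
    dup_reports = np.flatnonzero(dup_mask)
    pid2 = caseid * 10 + 2
    fda2 = fda if config.duplicate_fda_dt_ties else fda + rng.integers(1, 201, n)

    pid_str = pid1.astype(str)

    def emit(table: pd.DataFrame, report_col: np.ndarray) -> pd.DataFrame:
        """Duplicate v1 rows for duplicated reports under the v2 primaryid."""
        take = np.isin(report_col, dup_reports)
        v2 = table[take].copy()
        v2["primaryid"] = pid2[report_col[take]].astype(str)
        v2["_report"] = report_col[take]
        v2["_version"] = 2
        table = table.copy()
        table["_report"] = report_col
        table["_version"] = 1
        return pd.concat([table, v2], ignore_index=True)

    demo = pd.DataFrame({
        "primaryid": pid_str,
        "caseid": caseid.astype(str),
        "fda_dt": _fmt_dates(fda),
        "event_dt": _fmt_dates(event_dt, blank=miss_event, partial=partial_event),
        "sex": sex,
        "age": age_val,
        "age_cod": age_cod,
        "occr_country": country,
    })
    demo = demo[category != 4].reset_index(drop=True)
    demo = emit(demo, np.flatnonzero(category != 4))
    v2_rows = demo["_version"] == 2
    demo.loc[v2_rows, "fda_dt"] = _fmt_dates(
        fda2[demo.loc[v2_rows, "_report"].to_numpy()]
    ).to_numpy()

    drug_tbl = emit(
        pd.DataFrame({
            "primaryid": pid_str[mention_report],
            "drug_seq": mention_seq.astype(str),
            "drugname": names.to_numpy(),
            "role_cod": mention_role,
        }),
        mention_report,
    )
    reac_tbl = emit(
        pd.DataFrame({"primaryid": pid_str[reac_report], "pt": reac_pt}), reac_report
    )
    outc_tbl = emit(
        pd.DataFrame({"primaryid": pid_str[outc_report], "outc_cod": outc_code}),
        outc_report,
    )
    ther_tbl = emit(
        pd.DataFrame({
            "primaryid": pid_str[mention_report],
            "dsg_drug_seq": mention_seq.astype(str),
            "start_dt": _fmt_dates(mention_start, blank=mention_start_blank),
            "end_dt": _fmt_dates(ther_end, blank=ther_end_blank),
        }),
        mention_report,
    )
    indi_tbl = emit(
        pd.DataFrame({
            "primaryid": pid_str[indi_report],
            "indi_drug_seq": np.ones(indi_report.size, dtype=np.int64).astype(str),
            "indi_pt": indi_pt,
        }),
        indi_report,
    )

    # File placement: each version goes to the quarter of its own FDA_DT,
    # clipped into the configured range.
    q2 = np.minimum(
        np.searchsorted(q_start, fda2, side="right") - 1, len(periods) - 1
    )

    def quarter_labels(tbl: pd.DataFrame) -> np.ndarray:
        qi = np.where(tbl["_version"] == 1, q_idx[tbl["_report"]], q2[tbl["_report"]])
        return periods[qi].strftime("%yQ%q").to_numpy()

    tables = {
        "demo": demo, "drug": drug_tbl, "reac": reac_tbl,
        "outc": outc_tbl, "ther": ther_tbl, "indi": indi_tbl,
    }
    paths: dict[str, dict[str, Path]] = {}
    labels = periods.strftime("%yQ%q")
    for name, tbl in tables.items():
        tbl["_quarter"] = quarter_labels(tbl)
    for label in labels:
        paths[label] = {}
        for name, tbl in tables.items():
            sub = tbl[tbl["_quarter"] == label].drop(
                columns=["_report", "_version", "_quarter"]
            )
            path = out_dir / f"{name.upper()}{label}.txt"
            sub.to_csv(path, sep="$", index=False, lineterminator="\n")
            paths[label][name] = path

    write_dictionary(drug_names, out_dir / "drug_dictionary.tsv")

    err_ids: dict[str, list[str]] = {}
    for code, cname in enumerate(ERROR_CATEGORIES, start=1):
        err_ids[cname] = caseid[category == code].astype(str).tolist()
    planted: dict[str, dict[str, int]] = {}
    for j, s in enumerate(signals):
        mask = (driver == j) & has_event
        planted[s.name] = {str(caseid[i]): int(onset[i]) for i in np.flatnonzero(mask)}
    truth = GroundTruth(
        n_reports=n,
        baseline_event_prob=config.baseline_event_prob,
        drug_event_prob={
            **{d: config.baseline_event_prob for d in bg},
            **{s.name: s.rate_ratio * config.baseline_event_prob for s in signals},
        },
        drug_tto_params={
            **{d: (config.background_tto_shape, config.background_tto_scale_days) for d in bg},
            **{s.name: (s.tto_shape, s.tto_scale_days) for s in signals},
        },
        signal_drugs=[s.name for s in signals],
        signal_rate_ratio={s.name: s.rate_ratio for s in signals},
        signal_exposure_prob={s.name: s.exposure_prob for s in signals},
        duplicate_caseids=caseid[dup_mask].astype(str).tolist(),
        error_caseids=err_ids,
        planted_tto=planted,
    )
    truth.to_json(out_dir / "ground_truth.json")
    return paths, truth


def write_dictionary(generics: list[str], path: str | Path) -> Path:
    """Write the alias->generic lookup covering every mappable emitted alias."""
    rows = []
    for g in sorted(generics):
        rows.append((g.upper(), g))
        rows.append(("BR-" + g.upper(), g))
    pd.DataFrame(rows, columns=["alias", "generic"]).to_csv(path, sep="\t", index=False)
    return Path(path)


def planted_tto_sample(drug: str, truth: GroundTruth, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` onset intervals (whole days, >= 1) from a drug's true law."""
    if drug not in truth.drug_tto_params:
        raise LookupError(f"unknown drug {drug!r}")
    shape, scale = truth.drug_tto_params[drug]
    rng = np.random.default_rng(seed)
    draws = scale * rng.weibull(shape, n)
    return np.maximum(1, np.ceil(draws)).astype(np.int64)


def expected_event_prob(truth: GroundTruth) -> float:
    """Marginal P(target event) under the generator's sampling model.

    Exact enumeration over signal-exposure subsets (each signal drug is an
    independent Bernoulli exposure; the event factor is the largest exposed
    rate ratio).
    """
    names = truth.signal_drugs
    total = 0.0
    for subset in itertools.product([False, True], repeat=len(names)):
        prob = 1.0
        factor = 1.0
        for exposed, name in zip(subset, names):
            w = truth.signal_exposure_prob[name]
            prob *= w if exposed else 1.0 - w
            if exposed:
                factor = max(factor, truth.signal_rate_ratio[name])
        total += prob * factor
    return truth.baseline_event_prob * total


def ror_mc_envelope(
    truth: GroundTruth,
    drug: str,
    n_reports: int | None = None,
    n_sims: int = 2000,
    level: float = 0.99,
    seed: int = 12345,
) -> tuple[float, float]:
    """Monte-Carlo envelope for the ROR of a planted signal drug.

    Re-simulates the generator's own 2x2 sampling model (independent
    Bernoulli exposure at the drug's ``exposure_prob``, Bernoulli target
    events at the exposed and unexposed probabilities) ``n_sims`` times and
    returns the central ``level`` interval of the resulting ROR estimates.
    """
    if drug not in truth.signal_exposure_prob:
        raise LookupError(f"unknown signal drug {drug!r}")
    n = truth.n_reports if n_reports is None else n_reports
    w = truth.signal_exposure_prob[drug]
    p_exposed = truth.drug_event_prob[drug]
    marginal = expected_event_prob(truth)
    p_other = (marginal - w * p_exposed) / (1.0 - w)
    rng = np.random.default_rng(seed)
    n_exp = rng.binomial(n, w, n_sims)
    a = rng.binomial(n_exp, p_exposed)
    c = n_exp - a
    b = rng.binomial(n - n_exp, p_other)
    d = n - n_exp - b
    a, b, c, d = (x.astype(float) for x in (a, b, c, d))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    for x in (a, b, c, d):
        x[zero] += 0.5
    ror = a * d / (b * c)
    lo, hi = np.quantile(ror, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
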