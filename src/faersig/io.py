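"""Reading, deduplicating and cleaning FAERS-style quarterly files.

The FAERS ASCII dialect is $-delimited text with one header row.  Reading is
tolerant: unknown columns are ignored, data lines whose field count differs
from the header are tallied as unparseable rather than loaded, and cleaning
never raises on bad content — every removal is recorded in a
:class:`CleaningLog` whose totals reconcile exactly with the input.

The cleaning rules are the standard spontaneous-report validity screen:
keep one version per CASEID (the one with the latest FDA_DT, ties broken by
the larger primaryid), then exclude reports lacking any drug identifier,
lacking adverse-event terms, lacking a demographic row, or with an
implausible date ordering (event onset strictly before every parseable
therapy start date).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from faersig.errors import FormatError

MANDATORY_TABLES = ("demo", "drug", "reac")
OPTIONAL_TABLES = ("outc", "ther", "indi", "rpsr")

SEX_LABELS = {"F": "female", "M": "male"}
#: years per unit for FAERS age codes
AGE_UNIT_YEARS = {
    "YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25, "HR": 1.0 / (24.0 * 365.25), "": 1.0,
}


def parse_faers_date(value: str | None) -> dt.date | None:
    """Parse an 8-digit YYYYMMDD string to a date; anything else is None.

    Partial precisions (YYYYMM, YYYY) are deliberately treated as missing
    here: interval arithmetic and the implausibility screen need day
    precision.  Use :func:`date_year` for trend counting.
    """
    if value is None:
        return None
    value = value.strip()
    if len(value) != 8 or not value.isdigit():
        return None
    try:
        return dt.date(int(value[:4]), int(value[4:6]), int(value[6:8]))
    except ValueError:
        return None


def date_year(value: str | None) -> int | None:
    """Year of a FAERS date at any precision (YYYYMMDD, YYYYMM or YYYY)."""
    if value is None:
        return None
    value = value.strip()
    if len(value) in (4, 6, 8) and value.isdigit():
        year = int(value[:4])
        if 1900 <= year <= 2100:
            return year
    return None


@dataclass
class RawQuarter:
    """Raw string records of one quarter, plus unparseable-line tallies."""

    quarter: str
    tables: dict[str, pd.DataFrame]
    unparseable: dict[str, int] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        tbl = self.tables.get(name)
        if tbl is None:
            return pd.DataFrame(columns=["primaryid"])
        return tbl


@dataclass
class DrugMention:
    raw_name: str
    role: str
    seq: int
    start_dt: dt.date | None = None
    start_dt_raw: str = ""


@dataclass
class ReportCase:
    """One deduplicated, cleaned spontaneous report."""

    caseid: str
    primaryid: str
    fda_dt: dt.date | None
    sex: str = "unknown"
    age_years: float | None = None
    country: str | None = None
    event_dt: dt.date | None = None
    event_dt_raw: str = ""
    drugs: list[DrugMention] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    indications: list[str] = field(default_factory=list)

    def drug_names(self) -> set[str]:
        return {d.raw_name for d in self.drugs if d.raw_name}


@dataclass
class CleaningLog:
    """Per-rule removal tallies; input = retained + sum of removals."""

    total_input: int = 0
    retained: int = 0
    duplicates_superseded: int = 0
    missing_drug: int = 0
    missing_reaction: int = 0
    missing_demo: int = 0
    implausible_dates: int = 0
    unparseable: int = 0
    unparseable_lines: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.duplicates_superseded + self.missing_drug + self.missing_reaction
            + self.missing_demo + self.implausible_dates + self.unparseable
        )

    def is_reconciled(self) -> bool:
        return self.total_input == self.retained + self.total_removed

    def as_dict(self) -> dict[str, int]:
        return {
            "total_input": self.total_input,
            "retained": self.retained,
            "duplicates_superseded": self.duplicates_superseded,
            "missing_drug": self.missing_drug,
            "missing_reaction": self.missing_reaction,
            "missing_demo": self.missing_demo,
            "implausible_dates": self.implausible_dates,
            "unparseable": self.unparseable,
            "unparseable_lines": self.unparseable_lines,
        }


def _read_dollar_file(path: Path) -> tuple[pd.DataFrame, int]:
    """Read one $-delimited file; lines with the wrong field count are
    tallied and skipped, never loaded."""
    text = path.read_text()
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FormatError(f"{path}: empty file, no header")
    header = lines[0]
    n_fields = header.count("$") + 1
    good = [header]
    bad = 0
    for line in lines[1:]:
        if line.count("$") + 1 == n_fields:
            good.append(line)
        else:
            bad += 1
    frame = pd.read_csv(
        StringIO("\n".join(good)), sep="$", dtype=str, keep_default_na=False,
        engine="c",
    )
    frame.columns = [c.strip().lower() for c in frame.columns]
    if "primaryid" not in frame.columns:
        raise FormatError(f"{path}: header lacks 'primaryid'")
    return frame, bad


def read_quarter(paths: Mapping[str, str | Path], quarter: str = "") -> RawQuarter:
    """Read one quarter's files given a mapping ``{table_name: path}``.

    ``demo``, ``drug`` and ``reac`` are mandatory; other tables are loaded
    when present.  Raises ``FileNotFoundError`` for a missing mandatory file
    and :class:`~faersig.errors.FormatError` for a header without primaryid.
    """
    for name in MANDATORY_TABLES:
        if name not in paths:
            raise FileNotFoundError(f"quarter {quarter or '?'}: missing mandatory table {name!r}")
    tables: dict[str, pd.DataFrame] = {}
    unparseable: dict[str, int] = {}
    for name, path in paths.items():
        path = Path(path)
        if name in MANDATORY_TABLES and not path.exists():
            raise FileNotFoundError(f"missing mandatory file {path}")
        if not path.exists():
            continue
        tables[name], unparseable[name] = _read_dollar_file(path)
    return RawQuarter(quarter=quarter, tables=tables, unparseable=unparseable)


def find_quarters(directory: str | Path) -> list[RawQuarter]:
    """Load every quarter found in a directory of ``DEMOyyQq.txt``-style files."""
    directory = Path(directory)
    labels = sorted(
        p.name[len("DEMO"):-len(".txt")] for p in directory.glob("DEMO*.txt")
    )
    quarters = []
    for label in labels:
        paths = {
            name: directory / f"{name.upper()}{label}.txt"
            for name in MANDATORY_TABLES + OPTIONAL_TABLES
            if (directory / f"{name.upper()}{label}.txt").exists()
        }
        quarters.append(read_quarter(paths, quarter=label))
    return quarters


def deduplicate(demo: pd.DataFrame) -> tuple[pd.Index, dict[str, int]]:
    """Keep one primaryid per caseid — the latest FDA_DT, ties to the larger
    primaryid.  Returns kept primaryids and a log fragment with
    ``duplicates_superseded`` and ``unparseable`` (caseids whose every
    version has an unparseable FDA_DT).
    """
    if demo.empty:
        return pd.Index([], dtype=object), {"duplicates_superseded": 0, "unparseable": 0}
    work = demo[["primaryid", "caseid", "fda_dt"]].copy()
    work["_fda"] = pd.to_numeric(work["fda_dt"].str.strip(), errors="coerce")
    work.loc[work["fda_dt"].str.strip().str.len() != 8, "_fda"] = np.nan
    work["_pid"] = pd.to_numeric(work["primaryid"], errors="coerce")
    valid = work["_fda"].notna()
    bad_rows = int((~valid & work["caseid"].isin(
        work.loc[valid, "caseid"])).sum())
    candidates = work[valid].sort_values(["_fda", "_pid"], kind="mergesort")
    kept = candidates.groupby("caseid", sort=False).tail(1)
    superseded = int(len(candidates) - len(kept)) + bad_rows
    frag = {
        "duplicates_superseded": superseded,
        "unparseable": int((~valid).sum()) - bad_rows,
    }
    assert frag["unparseable"] >= 0 and len(demo) == len(kept) + superseded + frag["unparseable"]
    return pd.Index(kept["primaryid"]), frag


def clean_and_join(
    quarters: Sequence[RawQuarter],
    kept_ids: pd.Index | None = None,
) -> tuple[list[ReportCase], CleaningLog]:
    """Deduplicate, apply the validity exclusions, and join into report cases.

    ``kept_ids`` may be supplied to reuse an earlier deduplication; by
    default deduplication is performed here (dedup first, then exclusions).
    """
    log = CleaningLog()
    concat: dict[str, pd.DataFrame] = {}
    for name in MANDATORY_TABLES + OPTIONAL_TABLES:
        frames = [q.tables[name] for q in quarters if name in q.tables]
        concat[name] = (
            pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["primaryid"])
        )
    log.unparseable_lines = sum(sum(q.unparseable.values()) for q in quarters)

    demo = concat["demo"]
    if kept_ids is None:
        kept_ids, frag = deduplicate(demo)
        log.duplicates_superseded = frag["duplicates_superseded"]
        log.unparseable = frag["unparseable"]

    # Reports appearing only outside DEMO lack demographics entirely.
    demo_ids = set(demo["primaryid"]) if not demo.empty else set()
    other_ids: set[str] = set()
    for name in ("drug", "reac"):
        tbl = concat[name]
        if not tbl.empty:
            other_ids.update(tbl["primaryid"])
    orphan_ids = other_ids - demo_ids
    log.missing_demo = len(orphan_ids)
    log.total_input = len(demo) + len(orphan_ids)

    kept = demo[demo["primaryid"].isin(set(kept_ids))].drop_duplicates("primaryid")

    def rows_by_id(name: str, columns: Iterable[str]) -> dict[str, list[tuple]]:
        tbl = concat[name]
        if tbl.empty:
            return {}
        cols = [c for c in columns if c in tbl.columns]
        sub = tbl[tbl["primaryid"].isin(set(kept["primaryid"]))]
        out: dict[str, list[tuple]] = {}
        for row in sub[["primaryid", *cols]].itertuples(index=False, name=None):
            out.setdefault(row[0], []).append(row[1:])
        return out

    drug_rows = rows_by_id("drug", ["drug_seq", "drugname", "role_cod"])
    reac_rows = rows_by_id("reac", ["pt"])
    outc_rows = rows_by_id("outc", ["outc_cod"])
    ther_rows = rows_by_id("ther", ["dsg_drug_seq", "start_dt", "end_dt"])
    indi_rows = rows_by_id("indi", ["indi_pt"])

    cases: list[ReportCase] = []
    for row in kept.itertuples(index=False):
        pid = row.primaryid
        drugs_raw = drug_rows.get(pid, [])
        names = [r[1].strip() for r in drugs_raw if len(r) > 1]
        if not drugs_raw or not any(names):
            log.missing_drug += 1
            continue
        reacs = [r[0].strip() for r in reac_rows.get(pid, [])]
        reacs = [r for r in reacs if r]
        if not reacs:
            log.missing_reaction += 1
            continue

        event_raw = getattr(row, "event_dt", "") or ""
        event = parse_faers_date(event_raw)
        starts_by_seq: dict[str, tuple[dt.date | None, str]] = {}
        start_dates: list[dt.date] = []
        for t in ther_rows.get(pid, []):
            seq = t[0].strip() if t else ""
            raw = t[1].strip() if len(t) > 1 else ""
            parsed = parse_faers_date(raw)
            prev = starts_by_seq.get(seq)
            if prev is None or (parsed is not None and (prev[0] is None or parsed < prev[0])):
                starts_by_seq[seq] = (parsed, raw)
            if parsed is not None:
                start_dates.append(parsed)
        # Implausible ordering: event strictly before every parseable start.
        if event is not None and start_dates and all(event < s for s in start_dates):
            log.implausible_dates += 1
            continue

        mentions = []
        for t in drugs_raw:
            seq = (t[0] or "").strip()
            name = (t[1] or "").strip() if len(t) > 1 else ""
            role = (t[2] or "").strip() if len(t) > 2 else ""
            sd, sd_raw = starts_by_seq.get(seq, (None, ""))
            try:
                seq_i = int(seq)
            except ValueError:
                seq_i = 0
            mentions.append(DrugMention(name, role, seq_i, sd, sd_raw))

        cases.append(ReportCase(
            caseid=getattr(row, "caseid", pid),
            primaryid=pid,
            fda_dt=parse_faers_date(getattr(row, "fda_dt", "")),
            sex=SEX_LABELS.get((getattr(row, "sex", "") or "").strip().upper(), "unknown"),
            age_years=_parse_age(getattr(row, "age", ""), getattr(row, "age_cod", "")),
            country=(getattr(row, "occr_country", "") or "").strip() or None,
            event_dt=event,
            event_dt_raw=event_raw.strip(),
            drugs=mentions,
            reactions=reacs,
            outcomes=[o[0].strip() for o in outc_rows.get(pid, []) if o[0].strip()],
            indications=[i[0].strip() for i in indi_rows.get(pid, []) if i[0].strip()],
        ))
    log.retained = len(cases)
    return cases, log


def _parse_age(age: str, age_cod: str) -> float | None:
    age = (age or "").strip()
    if not age:
        return None
    try:
        value = float(age)
    except ValueError:
        return None
    unit = AGE_UNIT_YEARS.get((age_cod or "").strip().upper())
    if unit is None or value < 0:
        return None
    return value * unit


def write_cases_tsv(cases: Sequence[ReportCase], path: str | Path) -> Path:
    """Serialize cleaned cases: one row per report-drug-reaction triple,
    ISO-8601 dates."""
    rows = []
    for case in cases:
        for mention in case.drugs:
            for pt in case.reactions:
                rows.append({
                    "caseid": case.caseid,
                    "primaryid": case.primaryid,
                    "fda_dt": case.fda_dt.isoformat() if case.fda_dt else "",
                    "sex": case.sex,
                    "age_years": "" if case.age_years is None else f"{case.age_years:g}",
                    "country": case.country or "",
                    "event_dt": case.event_dt.isoformat() if case.event_dt else "",
                    "drug": mention.raw_name,
                    "role": mention.role,
                    "start_dt": mention.start_dt.isoformat() if mention.start_dt else "",
                    "reaction": pt,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
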