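"""Case definition by MedDRA preferred term and 2x2 contingency tables.

The counting unit is the unique report: a report mentioning a drug any
number of times contributes once to that drug's margin, and the four cells
partition all retained reports —

====================  ================  ===============
Counts of reports     Drug of interest  All other drugs
====================  ================  ===============
Event of interest     a                 b
All other events      c                 d
====================  ================  ===============
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from faersig.errors import ConfigurationError
from faersig.io import ReportCase


@dataclass(frozen=True)
class CaseDefinition:
    """A set of preferred terms (and optional MedDRA codes) defining the event.

    Matching is case-insensitive on the exact PT string, or exact on the
    numeric code when reaction fields carry codes.
    """

    pt_terms: frozenset[str]
    pt_codes: frozenset[str] = frozenset()
    label: str = "event"

    def __post_init__(self) -> None:
        if not self.pt_terms and not self.pt_codes:
            raise ConfigurationError("case definition needs at least one PT term or code")
        object.__setattr__(
            self, "pt_terms", frozenset(t.strip().lower() for t in self.pt_terms)
        )
        object.__setattr__(
            self, "pt_codes", frozenset(str(c).strip() for c in self.pt_codes)
        )

    def matches(self, reaction: str) -> bool:
        reaction = reaction.strip()
        return reaction.lower() in self.pt_terms or reaction in self.pt_codes


#: Default case definition: the PT "neuralgia", MedDRA code 10029223.
NEURALGIA = CaseDefinition(
    pt_terms=frozenset({"neuralgia"}), pt_codes=frozenset({"10029223"}), label="neuralgia"
)


def is_case(report: ReportCase, definition: CaseDefinition) -> bool:
    """True iff any reaction PT of the report matches the case definition."""
    return any(definition.matches(r) for r in report.reactions)


@dataclass
class ContingencyTable:
    """2x2 report counts for one drug against one event-term set."""

    a: int
    b: int
    c: int
    d: int
    drug: str = ""
    case_label: str = "event"
    flagged: str = ""

    def __post_init__(self) -> None:
        for cell, value in zip("abcd", (self.a, self.b, self.c, self.d)):
            if value < 0:
                raise ValueError(f"cell {cell} is negative ({value})")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def build_table(
    drug: str, cases: Sequence[ReportCase], definition: CaseDefinition
) -> ContingencyTable:
    """Count the 2x2 cells for one drug over all retained reports."""
    if not cases:
        raise ValueError("no cases supplied")
    a = b = c = d = 0
    for report in cases:
        has_drug = drug in report.drug_names()
        has_event = is_case(report, definition)
        if has_drug and has_event:
            a += 1
        elif has_event:
            b += 1
        elif has_drug:
            c += 1
        else:
            d += 1
    flagged = "drug absent from dataset" if a + c == 0 else ""
    return ContingencyTable(a, b, c, d, drug=drug, case_label=definition.label, flagged=flagged)


def all_tables(
    cases: Sequence[ReportCase],
    definition: CaseDefinition,
    min_a: int = 3,
    roles: Iterable[str] | None = None,
) -> list[ContingencyTable]:
    """One table per distinct drug with ``a >= min_a``.

    Tables are ordered by descending a, then drug name.  ``roles`` optionally
    restricts which drug roles count toward exposure (e.g. ``{"PS", "SS"}``
    for suspect-only); default counts all roles.
    """
    role_set = {r.upper() for r in roles} if roles is not None else None
    n_total = len(cases)
    n_cases = 0
    a_counts: dict[str, int] = {}
    totals: dict[str, int] = {}
    for report in cases:
        if role_set is None:
            drugs = report.drug_names()
        else:
            drugs = {
                m.raw_name for m in report.drugs
                if m.raw_name and m.role.upper() in role_set
            }
        event = is_case(report, definition)
        n_cases += event
        for drug in drugs:
            totals[drug] = totals.get(drug, 0) + 1
            if event:
                a_counts[drug] = a_counts.get(drug, 0) + 1
    tables = []
    for drug, total in totals.items():
        a = a_counts.get(drug, 0)
        if a < min_a:
            continue
        c = total - a
        b = n_cases - a
        d = n_total - a - b - c
        tables.append(ContingencyTable(a, b, c, d, drug=drug, case_label=definition.label))
    tables.sort(key=lambda t: (-t.a, t.drug))
    return tables
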