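"""Brand-to-generic drug-name normalization via a local dictionary.

Reported drug names arrive in mixed case, with stray whitespace and
dose/form suffixes, and often as brand names.  Names are normalized
(uppercase, trimmed, collapsed, suffix-stripped) and looked up in a
two-column alias->generic dictionary; by default a report containing any
unmappable mention is excluded entirely as invalid, mirroring common
pharmacovigilance practice, with a mention-level drop available for
sensitivity analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from faersig.errors import ConfigurationError
from faersig.io import ReportCase

#: Trailing tokens stripped during normalization (dose strengths are matched
#: by pattern, forms by literal token).
DEFAULT_SUFFIX_TOKENS = frozenset({
    "TABLET", "TABLETS", "TAB", "CAPSULE", "CAPSULES", "CAP", "INJECTION",
    "INJ", "SOLUTION", "CREAM", "GEL", "ORAL", "SYRUP", "PATCH",
})
DOSE_TOKEN_RE = re.compile(r"^\d+(\.\d+)?(MG|MCG|G|ML|IU|%|MG/ML)$")


def normalize_name(
    raw: str, suffix_tokens: Iterable[str] = DEFAULT_SUFFIX_TOKENS
) -> str:
    """Normalize a reported drug name to its dictionary alias form.

    Uppercases, strips surrounding whitespace and quotes, collapses internal
    whitespace, and removes trailing dose/form tokens.  Returns '' when
    nothing survives (the mention is then unmappable).
    """
    tokens = raw.strip().strip("'\"").upper().split()
    suffixes = {t.upper() for t in suffix_tokens}
    while tokens and (tokens[-1] in suffixes or DOSE_TOKEN_RE.match(tokens[-1])):
        tokens.pop()
    return " ".join(tokens)


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one report-drug mention."""

    primaryid: str
    raw_name: str
    alias: str
    generic: str | None

    @property
    def unmapped(self) -> bool:
        return self.generic is None


class DrugDictionary:
    """Alias -> generic lookup; every generic also maps to itself."""

    def __init__(self, mapping: dict[str, str], provenance: str = "local") -> None:
        self.provenance = provenance
        self._map: dict[str, str] = {}
        for alias, generic in mapping.items():
            norm = normalize_name(alias)
            if not norm:
                continue
            existing = self._map.get(norm)
            if existing is not None and existing != generic:
                raise ConfigurationError(
                    f"dictionary: alias {norm!r} maps to both {existing!r} and {generic!r}"
                )
            self._map[norm] = generic
        for generic in list(self._map.values()):
            self._map.setdefault(normalize_name(generic), generic)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, raw: str) -> bool:
        return normalize_name(raw) in self._map

    def lookup(self, raw: str) -> str | None:
        return self._map.get(normalize_name(raw))

    @property
    def generics(self) -> set[str]:
        return set(self._map.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugDictionary":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        cols = [c.strip().lower() for c in frame.columns]
        frame.columns = cols
        if "alias" not in cols or "generic" not in cols:
            raise ConfigurationError(f"{path}: dictionary needs 'alias' and 'generic' columns")
        return cls(dict(zip(frame["alias"], frame["generic"])), provenance=str(path))


def map_to_generic(
    cases: Sequence[ReportCase],
    dictionary: DrugDictionary,
    policy: Literal["exclude-report", "drop-mention"] = "exclude-report",
) -> tuple[list[ReportCase], int, list[MappingResult]]:
    """Replace every drug mention by its generic name.

    With the default ``exclude-report`` policy a report with at least one
    unmappable mention is excluded entirely; ``drop-mention`` instead drops
    only the offending mentions (excluding the report if none survive).
    Returns (mapped cases, excluded report count, per-mention audit).
    """
    if len(dictionary) == 0:
        raise ConfigurationError("drug dictionary is empty")
    if policy not in ("exclude-report", "drop-mention"):
        raise ConfigurationError(f"unknown mapping policy {policy!r}")
    mapped: list[ReportCase] = []
    audit: list[MappingResult] = []
    excluded = 0
    for case in cases:
        new_mentions = []
        any_unmapped = False
        for mention in case.drugs:
            if not mention.raw_name.strip():
                continue  # blank mentions carry no identity; cleaning kept the report
            alias = normalize_name(mention.raw_name)
            generic = dictionary.lookup(mention.raw_name) if alias else None
            audit.append(MappingResult(case.primaryid, mention.raw_name, alias, generic))
            if generic is None:
                any_unmapped = True
            else:
                new_mentions.append(replace(mention, raw_name=generic))
        if (any_unmapped and policy == "exclude-report") or not new_mentions:
            excluded += 1
            continue
        mapped.append(replace(case, drugs=new_mentions))
    return mapped, excluded, audit


def write_mapping_audit(audit: Sequence[MappingResult], path: str | Path) -> Path:
    pd.DataFrame(
        [
            {
                "primaryid": r.primaryid,
                "raw_name": r.raw_name,
                "alias": r.alias,
                "generic": r.generic if r.generic is not None else "UNMAPPED",
            }
            for r in audit
        ]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)
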