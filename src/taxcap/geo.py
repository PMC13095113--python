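"""Per-country counts of distinct collector/identifier agent strings.

Occurrence records carry free-text recordedBy/identifiedBy strings naming the
people (or organisations, or expeditions) who collected and identified
specimens. Distinctness is on the verbatim string (outer whitespace trimmed,
no case folding), because the field is an uncontrolled text string and any
normalisation silently conflates different agents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

MISMATCH_ISSUE = "COUNTRY_COORDINATE_MISMATCH"


@dataclass
class OccurrenceRecord:
    country_code: str
    year: int | None
    occurrence_status: str
    issues: set[str] = field(default_factory=set)
    recorded_by: str = ""
    identified_by: str = ""


@dataclass
class CountryAgentSummary:
    country_code: str
    n_records: int
    n_distinct_recorded_by: int
    n_distinct_identified_by: int


def read_occurrences_tsv(path) -> list[OccurrenceRecord]:
    """Read a Darwin-Core-termed occurrence table (one row per record)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        year_text = row.get("year", "").strip()
        records.append(
            OccurrenceRecord(
                country_code=row.get("countryCode", "").strip(),
                year=int(year_text) if year_text else None,
                occurrence_status=row.get("occurrenceStatus", "").strip(),
                issues=set(filter(None, row.get("issue", "").split(";"))),
                recorded_by=row.get("recordedBy", "").strip(),
                identified_by=row.get("identifiedBy", "").strip(),
            )
        )
    return records


def _keep(rec: OccurrenceRecord, year_start: int, year_end: int) -> bool:
    if rec.occurrence_status.casefold() != "present":
        return False
    if MISMATCH_ISSUE in rec.issues:
        return False
    if rec.year is None or not (year_start <= rec.year <= year_end):
        return False
    return True


def count_distinct_agents(
    records: list[OccurrenceRecord], year_start: int = 2014, year_end: int = 2023
) -> list[CountryAgentSummary]:
    """Distinct nonempty agent strings per country after the stated filters.

    Filters: occurrenceStatus PRESENT (case-insensitive), no
    COUNTRY_COORDINATE_MISMATCH issue, year within the inclusive bounds. The
    filters are independent predicates, so their order is immaterial. Output
    is sorted ascending by record count (country code breaks ties).
    """
    per_country: dict[str, dict] = {}
    for rec in records:
        if not _keep(rec, year_start, year_end):
            continue
        bucket = per_country.setdefault(
            rec.country_code, {"n": 0, "recorded": set(), "identified": set()}
        )
        bucket["n"] += 1
        if rec.recorded_by:
            bucket["recorded"].add(rec.recorded_by)
        if rec.identified_by:
            bucket["identified"].add(rec.identified_by)
    summaries = [
        CountryAgentSummary(
            country_code=code,
            n_records=data["n"],
            n_distinct_recorded_by=len(data["recorded"]),
            n_distinct_identified_by=len(data["identified"]),
        )
        for code, data in per_country.items()
    ]
    return sorted(summaries, key=lambda s: (s.n_records, s.country_code))


def per_capita(
    counts: dict[str, int], population: dict[str, int]
) -> dict[str, float]:
    """Counts as a percentage of each country's population.

    Countries with no population figure are omitted with a warning.
    """
    rates: dict[str, float] = {}
    for code, count in counts.items():
        pop = population.get(code)
        if not pop or pop <= 0:
            log.warning("no population figure for %s; reported as missing", code)
            continue
        rates[code] = 100.0 * count / pop
    return rates
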