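"""Species-name extraction: binomial pattern matching, backbone validation,
abbreviated-genus expansion, and article annotation.

Candidate names are word pairs capitalised like "Genus epithet"; only
candidates that exactly match a backbone name become mentions, so ordinary
capitalised prose ("Here we ...") is removed by the backbone gate rather than
by linguistic heuristics. Once an article has confirmed at least one full
binomial, abbreviated follow-up mentions of the same genus ("G. epithet") are
expanded and validated the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import re

from .backbone import BackboneIndex, TaxonRecord, match_binomial

log = logging.getLogger(__name__)

# Letters cover ASCII plus Latin-1 diacritics; genus remainder and epithet need
# >= 2 lowercase letters to suppress initials and particles, and the epithet
# may carry one internal hyphen.
_UC = "A-ZÀ-ÖØ-Þ"
_LC = "a-zà-öø-ÿ"
BINOMIAL_PATTERN = re.compile(
    rf"(?<![\w.-])([{_UC}][{_LC}]{{2,}})\s+([{_LC}]{{2,}}(?:-[{_LC}]{{2,}})?)(?![\w-])"
)
ABBREVIATION_PATTERN = re.compile(
    rf"(?<![\w.-])([{_UC}])\.\s*([{_LC}]{{2,}}(?:-[{_LC}]{{2,}})?)(?![\w-])"
)


@dataclass(frozen=True)
class SpeciesMention:
    """A validated species mention carried as article metadata."""

    verbatim: str
    canonical_name: str
    taxon_id: str
    expanded_from_abbreviation: bool = False
    lineage: tuple = ()  # ((rank, name), ...) genus -> kingdom

    def lineage_dict(self) -> dict[str, str]:
        return dict(self.lineage)

    def to_dict(self) -> dict:
        return {
            "verbatim": self.verbatim,
            "canonicalName": self.canonical_name,
            "taxonId": self.taxon_id,
            "expandedFromAbbreviation": self.expanded_from_abbreviation,
            "lineage": dict(self.lineage),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SpeciesMention":
        return cls(
            verbatim=data["verbatim"],
            canonical_name=data["canonicalName"],
            taxon_id=data["taxonId"],
            expanded_from_abbreviation=data.get("expandedFromAbbreviation", False),
            lineage=tuple(sorted(data.get("lineage", {}).items())),
        )


def _mention_from_record(
    verbatim: str, record: TaxonRecord, expanded: bool
) -> SpeciesMention:
    return SpeciesMention(
        verbatim=verbatim,
        canonical_name=record.scientific_name,
        taxon_id=record.taxon_id,
        expanded_from_abbreviation=expanded,
        lineage=tuple(sorted(record.lineage().items())),
    )


def extract_candidate_binomials(text: str) -> list[tuple[tuple[int, int], str]]:
    """Every maximal left-to-right, non-overlapping "Genus epithet" candidate.

    Returns ``[(span, "Genus epithet"), ...]``; no backbone validation here.
    """
    out = []
    for m in BINOMIAL_PATTERN.finditer(text):
        out.append((m.span(), f"{m.group(1)} {m.group(2)}"))
    return out


def expand_abbreviations(
    text: str,
    confirmed_genera: set[str],
    index: BackboneIndex,
) -> list[SpeciesMention]:
    """Expand "G. epithet" mentions against genera confirmed in the article.

    The single capital must be the initial of exactly one confirmed genus;
    ambiguous initials are skipped and logged. The expanded binomial is kept
    only when it matches the backbone.
    """
    by_initial: dict[str, list[str]] = {}
    for genus in confirmed_genera:
        by_initial.setdefault(genus[0], []).append(genus)

    mentions = []
    for m in ABBREVIATION_PATTERN.finditer(text):
        initial, epithet = m.group(1), m.group(2)
        genera = by_initial.get(initial, [])
        if len(genera) > 1:
            log.info("ambiguous abbreviation %r: genera %s", m.group(0),
                     sorted(genera))
            continue
        if not genera:
            continue
        record = match_binomial(index, f"{genera[0]} {epithet}")
        if record is not None:
            mentions.append(_mention_from_record(m.group(0), record, True))
    return mentions


def annotate_article_species(article, index: BackboneIndex):
    """Fill ``article.species_mentions`` from title+abstract (idempotent).

    Full binomials are validated first; their genera then seed abbreviation
    expansion over the same text. Duplicate taxa keep the first occurrence.
    """
    text = article.title + "\n" + article.abstract
    mentions: list[SpeciesMention] = []
    confirmed_genera: set[str] = set()
    for _span, candidate in extract_candidate_binomials(text):
        record = match_binomial(index, candidate)
        if record is not None:
            mentions.append(_mention_from_record(candidate, record, False))
            confirmed_genera.add(record.genus)
    mentions.extend(expand_abbreviations(text, confirmed_genera, index))

    seen: set[str] = set()
    unique = []
    for m in mentions:
        if m.taxon_id not in seen:
            seen.add(m.taxon_id)
            unique.append(m)
    article.species_mentions = unique
    return article
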