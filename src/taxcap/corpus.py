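"""Corpus construction: journal deduplication/selection and article filtering.

Articles are selected when they (a) appear in a usable journal, (b) fall in
the study window, (c) have at least one European-affiliated author, (d) sit in
the life-sciences domain, and (e) look taxonomic by multilingual keyword or
concept-tag evidence. Each predicate is independent, so the composition is
order-invariant.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .authors import Authorship

log = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")


def _normalise(text: str) -> str:
    return _WS_RUN.sub(" ", text).casefold()


@dataclass
class JournalRecord:
    """One journal with the identifiers it was discovered under."""

    display_name: str
    wikidata_id: str | None = None
    openalex_id: str | None = None
    issn_l: str | None = None
    issn: str | None = None
    ipni_pub_id: str | None = None
    zoobank_pub_id: str | None = None
    dissolved: bool = False
    dissolved_year: int | None = None
    discovery_methods: set[str] = field(default_factory=set)


@dataclass
class ArticleRecord:
    """One article: the unit that is filtered and annotated."""

    article_id: str
    journal_id: str
    title: str = ""
    abstract: str = ""
    language: str = "en"
    publication_date: str = ""
    concept_ids: set[str] = field(default_factory=set)
    domain_id: str = ""
    authorships: list[Authorship] = field(default_factory=list)
    species_mentions: list = field(default_factory=list)


@dataclass
class KeywordConfig:
    """Classification configuration: keyword lists, concepts, window, Europe."""

    keywords_by_language: dict[str, list[str]]
    abstract_only_keywords: list[str]
    taxonomic_concept_ids: set[str]
    life_sciences_domain_id: str
    window_start: date
    window_end: date
    european_country_codes: set[str]

    def __post_init__(self):
        if self.window_start > self.window_end:
            raise ValueError("window_start must not exceed window_end")
        if not self.european_country_codes:
            raise ValueError("european country code set must be nonempty")

    @classmethod
    def from_mapping(cls, data: dict) -> "KeywordConfig":
        return cls(
            keywords_by_language={
                k: list(v) for k, v in data["keywords_by_language"].items()
            },
            abstract_only_keywords=list(data["abstract_only_keywords"]),
            taxonomic_concept_ids=set(data["taxonomic_concept_ids"]),
            life_sciences_domain_id=data["life_sciences_domain_id"],
            window_start=date.fromisoformat(str(data["window_start"])),
            window_end=date.fromisoformat(str(data["window_end"])),
            european_country_codes=set(data["european_country_codes"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "KeywordConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "KeywordConfig":
        text = resources.files("taxcap.data").joinpath("keywords.yml").read_text(
            encoding="utf-8"
        )
        return cls.from_mapping(yaml.safe_load(text))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


_SCALAR_FIELDS = (
    "display_name",
    "wikidata_id",
    "openalex_id",
    "issn_l",
    "issn",
    "ipni_pub_id",
    "zoobank_pub_id",
    "dissolved_year",
)


def dedupe_journals(records: list[JournalRecord]) -> list[JournalRecord]:
    """Merge journals that share a Wikidata ID or an OpenAlex ID.

    Merging is the transitive closure (union-find) of the two shared-id
    relations; identifier fields take the union with first-seen precedence on
    conflicting non-null scalars (conflicts are logged), and discovery methods
    are unioned.
    """
    uf = _UnionFind(len(records))
    for key_attr in ("wikidata_id", "openalex_id"):
        seen: dict[str, int] = {}
        for i, rec in enumerate(records):
            key = getattr(rec, key_attr)
            if not key:
                continue
            if key in seen:
                uf.union(seen[key], i)
            else:
                seen[key] = i

    groups: dict[int, list[JournalRecord]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(uf.find(i), []).append(rec)

    merged: list[JournalRecord] = []
    for root in sorted(groups):
        members = groups[root]
        head = replace(members[0], discovery_methods=set(members[0].discovery_methods))
        for other in members[1:]:
            for attr in _SCALAR_FIELDS:
                ours, theirs = getattr(head, attr), getattr(other, attr)
                if theirs in (None, ""):
                    continue
                if ours in (None, ""):
                    setattr(head, attr, theirs)
                elif ours != theirs:
                    log.warning(
                        "journal merge conflict on %s: keeping %r, dropping %r",
                        attr, ours, theirs,
                    )
            head.dissolved = head.dissolved or other.dissolved
            head.discovery_methods |= other.discovery_methods
        merged.append(head)
    if len(merged) < len(records):
        log.info("dedupe_journals: %d -> %d records", len(records), len(merged))
    return merged


def select_usable_journals(records: list[JournalRecord]) -> list[JournalRecord]:
    """Keep journals with an OpenAlex ID; dissolved journals are retained."""
    usable = [r for r in records if r.openalex_id]
    log.info(
        "select_usable_journals: retained %d, excluded %d lacking an OpenAlex ID",
        len(usable), len(records) - len(usable),
    )
    return usable


def is_taxonomic_article(
    article: ArticleRecord, config: KeywordConfig
) -> tuple[bool, list[str]]:
    """Classify one article; returns the decision plus the matched evidence.

    True iff a keyword (any configured language) matches title or abstract, an
    abstract-only keyword matches the abstract, or a concept tag intersects the
    taxonomic concept set. Matching is case-insensitive substring matching on
    whitespace-normalised text; multi-word phrases match contiguously.
    """
    title = _normalise(article.title)
    abstract = _normalise(article.abstract)
    combined = title + " \n " + abstract
    evidence: list[str] = []
    for phrases in config.keywords_by_language.values():
        for phrase in phrases:
            if _normalise(phrase) in combined:
                evidence.append(phrase)
    for phrase in config.abstract_only_keywords:
        if _normalise(phrase) in abstract:
            evidence.append(phrase)
    for concept in sorted(article.concept_ids & config.taxonomic_concept_ids):
        evidence.append(concept)
    return bool(evidence), evidence


def _has_european_author(article: ArticleRecord, codes: set[str]) -> bool:
    return any(a.country_codes & codes for a in article.authorships)


def filter_articles(
    articles: list[ArticleRecord],
    usable_journals: list[JournalRecord],
    config: KeywordConfig,
) -> list[ArticleRecord]:
    """Apply all corpus filters; removal counts per filter are logged.

    Records whose publication date does not parse are skipped with a warning.
    """
    usable_ids = {j.openalex_id for j in usable_journals if j.openalex_id}
    removed = {"journal": 0, "window": 0, "european": 0, "domain": 0, "keyword": 0,
               "bad_date": 0}
    corpus: list[ArticleRecord] = []
    for art in articles:
        try:
            pub = date.fromisoformat(art.publication_date)
        except (TypeError, ValueError):
            removed["bad_date"] += 1
            log.warning("unparseable publication date on %s", art.article_id)
            continue
        ok = True
        if art.journal_id not in usable_ids:
            removed["journal"] += 1
            ok = False
        if not (config.window_start <= pub <= config.window_end):
            removed["window"] += 1
            ok = False
        if not _has_european_author(art, config.european_country_codes):
            removed["european"] += 1
            ok = False
        if art.domain_id != config.life_sciences_domain_id:
            removed["domain"] += 1
            ok = False
        if not is_taxonomic_article(art, config)[0]:
            removed["keyword"] += 1
            ok = False
        if ok:
            corpus.append(art)
    log.info("filter_articles: %d in, %d retained, removals %s",
             len(articles), len(corpus), removed)
    return corpus


# ---------------------------------------------------------------------------
# I/O: journals TSV, articles JSONL (strict subsets of the upstream schemas)

_JOURNAL_COLS = {
    "displayName": "display_name",
    "wikidataId": "wikidata_id",
    "openalexId": "openalex_id",
    "issnL": "issn_l",
    "issn": "issn",
    "ipniPubId": "ipni_pub_id",
    "zoobankPubId": "zoobank_pub_id",
}


def read_journals_tsv(path) -> list[JournalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        methods = row.get("discoveryMethods", "")
        records.append(
            JournalRecord(
                **{attr: (row.get(col) or None) for col, attr in _JOURNAL_COLS.items()},
                dissolved=str(row.get("dissolved", "")).lower() in ("true", "1"),
                dissolved_year=int(row["dissolvedYear"])
                if row.get("dissolvedYear") else None,
                discovery_methods=set(filter(None, methods.split(";"))),
            )
        )
    return records


def write_journals_tsv(records: list[JournalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "displayName": r.display_name,
            "wikidataId": r.wikidata_id or "",
            "openalexId": r.openalex_id or "",
            "issnL": r.issn_l or "",
            "issn": r.issn or "",
            "ipniPubId": r.ipni_pub_id or "",
            "zoobankPubId": r.zoobank_pub_id or "",
            "dissolved": str(r.dissolved).lower(),
            "dissolvedYear": r.dissolved_year if r.dissolved_year else "",
            "discoveryMethods": ";".join(sorted(r.discovery_methods)),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def article_to_dict(article: ArticleRecord) -> dict:
    return {
        "articleId": article.article_id,
        "journalId": article.journal_id,
        "title": article.title,
        "abstract": article.abstract,
        "language": article.language,
        "publicationDate": article.publication_date,
        "conceptIds": sorted(article.concept_ids),
        "domainId": article.domain_id,
        "authorships": [
            {
                "authorId": a.author_id,
                "displayName": a.display_name,
                "institutionIds": sorted(a.institution_ids),
                "institutionNames": list(a.institution_names),
                "countryCodes": sorted(a.country_codes),
            }
            for a in article.authorships
        ],
        "speciesMentions": [m.to_dict() for m in article.species_mentions],
    }


def article_from_dict(data: dict) -> ArticleRecord:
    from .names import SpeciesMention

    return ArticleRecord(
        article_id=data["articleId"],
        journal_id=data["journalId"],
        title=data.get("title", ""),
        abstract=data.get("abstract", ""),
        language=data.get("language", "en"),
        publication_date=data.get("publicationDate", ""),
        concept_ids=set(data.get("conceptIds", [])),
        domain_id=data.get("domainId", ""),
        authorships=[
            Authorship(
                author_id=a["authorId"],
                display_name=a["displayName"],
                institution_ids=set(a.get("institutionIds", [])),
                institution_names=list(a.get("institutionNames", [])),
                country_codes=set(a.get("countryCodes", [])),
            )
            for a in data.get("authorships", [])
        ],
        species_mentions=[
            SpeciesMention.from_dict(m) for m in data.get("speciesMentions", [])
        ],
    )


def read_articles_jsonl(path) -> list[ArticleRecord]:
    articles = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                articles.append(article_from_dict(json.loads(line)))
    return articles


def write_articles_jsonl(articles: list[ArticleRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for art in articles:
            fh.write(json.dumps(article_to_dict(art), ensure_ascii=False,
                                sort_keys=True) + "\n")
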