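"""Taxonomic backbone: exact binomial matching, lineage lookup, order richness.

The backbone is a Darwin-Core-style taxon table (one row per name, with
accepted/synonym status and a genus -> kingdom lineage). It is the substrate
both for validating species-name mentions extracted from article text and for
counting accepted species per order (the richness predictor of the
supply-demand regression).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "taxonID",
    "scientificName",
    "taxonRank",
    "taxonomicStatus",
    "genus",
    "family",
    "order",
    "class",
    "phylum",
    "kingdom",
)

#: strict "Genus epithet" shape; hybrids ("x"), infraspecifics and authorship
#: strings fall outside it and are skipped at load time.
_BINOMIAL_SHAPE = re.compile(
    r"^[A-ZÀ-ÖØ-Þ][a-zà-öø-ÿ]+ [a-zà-öø-ÿ]+(?:-[a-zà-öø-ÿ]+)?$"
)

_WS_RUN = re.compile(r"\s+")


def canonicalise(name: str) -> str:
    """Strip outer whitespace and collapse internal runs to single spaces."""
    return _WS_RUN.sub(" ", name.strip())


@dataclass(frozen=True)
class TaxonRecord:
    """One backbone row: a species-rank name with its lineage."""

    taxon_id: str
    scientific_name: str
    taxon_rank: str
    taxonomic_status: str  # "accepted" or "synonym"
    genus: str
    family: str
    order: str
    class_: str
    phylum: str
    kingdom: str
    accepted_taxon_id: str = ""

    @property
    def is_accepted(self) -> bool:
        return self.taxonomic_status == "accepted"

    def lineage(self) -> dict[str, str]:
        return {
            "genus": self.genus,
            "family": self.family,
            "order": self.order,
            "class": self.class_,
            "phylum": self.phylum,
            "kingdom": self.kingdom,
        }


@dataclass
class BackboneIndex:
    """Indexes over the backbone for exact matching and richness counts.

    ``by_binomial`` maps canonical "Genus epithet" strings to their records
    (case-sensitive on the stored canonical form, synonyms included);
    ``by_genus`` maps each genus to its set of epithets; ``richness_by_order``
    counts accepted species-rank records per order.
    """

    by_binomial: dict[str, TaxonRecord] = field(default_factory=dict)
    by_genus: dict[str, set[str]] = field(default_factory=dict)
    richness_by_order: dict[str, int] = field(default_factory=dict)
    by_id: dict[str, TaxonRecord] = field(default_factory=dict)
    n_skipped: int = 0

    def add(self, record: TaxonRecord) -> None:
        name = record.scientific_name
        if name in self.by_binomial:
            return  # first-seen wins; duplicates are backbone noise
        self.by_binomial[name] = record
        self.by_id[record.taxon_id] = record
        genus, epithet = name.split(" ", 1)
        self.by_genus.setdefault(genus, set()).add(epithet)
        if record.is_accepted and record.order:
            self.richness_by_order[record.order] = (
                self.richness_by_order.get(record.order, 0) + 1
            )

    def resolve_accepted(self, record: TaxonRecord) -> TaxonRecord:
        """Follow a synonym's acceptedTaxonId to its accepted record if known."""
        if record.is_accepted or not record.accepted_taxon_id:
            return record
        return self.by_id.get(record.accepted_taxon_id, record)

    def __len__(self) -> int:
        return len(self.by_binomial)


def load_backbone(path) -> BackboneIndex:
    """Load a tab-delimited Darwin-Core-style taxon table into an index.

    Malformed rows (missing name or rank, or species-rank names that are not
    plain two-token binomials, e.g. hybrids) are counted, logged and skipped.

    Raises
    ------
    InputError
        If the file does not exist.
    FormatError
        If the header lacks a required column (the error names it).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError as exc:
        raise InputError(f"backbone file not found: {path}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"backbone header is missing required column {col!r}")
    has_accepted = "acceptedTaxonID" in df.columns

    index = BackboneIndex()
    skipped = 0
    for row in df.to_dict("records"):
        name = canonicalise(row["scientificName"])
        rank = row["taxonRank"].strip()
        if not name or not rank:
            skipped += 1
            continue
        if rank != "species":
            continue  # genus-rank and higher rows carry no binomial to index
        if not _BINOMIAL_SHAPE.match(name):
            skipped += 1
            log.warning("skipping non-binomial species-rank name: %r", name)
            continue
        index.add(
            TaxonRecord(
                taxon_id=row["taxonID"],
                scientific_name=name,
                taxon_rank=rank,
                taxonomic_status=row["taxonomicStatus"].strip(),
                genus=name.split(" ", 1)[0],
                family=row["family"].strip(),
                order=row["order"].strip(),
                class_=row["class"].strip(),
                phylum=row["phylum"].strip(),
                kingdom=row["kingdom"].strip(),
                accepted_taxon_id=(
                    row["acceptedTaxonID"].strip() if has_accepted else ""
                ),
            )
        )
    index.n_skipped = skipped
    if skipped:
        log.info("backbone load: skipped %d malformed rows", skipped)
    log.info("backbone load: indexed %d binomials", len(index))
    return index


def match_binomial(index: BackboneIndex, candidate: str) -> TaxonRecord | None:
    """Exact lookup of a two-token candidate against the backbone.

    Absence is a value (None), never an error; no fuzzy matching.
    """
    return index.by_binomial.get(canonicalise(candidate))


def order_richness(index: BackboneIndex, order: str) -> int:
    """Number of accepted species-rank records in ``order`` (0 if unknown)."""
    return index.richness_by_order.get(order, 0)
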