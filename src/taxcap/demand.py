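"""Policy demand: species lists, the order x policy matrix, and summaries.

Nine policy instruments supply the demand-side predictors: IUCN Red List
"Taxonomic Research Needed", crop wild relatives, the IAS list of Union
Concern, horizon-scan invasives, the Habitats, Marine Strategy Framework and
Birds Directives, the full European Red List, and the Pollinators Initiative.
Each list is resolved against the backbone; per-order counts (plus species
richness and disambiguated author counts) form the regression substrate.
Names that fail to resolve are kept in an explicit unresolved ledger — policy
lists rarely carry persistent identifiers, so match failure is informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .backbone import BackboneIndex, match_binomial, order_richness
from .errors import InputError

log = logging.getLogger(__name__)

POLICY_IDS = (
    "taxonomicResearchNeeded",
    "cropWildRelatives",
    "iasListConcern",
    "horizonInvasives",
    "habitatsDir",
    "marineDir",
    "redlistFull",
    "birdDir",
    "pollinators",
)


@dataclass
class PolicyList:
    policy_id: str
    species_names: list[str]
    attributes: dict[str, str] = field(default_factory=dict)  # name -> category
    groups: dict[str, str] = field(default_factory=dict)  # name -> group

    def __post_init__(self):
        if self.policy_id not in POLICY_IDS:
            raise InputError(f"unknown policy id {self.policy_id!r}")


@dataclass
class PolicyMatrix:
    """Order x (nine policies + speciesRichness + authorCount) count table."""

    table: pd.DataFrame
    unresolved: dict[str, list[str]]


def load_policy_lists(paths: dict[str, str]) -> list[PolicyList]:
    """Load each policy's TSV (scientificName [, category] [, group]).

    Duplicate names within a list are collapsed with a warning.
    """
    lists = []
    for policy_id, path in paths.items():
        if policy_id not in POLICY_IDS:
            raise InputError(f"unknown policy id {policy_id!r}")
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "scientificName" not in df.columns:
            raise InputError(f"policy list {path} lacks a scientificName column")
        names: list[str] = []
        attributes: dict[str, str] = {}
        groups: dict[str, str] = {}
        for row in df.to_dict("records"):
            name = row["scientificName"].strip()
            if not name:
                continue
            if name in names:
                log.warning("duplicate name %r in policy list %s", name, policy_id)
                continue
            names.append(name)
            if row.get("category"):
                attributes[name] = row["category"]
            if row.get("group"):
                groups[name] = row["group"]
        lists.append(PolicyList(policy_id, names, attributes, groups))
    return lists


def build_policy_matrix(
    lists: list[PolicyList],
    index: BackboneIndex,
    authors_by_order: dict[str, int],
    *,
    remap_synonyms: bool = True,
) -> PolicyMatrix:
    """Count each policy's species per order, next to richness and authors.

    With ``remap_synonyms`` (the default), a name matching a synonym is
    attributed to its accepted record's order when an accepted-taxon link is
    present; otherwise the synonym row's own lineage is used.
    """
    orders = sorted(index.richness_by_order)
    table = pd.DataFrame(
        0, index=pd.Index(orders, name="order"),
        columns=["speciesRichness", *POLICY_IDS, "authorCount"],
    )
    for order in orders:
        table.loc[order, "speciesRichness"] = order_richness(index, order)
        table.loc[order, "authorCount"] = authors_by_order.get(order, 0)
    unresolved: dict[str, list[str]] = {pl.policy_id: [] for pl in lists}
    for pl in lists:
        for name in pl.species_names:
            record = match_binomial(index, name)
            if record is None:
                unresolved[pl.policy_id].append(name)
                continue
            if remap_synonyms:
                record = index.resolve_accepted(record)
            if record.order in table.index:
                table.loc[record.order, pl.policy_id] += 1
            else:
                # resolvable name whose order has no accepted species indexed
                unresolved[pl.policy_id].append(name)
    return PolicyMatrix(table=table, unresolved=unresolved)


def redlist_summary(counts: dict[str, int], total: int) -> dict[str, float]:
    """Category shares as percentages, rounded half-up to one decimal."""
    if total <= 0:
        raise InputError("total must be positive")
    out = {}
    for category, count in counts.items():
        if count > total:
            raise InputError(f"count for {category!r} exceeds the total")
        pct = Decimal(100 * count) / Decimal(total)
        out[category] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


def policy_totals(
    policy_list: PolicyList, partition: dict[str, str]
) -> tuple[dict[str, int], int]:
    """Per-group species counts for one policy list plus the grand total.

    Names absent from the partition are grouped as "other".
    """
    groups: dict[str, int] = {}
    for name in policy_list.species_names:
        group = partition.get(name, "other")
        groups[group] = groups.get(group, 0) + 1
    return groups, sum(groups.values())
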