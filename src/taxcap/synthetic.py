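"""Synthetic bibliographic data with known ground truth.

Every pipeline input — backbone, journals, articles, author identities,
policy lists, regression matrix, occurrence records — can be generated
offline with planted structure: which articles are taxonomic, which binomials
(and abbreviated follow-ups) each abstract contains, which author IDs belong
to the same person, the regression coefficients behind the counts, and the
distinct agent pools per country. Tests recover these plants through the real
pipeline code.

All randomness flows through one numpy Generator seeded from the config, so a
fixed seed reproduces every file byte for byte. Taxon and person names are
built from a pronounceable-syllable generator and are deliberately not real
names.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .authors import Authorship
from .corpus import ArticleRecord, JournalRecord, write_articles_jsonl, write_journals_tsv
from .demand import POLICY_IDS

_SYLLABLES = [
    "ba", "ce", "da", "fo", "ga", "hi", "ke", "la", "mo",
    "na", "pi", "ra", "se", "tu", "ve", "zo", "lu", "mi",
]

_EURO_COUNTRIES = ["BE", "DE", "FR", "ES", "PL", "CZ", "EE", "PT", "NO", "IT"]
_NON_EURO_COUNTRIES = ["US", "BR", "CN", "AU"]

#: default coefficients on the ln(x+1) scale: intercept, richness, then the
#: nine policies. Magnitudes follow the reported pattern: richness and
#: research-needed/habitats/birds positive, marine negative, the rest weak.
DEFAULT_TRUE_BETA = (
    1.0,   # intercept
    0.471,  # speciesRichness
    0.541,  # taxonomicResearchNeeded
    0.05,   # cropWildRelatives
    0.0,    # iasListConcern
    0.0,    # horizonInvasives
    0.348,  # habitatsDir
    -0.273,  # marineDir
    0.05,   # redlistFull
    0.369,  # birdDir
    0.0,    # pollinators
)


@dataclass
class GeneratorConfig:
    """Knobs for every generator; defaults define the study conditions."""

    seed: int = 0
    # backbone
    n_orders: int = 20
    species_per_order: int = 30
    #: relative spread of per-order species counts around species_per_order;
    #: 0 makes every order exactly species_per_order species
    richness_variation: float = 0.5
    genera_per_order: int = 6
    synonym_fraction: float = 0.2
    # journals
    n_journals: int = 30
    journal_missing_openalex_rate: float = 0.25
    journal_duplicate_rate: float = 0.15
    journal_dissolved_rate: float = 0.2
    # articles
    n_articles: int = 220
    taxonomic_fraction: float = 0.5
    decoy_rate: float = 0.5
    abbreviation_rate: float = 0.3
    keyword_collision_rate: float = 0.0
    out_of_window_rate: float = 0.2
    non_european_rate: float = 0.2
    # author identities
    n_persons: int = 70
    duplicate_id_rate: float = 0.15
    name_collision_rate: float = 0.1
    # regression
    n_regression_orders: int = 120
    true_beta: tuple = DEFAULT_TRUE_BETA
    noise_sigma: float = 0.3
    contamination_rate: float = 0.0
    #: fraction of orders a given policy list touches (order-level sparsity)
    policy_incidence: float = 0.35
    # occurrences
    n_countries: int = 8
    occurrences_per_country: int = 40
    occ_mismatch_rate: float = 0.1
    occ_absent_rate: float = 0.1

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way the pipeline reports it."""

    article_labels: dict[str, bool] = field(default_factory=dict)
    expected_corpus_ids: set[str] = field(default_factory=set)
    #: non-taxonomic articles that both carry a planted keyword collision and
    #: pass every other filter — the corpus's designed false positives
    collision_ids: set[str] = field(default_factory=set)
    planted_mentions: dict[str, set[str]] = field(default_factory=dict)
    person_partition: dict[str, str] = field(default_factory=dict)
    true_beta: tuple = ()
    agent_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    order_richness: dict[str, int] = field(default_factory=dict)


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    idx = rng.integers(0, len(_SYLLABLES), size=n_syllables)
    return "".join(_SYLLABLES[i] for i in idx)


def _unique_word(rng, n_syllables: int, used: set[str], capital: bool) -> str:
    while True:
        word = _word(rng, n_syllables)
        if capital:
            word = word.capitalize()
        if word not in used:
            used.add(word)
            return word


# ---------------------------------------------------------------------------
# backbone


@dataclass
class BackboneBundle:
    table: pd.DataFrame
    #: order -> list of (canonical binomial, genus, family) for accepted species
    species_by_order: dict[str, list[tuple[str, str, str]]]
    #: genus -> epithets of accepted species
    genus_species: dict[str, list[str]]
    richness: dict[str, int]


def generate_backbone(config: GeneratorConfig, rng=None) -> BackboneBundle:
    """Synthetic backbone: per-order accepted species plus synonym rows.

    Every order holds exactly ``species_per_order`` accepted species spread
    over ``genera_per_order`` genera, so order richness is known by
    construction; synonyms point at accepted rows through acceptedTaxonID and
    never count toward richness.
    """
    rng = config.rng() if rng is None else rng
    kingdoms = ["Animalia", "Plantae", "Fungi"]
    used_words: set[str] = set()
    rows = []
    species_by_order: dict[str, list[tuple[str, str, str]]] = {}
    genus_species: dict[str, list[str]] = {}
    taxon_counter = 0

    for oi in range(config.n_orders):
        order = _unique_word(rng, 3, used_words, True) + "iformes"
        kingdom = kingdoms[oi % 3]
        phylum = _unique_word(rng, 2, used_words, True) + "phyta"
        class_ = _unique_word(rng, 2, used_words, True) + "opsida"
        families = [
            _unique_word(rng, 3, used_words, True) + "idae"
            for _ in range(max(2, config.genera_per_order // 2))
        ]
        genera = [_unique_word(rng, 3, used_words, True)
                  for _ in range(config.genera_per_order)]
        if config.richness_variation > 0:
            spread = config.richness_variation
            low = max(len(genera), int(round(config.species_per_order * (1 - spread))))
            high = int(round(config.species_per_order * (1 + spread)))
            n_species = int(rng.integers(low, high + 1))
        else:
            n_species = config.species_per_order
        accepted_ids = []
        species_by_order[order] = []
        for si in range(n_species):
            genus = genera[si % len(genera)]
            family = families[(si % len(genera)) % len(families)]
            used_epithets = set(genus_species.get(genus, []))
            epithet = _unique_word(rng, 3, used_epithets, False)
            genus_species.setdefault(genus, []).append(epithet)
            taxon_counter += 1
            tid = f"T{taxon_counter}"
            name = f"{genus} {epithet}"
            rows.append({
                "taxonID": tid, "scientificName": name, "taxonRank": "species",
                "taxonomicStatus": "accepted", "genus": genus, "family": family,
                "order": order, "class": class_, "phylum": phylum,
                "kingdom": kingdom, "acceptedTaxonID": "",
            })
            accepted_ids.append(tid)
            species_by_order[order].append((name, genus, family))
        n_syn = int(round(config.synonym_fraction * n_species))
        for si in range(n_syn):
            genus = genera[si % len(genera)]
            used_epithets = set(genus_species.get(genus, []))
            epithet = _unique_word(rng, 3, used_epithets, False)
            genus_species.setdefault(genus, []).append(epithet)
            taxon_counter += 1
            rows.append({
                "taxonID": f"T{taxon_counter}",
                "scientificName": f"{genus} {epithet}",
                "taxonRank": "species", "taxonomicStatus": "synonym",
                "genus": genus, "family": families[si % len(families)],
                "order": order, "class": class_, "phylum": phylum,
                "kingdom": kingdom,
                "acceptedTaxonID": accepted_ids[int(rng.integers(0, len(accepted_ids)))],
            })
        # one genus-rank row per order for loader realism
        taxon_counter += 1
        rows.append({
            "taxonID": f"T{taxon_counter}", "scientificName": genera[0],
            "taxonRank": "genus", "taxonomicStatus": "accepted",
            "genus": genera[0], "family": families[0], "order": order,
            "class": class_, "phylum": phylum, "kingdom": kingdom,
            "acceptedTaxonID": "",
        })

    table = pd.DataFrame(rows)
    richness = {order: len(rows_) for order, rows_ in species_by_order.items()}
    return BackboneBundle(table, species_by_order, genus_species, richness)


# ---------------------------------------------------------------------------
# journals


def generate_journals(config: GeneratorConfig, rng) -> tuple[list[JournalRecord], int]:
    """Journal table with planted duplicate rows and missing OpenAlex IDs.

    Returns the records plus the number of unique journals after dedup.
    """
    records = []
    n_missing = int(round(config.journal_missing_openalex_rate * config.n_journals))
    for ji in range(config.n_journals):
        has_openalex = ji >= n_missing
        dissolved = rng.random() < config.journal_dissolved_rate
        rec = JournalRecord(
            display_name=f"Journal of {_word(rng, 3).capitalize()} Studies",
            wikidata_id=f"Q{9000 + ji}",
            openalex_id=f"S{100 + ji}" if has_openalex else None,
            issn_l=f"{1000 + ji:04d}-{2000 + ji:04d}",
            dissolved=dissolved,
            dissolved_year=2010 if dissolved else None,
            discovery_methods={"ipni_or_zoobank_id"},
        )
        records.append(rec)
        if rng.random() < config.journal_duplicate_rate:
            records.append(JournalRecord(
                display_name=rec.display_name,
                wikidata_id=rec.wikidata_id,
                openalex_id=None,
                discovery_methods={"wikidata_subject"},
            ))
    return records, config.n_journals


# ---------------------------------------------------------------------------
# persons / author identities


@dataclass
class _Person:
    person_id: str
    author_ids: list[str]
    display_names: dict[str, str]  # author id -> name variant
    institution_id: str
    institution_name: str
    country: str
    focus_order: str


def generate_authors_truth(
    config: GeneratorConfig, orders: list[str], rng
) -> tuple[list[_Person], dict[str, str]]:
    """Person pool with planted duplicate IDs and truncated-name collisions.

    A ``duplicate_id_rate`` fraction of persons carry two author IDs whose
    name variants satisfy merge Rule 1 (identical stripped names) or Rule 2
    (identical truncated names plus shared institution and focus order). A
    ``name_collision_rate`` fraction of persons get a twin sharing their
    truncated name at a different institution with a different focus order —
    plants that must never merge.
    """
    institutions = []
    for k, country in enumerate(_EURO_COUNTRIES):
        institutions.append((f"I{k}", f"{_word(rng, 3).capitalize()} Institute", country))
    used_last: set[str] = set()
    used_first: set[str] = set()
    persons: list[_Person] = []
    partition: dict[str, str] = {}
    author_counter = 0

    def new_author_id() -> str:
        nonlocal author_counter
        author_counter += 1
        return f"A{author_counter}"

    n_dup = int(round(config.duplicate_id_rate * config.n_persons))
    n_coll = int(round(config.name_collision_rate * config.n_persons))

    for pi in range(config.n_persons):
        first = _unique_word(rng, 2, used_first, True)
        last = _unique_word(rng, 3, used_last, True)
        inst = institutions[int(rng.integers(0, len(institutions)))]
        order = orders[int(rng.integers(0, len(orders)))]
        pid = f"P{pi}"
        aid = new_author_id()
        person = _Person(pid, [aid], {aid: f"{first} {last}"},
                         inst[0], inst[1], inst[2], order)
        if pi < n_dup:
            aid2 = new_author_id()
            person.author_ids.append(aid2)
            if pi % 2 == 0:
                # Rule 1 plant: punctuation variant with an identical stripped name
                person.display_names[aid] = f"{first} J. {last}"
                person.display_names[aid2] = f"{first} J {last}"
            else:
                # Rule 2 plant: initialised variant, same institution + order
                person.display_names[aid2] = f"{first[0]}. {last}"
        persons.append(person)
        for a in person.author_ids:
            partition[a] = pid

    # never-merge plants: same truncated name, different institution and order
    for ci in range(n_coll):
        base = persons[ci]
        base_first = base.display_names[base.author_ids[0]].split()[0]
        # twin first name: same initial, different person; candidates are
        # drawn without consuming the name pool
        twin_first = None
        while twin_first is None:
            cand = (base_first[0] + _word(rng, 2)).strip()
            if cand not in used_first and cand != base_first:
                twin_first = cand
                used_first.add(cand)
        base_last = base.display_names[base.author_ids[0]].split()[-1]
        others = [i for i in institutions if i[0] != base.institution_id]
        inst = others[int(rng.integers(0, len(others)))]
        other_orders = [o for o in orders if o != base.focus_order]
        order = other_orders[int(rng.integers(0, len(other_orders)))]
        pid = f"P{config.n_persons + ci}"
        aid = new_author_id()
        persons.append(_Person(pid, [aid], {aid: f"{twin_first} {base_last}"},
                               inst[0], inst[1], inst[2], order))
        partition[aid] = pid

    return persons, partition


# ---------------------------------------------------------------------------
# articles


_SAFE_TITLE_WORDS = [
    "soil moisture dynamics", "river discharge modelling",
    "enzyme kinetics of yeast cultures", "sediment transport rates",
    "microclimate variation in greenhouses", "acoustic monitoring of wind farms",
]

_KEYWORD_PLANTS = [
    ("en", "new species", "title"),
    ("en", "taxonomic", "title"),
    ("en", "checklist", "title"),
    ("de", "neue Art", "title"),
    ("fr", "nouvelle espèce", "title"),
    ("es", "nueva especie", "title"),
    ("en", "nov.", "abstract"),
    ("en", None, "concept"),
]

_TAX_CONCEPT = "C58642233"
_OTHER_CONCEPT = "C999999"
_LIFE_DOMAIN = "https://openalex.org/domains/1"
_OTHER_DOMAIN = "https://openalex.org/domains/2"


def _random_date(rng, start_year: int, end_year: int) -> str:
    year = int(rng.integers(start_year, end_year + 1))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return f"{year:04d}-{month:02d}-{day:02d}"


@dataclass
class CorpusBundle:
    journals: list[JournalRecord]
    articles: list[ArticleRecord]
    persons: list[_Person]
    truth: GroundTruth


def _authorship_for(person: _Person, aid: str) -> Authorship:
    return Authorship(
        author_id=aid,
        display_name=person.display_names[aid],
        institution_ids={person.institution_id},
        institution_names=[person.institution_name],
        country_codes={person.country},
    )


def generate_corpus(
    config: GeneratorConfig, backbone: BackboneBundle, rng=None
) -> CorpusBundle:
    """Articles with planted keywords, binomials, decoys and author structure.

    Taxonomic articles always satisfy every non-keyword corpus filter (usable
    journal, in-window date, European affiliation, life-sciences domain), so
    label recovery isolates the keyword/concept classifier. Non-taxonomic
    articles exercise the other filters: out-of-window dates, non-European
    affiliations, foreign domains, and (at ``keyword_collision_rate``)
    keyword-bearing false positives.
    """
    rng = config.rng() if rng is None else rng
    journals, _ = generate_journals(config, rng)
    usable = [j for j in journals if j.openalex_id]
    orders = sorted(backbone.species_by_order)
    persons, partition = generate_authors_truth(config, orders, rng)
    author_slots = [(p, aid) for p in persons for aid in p.author_ids]

    used_genus_words = set(backbone.genus_species)
    truth = GroundTruth(person_partition=partition,
                        order_richness=dict(backbone.richness))
    articles: list[ArticleRecord] = []
    n_tax = int(round(config.taxonomic_fraction * config.n_articles))
    if n_tax < len(author_slots):
        raise ValueError(
            "not enough taxonomic articles to give every author identity a "
            f"publication: need >= {len(author_slots)}, have {n_tax}"
        )

    for ai in range(config.n_articles):
        article_id = f"W{ai}"
        taxonomic = ai < n_tax
        if taxonomic:
            person, aid = author_slots[ai % len(author_slots)]
            journal = usable[int(rng.integers(0, len(usable)))]
            pool = backbone.species_by_order[person.focus_order]
            n_plant = int(rng.integers(1, 4))
            picks = [pool[int(i)] for i in
                     rng.choice(len(pool), size=min(n_plant, len(pool)),
                                replace=False)]
            # keep genus initials unique so abbreviation expansion is never
            # ambiguous within an article
            seen_initials: set[str] = set()
            kept = []
            for name, genus, family in picks:
                if genus[0] in seen_initials:
                    continue
                seen_initials.add(genus[0])
                kept.append((name, genus, family))
            mentions = {name for name, _g, _f in kept}
            sentences = [f"Specimens of {name} were examined." for name, _g, _f in kept]

            if rng.random() < config.abbreviation_rate:
                for name, genus, _f in kept:
                    siblings = [e for e in backbone.genus_species[genus]
                                if f"{genus} {e}" != name
                                and f"{genus} {e}" in
                                {n for n, _g2, _f2 in pool}]
                    if siblings:
                        epithet = siblings[int(rng.integers(0, len(siblings)))]
                        sentences.append(
                            f"Additional material of {genus[0]}. {epithet} was studied."
                        )
                        mentions.add(f"{genus} {epithet}")
                        break
            if rng.random() < config.decoy_rate:
                decoy_genus = _unique_word(rng, 4, used_genus_words, True)
                sentences.append(
                    f"The habitat resembles that of {decoy_genus} {_word(rng, 3)}."
                )

            lang, phrase, where = _KEYWORD_PLANTS[int(rng.integers(0, len(_KEYWORD_PLANTS)))]
            title = f"Studies on the genus {kept[0][1]}"
            concepts = {_OTHER_CONCEPT}
            if where == "title" and phrase:
                title = f"{phrase.capitalize()}: studies on the genus {kept[0][1]}"
            elif where == "abstract":
                sentences.append(f"{kept[0][0]} sp. nov. is described.")
            elif where == "concept":
                concepts = {_TAX_CONCEPT, _OTHER_CONCEPT}
                lang = "en"
            abstract = " ".join(sentences)
            art = ArticleRecord(
                article_id=article_id,
                journal_id=journal.openalex_id,
                title=title,
                abstract=abstract,
                language=lang,
                publication_date=_random_date(rng, 2014, 2023),
                concept_ids=concepts,
                domain_id=_LIFE_DOMAIN,
                authorships=[_authorship_for(person, aid)],
            )
            # occasional European co-author
            if rng.random() < 0.3:
                co, co_aid = author_slots[int(rng.integers(0, len(author_slots)))]
                if co_aid != aid:
                    art.authorships.append(_authorship_for(co, co_aid))
            truth.article_labels[article_id] = True
            truth.expected_corpus_ids.add(article_id)
            truth.planted_mentions[article_id] = mentions
        else:
            person, aid = author_slots[int(rng.integers(0, len(author_slots)))]
            topic = _SAFE_TITLE_WORDS[int(rng.integers(0, len(_SAFE_TITLE_WORDS)))]
            journal = usable[int(rng.integers(0, len(usable)))]
            pub_date = _random_date(rng, 2015, 2022)
            domain = _LIFE_DOMAIN
            authorships = [_authorship_for(person, aid)]
            roll = rng.random()
            if roll < config.out_of_window_rate:
                pub_date = _random_date(rng, 2008, 2012)
            elif roll < config.out_of_window_rate + config.non_european_rate:
                country = _NON_EURO_COUNTRIES[int(rng.integers(0, len(_NON_EURO_COUNTRIES)))]
                authorships = [Authorship(
                    author_id=f"X{ai}", display_name=f"{_word(rng, 2).capitalize()} {_word(rng, 3).capitalize()}",
                    institution_ids={f"IX{ai}"},
                    institution_names=["Overseas Institute"],
                    country_codes={country},
                )]
            elif roll < config.out_of_window_rate + config.non_european_rate + 0.1:
                domain = _OTHER_DOMAIN
            passes_others = roll >= (config.out_of_window_rate
                                     + config.non_european_rate + 0.1)
            title = f"Advances in {topic}"
            if rng.random() < config.keyword_collision_rate:
                title = f"Surprising new species aspects of {topic}"
                if passes_others:
                    truth.collision_ids.add(article_id)
            art = ArticleRecord(
                article_id=article_id,
                journal_id=journal.openalex_id,
                title=title,
                abstract=f"We analyse {topic} using replicated field measurements.",
                language="en",
                publication_date=pub_date,
                concept_ids={_OTHER_CONCEPT},
                domain_id=domain,
                authorships=authorships,
            )
            truth.article_labels[article_id] = False
            truth.planted_mentions[article_id] = set()
        articles.append(art)

    return CorpusBundle(journals=journals, articles=articles, persons=persons,
                        truth=truth)


# ---------------------------------------------------------------------------
# policy lists, regression data, occurrences


def generate_policy_lists(
    config: GeneratorConfig, backbone: BackboneBundle, rng=None,
    unresolved_per_policy: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-policy species tables sampled from the backbone, plus plants that
    cannot resolve (absent from the backbone), for conservation checks."""
    rng = config.rng() if rng is None else rng
    all_species = [
        (name, order) for order, rows in sorted(backbone.species_by_order.items())
        for name, _g, _f in rows
    ]
    categories = ["CR", "EN", "VU", "DD", "LC"]
    out = {}
    used = set(backbone.genus_species)
    for policy in POLICY_IDS:
        size = int(rng.integers(10, 31))
        idx = rng.choice(len(all_species), size=min(size, len(all_species)),
                         replace=False)
        rows = []
        for i in idx:
            name, _order = all_species[int(i)]
            rows.append({
                "scientificName": name,
                "category": categories[int(rng.integers(0, len(categories)))],
                "group": "plants" if rng.random() < 0.5 else "animals",
            })
        for _ in range(unresolved_per_policy):
            fake = f"{_unique_word(rng, 4, used, True)} {_word(rng, 3)}"
            rows.append({"scientificName": fake, "category": "DD", "group": "other"})
        out[policy] = pd.DataFrame(rows)
    return out


def generate_regression_data(
    config: GeneratorConfig, rng=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Order-level count matrix whose ln(x+1) relation follows ``true_beta``.

    Counts are drawn on the ln scale, rounded to integers, and the response is
    rebuilt from the *rounded* predictors, so the only deviations from the
    linear model are the Gaussian noise, the response rounding, and (when
    configured) gross contamination of a fraction of responses.
    """
    rng = config.rng() if rng is None else rng
    beta = np.asarray(config.true_beta, dtype=float)
    if beta.size != 2 + len(POLICY_IDS):
        raise ValueError("true_beta must cover intercept + richness + 9 policies")
    n = config.n_regression_orders
    # order sizes span a handful of species to many thousands; policy lists
    # are sparse at order level (most orders appear in no list, as with
    # taxon-specific instruments), so each policy touches only a fraction of
    # the orders and contributes zero counts elsewhere
    ln_richness = rng.uniform(0.5, 9.5, size=n)
    incidence = rng.random(size=(n, len(POLICY_IDS))) < config.policy_incidence
    ln_policies = np.where(
        incidence, rng.uniform(0.5, 4.0, size=(n, len(POLICY_IDS))), 0.0
    )
    richness = np.round(np.expm1(ln_richness)).astype(int)
    policies = np.round(np.expm1(ln_policies)).astype(int)
    X = np.column_stack([
        np.ones(n), np.log1p(richness), np.log1p(policies),
    ])
    ln_y = X @ beta + rng.normal(0.0, config.noise_sigma, size=n)
    n_contam = int(round(config.contamination_rate * n))
    if n_contam:
        rows = rng.choice(n, size=n_contam, replace=False)
        ln_y[rows] += rng.choice([-1.0, 1.0], size=n_contam) * rng.uniform(
            4.0, 8.0, size=n_contam
        )
    authors = np.maximum(0, np.round(np.expm1(ln_y))).astype(int)
    table = pd.DataFrame({"order": [f"O{i}" for i in range(n)],
                          "speciesRichness": richness})
    for j, policy in enumerate(POLICY_IDS):
        table[policy] = policies[:, j]
    table["authorCount"] = authors
    return table.set_index("order"), beta


def generate_occurrences(
    config: GeneratorConfig, rng=None
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Occurrence records with controlled per-country distinct agent pools.

    Every agent in a country's pool appears in at least one clean record, so
    the post-filter distinct counts are exactly the pool sizes; contaminated
    records (wrong status, mismatch flag, out-of-window year) use agent
    strings outside the pools and must not count.
    """
    rng = config.rng() if rng is None else rng
    countries = _EURO_COUNTRIES[: config.n_countries]
    rows = []
    counts: dict[str, dict[str, int]] = {}
    for country in countries:
        n_recorded = int(rng.integers(3, 11))
        n_identified = int(rng.integers(1, n_recorded + 1))
        recorded_pool = [f"{_word(rng, 2).capitalize()} {_word(rng, 3).capitalize()} ({country})"
                         for _ in range(n_recorded)]
        identified_pool = recorded_pool[:n_identified]
        clean = []
        for i, agent in enumerate(recorded_pool):
            clean.append((agent, identified_pool[i % n_identified]))
        n_extra = max(0, config.occurrences_per_country - len(clean))
        for _ in range(n_extra):
            agent = recorded_pool[int(rng.integers(0, n_recorded))]
            ident = (identified_pool[int(rng.integers(0, n_identified))]
                     if rng.random() < 0.5 else "")
            clean.append((agent, ident))
        for agent, ident in clean:
            rows.append({
                "countryCode": country,
                "year": int(rng.integers(2014, 2024)),
                "occurrenceStatus": "PRESENT",
                "issue": "",
                "recordedBy": agent,
                "identifiedBy": ident,
            })
        counts[country] = {
            "nRecords": len(clean),
            "nDistinctRecordedBy": n_recorded,
            "nDistinctIdentifiedBy": n_identified,
        }
        # contaminated records: excluded by exactly one filter each
        stray = f"Stray Agent ({country})"
        n_bad = int(round((config.occ_mismatch_rate + config.occ_absent_rate)
                          * config.occurrences_per_country))
        for bi in range(n_bad):
            kind = bi % 3
            rows.append({
                "countryCode": country,
                "year": 2010 if kind == 2 else int(rng.integers(2014, 2024)),
                "occurrenceStatus": "ABSENT" if kind == 0 else "PRESENT",
                "issue": MISMATCH if kind == 1 else "",
                "recordedBy": stray,
                "identifiedBy": stray,
            })
    return pd.DataFrame(rows), counts


MISMATCH = "COUNTRY_COORDINATE_MISMATCH"


def generate_population(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    rng = config.rng() if rng is None else rng
    countries = _EURO_COUNTRIES[: config.n_countries]
    return pd.DataFrame({
        "countryCode": countries,
        "population": [int(rng.integers(1, 85) * 1_000_000) for _ in countries],
    })


# ---------------------------------------------------------------------------
# fixture sets on disk


def write_fixture_set(config: GeneratorConfig, outdir) -> dict[str, Path]:
    """Generate every input and write it under ``outdir``; returns the paths.

    The same seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    backbone = generate_backbone(config, rng)
    corpus = generate_corpus(config, backbone, rng)
    policies = generate_policy_lists(config, backbone, rng)
    occurrences, agent_counts = generate_occurrences(config, rng)
    population = generate_population(config, rng)
    corpus.truth.agent_counts = agent_counts
    corpus.truth.true_beta = tuple(config.true_beta)

    paths = {}
    paths["backbone"] = outdir / "backbone.tsv"
    backbone.table.to_csv(paths["backbone"], sep="\t", index=False)
    paths["journals"] = outdir / "journals.tsv"
    write_journals_tsv(corpus.journals, paths["journals"])
    paths["articles"] = outdir / "articles.jsonl"
    write_articles_jsonl(corpus.articles, paths["articles"])
    policy_dir = outdir / "policies"
    policy_dir.mkdir(exist_ok=True)
    for policy, df in policies.items():
        paths[f"policy:{policy}"] = policy_dir / f"{policy}.tsv"
        df.to_csv(paths[f"policy:{policy}"], sep="\t", index=False)
    paths["occurrences"] = outdir / "occurrences.tsv"
    occurrences.to_csv(paths["occurrences"], sep="\t", index=False)
    paths["population"] = outdir / "population.tsv"
    population.to_csv(paths["population"], sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.json"
    truth = corpus.truth
    serialisable = {
        "articleLabels": truth.article_labels,
        "expectedCorpusIds": sorted(truth.expected_corpus_ids),
        "collisionIds": sorted(truth.collision_ids),
        "plantedMentions": {k: sorted(v) for k, v in truth.planted_mentions.items()},
        "personPartition": truth.person_partition,
        "trueBeta": list(truth.true_beta),
        "agentCounts": truth.agent_counts,
        "orderRichness": truth.order_richness,
    }
    paths["ground_truth"].write_text(
        json.dumps(serialisable, indent=1, sort_keys=True, ensure_ascii=False),
        encoding="utf-8",
    )
    return paths
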