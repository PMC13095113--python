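# Methods

This note documents the models, rules and numerical choices implemented in
`taxcap`, the parameters that matter, and what the synthetic-data generator
does and does not emulate.

## Corpus construction

Journal records arrive from several discovery routes and are merged when
they share a Wikidata ID **or** an OpenAlex ID; the merge is the transitive
closure of those two relations (union-find), so the result is independent of
record order. Identifier fields take the union, with first-seen precedence
on conflicting scalars (conflicts are logged rather than resolved
heuristically). Only journals with an OpenAlex ID are usable downstream;
dissolved journals are retained because the date window removes their
articles naturally.

Article selection is a conjunction of five independent predicates — usable
journal, publication date in [2014-01-01, 2023-12-31], at least one author
with a European affiliation, life-sciences domain, and a positive
taxonomic-content test — so filter order cannot change the corpus. The
content test matches configured phrases case-insensitively as contiguous
substrings of the whitespace-normalised title and abstract. `nov.` is
matched with its literal period and in the abstract only, which makes it
hit `sp. nov.` and `gen. nov.` without firing on titles that quote
nomenclatural strings. The shipped keyword configuration
(`taxcap/data/keywords.yml`) seeds English phrases and standard
translations in eleven further languages; it is data, not code, and users
are expected to extend it. Europe is an explicit editable list of ISO
3166-1 alpha-2 codes (European Political Community members plus Vatican
City and European dependencies). Matching was chosen case-insensitive; the
alternative is not defensible for title-cased titles.

## Species-name extraction

Candidates are word pairs shaped like "Genus epithet": an uppercase letter
followed by ≥ 2 lowercase letters, whitespace, then ≥ 2 lowercase letters
with an optional internal hyphen. Letters cover ASCII plus Latin-1
diacritics. The pattern deliberately over-generates (e.g. a sentence like
"Here we…" yields a candidate): validation is exact lookup against the
backbone, and only backbone hits become mentions, so ordinary prose is
removed by the data rather than by linguistic special-casing. The ≥ 2
lower-case bounds suppress initials ("E. coli" as a *full* binomial) and
one-letter particles.

Abbreviated mentions ("C. monilis") are expanded only against genera
already confirmed by a full binomial in the same article, and only when the
initial matches exactly one confirmed genus; ambiguous initials are skipped
and logged, never guessed. Expanded candidates pass through the same
backbone gate. Duplicate taxa within an article collapse to the first
occurrence. Annotation replaces the mention list wholesale, so it is
idempotent.

The backbone loader indexes species-rank rows whose names are plain
two-token binomials; hybrid-marked and infraspecific names are counted and
skipped with a warning. Synonyms are indexed and matchable — a synonym
mention is still a backbone hit — but only accepted species count toward
per-order richness. Synonym hits can optionally be remapped to their
accepted record's order through `acceptedTaxonID` (default on in the demand
matrix); both behaviours are exposed because source lists differ in whether
their taxonomy is pre-reconciled.

## Author disambiguation

Author identities are first collapsed by their source author ID and
restricted to records with at least one European affiliation. Each record
carries two keys: the stripped name (spaces, periods, hyphens removed) and
the truncated name (first initial + last name, same removals; "Last,
First" inversions are normalised first). Two records merge when they have

* the same stripped name and a shared institution (**Rule 1**), or
* the same truncated name, a shared institution, and intersecting sets of
  taxonomic orders published on (**Rule 2**); when a record has no
  order-rank information the intersection test falls back to families.

Key comparison is case-insensitive; diacritics are preserved by default
because ASCII folding conflates distinct Eastern-European names (an
optional folding switch exists). "Shared institution" means intersecting
institution-identifier sets, with name-string equality as a fallback only
when both records lack identifiers. "Same taxonomic orders" is a nonempty
intersection rather than set equality — equality would essentially never
hold for multi-order authors. Pairwise matches are closed transitively with
union-find, so the merged partition is order-independent and a second pass
merges nothing.

Merge quality is scored pairwise against a ground-truth partition:
precision and recall over same-person pairs, with precision reported as 1.0
(with a warning) when the system proposes no pairs. The residual-duplicate
bound multiplies the missed-pair rate observed in a validation sample by
the fraction of authors sharing truncated names — only such authors can be
residual duplicates — and reports the product as a percentage.

## Demand matrix and regression

Nine policy instruments define the demand predictors:
`taxonomicResearchNeeded`, `cropWildRelatives`, `iasListConcern`,
`horizonInvasives`, `habitatsDir`, `marineDir`, `redlistFull`, `birdDir`,
`pollinators`. Each list resolves against the backbone; unresolved names
are kept in a per-policy ledger rather than dropped, since policy lists
rarely carry persistent identifiers and match failure is itself a finding.
The matrix rows are backbone orders; columns are the nine policy counts,
accepted-species richness, and disambiguated author counts.

All counts enter the regression as ln(x + 1). The fit is Huber-T
M-estimation via IRLS:

* tuning constant c = 1.345 (95% efficiency at the Gaussian), configurable;
* scale re-estimated each iteration as MAD about zero divided by 0.6745;
* convergence when the max absolute coefficient change < 1e-8 (≤ 50
  iterations; non-convergence returns a flagged result rather than raising);
* standard errors from the standard Huber sandwich with the small-sample
  correction factor, p-values asymptotic normal (how robust-coefficient
  p-values should be computed is genuinely open; the asymptotic choice is
  the common default and is stated, not hidden);
* an exactly interpolating fit (zero MAD) short-circuits with unit weights
  and zero scale.

The implementation agrees with an established robust-regression routine to
~1e-5 on shared test problems; that routine is used only as a cross-check
oracle, never as the implementation.

The combined model (richness + nine policies) is compared with the
species-only model by an F-test on residual sums of squares weighted by the
full model's final IRLS weights. This construction is an explicit choice —
robust model comparison has no single canonical form — and is pinned by its
OLS limit: with all weights 1 it reduces exactly to the textbook
nested-model F-test. Identical designs return F = 0, p = 1.

Diagnostics: Shapiro–Wilk on residuals (delegated to scipy), Durbin–Watson
(Σ of squared successive differences over Σ of squares, always in [0, 4]),
and the Breusch–Pagan LM statistic (n·R² of squared residuals on the
design; the exactly-homoscedastic degenerate case returns 0 by definition).
Rows with |residual| / σ̂ above a threshold (default 3) are flagged as
outlier orders, sorted by magnitude. Intercepts are always included;
predictors are never standardised for fitting — the separate
relative-importance report uses |β̂ⱼ|·sd(Xⱼ)/sd(y). Per-coefficient
p-values are reported unadjusted.

Per-order taxonomist-per-species ratios are author count / richness to
three decimals (undefined, reported missing, at zero richness), and
country-level counts are related to population by Pearson correlation with
the two-sided t-transform p-value.

## Occurrence agents

Occurrence records are filtered to status PRESENT (case-insensitive), no
COUNTRY_COORDINATE_MISMATCH flag, and years 2014–2023 inclusive; the three
filters are independent predicates. Distinctness of `recordedBy` /
`identifiedBy` is on the verbatim string with only outer whitespace
trimmed — the fields are uncontrolled text that may name a person, an
organisation or an expedition, and any normalisation silently conflates
agents. Empty strings never count. Output is sorted ascending by record
count.

## The synthetic-data generator

The generator defines the package's study conditions. Defaults: 20 orders
with 30 ± 50% accepted species each (the spread keeps ln-richness from
being collinear with the intercept), 20% synonym rows, 30 journals (25%
lacking an OpenAlex ID, planted duplicate rows), 220 articles of which half
are taxonomic, 70 persons with 15% carrying duplicate IDs (alternating
Rule-1 and Rule-2 name variants) and 10% truncated-name collision twins at
different institutions, and 8 countries of occurrence records with known
agent pools.

Taxonomic articles always satisfy every non-keyword filter, so label
recovery isolates the classifier; keyword evidence is planted across
languages, including abstract-only `nov.` cases and concept-tag-only cases.
Planted binomials come from the backbone, decoy look-alikes do not, and
abbreviation plants use genus initials kept unique within an article so
expansion is never ambiguous. Non-taxonomic articles exercise the other
filters (out-of-window dates, non-European-only affiliations, foreign
domains) and, under a configurable collision rate, carry planted keyword
false positives recorded in the ground truth.

Regression data are drawn on the ln scale with ln-richness ~ U(0.5, 9.5)
(order sizes from a handful of species to ~10⁴) and sparse policy
incidence: each policy touches ~35% of orders and contributes zero
elsewhere, as taxon-specific instruments do. The response is rebuilt from
the rounded integer predictors, so the only departures from the linear
model are the Gaussian noise (default σ = 0.3), response rounding, and any
configured gross contamination (± 4–8 ln units on a fraction of rows).
Default coefficients follow the qualitative pattern of interest — richness
and research-needed/habitats/birds positive, marine negative, the rest
weak or zero.

All randomness flows through one seeded generator; a fixed seed regenerates
every file byte for byte. Synthetic taxon and person names are
syllable-built non-words, so no statement about real taxa is implied.

What the generator does **not** emulate: citation-network structure,
realistic journal titles, abstract reconstruction from inverted indexes,
OCR noise, author-name transliteration variants beyond the planted rules,
multi-person agent strings, and the long-tailed richness distribution of a
real backbone. Passing tests therefore demonstrate correctness of the
rules and estimators under controlled conditions, not field performance of
the classifier or the disambiguator on real bibliographic noise.

## Problem sizes and limitations

The test suite runs the whole battery — 100-seed parameter-recovery and
contamination studies at n = 120, a 1,000-replicate Breusch–Pagan
calibration at n = 200, and the end-to-end pipeline on the default fixture
set — in a few seconds on one CPU; these sizes were chosen as the smallest
at which the sampling error of the checked statistics is comfortably below
the asserted bounds.

Known limitations: exact backbone matching means misspelled names are
invisible (no fuzzy matching by design); the disambiguator cannot split one
author ID shared by two people; agent-string counts conflate people,
organisations and expeditions; and the regression is associational — the
direction of influence between policy attention and taxonomic effort is not
identified by this design.
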