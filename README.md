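# taxcap

Measuring the supply of taxonomic expertise against biodiversity-policy
demand, from bibliographic metadata.

Taxonomy underpins conservation law — the EU Birds and Habitats Directives,
the Marine Strategy Framework Directive, invasive-species regulation, Red
List assessment — yet the people able to identify and describe species are
unevenly spread across taxa and countries (the "taxonomic impediment").
`taxcap` implements an offline, reproducible version of a bibliometric
workflow that quantifies this mismatch for researchers and science-policy
analysts:

1. **corpus** — deduplicate journal records (union-find over shared
   Wikidata/OpenAlex identifiers), keep usable journals, and select
   taxonomic articles by a 2014–2023 window, a European-affiliation
   requirement, a life-sciences domain gate, and a multilingual
   keyword/concept filter (*taxonomic*, *new species*, *nov.*
   abstract-only, … in 12 languages).
2. **names** — extract "Genus species" word pairs from titles and abstracts
   by capitalisation pattern, validate every candidate against a
   Darwin-Core-style taxonomic backbone (exact match only), and expand
   abbreviated "G. species" follow-ups of genera already confirmed in the
   same article.
3. **authors** — build stripped (`QuirinaJGroot`) and truncated (`QGroot`)
   name keys, merge duplicate author identities when they share a stripped
   name and an institution, or a truncated name, an institution and a
   taxonomic order (family-rank fallback), with union-find closure; quantify
   merge precision/recall against ground truth.
4. **demand** — resolve nine policy species lists against the backbone into
   an order × policy count matrix, alongside per-order accepted-species
   richness and disambiguated author counts.
5. **supply_demand** — fit the robust log-log regression

   ln(authors + 1) = β₀ + β₁ ln(richness + 1) + Σⱼ βⱼ ln(policyⱼ + 1) + ε

   by Huber-T M-estimation (IRLS, MAD scale, c = 1.345), compare the
   combined model against the species-only model with a nested F-test on
   robustly weighted residual sums of squares, and run Shapiro–Wilk,
   Durbin–Watson and Breusch–Pagan diagnostics plus standardized-residual
   outlier flags (|r|/σ̂ > 3).
6. **geo** — count distinct verbatim `recordedBy` / `identifiedBy` agent
   strings per country from occurrence records (status PRESENT, no
   country–coordinate mismatch, 2014–2023) and relate counts to population.
7. **synthetic** — generate every input with planted ground truth (article
   labels, species mentions, duplicate-author structure, regression
   coefficients, agent pools) so the whole pipeline is testable offline.

Live harvesting from bibliographic and occurrence APIs is out of scope; the
package operates on files (TSV/JSONL) whose schemas are strict subsets of
the upstream services' records, and ships a generator that emulates them.

## Worked example

Generate a synthetic order-level dataset with known coefficients
(n = 120 orders, noise σ = 0.3) and refit it:

```python
from taxcap.synthetic import GeneratorConfig, generate_regression_data
from taxcap.supply_demand import build_regression_dataset, fit_huber_rlm

table, beta = generate_regression_data(GeneratorConfig(seed=42))
ds = build_regression_dataset(table)
fit = fit_huber_rlm(ds.X, ds.y, column_names=ds.column_names)
for name, t, c in zip(ds.column_names, beta, fit.coefficients):
    print(f"{name:>25s}  true={t:+.3f}  est={c:+.3f}")
```

```
                intercept  true=+1.000  est=+1.095
          speciesRichness  true=+0.471  est=+0.462
  taxonomicResearchNeeded  true=+0.541  est=+0.578
        cropWildRelatives  true=+0.050  est=+0.064
           iasListConcern  true=+0.000  est=-0.016
         horizonInvasives  true=+0.000  est=-0.002
              habitatsDir  true=+0.348  est=+0.287
                marineDir  true=-0.273  est=-0.248
              redlistFull  true=+0.050  est=+0.033
                  birdDir  true=+0.369  est=+0.376
              pollinators  true=+0.000  est=+0.001
```

Each estimate is the Huber-robust slope on the ln scale: +0.46 for species
richness means a doubling of an order's described species multiplies its
expected author count by roughly 2^0.46 ≈ 1.4, holding policy demand fixed;
the negative marine coefficient means marine-listed orders attract fewer
authors than their richness alone predicts.

The full pipeline runs from the shell over a generated fixture directory:

```sh
taxcap simulate --seed 42 --outdir fixtures/
taxcap run --fixtures fixtures/ --outdir out/
```

which prints the per-stage accounting (journals deduplicated 32 → 30, 22
usable; 220 articles in, 110 retained; 87 author identities merged to 77)
and writes `out/report.json` with the fit, diagnostics and per-country
summaries.

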