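"""End-to-end orchestration: corpus -> names -> authors -> demand ->
regression -> geo, with materialised intermediates and a machine-readable
run report.

Every stage writes its artifact (JSONL/CSV) so any stage can be rerun in
isolation; the report is the single source of truth for the run's numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import authors as authors_mod
from . import backbone as backbone_mod
from . import corpus as corpus_mod
from . import demand as demand_mod
from . import geo as geo_mod
from . import names as names_mod
from . import supply_demand as sd_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    backbone_path: str
    journals_path: str
    articles_path: str
    policy_paths: dict[str, str]
    output_dir: str
    occurrences_path: str | None = None
    population_path: str | None = None
    keyword_config_path: str | None = None
    fit_config: sd_mod.FitConfig = field(default_factory=sd_mod.FitConfig)
    remap_synonyms: bool = True
    outlier_threshold: float = 3.0
    agent_year_start: int = 2014
    agent_year_end: int = 2023


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, set):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    kw = (corpus_mod.KeywordConfig.from_yaml(config.keyword_config_path)
          if config.keyword_config_path else corpus_mod.KeywordConfig.default())

    # corpus
    journals = corpus_mod.read_journals_tsv(config.journals_path)
    deduped = corpus_mod.dedupe_journals(journals)
    usable = corpus_mod.select_usable_journals(deduped)
    articles = corpus_mod.read_articles_jsonl(config.articles_path)
    corpus = corpus_mod.filter_articles(articles, usable, kw)
    corpus_mod.write_articles_jsonl(corpus, outdir / "corpus.jsonl")
    report["stages"]["corpus"] = {
        "journals_in": len(journals),
        "journals_deduped": len(deduped),
        "journals_usable": len(usable),
        "articles_in": len(articles),
        "articles_retained": len(corpus),
    }

    # names
    index = backbone_mod.load_backbone(config.backbone_path)
    for article in corpus:
        names_mod.annotate_article_species(article, index)
    corpus_mod.write_articles_jsonl(corpus, outdir / "annotated.jsonl")
    report["stages"]["names"] = {
        "backbone_binomials": len(index),
        "articles_with_mentions": sum(1 for a in corpus if a.species_mentions),
        "total_mentions": sum(len(a.species_mentions) for a in corpus),
    }

    # authors
    author_records = authors_mod.extract_authors(corpus, kw.european_country_codes)
    merged, merge_report = authors_mod.merge_duplicates(author_records)
    report["stages"]["authors"] = {
        "authors_before_merge": merge_report.n_before,
        "authors_after_merge": merge_report.n_after,
        "merged_pairs": len(merge_report.merged_pairs),
    }
    with open(outdir / "authors_merged.jsonl", "w", encoding="utf-8") as fh:
        for rec in merged:
            fh.write(json.dumps(_jsonable(rec), sort_keys=True) + "\n")

    # demand
    policy_lists = demand_mod.load_policy_lists(config.policy_paths)
    authors_by_order: dict[str, int] = {}
    for rec in merged:
        for order in rec.orders_published:
            authors_by_order[order] = authors_by_order.get(order, 0) + 1
    matrix = demand_mod.build_policy_matrix(
        policy_lists, index, authors_by_order, remap_synonyms=config.remap_synonyms
    )
    matrix.table.to_csv(outdir / "matrix.csv")
    report["stages"]["demand"] = {
        "orders": len(matrix.table),
        "unresolved": {k: len(v) for k, v in matrix.unresolved.items()},
    }

    # supply vs demand regression
    dataset = sd_mod.build_regression_dataset(matrix)
    n, p = dataset.X.shape
    if n > p and np.linalg.matrix_rank(dataset.X) == p:
        full = sd_mod.fit_huber_rlm(
            dataset.X, dataset.y, config.fit_config,
            column_names=dataset.column_names, row_labels=dataset.row_labels,
        )
        X_reduced = dataset.X[:, :2]  # intercept + richness
        reduced = sd_mod.fit_huber_rlm(
            X_reduced, dataset.y, config.fit_config,
            column_names=dataset.column_names[:2], row_labels=dataset.row_labels,
        )
        comparison = sd_mod.compare_models_f(full, reduced, dataset.X, X_reduced)
        diag = (sd_mod.diagnostics(full, dataset.X, config.outlier_threshold)
                if full.scale > 0 else None)
        ratios = {
            label: sd_mod.taxonomists_per_species(
                int(matrix.table.loc[label, "authorCount"]),
                int(matrix.table.loc[label, "speciesRichness"]),
            )
            for label in matrix.table.index
        }
        report["stages"]["regression"] = {
            "fit": _jsonable(full),
            "reduced_fit_coefficients": _jsonable(reduced.coefficients),
            "model_comparison": _jsonable(comparison),
            "diagnostics": _jsonable(diag) if diag else None,
            "taxonomists_per_species": _jsonable(ratios),
        }
    else:
        report["stages"]["regression"] = {
            "skipped": f"design not estimable ({n} rows, {p} columns)"
        }

    # geo (optional stage)
    if config.occurrences_path and Path(config.occurrences_path).exists():
        occurrences = geo_mod.read_occurrences_tsv(config.occurrences_path)
        summaries = geo_mod.count_distinct_agents(
            occurrences, config.agent_year_start, config.agent_year_end
        )
        geo_report = {"countries": [_jsonable(s) for s in summaries]}
        if config.population_path and Path(config.population_path).exists():
            import pandas as pd

            pop_df = pd.read_csv(config.population_path, sep="\t")
            population = dict(zip(pop_df["countryCode"], pop_df["population"]))
            counts = {s.country_code: s.n_distinct_recorded_by for s in summaries}
            geo_report["per_capita_pct"] = _jsonable(
                geo_mod.per_capita(counts, population)
            )
            if len(counts) >= 3:
                codes = [c for c in counts if c in population]
                r, p_val = sd_mod.pearson_correlation(
                    [counts[c] for c in codes], [population[c] for c in codes]
                )
                geo_report["population_correlation"] = {"r": r, "p": p_val}
        report["stages"]["geo"] = geo_report
    else:
        report["stages"]["geo"] = {"skipped": "no occurrence file configured"}
        log.info("geo stage skipped: no occurrence file")

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report
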