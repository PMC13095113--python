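import json
import pathlib

import pandas as pd
import pytest

from taxcap import backbone, corpus
from taxcap.synthetic import GeneratorConfig, write_fixture_set

BACKBONE_ROWS = [
    # taxonID, scientificName, rank, status, genus, family, order, class, phylum, kingdom, accepted
    ("T1", "Carabus auratus", "species", "accepted", "Carabus", "Carabidae",
     "Coleoptera", "Insecta", "Arthropoda", "Animalia", ""),
    ("T2", "Carabus monilis", "species", "accepted", "Carabus", "Carabidae",
     "Coleoptera", "Insecta", "Arthropoda", "Animalia", ""),
    ("T3", "Calosoma inquisitor", "species", "accepted", "Calosoma", "Carabidae",
     "Coleoptera", "Insecta", "Arthropoda", "Animalia", ""),
    ("T4", "Carabus cupreus", "species", "synonym", "Carabus", "Carabidae",
     "Coleoptera", "Insecta", "Arthropoda", "Animalia", "T1"),
    ("T5", "Carabus", "genus", "accepted", "Carabus", "Carabidae",
     "Coleoptera", "Insecta", "Arthropoda", "Animalia", ""),
    ("T6", "Abies alba", "species", "accepted", "Abies", "Pinaceae",
     "Pinales", "Pinopsida", "Tracheophyta", "Plantae", ""),
    ("T7", "Abies borisii", "species", "accepted", "Abies", "Pinaceae",
     "Pinales", "Pinopsida", "Tracheophyta", "Plantae", ""),
]

COLUMNS = ["taxonID", "scientificName", "taxonRank", "taxonomicStatus", "genus",
           "family", "order", "class", "phylum", "kingdom", "acceptedTaxonID"]


def write_backbone_tsv(path: pathlib.Path, rows=BACKBONE_ROWS) -> pathlib.Path:
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def small_backbone(tmp_path) -> backbone.BackboneIndex:
    """Seven-row hand-built backbone: 3+2 accepted species, 1 synonym, 1 genus row."""
    return backbone.load_backbone(write_backbone_tsv(tmp_path / "backbone.tsv"))


@pytest.fixture
def keyword_config() -> corpus.KeywordConfig:
    return corpus.KeywordConfig.default()


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One deterministic generated fixture set shared across the session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    config = GeneratorConfig(seed=20140101)
    paths = write_fixture_set(config, outdir)
    truth = json.loads(pathlib.Path(paths["ground_truth"]).read_text())
    return {"config": config, "paths": paths, "truth": truth, "dir": outdir}
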