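import numpy as np
import pytest

from soilbiogeo import (OtuTable, SyntheticConfig, generate_dataset,
                        load_maize_soil_metadata, rarefy)
from soilbiogeo.io import Lineage


@pytest.fixture(scope="session")
def survey_metadata():
    """The bundled 21-site maize-soil survey metadata."""
    return load_maize_soil_metadata()


@pytest.fixture
def tiny_table():
    """3 samples x 3 OTUs with simple hand-checkable counts."""
    lineages = [
        Lineage.parse("k__Bacteria; p__Proteobacteria; c__; o__; f__; g__Ramlibacter"),
        Lineage.parse("k__Bacteria; p__Actinobacteria; c__; o__; f__; g__Rhodococcus"),
        Lineage.parse("k__Bacteria; p__Actinobacteria; c__; o__; f__; g__"),
    ]
    counts = np.array([[3, 1, 0], [1, 1, 2], [2, 2, 2]])
    return OtuTable(["s1", "s2", "s3"], ["O1", "O2", "O3"], counts, lineages)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-structure synthetic survey at reduced OTU count (seeded)."""
    cfg = SyntheticConfig(n_otus=200, n_core=20, seed=7)
    landscape, table, tree, truth = generate_dataset(cfg)
    return cfg, landscape, table, tree, truth


@pytest.fixture(scope="session")
def synthetic_rarefied(synthetic_dataset):
    _, _, table, _, _ = synthetic_dataset
    return rarefy(table, seed=1)
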