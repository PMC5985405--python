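import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from magprofiler import synthetic
from magprofiler.core_io import GeneRecord


@pytest.fixture(scope="session")
def small_community():
    """A modest synthetic community reused by IO and pipeline tests."""
    cfg = synthetic.SimulationConfig(seed=20240911, n_pgs=30, genes_per_pg=(20, 40))
    return synthetic.generate_community(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1729)


def make_gene(gene_id, pg_id, sequence, categories=()):
    return GeneRecord(
        gene_id=gene_id, pg_id=pg_id, sequence=sequence, categories=set(categories)
    )


@pytest.fixture()
def quality_tsv(tmp_path):
    path = tmp_path / "quality.tsv"
    pd.DataFrame(
        {
            "pg_id": ["DTU247", "X50", "X60"],
            "completeness": [93.0, 50.0, 60.0],
            "contamination": [4.0, 0.0, 15.0],
        }
    ).to_csv(path, sep="\t", index=False)
    return path
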