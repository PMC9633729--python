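import numpy as np
import pandas as pd
import pytest

from riborescue.de_core import CountMatrix, SampleSheet


def make_sheet(conditions=("WT", "KO"), assays=("RNA",), replicates=2,
               library_size=1_000_000):
    rows = []
    for assay in assays:
        for cond in conditions:
            for rep in range(1, replicates + 1):
                rows.append({
                    "sample_id": f"{assay}_{cond}_r{rep}",
                    "condition": cond, "assay": assay, "replicate": rep,
                    "library_size": library_size,
                })
    return SampleSheet(pd.DataFrame(rows))


def make_counts(values, sample_ids, assay="RNA", gene_ids=None):
    values = np.asarray(values)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    return CountMatrix(counts=df, assay=assay)


@pytest.fixture
def two_group_sheet():
    return make_sheet()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
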