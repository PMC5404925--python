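import numpy as np
import pandas as pd
import pytest

from osncistrans import (CisTransOptions, CountMatrix, cistrans_analysis,
                         infer_gene_classes, simulate_cistrans_dataset)


def make_matrix(counts, genes=None, samples=None, classes=None, meta=None) -> CountMatrix:
    """Small helper: wrap a 2-D array into a CountMatrix."""
    counts = np.asarray(counts)
    genes = genes or [f"Olfr{i + 1:04d}" for i in range(counts.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                      columns=pd.Index(samples, name="sample"))
    if classes is None:
        gene_class = infer_gene_classes(genes)
    else:
        gene_class = pd.Series(classes, index=df.index)
    return CountMatrix(df, gene_class, meta)


@pytest.fixture(scope="session")
def cis_dataset():
    """Reference cis-mode study: 1000 OR genes, 3+3 parental and 3 F1 replicates."""
    return simulate_cistrans_dataset(mode="cis", seed=1)


@pytest.fixture(scope="session")
def cis_report(cis_dataset):
    return cistrans_analysis(cis_dataset["b6"], cis_dataset["cast"],
                             cis_dataset["f1_total"], cis_dataset["f1_allelic"],
                             CisTransOptions(seed=1))


@pytest.fixture(scope="session")
def trans_dataset():
    return simulate_cistrans_dataset(mode="trans", seed=1)


@pytest.fixture(scope="session")
def trans_report(trans_dataset):
    return cistrans_analysis(trans_dataset["b6"], trans_dataset["cast"],
                             trans_dataset["f1_total"], trans_dataset["f1_allelic"],
                             CisTransOptions(seed=1))
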