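import numpy as np
import pandas as pd
import pytest

from stemscreen import synthetic as syn
from stemscreen.de import CountMatrix


@pytest.fixture(scope="session")
def small_screen():
    """A 40-gene screen with the default three planted GSC hits."""
    truth = syn.default_screen_truth(cells_per_well=100)
    return truth, syn.gen_screen(truth, n_genes=40, seed=11)


@pytest.fixture(scope="session")
def planted_counts():
    """2000-gene, 3-pair paired count matrix with 10% planted DE at +-1.5."""
    truth = syn.make_de_truth(n_genes=2000, n_pairs=3, seed=7)
    return truth, syn.gen_counts(truth, seed=7)


@pytest.fixture(scope="session")
def planted_collection():
    """Four planted clusters x eight sets, disjoint gene pools."""
    truth = syn.make_cluster_truth(seed=5)
    return truth, syn.gen_genesets(truth, seed=5)


@pytest.fixture(scope="session")
def planted_cells():
    """5000 cells per condition under the default assay scenario."""
    truth = syn.default_cell_truth()
    cells = pd.concat(
        [syn.gen_cells(truth, n_cells=5000, condition=c, seed=13)
         for c in ("control", "treated")],
        ignore_index=True,
    )
    return truth, cells


def tiny_count_matrix(counts, lengths=None, pairs=None):
    """Hand-built CountMatrix: `counts` is gene -> per-sample list."""
    genes = list(counts)
    n = len(next(iter(counts.values())))
    samples = [f"P{i // 2 + 1}_{'AB'[i % 2]}" for i in range(n)]
    counts_df = pd.DataFrame.from_dict(counts, orient="index", columns=samples)
    lengths = pd.Series(lengths if lengths is not None else 1000, index=genes, dtype=float)
    meta = pd.DataFrame({
        "condition": ["AB"[i % 2] for i in range(n)],
        "pair": pairs if pairs is not None else [f"P{i // 2 + 1}" for i in range(n)],
    }, index=pd.Index(samples, name="sample"))
    return CountMatrix(counts_df, lengths, meta)
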