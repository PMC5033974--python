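import pandas as pd
import pytest

from polydosage.expression_io import average_replicates, compute_fpkm
from polydosage.panel import build_genotype_panel
from polydosage.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def panel():
    return build_genotype_panel()


@pytest.fixture(scope="session")
def small_sim(panel):
    """A modest default-condition simulation shared across test modules."""
    config = SimConfig(n_pairs=200, seed=11)
    dataset, truth = generate_dataset(config, panel)
    return config, dataset, truth


@pytest.fixture(scope="session")
def small_sim_means(small_sim):
    """FPKM genotype means and gene->subgenome map for the shared simulation."""
    _, dataset, _ = small_sim
    fpkm = compute_fpkm(dataset.counts, dataset.lengths, dataset.totals())
    gmeans = average_replicates(fpkm, dataset.samples)
    gene_subgenome = pd.Series(
        ["A"] * len(dataset.pairs) + ["C"] * len(dataset.pairs),
        index=list(dataset.pairs["a_gene_id"]) + list(dataset.pairs["c_gene_id"]),
    )
    return fpkm, gmeans, gene_subgenome
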