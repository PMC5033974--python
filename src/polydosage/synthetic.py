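"""Synthetic allopolyploid transcriptome generator with known ground truth.

The generator emulates the study design that motivates this package: a panel
of six genotypes built from two parental subgenomes, two biological
replicates per genotype, and homoeologous gene pairs whose expression
responds to the *relative* dosage of their subgenome.

Per homoeolog-pair model
------------------------
Every pair draws one lognormal per-copy transcription rate.  Each pair
member is independently labelled:

``dependent``
    expected abundance proportional to rate x relative dosage, so FPKM
    tracks the dosage series (1, 2/3, 1/2, 1/2, 1/3) exactly at zero noise;
``independent``
    expected abundance constant across every genotype carrying the
    subgenome (full dosage compensation);
``inverse``
    expected abundance proportional to rate x (ceiling - relative dosage)
    with ceiling > 1, a strictly decreasing function of dosage.

Each pair additionally carries a regulatory-divergence label:

``cis``
    the two homoeologs get per-copy rates offset by ``cis_log2_offset``
    log2 units, identically in parents and hybrids (ratio preserved);
``trans``
    parental rates are offset but both homoeologs revert to the shared base
    rate in any genotype containing both subgenomes.

Reads compete for a fixed library.  The analysed homoeolog pairs are
modelled as a subset of a larger, compositionally stable transcriptome: each
gene's expected fraction of the library is its abundance divided by a single
genotype-independent normaliser (``background_scale`` times the largest
per-genotype abundance mass); the remaining reads are background (genes
outside the pair set).  Replicate counts are negative binomial
(gamma-Poisson) around the expected fraction x library size, or exactly
multinomial when ``dispersion`` is zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .panel import GenotypePanel, build_genotype_panel, relative_dosage

DEPENDENCE_LABELS = ("dependent", "independent", "inverse")
DIVERGENCE_LABELS = ("none", "cis", "trans")

# Fixed per-stage offsets mixed into the seed so that the labelling, count
# and gene-length streams are independent yet individually reproducible.
_SEED_LABELS = 11
_SEED_COUNTS = 13
_SEED_LENGTHS = 17


@dataclass
class SimConfig:
    """Parameters of the synthetic allopolyploid experiment.

    Defaults describe the reference condition: ~60% dosage-dependent genes,
    a small inverse-dosage minority, two replicates, and overdispersed
    counts at a depth where most pairs clear an FPKM > 1 parental filter.
    """

    n_pairs: int = 2000
    fraction_dependent: float = 0.6
    fraction_inverse: float = 0.005
    fraction_cis_divergent: float = 0.17
    fraction_trans_divergent: float = 0.11
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.2
    dispersion: float = 0.05
    library_size: int = 2_000_000
    n_replicates: int = 2
    seed: int = 0
    gene_length_range: Tuple[int, int] = (500, 5000)
    cis_log2_offset: float = 1.5
    trans_log2_offset: float = 1.5
    background_scale: float = 2.0
    inverse_ceiling: float = 1.5

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in (
            "fraction_dependent",
            "fraction_inverse",
            "fraction_cis_divergent",
            "fraction_trans_divergent",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.fraction_dependent + self.fraction_inverse > 1.0 + 1e-12:
            raise ValueError(
                "fraction_dependent + fraction_inverse exceeds 1; the "
                "remainder is the dosage-independent mass"
            )
        if self.fraction_cis_divergent + self.fraction_trans_divergent > 1.0 + 1e-12:
            raise ValueError("cis + trans divergence fractions exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.background_scale < 1.0:
            raise ValueError("background_scale must be >= 1")
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must satisfy 1 <= min <= max")
        if self.inverse_ceiling <= 1.0:
            raise ValueError("inverse_ceiling must exceed the maximal dosage (1)")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["gene_length_range"] = list(self.gene_length_range)
        return out


@dataclass
class SimTruth:
    """Generative ground truth for one simulated dataset.

    ``genes`` is indexed by gene id with columns ``pair_id``, ``subgenome``,
    ``dependence``, ``rate_parent`` and ``rate_hybrid`` (per-copy rates in
    the pure-parent and mixed-genotype contexts; they differ only for
    trans-divergent pairs).  ``pairs`` is indexed by pair id with columns
    ``a_gene_id``, ``c_gene_id`` and ``divergence``.
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame


def _gene_ids(n_pairs: int) -> Tuple[list, list, list]:
    width = max(5, len(str(n_pairs)))
    pair_ids = [f"p{i:0{width}d}" for i in range(1, n_pairs + 1)]
    a_genes = [f"gA{i:0{width}d}" for i in range(1, n_pairs + 1)]
    c_genes = [f"gC{i:0{width}d}" for i in range(1, n_pairs + 1)]
    return pair_ids, a_genes, c_genes


def assign_regulatory_classes(config: SimConfig) -> SimTruth:
    """Draw dependence labels, divergence labels and per-copy rates.

    Dependence labels are drawn independently for the A and C member of each
    pair, so pair-group frequencies follow the product of the marginals.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _SEED_LABELS])
    n = config.n_pairs
    pair_ids, a_genes, c_genes = _gene_ids(n)

    p_dep = config.fraction_dependent
    p_inv = config.fraction_inverse
    dep_labels = rng.choice(
        DEPENDENCE_LABELS, size=2 * n, p=[p_dep, 1.0 - p_dep - p_inv, p_inv]
    )
    p_cis = config.fraction_cis_divergent
    p_trans = config.fraction_trans_divergent
    div_labels = rng.choice(
        DIVERGENCE_LABELS, size=n, p=[1.0 - p_cis - p_trans, p_cis, p_trans]
    )

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    offset = np.where(
        div_labels == "cis",
        config.cis_log2_offset,
        np.where(div_labels == "trans", config.trans_log2_offset, 0.0),
    )
    half = sign * offset / 2.0
    rate_a_parent = base * np.exp2(half)
    rate_c_parent = base * np.exp2(-half)
    # Trans divergence acts through diffusible factors shared in a common
    # nucleus: both homoeologs revert to the base rate in mixed genotypes.
    is_trans = div_labels == "trans"
    rate_a_hybrid = np.where(is_trans, base, rate_a_parent)
    rate_c_hybrid = np.where(is_trans, base, rate_c_parent)

    genes = pd.DataFrame(
        {
            "pair_id": pair_ids + pair_ids,
            "subgenome": ["A"] * n + ["C"] * n,
            "dependence": dep_labels,
            "rate_parent": np.concatenate([rate_a_parent, rate_c_parent]),
            "rate_hybrid": np.concatenate([rate_a_hybrid, rate_c_hybrid]),
        },
        index=pd.Index(a_genes + c_genes, name="gene_id"),
    )
    pairs = pd.DataFrame(
        {"a_gene_id": a_genes, "c_gene_id": c_genes, "divergence": div_labels},
        index=pd.Index(pair_ids, name="pair_id"),
    )
    return SimTruth(genes=genes, pairs=pairs)


def simulate_true_abundance(
    truth: SimTruth,
    panel: Optional[GenotypePanel] = None,
    inverse_ceiling: float = 1.5,
) -> pd.DataFrame:
    """Expected (noise-free) transcript abundance per gene and genotype.

    Abundances are on the per-copy-rate scale: a dependent gene contributes
    ``rate x relative_dosage``, an independent gene ``rate`` wherever its
    subgenome is present, an inverse gene ``rate x (ceiling - dosage)``.
    Genes of an absent subgenome contribute zero.
    """
    if panel is None:
        panel = build_genotype_panel()
    genes = truth.genes
    out = pd.DataFrame(0.0, index=genes.index, columns=panel.names)
    dep = genes["dependence"].to_numpy()
    for genotype in panel.names:
        a, c = panel.copies(genotype)
        context = "rate_parent" if (a == 0 or c == 0) else "rate_hybrid"
        rate = genes[context].to_numpy()
        dosage = np.where(
            genes["subgenome"].to_numpy() == "A",
            relative_dosage(panel, genotype, "A"),
            relative_dosage(panel, genotype, "C"),
        )
        present = dosage > 0
        factor = np.select(
            [dep == "dependent", dep == "inverse"],
            [dosage, inverse_ceiling - dosage],
            default=1.0,
        )
        out[genotype] = np.where(present, rate * factor, 0.0)
    return out


def sample_counts(
    shares: pd.DataFrame,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw an integer count matrix (genes x samples) from expected abundances.

    ``shares`` has one column per genotype.  Each genotype is expanded to
    ``config.n_replicates`` samples named ``<genotype>_r<k>``.  The expected
    library fraction of gene g is ``shares[g] / K`` with the fixed
    normaliser ``K = background_scale x max per-genotype abundance mass``;
    counts are multinomial over genes plus a background bin when
    ``dispersion == 0``, otherwise gamma-Poisson per gene.
    """
    config.validate()
    values = shares.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("shares must be non-negative")
    col_sums = values.sum(axis=0)
    if (col_sums <= 0).any():
        bad = shares.columns[np.flatnonzero(col_sums <= 0)[0]]
        raise ValueError(f"all-zero abundance vector for genotype {bad!r}")
    if rng is None:
        rng = np.random.default_rng([config.seed, _SEED_COUNTS])
    norm = config.background_scale * col_sums.max()
    lib = config.library_size
    columns = {}
    for j, genotype in enumerate(shares.columns):
        frac = values[:, j] / norm
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion == 0:
                probs = np.append(frac, max(0.0, 1.0 - frac.sum()))
                draw = rng.multinomial(lib, probs / probs.sum())[:-1]
            else:
                mu = lib * frac
                shape = 1.0 / config.dispersion
                lam = np.where(
                    mu > 0,
                    rng.gamma(shape, np.maximum(mu, 1e-300) * config.dispersion),
                    0.0,
                )
                draw = rng.poisson(lam)
            columns[f"{genotype}_r{rep}"] = draw.astype(np.int64)
    out = pd.DataFrame(columns, index=shares.index)
    out.index.name = "gene_id"
    return out


def generate_dataset(
    config: SimConfig,
    panel: Optional[GenotypePanel] = None,
    out_dir: Optional[Path] = None,
):
    """Generate a full synthetic dataset and its ground truth.

    Returns ``(ExpressionDataset, SimTruth)``.  When ``out_dir`` is given the
    dataset and truth tables are also written there as TSV files that
    round-trip losslessly through :mod:`polydosage.expression_io`.
    """
    from .expression_io import ExpressionDataset, write_dataset

    config.validate()
    if panel is None:
        panel = build_genotype_panel()
    truth = assign_regulatory_classes(config)
    shares = simulate_true_abundance(truth, panel, config.inverse_ceiling)
    counts = sample_counts(shares, config)

    rng = np.random.default_rng([config.seed, _SEED_LENGTHS])
    lo, hi = config.gene_length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=len(truth.genes)),
        index=truth.genes.index,
        name="length_bp",
    )
    samples = pd.DataFrame(
        {
            "sample_id": list(counts.columns),
            "genotype": [s.rsplit("_r", 1)[0] for s in counts.columns],
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in counts.columns],
            # Total mapped reads of the library; the simulated pairs are a
            # subset of the transcriptome, so this exceeds the column sum.
            "total_reads": config.library_size,
        }
    )
    pairs = truth.pairs.reset_index()[["pair_id", "a_gene_id", "c_gene_id"]]
    dataset = ExpressionDataset(
        counts=counts, fpkm=None, samples=samples, pairs=pairs, lengths=lengths
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_dataset(dataset, out_dir)
        write_truth(truth, out_dir)
    return dataset, truth


def write_truth(truth: SimTruth, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    truth.genes.to_csv(out_dir / "truth_genes.tsv", sep="\t")
    truth.pairs.to_csv(out_dir / "truth_pairs.tsv", sep="\t")


def read_truth(in_dir: Path) -> SimTruth:
    in_dir = Path(in_dir)
    genes = pd.read_csv(in_dir / "truth_genes.tsv", sep="\t", index_col="gene_id")
    pairs = pd.read_csv(in_dir / "truth_pairs.tsv", sep="\t", index_col="pair_id")
    return SimTruth(genes=genes, pairs=pairs)
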