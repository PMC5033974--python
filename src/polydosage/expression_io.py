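"""Expression dataset container, FPKM, replicate averaging and pair filtering.

The pipeline starts from a gene-level count (or FPKM) matrix, a sample sheet
mapping libraries to genotypes and replicates, a homoeolog-pair table and
gene lengths.  This module reads and writes those tables, converts counts to
FPKM, averages replicates into per-genotype means, applies the
parental-expression filter (both homoeologs above an FPKM threshold in their
diploid parent) and computes mid-parent values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

PARENT_A = "AA"
PARENT_C = "CC"


@dataclass
class ExpressionDataset:
    """Counts and/or FPKM plus the sample, pair and length tables.

    Invariants checked on construction: at least one expression matrix is
    present; matrix columns and the sample sheet agree; identifiers are
    unique; every pair member is a row of the matrix; lengths (when present)
    are positive and cover every gene.
    """

    counts: Optional[pd.DataFrame]
    fpkm: Optional[pd.DataFrame]
    samples: pd.DataFrame
    pairs: pd.DataFrame
    lengths: Optional[pd.Series]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def matrix(self) -> pd.DataFrame:
        """The primary expression matrix (counts if present, else FPKM)."""
        return self.counts if self.counts is not None else self.fpkm

    def validate(self) -> None:
        if self.counts is None and self.fpkm is None:
            raise ValueError("dataset needs a count or an FPKM matrix")
        for required in ("sample_id", "genotype", "replicate"):
            if required not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {required!r}")
        sheet_ids = self.samples["sample_id"]
        if sheet_ids.duplicated().any():
            raise ValueError("duplicated sample_id in sample sheet")
        for mat, name in ((self.counts, "counts"), (self.fpkm, "fpkm")):
            if mat is None:
                continue
            if mat.index.duplicated().any():
                raise ValueError(f"duplicated gene ids in {name} matrix")
            missing = set(mat.columns) - set(sheet_ids)
            if missing:
                raise ValueError(
                    f"samples {sorted(missing)} in {name} matrix absent from sheet"
                )
        genes = set(self.matrix.index)
        for col in ("pair_id", "a_gene_id", "c_gene_id"):
            if col not in self.pairs.columns:
                raise ValueError(f"pair table lacks column {col!r}")
        if self.pairs["pair_id"].duplicated().any():
            raise ValueError("duplicated pair_id in pair table")
        for col in ("a_gene_id", "c_gene_id"):
            absent = set(self.pairs[col]) - genes
            if absent:
                raise ValueError(f"pair members missing from matrix: {sorted(absent)[:5]}")
        if self.lengths is not None:
            uncovered = genes - set(self.lengths.index)
            if uncovered:
                raise ValueError(f"genes without length: {sorted(uncovered)[:5]}")
            if (self.lengths <= 0).any():
                bad = self.lengths.index[self.lengths <= 0][0]
                raise ValueError(f"non-positive length for gene {bad!r}")

    def totals(self) -> pd.Series:
        """Per-sample total mapped reads for FPKM denominators.

        Uses the ``total_reads`` column of the sample sheet when present
        (the library may contain reads outside the analysed gene set),
        otherwise falls back to the column sums of the count matrix.
        """
        if "total_reads" in self.samples.columns:
            totals = self.samples.set_index("sample_id")["total_reads"]
            return totals.reindex(self.matrix.columns).astype(float)
        if self.counts is None:
            raise ValueError("no total_reads column and no count matrix")
        return self.counts.sum(axis=0).astype(float)


def compute_fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    totals: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm[g, s] = 1e9 * counts[g, s] / (totals[s] * lengths[g])``.
    ``totals`` defaults to the per-sample column sums of ``counts``.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if totals.isna().any():
        bad = totals.index[totals.isna()][0]
        raise ValueError(f"no read total for sample {bad!r}")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"non-positive read total for sample {bad!r}")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise ValueError(f"no length for gene {bad!r}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    fpkm = counts.div(totals.astype(float), axis=1).div(lengths.astype(float), axis=0)
    return fpkm * 1e9


def average_replicates(
    fpkm: pd.DataFrame,
    samples: pd.DataFrame,
    genotype_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Arithmetic mean of replicate FPKM per genotype (genes x genotypes)."""
    by_genotype = samples.set_index("sample_id")["genotype"].reindex(fpkm.columns)
    if genotype_order is None:
        genotype_order = list(dict.fromkeys(by_genotype))
    out = {}
    for genotype in genotype_order:
        cols = by_genotype.index[by_genotype == genotype]
        if len(cols) == 0:
            raise ValueError(f"genotype {genotype!r} has no samples")
        out[genotype] = fpkm[cols].mean(axis=1)
    means = pd.DataFrame(out)
    means.index.name = fpkm.index.name
    return means


def filter_expressed_pairs(
    pairs: pd.DataFrame,
    genotype_means: pd.DataFrame,
    threshold: float = 1.0,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Keep pairs expressed above ``threshold`` FPKM in both diploid parents.

    A pair is retained iff the A member exceeds the threshold in the AA
    parent *and* the C member exceeds it in the CC parent (strict
    inequality).  Returns the retained pair table and a report with counts
    and integer percentages.
    """
    for parent in (PARENT_A, PARENT_C):
        if parent not in genotype_means.columns:
            raise ValueError(f"parental genotype {parent!r} missing from means")
    a_expr = genotype_means[PARENT_A].reindex(pairs["a_gene_id"]).to_numpy()
    c_expr = genotype_means[PARENT_C].reindex(pairs["c_gene_id"]).to_numpy()
    keep = (a_expr > threshold) & (c_expr > threshold)
    retained = pairs.loc[keep].reset_index(drop=True)
    n_input = len(pairs)
    n_retained = int(keep.sum())
    n_removed = n_input - n_retained
    percent_removed = int(round(100.0 * n_removed / n_input)) if n_input else 0
    report = {
        "n_input": n_input,
        "n_retained": n_retained,
        "n_removed": n_removed,
        "percent_removed": percent_removed,
        "percent_retained": 100 - percent_removed if n_input else 0,
        "threshold": threshold,
    }
    return retained, report


def compute_mpv(genotype_means: pd.DataFrame) -> pd.Series:
    """Mid-parent value: per-gene mean of the two diploid parents' FPKM.

    For a subgenome-specific gene the non-carrier parent contributes
    whatever the matrix contains (zero in synthetic data), so the MPV is
    about half the carrier-parent expression.
    """
    for parent in (PARENT_A, PARENT_C):
        if parent not in genotype_means.columns:
            raise ValueError(f"parental genotype {parent!r} missing from means")
    mpv = (genotype_means[PARENT_A] + genotype_means[PARENT_C]) / 2.0
    mpv.name = "mpv"
    return mpv


# ---------------------------------------------------------------------------
# TSV round-trip

def write_dataset(dataset: ExpressionDataset, out_dir: Path) -> None:
    """Write the dataset as counts/fpkm, samples, pairs and lengths TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataset.counts is not None:
        dataset.counts.to_csv(out_dir / "counts.tsv", sep="\t")
    if dataset.fpkm is not None:
        dataset.fpkm.to_csv(out_dir / "fpkm.tsv", sep="\t")
    dataset.samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    dataset.pairs.to_csv(out_dir / "pairs.tsv", sep="\t", index=False)
    if dataset.lengths is not None:
        dataset.lengths.rename("length_bp").to_csv(
            out_dir / "lengths.tsv", sep="\t", index_label="gene_id"
        )


def read_dataset(in_dir: Path) -> ExpressionDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    counts = fpkm = lengths = None
    counts_path = in_dir / "counts.tsv"
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    fpkm_path = in_dir / "fpkm.tsv"
    if fpkm_path.exists():
        fpkm = pd.read_csv(fpkm_path, sep="\t", index_col="gene_id")
    samples = pd.read_csv(in_dir / "samples.tsv", sep="\t")
    pairs = pd.read_csv(in_dir / "pairs.tsv", sep="\t")
    lengths_path = in_dir / "lengths.tsv"
    if lengths_path.exists():
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length_bp"]
    return ExpressionDataset(
        counts=counts, fpkm=fpkm, samples=samples, pairs=pairs, lengths=lengths
    )
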