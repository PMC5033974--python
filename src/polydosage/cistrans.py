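"""Cis/trans partitioning of homoeolog regulatory divergence.

For a homoeolog pair with parental expressions PA (A member in its diploid
parent) and PC (C member in its parent), and hybrid expressions F1A and F1C
measured in one nucleus, the classical decomposition is

    A = log2(PA / PC)      total divergence (cis + trans)
    B = log2(F1A / F1C)    divergence surviving in a common trans
                           environment (cis)
    A - B                  trans component

Two significance calls decide the four-way category: a Fisher exact test of
the 2x2 count table [[PA, PC], [F1A, F1C]] for "A != B", and an exact
binomial test of F1A against F1A + F1C for "B != 0".  After BH adjustment
within each genotype and test family:

    A = B, B != 0  -> only_cis        A != B, B = 0  -> only_trans
    A = B, B = 0   -> no_effect       A != B, B != 0 -> cis_trans

Exact tests use replicate-summed integer read counts, library-normalised to
the smallest involved library; FPKM enters only the log-ratio point
estimates.  The binomial reference is 1/2 by default; with
``copy_correct=True`` it becomes the genotype's homoeolog copy ratio (2/3
in AAC, 1/3 in CCA), testing divergence beyond the copy-number expectation.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import adjust_bh
from .expression_io import PARENT_A, PARENT_C, ExpressionDataset
from .panel import GenotypePanel

CATEGORIES = ("no_effect", "only_cis", "only_trans", "cis_trans")


def log_ratio_components(
    pa, pc, f1a, f1c, pseudocount: float = 0.5
) -> Tuple[float, float, float]:
    """A, B and A - B log2 ratios with pseudocount-stabilised zeros.

    The pseudocount replaces exact zeros only; positive values are used as
    given.  ``trans = A - B`` holds as an exact arithmetic identity.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.asarray([pa, pc, f1a, f1c], dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    pa_, pc_, f1a_, f1c_ = np.where(vals > 0, vals, pseudocount)
    a_stat = float(np.log2(pa_ / pc_))
    b_stat = float(np.log2(f1a_ / f1c_))
    return a_stat, b_stat, a_stat - b_stat


def _as_count(x, name: str) -> int:
    xf = float(x)
    if xf < 0 or xf != int(xf):
        raise ValueError(f"{name} must be a non-negative integer count, got {x!r}")
    return int(xf)


def ratio_difference_test(pa_count, pc_count, f1a_count, f1c_count) -> float:
    """Two-sided Fisher exact p for parental vs hybrid homoeolog ratios."""
    table = [
        [_as_count(pa_count, "PA"), _as_count(pc_count, "PC")],
        [_as_count(f1a_count, "F1A"), _as_count(f1c_count, "F1C")],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def hybrid_balance_test(
    f1a_count, f1c_count, expected_a_fraction: float = 0.5
) -> Tuple[float, bool]:
    """Two-sided exact binomial test of the hybrid homoeolog ratio.

    Tests F1A successes out of F1A + F1C trials against the expected A
    fraction.  Returns ``(p, zero_flag)``; both counts zero is reported as
    p = 1 with the flag set.
    """
    if not 0.0 < expected_a_fraction < 1.0:
        raise ValueError("expected_a_fraction must be in (0, 1)")
    f1a = _as_count(f1a_count, "F1A")
    f1c = _as_count(f1c_count, "F1C")
    n = f1a + f1c
    if n == 0:
        return 1.0, True
    p = stats.binomtest(f1a, n, expected_a_fraction, alternative="two-sided").pvalue
    return float(p), False


def classify_cis_trans(p_diff_adj, p_b_adj, alpha: float = 0.05):
    """Four-way category from the two adjusted significance calls.

    "Equality" (A = B, or B = 0) means not significant at ``alpha``.
    Accepts scalars or arrays.
    """
    diff = np.asarray(p_diff_adj, dtype=float) < alpha
    bnz = np.asarray(p_b_adj, dtype=float) < alpha
    out = np.select(
        [~diff & bnz, diff & ~bnz, diff & bnz],
        ["only_cis", "only_trans", "cis_trans"],
        default="no_effect",
    )
    return out if out.ndim else str(out)


def _genotype_counts(
    dataset: ExpressionDataset,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Replicate-summed counts and total library sizes per genotype."""
    if dataset.counts is None:
        raise ValueError("cis/trans exact tests require a count matrix")
    genotype_of = dataset.samples.set_index("sample_id")["genotype"]
    totals = dataset.totals()
    summed = {}
    gtot = {}
    for genotype in dict.fromkeys(genotype_of):
        cols = [s for s in dataset.counts.columns if genotype_of[s] == genotype]
        summed[genotype] = dataset.counts[cols].sum(axis=1)
        gtot[genotype] = float(totals[cols].sum())
    return pd.DataFrame(summed), pd.Series(gtot)


def call_cis_trans(
    dataset: ExpressionDataset,
    genotype_means: pd.DataFrame,
    pairs: pd.DataFrame,
    panel: GenotypePanel,
    hybrids: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    copy_correct: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify every pair in every hybrid/polyploid genotype.

    Returns a long frame with one row per (pair, genotype): the A, B and
    A - B statistics (from genotype-mean FPKM), raw and BH-adjusted
    p-values of the two exact tests (from depth-normalised, replicate-
    summed counts), and the four-way category.
    """
    if hybrids is None:
        hybrids = [
            g
            for g in panel.names
            if panel.has_subgenome(g, "A") and panel.has_subgenome(g, "C")
        ]
    gcounts, gtotals = _genotype_counts(dataset)
    for parent in (PARENT_A, PARENT_C):
        if parent not in gcounts.columns:
            raise ValueError(f"parental genotype {parent!r} missing from counts")
    a_genes = pairs["a_gene_id"].to_numpy()
    c_genes = pairs["c_gene_id"].to_numpy()
    rows = []
    for genotype in hybrids:
        if genotype not in gcounts.columns:
            raise ValueError(f"hybrid genotype {genotype!r} missing from counts")
        ref = gtotals[[PARENT_A, PARENT_C, genotype]].min()
        scaled = {
            g: np.rint(gcounts[g].to_numpy() * (ref / gtotals[g])).astype(np.int64)
            for g in (PARENT_A, PARENT_C, genotype)
        }
        by_gene = {g: pd.Series(scaled[g], index=gcounts.index) for g in scaled}
        pa_c = by_gene[PARENT_A].reindex(a_genes).to_numpy()
        pc_c = by_gene[PARENT_C].reindex(c_genes).to_numpy()
        f1a_c = by_gene[genotype].reindex(a_genes).to_numpy()
        f1c_c = by_gene[genotype].reindex(c_genes).to_numpy()
        if copy_correct:
            a_copies, c_copies = panel.copies(genotype)
            expected = a_copies / (a_copies + c_copies)
        else:
            expected = 0.5
        pa_f = genotype_means[PARENT_A].reindex(a_genes).to_numpy()
        pc_f = genotype_means[PARENT_C].reindex(c_genes).to_numpy()
        f1a_f = genotype_means[genotype].reindex(a_genes).to_numpy()
        f1c_f = genotype_means[genotype].reindex(c_genes).to_numpy()
        for i, pair_id in enumerate(pairs["pair_id"].to_numpy()):
            a_stat, b_stat, t_stat = log_ratio_components(
                pa_f[i], pc_f[i], f1a_f[i], f1c_f[i], pseudocount
            )
            p_diff = ratio_difference_test(pa_c[i], pc_c[i], f1a_c[i], f1c_c[i])
            p_b, zero_flag = hybrid_balance_test(f1a_c[i], f1c_c[i], expected)
            rows.append(
                {
                    "pair_id": pair_id,
                    "genotype": genotype,
                    "A_stat": a_stat,
                    "B_stat": b_stat,
                    "trans_stat": t_stat,
                    "p_diff": p_diff,
                    "p_B": p_b,
                    "zero_hybrid_flag": zero_flag,
                }
            )
    calls = pd.DataFrame(rows)
    calls["p_diff_adj"] = np.nan
    calls["p_B_adj"] = np.nan
    # BH within each genotype, separately for the two test families.
    for genotype, idx in calls.groupby("genotype").groups.items():
        calls.loc[idx, "p_diff_adj"] = adjust_bh(calls.loc[idx, "p_diff"].to_numpy())
        calls.loc[idx, "p_B_adj"] = adjust_bh(calls.loc[idx, "p_B"].to_numpy())
    calls["category"] = classify_cis_trans(
        calls["p_diff_adj"].to_numpy(), calls["p_B_adj"].to_numpy(), alpha
    )
    calls.attrs["alpha"] = alpha
    calls.attrs["binomial_reference"] = "copy_ratio" if copy_correct else "half"
    return calls


def summarize_categories(calls: pd.DataFrame) -> Dict:
    """Category counts and percentages per genotype (result-table shape)."""
    out = {}
    for genotype, sub in calls.groupby("genotype"):
        n = len(sub)
        counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
        out[genotype] = {
            "n_pairs": n,
            "counts": counts,
            "percent": {c: 100.0 * counts[c] / n for c in CATEGORIES},
        }
    return out


def crosstab_categories(
    calls: pd.DataFrame,
    pair_groups: pd.Series,
    focus_groups: Sequence[str] = ("AdCd", "AiCi"),
) -> Dict:
    """Enrichment of dosage groups within only_cis / only_trans categories.

    For each genotype and each of the two effect categories, compares the
    observed count of pairs in a focus group (AdCd or AiCi) against the
    expectation from the group's overall frequency, with a 2x2 chi-square
    (category membership x group membership, no continuity correction) and
    an enrichment direction flag.
    """
    out = {}
    for genotype, sub in calls.groupby("genotype"):
        groups = pair_groups.reindex(sub["pair_id"]).to_numpy()
        if pd.isna(groups).any():
            raise ValueError("pair_groups does not cover all tested pairs")
        n = len(sub)
        res = {}
        for category in ("only_cis", "only_trans"):
            in_cat = (sub["category"] == category).to_numpy()
            n_cat = int(in_cat.sum())
            if n_cat == 0:
                warnings.warn(
                    f"no {category} pairs in {genotype}; cross-tab cell omitted",
                    stacklevel=2,
                )
                continue
            cells = {}
            for group in focus_groups:
                in_grp = groups == group
                observed = int((in_cat & in_grp).sum())
                expected = n_cat * in_grp.mean()
                table = np.array(
                    [
                        [observed, n_cat - observed],
                        [int((~in_cat & in_grp).sum()), int((~in_cat & ~in_grp).sum())],
                    ]
                )
                if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                else:
                    chi2, p = float("nan"), float("nan")
                cells[group] = {
                    "observed": observed,
                    "expected": float(expected),
                    "chi2": float(chi2),
                    "p": float(p),
                    "direction": "enriched" if observed > expected else (
                        "depleted" if observed < expected else "as_expected"
                    ),
                }
            res[category] = {"n": n_cat, "groups": cells}
        out[genotype] = {"n_pairs": n, "categories": res}
    return out
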