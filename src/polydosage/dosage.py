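"""Dosage-response correlation screen and gene/pair classification.

Each gene's replicate-averaged expression across the genotypes carrying its
subgenome is correlated (Pearson) against the relative-dosage series
(1, 2/3, 1/2, 1/2, 1/3).  Two-sided p-values come from the t transform
``t = r * sqrt(n - 2) / sqrt(1 - r^2)`` with ``n - 2`` degrees of freedom
and are Benjamini-Hochberg adjusted within each subgenome.  A gene is
*dosage dependent* when its adjusted p falls below alpha with positive r;
significant negative-r genes form the separate *inverse dosage effect* set;
everything else is *dosage independent* (compensated).  The empirical R^2
cutoff separating the classes is recomputed from each dataset rather than
hard-coded: it is an emergent consequence of the adaptive BH threshold.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import GenotypePanel, dosage_vector

GROUPS = ("AdCd", "AdCi", "AiCd", "AiCi")


def dosage_correlation(expr, dosage) -> Tuple[float, float, float]:
    """Pearson r, r^2 and two-sided p between expression and dosage.

    Constant input on either side yields ``(0, 0, 1)``: a perfectly flat
    (fully compensated) gene carries no evidence of a dosage response.
    Fewer than 3 points is an error.
    """
    expr = np.asarray(expr, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    if expr.shape != dosage.shape:
        raise ValueError("expression and dosage vectors differ in length")
    if expr.size < 3:
        raise ValueError("need at least 3 genotypes for a dosage correlation")
    if not (np.isfinite(expr).all() and np.isfinite(dosage).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(expr) == 0 or np.ptp(dosage) == 0:
        return 0.0, 0.0, 1.0
    r, p = stats.pearsonr(expr, dosage)
    r = float(np.clip(r, -1.0, 1.0))
    return r, r * r, float(p)


def _pearson_rows(values: np.ndarray, dosage: np.ndarray):
    """Row-wise Pearson r and two-sided t-test p for a genes x points matrix."""
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 dosage points")
    xc = values - values.mean(axis=1, keepdims=True)
    dc = dosage - dosage.mean()
    num = xc @ dc
    den = np.sqrt((xc**2).sum(axis=1) * (dc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    one_minus_r2 = np.maximum(1.0 - r * r, 0.0)
    t = np.where(
        one_minus_r2 > 0,
        r * np.sqrt(n - 2) / np.sqrt(np.where(one_minus_r2 > 0, one_minus_r2, 1.0)),
        np.where(r >= 0, np.inf, -np.inf),
    )
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(den > 0, np.minimum(p, 1.0), 1.0)
    return r, p


def dosage_screen(values: pd.DataFrame, dosage: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson screen of an expression matrix against a dosage series.

    ``values`` columns must match ``dosage``'s index (genotypes, or samples
    in replicate-level mode).  Returns a frame with columns r, r2, p.
    """
    aligned = values[list(dosage.index)]
    r, p = _pearson_rows(aligned.to_numpy(dtype=float), dosage.to_numpy(dtype=float))
    return pd.DataFrame({"r": r, "r2": r * r, "p": p}, index=values.index)


def screen_genes(
    genotype_means: pd.DataFrame,
    gene_subgenome: pd.Series,
    panel: GenotypePanel,
    fpkm: Optional[pd.DataFrame] = None,
    samples: Optional[pd.DataFrame] = None,
    mode: str = "genotype_mean",
) -> pd.DataFrame:
    """Run the dosage screen for both subgenomes.

    ``mode='genotype_mean'`` correlates the replicate-averaged values over
    the 5 carrier genotypes (one value per genotype, as in the worked
    series).  ``mode='replicate'`` instead uses every replicate library as
    its own point, which requires ``fpkm`` and ``samples``.
    The non-carrier parent is excluded from the correlation in both modes.
    """
    if mode not in ("genotype_mean", "replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    frames = []
    for subgenome in ("A", "C"):
        genes = gene_subgenome.index[gene_subgenome == subgenome]
        if len(genes) == 0:
            continue
        dosage = dosage_vector(panel, subgenome)
        if mode == "genotype_mean":
            res = dosage_screen(genotype_means.loc[genes], dosage)
        else:
            if fpkm is None or samples is None:
                raise ValueError("replicate mode needs fpkm and samples")
            genotype_of = samples.set_index("sample_id")["genotype"]
            cols = [s for s in fpkm.columns if genotype_of[s] in dosage.index]
            per_sample = pd.Series(
                [dosage[genotype_of[s]] for s in cols], index=cols
            )
            res = dosage_screen(fpkm.loc[genes, cols], per_sample)
        res.insert(0, "subgenome", subgenome)
        frames.append(res)
    if not frames:
        raise ValueError("no genes to screen")
    return pd.concat(frames)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_genes(
    screen: pd.DataFrame, alpha: float = 0.05
) -> Tuple[pd.DataFrame, Dict[str, Optional[float]]]:
    """Assign dependent/independent classes and report empirical r^2 cutoffs.

    BH adjustment is applied within each subgenome's family of tests.
    ``dependent`` requires adjusted p < alpha *and* r > 0; significant
    negative-r genes keep the ``independent`` class but are flagged as
    inverse-dosage.  The cutoff reported per subgenome is the minimum r^2
    among its dependent genes (None when there are none).
    """
    if len(screen) == 0:
        raise ValueError("empty screen results")
    out = screen.copy()
    out["p_adj"] = np.nan
    for subgenome, idx in out.groupby("subgenome").groups.items():
        out.loc[idx, "p_adj"] = adjust_bh(out.loc[idx, "p"].to_numpy())
    significant = out["p_adj"] < alpha
    out["class"] = np.where(significant & (out["r"] > 0), "dependent", "independent")
    out["inverse_flag"] = significant & (out["r"] < 0)
    cutoffs: Dict[str, Optional[float]] = {}
    for subgenome, sub in out.groupby("subgenome"):
        dependent_r2 = sub.loc[sub["class"] == "dependent", "r2"]
        cutoffs[subgenome] = float(dependent_r2.min()) if len(dependent_r2) else None
    return out, cutoffs


def group_pairs(classes: pd.Series, pairs: pd.DataFrame) -> Dict:
    """Cross-classify homoeolog pairs into AdCd / AdCi / AiCd / AiCi.

    ``classes`` maps gene id to 'dependent'/'independent'.  Expected group
    proportions are the products of the two marginal class proportions; the
    observed counts are compared to them with a chi-square goodness-of-fit
    test (df = 3, no continuity correction).
    """
    for col in ("a_gene_id", "c_gene_id"):
        missing = set(pairs[col]) - set(classes.index)
        if missing:
            raise ValueError(f"unclassified pair members: {sorted(missing)[:5]}")
    a_dep = (classes.reindex(pairs["a_gene_id"]) == "dependent").to_numpy()
    c_dep = (classes.reindex(pairs["c_gene_id"]) == "dependent").to_numpy()
    group = np.select(
        [a_dep & c_dep, a_dep & ~c_dep, ~a_dep & c_dep],
        ["AdCd", "AdCi", "AiCd"],
        default="AiCi",
    )
    groups = pd.Series(group, index=pairs["pair_id"].to_numpy(), name="group")
    n = len(pairs)
    counts = {g: int((group == g).sum()) for g in GROUPS}
    p_a, p_c = a_dep.mean(), c_dep.mean()
    expected_prop = {
        "AdCd": p_a * p_c,
        "AdCi": p_a * (1 - p_c),
        "AiCd": (1 - p_a) * p_c,
        "AiCi": (1 - p_a) * (1 - p_c),
    }
    expected_counts = np.array([expected_prop[g] * n for g in GROUPS])
    observed = np.array([counts[g] for g in GROUPS], dtype=float)
    if expected_counts.min() > 0:
        chi2, p = stats.chisquare(observed, f_exp=expected_counts)
        chi2, p = float(chi2), float(p)
    else:  # degenerate marginals: the test is undefined
        chi2 = p = float("nan")
    return {
        "n_pairs": n,
        "counts": counts,
        "observed_percent": {g: 100.0 * counts[g] / n for g in GROUPS},
        "expected_percent": {g: 100.0 * expected_prop[g] for g in GROUPS},
        "expected_percent_rounded": {
            g: int(round(100.0 * expected_prop[g])) for g in GROUPS
        },
        "marginal_dependent": {"A": float(p_a), "C": float(p_c)},
        "chi2": chi2,
        "chi2_p": p,
        "groups": groups,
    }


def detect_inverse_dosage(classified: pd.DataFrame) -> Dict:
    """Negative-correlation genes, with the significant subset per subgenome."""
    negative = classified[classified["r"] < 0]
    significant = classified[classified["inverse_flag"]]
    counts = {}
    for subgenome in ("A", "C"):
        sub_all = negative[negative["subgenome"] == subgenome]
        sub_sig = significant[significant["subgenome"] == subgenome]
        counts[subgenome] = {
            "negative": int(len(sub_all)),
            "significant": int(len(sub_sig)),
        }
    return {"negative": negative, "significant": significant, "counts": counts}
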