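"""Mid-parent fold-change analysis of expression divergence.

The additivity baseline for every gene is its mid-parent value (MPV); the
fold change ``FC = genotype-mean FPKM / MPV`` quantifies divergence from it.
This module builds the per-gene fold-change table, summarises its
distribution (median and interquartile bounds) per genotype and subgenome,
compares subgenomes with Wilcoxon tests, and bins fold changes inside/
outside a near-additive band (0.5-1.5 by default, closed on both sides) per
dosage class.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def fold_change(
    genotype_means: pd.DataFrame, mpv: pd.Series
) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-gene, per-genotype fold change over the mid-parent value.

    Genes with MPV = 0 have no defined fold change: their rows are NaN and
    they are flagged for exclusion from all summaries.
    """
    mpv = mpv.reindex(genotype_means.index)
    flagged = (mpv == 0) | mpv.isna()
    flagged.name = "zero_mpv"
    safe = mpv.where(~flagged)
    fc = genotype_means.div(safe, axis=0)
    return fc, flagged


def summarize_fc(values) -> Dict[str, float]:
    """Median and interquartile bounds of fold-change values.

    Uses the linear-interpolation quantile convention; NaN (flagged) values
    are dropped first.  An empty value set is an error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no fold-change values to summarise")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n": int(arr.size),
        "quantile_method": "linear",
    }


def compare_subgenomes(values_a, values_b, paired: bool = False) -> Tuple[float, float]:
    """Wilcoxon comparison of two sets of expression or fold-change values.

    ``paired=True`` runs the signed-rank test on homoeolog differences
    (vectors must align); otherwise the rank-sum (Mann-Whitney U) test.
    Identical paired vectors carry no evidence and return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired mode requires equal-length vectors")
        diffs = a - b
        if np.all(diffs == 0):
            return 0.0, 1.0
        stat, p = stats.wilcoxon(a, b)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)


def bin_fc_by_class(
    fc_values: pd.Series,
    class_labels: pd.Series,
    bounds: Tuple[float, float] = (0.5, 1.5),
) -> Dict:
    """Fraction of fold changes inside the near-additive band per dosage class.

    ``class_labels`` maps gene id to one of Ad/Ai/Cd/Ci.  The band is closed
    on both sides, so FC equal to a bound counts as inside; the complement
    is strictly outside.  Per subgenome, a 2x2 chi-square (no continuity
    correction) compares the dependent against the independent class.
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    joined = pd.DataFrame(
        {"fc": fc_values, "label": class_labels.reindex(fc_values.index)}
    ).dropna()
    per_class = {}
    for label, sub in joined.groupby("label"):
        inside = int(((sub["fc"] >= lo) & (sub["fc"] <= hi)).sum())
        n = int(len(sub))
        per_class[label] = {
            "n": n,
            "n_inside": inside,
            "n_outside": n - inside,
            "fraction_inside": inside / n if n else float("nan"),
            "fraction_outside": (n - inside) / n if n else float("nan"),
        }
    tests = {}
    for subgenome, dep, ind in (("A", "Ad", "Ai"), ("C", "Cd", "Ci")):
        if dep in per_class and ind in per_class:
            table = np.array(
                [
                    [per_class[dep]["n_inside"], per_class[dep]["n_outside"]],
                    [per_class[ind]["n_inside"], per_class[ind]["n_outside"]],
                ]
            )
            if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                tests[subgenome] = {"chi2": float(chi2), "p": float(p)}
            else:
                tests[subgenome] = {"chi2": float("nan"), "p": float("nan")}
    return {"bounds": [lo, hi], "classes": per_class, "chi2_dep_vs_indep": tests}
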