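"""End-to-end orchestration: simulate or load, then screen, fold-change and
cis/trans stages, with machine-readable summaries and a text report.

The pipeline runs the stages in a fixed order -- expression I/O (FPKM,
replicate averaging, parental filter, MPV), dosage-response classification,
mid-parent fold-change analysis, cis/trans partitioning -- writing each
stage's tables beside a single ``summary.json`` that aggregates counts,
class marginals, fold-change summaries and the cis/trans category table.
Every threshold and mode used is echoed into the summary, and a fixed seed
reproduces the output bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import cistrans as ct
from . import dosage as ds
from . import foldchange as fc_mod
from .expression_io import (
    PARENT_A,
    PARENT_C,
    ExpressionDataset,
    average_replicates,
    compute_fpkm,
    compute_mpv,
    filter_expressed_pairs,
    read_dataset,
)
from .panel import GenotypePanel, build_genotype_panel
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger("polydosage")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (a dataset directory of TSV tables) or
    ``simulation`` (a :class:`~polydosage.synthetic.SimConfig`) must be
    given.  Defaults mirror the reference analysis: alpha 0.05, parental
    FPKM threshold 1.0, near-additive fold-change band 0.5-1.5, BH
    correction everywhere.
    """

    out_dir: Path
    input_dir: Optional[Path] = None
    simulation: Optional[SimConfig] = None
    alpha: float = 0.05
    fpkm_threshold: float = 1.0
    fc_bounds: Tuple[float, float] = (0.5, 1.5)
    copy_correct: bool = False
    pseudocount: float = 0.5
    replicate_mode: str = "genotype_mean"
    seed: Optional[int] = None

    def validate(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_dir or simulation")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.replicate_mode not in ("genotype_mean", "replicate"):
            raise ValueError(f"unknown replicate_mode {self.replicate_mode!r}")
        lo, hi = self.fc_bounds
        if not 0 <= lo < hi:
            raise ValueError("fc_bounds must satisfy 0 <= lo < hi")
        if self.simulation is not None:
            self.simulation.validate()

    def effective_settings(self) -> Dict:
        out = {
            "alpha": self.alpha,
            "fpkm_threshold": self.fpkm_threshold,
            "fc_bounds": list(self.fc_bounds),
            "copy_correct": self.copy_correct,
            "pseudocount": self.pseudocount,
            "replicate_mode": self.replicate_mode,
            "seed": self.seed,
            "input_dir": str(self.input_dir) if self.input_dir else None,
        }
        if self.simulation is not None:
            out["simulation"] = self.simulation.to_dict()
        return out


def load_config(path: Path) -> PipelineConfig:
    """Read a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        sim = SimConfig(**sim)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "fc_bounds" in raw:
        raw["fc_bounds"] = tuple(raw["fc_bounds"])
    return PipelineConfig(simulation=sim, **raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _check_genotypes(dataset: ExpressionDataset, panel: GenotypePanel) -> None:
    present = set(dataset.samples["genotype"])
    unknown = present - set(panel.names)
    if unknown:
        raise ValueError(f"genotypes not in panel: {sorted(unknown)}")
    for parent in (PARENT_A, PARENT_C):
        if parent not in present:
            raise ValueError(f"required parental genotype {parent!r} missing")
    hybrids = [
        g
        for g in present
        if panel.has_subgenome(g, "A") and panel.has_subgenome(g, "C")
    ]
    if not hybrids:
        raise ValueError("need at least one genotype carrying both subgenomes")


def prepare_expression(
    dataset: ExpressionDataset,
    panel: GenotypePanel,
    fpkm_threshold: float = 1.0,
) -> Dict:
    """Shared expression stage: FPKM, genotype means, pair filter, MPV.

    Returns a dict with keys fpkm, genotype_means, retained, filter_report,
    mpv, gene_subgenome and genotypes_present.
    """
    _check_genotypes(dataset, panel)
    if dataset.fpkm is not None:
        fpkm = dataset.fpkm
        fpkm_computed = False
    else:
        fpkm = compute_fpkm(dataset.counts, dataset.lengths, dataset.totals())
        fpkm_computed = True
    genotypes_present = [g for g in panel.names if g in set(dataset.samples["genotype"])]
    gmeans = average_replicates(fpkm, dataset.samples, genotypes_present)
    retained, filter_report = filter_expressed_pairs(dataset.pairs, gmeans, fpkm_threshold)
    if filter_report["n_retained"] == 0:
        raise ValueError("no pairs survive the parental expression filter")
    mpv = compute_mpv(gmeans)
    gene_subgenome = pd.Series(
        ["A"] * len(retained) + ["C"] * len(retained),
        index=list(retained["a_gene_id"]) + list(retained["c_gene_id"]),
    )
    return {
        "fpkm": fpkm,
        "fpkm_computed": fpkm_computed,
        "genotype_means": gmeans,
        "retained": retained,
        "filter_report": filter_report,
        "mpv": mpv,
        "gene_subgenome": gene_subgenome,
        "genotypes_present": genotypes_present,
    }


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute every stage and write the result bundle under ``out_dir``."""
    config.validate()
    panel = build_genotype_panel()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        dataset, truth = generate_dataset(sim, panel, out_dir=out_dir)
        logger.info("simulated %d pairs, %d samples", len(dataset.pairs),
                    len(dataset.samples))
    else:
        dataset = read_dataset(config.input_dir)
        logger.info("loaded dataset from %s", config.input_dir)
    summary: Dict = {"settings": config.effective_settings()}

    # --- expression stage -------------------------------------------------
    prep = prepare_expression(dataset, panel, config.fpkm_threshold)
    fpkm = prep["fpkm"]
    gmeans = prep["genotype_means"]
    retained = prep["retained"]
    filter_report = prep["filter_report"]
    mpv = prep["mpv"]
    gene_subgenome = prep["gene_subgenome"]
    genotypes_present = prep["genotypes_present"]
    if prep["fpkm_computed"]:
        fpkm.to_csv(out_dir / "fpkm.tsv", sep="\t")
    gmeans.to_csv(out_dir / "genotype_means.tsv", sep="\t")
    logger.info(
        "parental filter: %d pairs in, %d retained (%d%% removed)",
        filter_report["n_input"], filter_report["n_retained"],
        filter_report["percent_removed"],
    )
    summary["filter"] = filter_report

    # --- dosage stage -----------------------------------------------------
    screen = ds.screen_genes(
        gmeans,
        gene_subgenome,
        panel,
        fpkm=fpkm,
        samples=dataset.samples,
        mode=config.replicate_mode,
    )
    classified, cutoffs = ds.classify_genes(screen, config.alpha)
    group_summary = ds.group_pairs(classified["class"], retained)
    groups = group_summary.pop("groups")
    inverse = ds.detect_inverse_dosage(classified)
    classified.to_csv(out_dir / "dosage_results.tsv", sep="\t", index_label="gene_id")
    groups.rename("group").to_csv(
        out_dir / "pair_groups.tsv", sep="\t", index_label="pair_id"
    )
    class_counts = {
        sg: {
            "dependent": int(
                ((classified["subgenome"] == sg) & (classified["class"] == "dependent")).sum()
            ),
            "independent": int(
                ((classified["subgenome"] == sg) & (classified["class"] == "independent")).sum()
            ),
        }
        for sg in ("A", "C")
    }
    summary["dosage"] = {
        "alpha": config.alpha,
        "mode": config.replicate_mode,
        "class_counts": class_counts,
        "r2_cutoffs": cutoffs,
        "groups": group_summary,
        "inverse_counts": inverse["counts"],
    }
    _write_json(summary["dosage"], out_dir / "dosage_summary.json")
    logger.info("dosage classes: %s", class_counts)

    # --- fold-change stage ------------------------------------------------
    pair_genes = gene_subgenome.index
    fc_table, flagged = fc_mod.fold_change(gmeans.loc[pair_genes], mpv.loc[pair_genes])
    long = fc_table.rename_axis("gene_id").reset_index().melt(
        id_vars="gene_id", var_name="genotype", value_name="fc"
    )
    long["zero_mpv"] = flagged.reindex(long["gene_id"]).to_numpy()
    long.to_csv(out_dir / "fc_table.tsv", sep="\t", index=False)

    class_label = (
        gene_subgenome
        + classified["class"].reindex(gene_subgenome.index).map(
            {"dependent": "d", "independent": "i"}
        )
    )
    hybrids = [
        g
        for g in genotypes_present
        if panel.has_subgenome(g, "A") and panel.has_subgenome(g, "C")
    ]
    fc_summary: Dict = {
        "n_zero_mpv_excluded": int(flagged.sum()),
        "genotypes": {},
        "bins": {},
        "tests": {},
    }
    a_genes = retained["a_gene_id"].to_numpy()
    c_genes = retained["c_gene_id"].to_numpy()
    for genotype in hybrids:
        per_sub = {}
        for sg, genes in (("A", a_genes), ("C", c_genes)):
            vals = fc_table.loc[genes, genotype]
            per_sub[sg] = fc_mod.summarize_fc(vals)
        fc_summary["genotypes"][genotype] = per_sub
        stat_p, p_paired = fc_mod.compare_subgenomes(
            gmeans.loc[a_genes, genotype], gmeans.loc[c_genes, genotype], paired=True
        )
        fc_a = fc_table.loc[a_genes, genotype].dropna()
        fc_c = fc_table.loc[c_genes, genotype].dropna()
        stat_u, p_fc = fc_mod.compare_subgenomes(fc_a, fc_c, paired=False)
        fc_summary["tests"][genotype] = {
            "homoeolog_signed_rank_p": p_paired,
            "fc_rank_sum_p": p_fc,
        }
        fc_summary["bins"][genotype] = fc_mod.bin_fc_by_class(
            fc_table[genotype], class_label, config.fc_bounds
        )
    summary["fold_change"] = fc_summary
    _write_json(fc_summary, out_dir / "fc_summary.json")
    logger.info("fold-change summaries for %s", hybrids)

    # --- cis/trans stage --------------------------------------------------
    if dataset.counts is not None:
        calls = ct.call_cis_trans(
            dataset,
            gmeans,
            retained,
            panel,
            hybrids=hybrids,
            alpha=config.alpha,
            copy_correct=config.copy_correct,
            pseudocount=config.pseudocount,
        )
        calls.to_csv(out_dir / "cistrans.tsv", sep="\t", index=False)
        ct_summary = {
            "binomial_reference": calls.attrs["binomial_reference"],
            "categories": ct.summarize_categories(calls),
            "crosstab": ct.crosstab_categories(calls, groups),
        }
        summary["cis_trans"] = ct_summary
        _write_json(ct_summary, out_dir / "cistrans_summary.json")
        logger.info("cis/trans calls for %d pair-genotype combinations", len(calls))
    else:
        summary["cis_trans"] = None
        logger.info("no count matrix: cis/trans exact tests skipped")

    if truth is not None:
        summary["truth_recovery"] = evaluate_truth_recovery(
            classified, truth, calls if dataset.counts is not None else None
        )

    _write_json(summary, out_dir / "summary.json")
    (out_dir / "report.txt").write_text(write_report(summary))
    return summary


def evaluate_truth_recovery(classified, truth, calls=None) -> Dict:
    """Agreement between inferred labels and generator ground truth."""
    truth_dep = truth.genes["dependence"].reindex(classified.index)
    inferred = np.where(
        classified["inverse_flag"], "inverse", classified["class"].to_numpy()
    )
    known = truth_dep.notna().to_numpy()
    # inverse truth genes are recovered when flagged; dependent/independent
    # when the class matches.
    agree = (inferred == truth_dep.to_numpy()) & known
    out = {
        "n_genes": int(known.sum()),
        "dependence_agreement": float(agree.sum() / known.sum()) if known.any() else None,
    }
    truth_inverse = truth.genes.index[truth.genes["dependence"] == "inverse"]
    in_screen = truth_inverse.intersection(classified.index)
    if len(in_screen):
        flagged = classified.loc[in_screen, "inverse_flag"]
        out["inverse_recall"] = float(flagged.mean())
        out["n_inverse_truth"] = int(len(in_screen))
    if calls is not None:
        div = truth.pairs["divergence"]
        rec = {}
        for genotype, sub in calls.groupby("genotype"):
            sub = sub.set_index("pair_id")
            for label, target in (("cis", "only_cis"), ("trans", "only_trans")):
                pids = div.index[div == label].intersection(sub.index)
                if len(pids):
                    rec[f"{genotype}_{label}"] = float(
                        (sub.loc[pids, "category"] == target).mean()
                    )
        out["divergence_recovery"] = rec
    return out


def write_report(summary: Dict) -> str:
    """Render the summary as a human-readable text report."""
    lines = ["polydosage pipeline report", "=" * 26, ""]
    settings = summary.get("settings", {})
    lines += [
        "Settings",
        "--------",
        f"alpha: {settings.get('alpha')}   FPKM threshold: {settings.get('fpkm_threshold')}"
        f"   FC band: {settings.get('fc_bounds')}",
        f"replicate mode: {settings.get('replicate_mode')}"
        f"   binomial reference: "
        f"{'copy ratio' if settings.get('copy_correct') else '1/2'}",
        "",
    ]
    filt = summary.get("filter", {})
    lines += [
        "Parental expression filter",
        "--------------------------",
        f"{filt.get('n_input')} pairs in, {filt.get('n_retained')} retained "
        f"({filt.get('percent_removed')}% removed at FPKM > {filt.get('threshold')}).",
        "",
    ]
    dosage = summary.get("dosage", {})
    if dosage:
        groups = dosage.get("groups", {})
        counts = groups.get("counts", {})
        obs = groups.get("observed_percent", {})
        exp = groups.get("expected_percent", {})
        lines += [
            "Dosage-dependence groups (observed vs expected)",
            "-----------------------------------------------",
            f"{'group':>6} {'n':>8} {'obs %':>8} {'exp %':>8}",
        ]
        for g in ("AdCd", "AdCi", "AiCd", "AiCi"):
            lines.append(
                f"{g:>6} {counts.get(g, 0):>8} {obs.get(g, float('nan')):>8.1f} "
                f"{exp.get(g, float('nan')):>8.1f}"
            )
        chi2_p = groups.get("chi2_p")
        chi2_str = f"{chi2_p:.3g}" if isinstance(chi2_p, float) else "n/a"
        lines += [
            f"chi-square obs vs expected: p = {chi2_str}",
            f"empirical r2 cutoffs: {dosage.get('r2_cutoffs')}",
            f"inverse-dosage counts: {dosage.get('inverse_counts')}",
            "",
        ]
    fold = summary.get("fold_change", {})
    if fold:
        lines += ["Fold change vs mid-parent value", "-------------------------------"]
        for genotype, per_sub in sorted(fold.get("genotypes", {}).items()):
            for sg, s in sorted(per_sub.items()):
                lines.append(
                    f"{genotype:>5} {sg}: median {s['median']:.2f} "
                    f"(IQR {s['q1']:.2f}-{s['q3']:.2f}, n={s['n']})"
                )
        lines.append(
            f"zero-MPV genes excluded: {fold.get('n_zero_mpv_excluded')}"
        )
        lines.append("")
    cis = summary.get("cis_trans")
    lines += ["Cis/trans effects", "-----------------"]
    if cis:
        lines.append(
            f"{'genotype':>8} {'no effect':>12} {'only cis':>12} "
            f"{'only trans':>12} {'cis-trans':>12}"
        )
        for genotype, s in sorted(cis.get("categories", {}).items()):
            c, pct = s["counts"], s["percent"]
            cells = [
                f"{c[k]} ({pct[k]:.1f}%)"
                for k in ("no_effect", "only_cis", "only_trans", "cis_trans")
            ]
            lines.append(
                f"{genotype:>8} {cells[0]:>12} {cells[1]:>12} {cells[2]:>12} {cells[3]:>12}"
            )
    else:
        lines.append("stage omitted (no count matrix available).")
    lines.append("")
    return "\n".join(lines)
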