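import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polydosage.dosage import (
    adjust_bh,
    classify_genes,
    detect_inverse_dosage,
    dosage_correlation,
    dosage_screen,
    group_pairs,
    screen_genes,
)
from polydosage.panel import dosage_vector
from polydosage.synthetic import SimConfig, assign_regulatory_classes, simulate_true_abundance

DOSAGE = np.array([1.0, 2 / 3, 0.5, 0.5, 1 / 3])


def bh_oracle(pvalues):
    """Independent step-up enumeration: p_adj(i) = min over j>=i of p(j)*m/j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def pearson_t_oracle(x, y):
    """Brute-force Pearson r and two-sided t-transform p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    return r, 2 * stats.t.sf(abs(t), n - 2)


class TestDosageCorrelation:
    def test_worked_series(self):
        r, r2, p = dosage_correlation([22.22, 11.37, 7.41, 8.98, 6.34], DOSAGE)
        assert round(r, 2) == 0.97
        assert r == pytest.approx(0.9746, abs=5e-4)
        assert r2 == pytest.approx(r * r, abs=0)

    def test_proportional_expression_is_perfectly_correlated(self):
        r, r2, p = dosage_correlation(13.7 * DOSAGE, DOSAGE)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-6

    def test_flat_series_has_negligible_r2(self):
        _, r2, _ = dosage_correlation([96.35, 71.47, 94.49, 71.31, 99.86], DOSAGE)
        assert r2 < 1e-4

    def test_constant_expression_defined_as_independent(self):
        assert dosage_correlation([5.0] * 5, DOSAGE) == (0.0, 0.0, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dosage_correlation([1.0, 2.0], [1.0, 0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dosage_correlation([1.0, 2.0, 3.0], DOSAGE)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = rng.integers(3, 9)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, _, p = dosage_correlation(x, y)
            r_o, p_o = pearson_t_oracle(x, y)
            assert abs(r - r_o) < 1e-10
            assert abs(p - p_o) < 1e-10

    def test_vectorised_screen_matches_scalar(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.uniform(0, 50, size=(40, 5)),
            index=[f"g{i}" for i in range(40)],
            columns=list("ABCDE"),
        )
        dosage = pd.Series(DOSAGE, index=list("ABCDE"))
        screen = dosage_screen(values, dosage)
        for gene in values.index[::7]:
            r, r2, p = dosage_correlation(values.loc[gene], DOSAGE)
            assert screen.loc[gene, "r"] == pytest.approx(r, abs=1e-12)
            assert screen.loc[gene, "p"] == pytest.approx(p, abs=1e-10)


class TestAdjustBH:
    def test_singleton_identity(self):
        assert adjust_bh([0.05]) == pytest.approx([0.05])

    def test_hand_enumerated_step_up(self):
        assert adjust_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_caps_at_one(self):
        assert adjust_bh([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])

    def test_exhaustive_small_grids_match_oracle(self):
        grid = [0.0, 0.005, 0.02, 0.05, 0.5, 1.0]
        for m in (1, 2, 3):
            for combo in itertools.product(grid, repeat=m):
                assert adjust_bh(list(combo)) == pytest.approx(
                    bh_oracle(combo), abs=1e-12
                )

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sampled_from([i / 40 for i in range(41)]), min_size=1, max_size=8
        )
    )
    def test_longer_grid_vectors_match_oracle(self, pvec):
        assert adjust_bh(pvec) == pytest.approx(bh_oracle(pvec), abs=1e-12)

    def test_monotone_in_ranks_and_idempotent_on_uniform(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        flat = adjust_bh([0.3] * 6)
        assert adjust_bh(flat) == pytest.approx(flat)


class TestClassification:
    def test_zero_noise_dependent_genes_all_recovered(self, panel):
        config = SimConfig(n_pairs=30, fraction_dependent=1.0, fraction_inverse=0.0,
                           fraction_cis_divergent=0.0, fraction_trans_divergent=0.0, seed=6)
        truth = assign_regulatory_classes(config)
        shares = simulate_true_abundance(truth, panel)
        subg = truth.genes["subgenome"]
        screen = screen_genes(shares, subg, panel)
        classified, cutoffs = classify_genes(screen, alpha=0.05)
        assert (classified["class"] == "dependent").all()
        assert cutoffs["A"] == pytest.approx(1.0, abs=1e-9)
        assert cutoffs["C"] == pytest.approx(1.0, abs=1e-9)

    def test_all_null_pvalues_give_all_independent(self):
        screen = pd.DataFrame(
            {"subgenome": ["A", "A", "C"], "r": [0.1, -0.2, 0.0],
             "r2": [0.01, 0.04, 0.0], "p": [1.0, 1.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        classified, cutoffs = classify_genes(screen)
        assert (classified["class"] == "independent").all()
        assert cutoffs == {"A": None, "C": None}

    def test_significant_negative_r_is_inverse_not_dependent(self):
        screen = pd.DataFrame(
            {"subgenome": ["A", "A"], "r": [-0.99, 0.99],
             "r2": [0.98, 0.98], "p": [1e-6, 1e-6]},
            index=["neg", "pos"],
        )
        classified, _ = classify_genes(screen)
        assert classified.loc["neg", "class"] == "independent"
        assert bool(classified.loc["neg", "inverse_flag"])
        assert classified.loc["pos", "class"] == "dependent"
        assert not bool(classified.loc["pos", "inverse_flag"])

    def test_partition_counts(self, small_sim_means, panel):
        _, gmeans, gene_subgenome = small_sim_means
        screen = screen_genes(gmeans, gene_subgenome, panel)
        classified, _ = classify_genes(screen)
        for sg in ("A", "C"):
            sub = classified[classified["subgenome"] == sg]
            n_dep = (sub["class"] == "dependent").sum()
            n_ind = (sub["class"] == "independent").sum()
            assert n_dep + n_ind == len(sub)

    def test_empty_screen_rejected(self):
        with pytest.raises(ValueError):
            classify_genes(pd.DataFrame(columns=["subgenome", "r", "r2", "p"]))


class TestGroupPairs:
    def _classes(self, n, n_a_dep, n_c_dep):
        genes = [f"a{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        labels = (
            ["dependent"] * n_a_dep + ["independent"] * (n - n_a_dep)
            + ["dependent"] * n_c_dep + ["independent"] * (n - n_c_dep)
        )
        pairs = pd.DataFrame(
            {"pair_id": [f"p{i}" for i in range(n)],
             "a_gene_id": [f"a{i}" for i in range(n)],
             "c_gene_id": [f"c{i}" for i in range(n)]}
        )
        return pd.Series(labels, index=genes), pairs

    def test_reference_marginals_reproduce_expected_percentages(self):
        """Marginals 8930/14380 (Ad) and 8582/14380 (Cd) imply expected
        percentages 37/25/23/15 under independence."""
        classes, pairs = self._classes(14_380, 8_930, 8_582)
        result = group_pairs(classes, pairs)
        assert result["expected_percent_rounded"] == {
            "AdCd": 37, "AdCi": 25, "AiCd": 23, "AiCi": 15
        }
        assert sum(result["expected_percent"].values()) == pytest.approx(100.0)

    def test_all_dependent_is_degenerate(self):
        classes, pairs = self._classes(10, 10, 10)
        result = group_pairs(classes, pairs)
        assert result["counts"] == {"AdCd": 10, "AdCi": 0, "AiCd": 0, "AiCi": 0}
        assert result["observed_percent"]["AdCd"] == 100.0
        assert np.isnan(result["chi2"])

    def test_counts_sum_to_pair_total(self):
        classes, pairs = self._classes(50, 20, 35)
        result = group_pairs(classes, pairs)
        assert sum(result["counts"].values()) == 50
        assert len(result["groups"]) == 50

    def test_unclassified_member_rejected(self):
        classes, pairs = self._classes(5, 3, 3)
        with pytest.raises(ValueError, match="a4"):
            group_pairs(classes.drop("a4"), pairs)


class TestInverseDosage:
    def _frame(self):
        return pd.DataFrame(
            {
                "subgenome": ["A", "A", "C"],
                "r": [-0.99, -0.10, 0.8],
                "r2": [0.98, 0.01, 0.64],
                "p": [0.001, 0.8, 0.01],
                "p_adj": [0.001, 0.9, 0.02],
                "class": ["independent", "independent", "dependent"],
                "inverse_flag": [True, False, False],
            },
            index=["strong_neg", "weak_neg", "pos"],
        )

    def test_significant_and_nonsignificant_negatives_separated(self):
        result = detect_inverse_dosage(self._frame())
        assert set(result["negative"].index) == {"strong_neg", "weak_neg"}
        assert set(result["significant"].index) == {"strong_neg"}
        assert result["counts"]["A"] == {"negative": 2, "significant": 1}
        assert result["counts"]["C"] == {"negative": 0, "significant": 0}


def test_null_simulation_type_one_error_calibrated(panel):
    """All-independent simulation: raw p < 0.05 in about 5% of genes."""
    config = SimConfig(n_pairs=1500, seed=8, fraction_dependent=0.0,
                       fraction_inverse=0.0, fraction_cis_divergent=0.0,
                       fraction_trans_divergent=0.0)
    from polydosage.expression_io import average_replicates, compute_fpkm
    from polydosage.synthetic import generate_dataset

    dataset, truth = generate_dataset(config, panel)
    fpkm = compute_fpkm(dataset.counts, dataset.lengths, dataset.totals())
    gmeans = average_replicates(fpkm, dataset.samples)
    screen = screen_genes(gmeans, truth.genes["subgenome"], panel)
    frac = (screen["p"] < 0.05).mean()
    n = len(screen)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.05) / n
    assert lo <= frac <= hi


def test_replicate_mode_uses_all_libraries(small_sim, small_sim_means, panel):
    _, dataset, truth = small_sim
    fpkm, gmeans, gene_subgenome = small_sim_means
    rep = screen_genes(gmeans, gene_subgenome, panel, fpkm=fpkm,
                       samples=dataset.samples, mode="replicate")
    mean_mode = screen_genes(gmeans, gene_subgenome, panel)
    # same genes, broadly concordant correlations, but not identical values
    assert set(rep.index) == set(mean_mode.index)
    corr = np.corrcoef(rep["r"], mean_mode.loc[rep.index, "r"])[0, 1]
    assert corr > 0.9
    assert not np.allclose(rep["r"], mean_mode.loc[rep.index, "r"])


def test_dosage_vector_used_by_screen_excludes_noncarrier(panel):
    vec = dosage_vector(panel, "A")
    assert "CC" not in vec.index
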