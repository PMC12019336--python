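import numpy as np
import pandas as pd
import pytest
from scipy import stats

import blineage as bl
from blineage.expression import (
    CountMatrix,
    clr_normalize,
    module_score,
    normalize,
    qc_filter,
    wilcoxon_de,
)


def _count_matrix(counts, mito=None, groups=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if mito is None:
        mito = np.zeros(n_genes, dtype=bool)
    return CountMatrix(
        counts=counts,
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        mito_flags=np.asarray(mito, dtype=bool),
        groups=None if groups is None else np.asarray(groups, dtype=object),
    )


def _planted_qc_fixture():
    """10 cells, 600 genes; thresholds genes>=500, counts>=600, mito<=0.5.

    Planted failures: 2 gene-poor, 1 low-count, 1 high-mito and 1 cell
    failing two criteria -> exactly 5 survivors.
    """
    rng = np.random.default_rng(0)
    n_genes = 600
    counts = np.zeros((n_genes, 10), dtype=np.int64)

    def fill(j, n_expressed, per_gene):
        idx = rng.choice(n_genes - 1, size=n_expressed, replace=False) + 1
        counts[idx, j] = per_gene

    for j in range(5):            # clean cells
        fill(j, 520, 2)
    fill(5, 450, 2)               # gene-poor (900 counts ok)
    fill(6, 450, 2)               # gene-poor
    fill(7, 510, 1)               # low-count (510 < 600)
    fill(8, 520, 2)               # high-mito below
    counts[0, 8] = 2000           # gene 0 is mitochondrial
    fill(9, 450, 1)               # doubly failing: gene-poor AND low-count
    mito = np.zeros(n_genes, dtype=bool)
    mito[0] = True
    return _count_matrix(counts, mito=mito)


class TestQCFilter:
    def test_cell_just_below_gene_threshold_removed(self):
        counts = np.zeros((600, 2), dtype=np.int64)
        counts[:499, 0] = 10   # 499 expressed genes, plenty of counts
        counts[:550, 1] = 10
        filtered, report = qc_filter(_count_matrix(counts), min_genes=500,
                                     min_counts=200, max_mito=0.5)
        assert filtered.n_cells == 1
        assert report.removed_low_genes == 1

    def test_clean_input_passes_through(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 10, size=(700, 8))
        cm = _count_matrix(counts)
        filtered, report = qc_filter(cm)
        assert filtered.n_cells == 8
        assert report.n_removed == 0
        np.testing.assert_array_equal(filtered.counts, cm.counts)

    def test_planted_fixture_yields_five_survivors(self):
        cm = _planted_qc_fixture()
        filtered, report = qc_filter(cm, min_genes=500, min_counts=600,
                                     max_mito=0.5)
        assert filtered.n_cells == 5
        assert report.n_removed == 5
        assert report.removed_low_genes == 3    # 2 gene-poor + doubly failing
        assert report.removed_low_counts == 2   # low-count + doubly failing
        assert report.removed_high_mito == 1

    def test_monotone_in_thresholds(self):
        cm = _planted_qc_fixture()
        strict, _ = qc_filter(cm, min_genes=500, min_counts=600, max_mito=0.5)
        loose, _ = qc_filter(cm, min_genes=400, min_counts=600, max_mito=0.5)
        assert set(strict.cell_ids) <= set(loose.cell_ids)

    def test_alternative_conjunction_rule(self):
        cm = _planted_qc_fixture()
        filtered, _ = qc_filter(cm, min_genes=500, min_counts=600, max_mito=0.5,
                                rule="genes_or_counts_and_mito")
        # no planted cell fails (genes-or-counts) AND mito simultaneously
        assert filtered.n_cells == 10


class TestNormalize:
    def test_library_size_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(1, 20, size=(50, 6))
        doubled = counts.copy()
        doubled[:, 0] *= 2
        n1 = normalize(_count_matrix(counts), regress_mito=False)
        n2 = normalize(_count_matrix(doubled), regress_mito=False)
        np.testing.assert_allclose(n1.iloc[:, 0], n2.iloc[:, 0], atol=1e-12)

    def test_constant_covariate_is_identity(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 20, size=(40, 6))
        # no mito genes -> zero covariate variance -> residual step inert
        with_reg = normalize(_count_matrix(counts), regress_mito=True)
        without = normalize(_count_matrix(counts), regress_mito=False)
        np.testing.assert_allclose(with_reg.to_numpy(), without.to_numpy())

    def test_mito_correlated_gene_decorrelated(self):
        rng = np.random.default_rng(4)
        n_cells = 500
        mito_load = rng.uniform(1, 60, size=n_cells)
        counts = rng.poisson(5.0, size=(100, n_cells))
        counts[0] = rng.poisson(mito_load)                  # the mito gene
        counts[1] = rng.poisson(2.0 + 0.5 * mito_load)      # confounded gene
        mito = np.zeros(100, dtype=bool)
        mito[0] = True
        norm = normalize(_count_matrix(counts, mito=mito))
        mito_frac = counts[0] / counts.sum(axis=0)
        r = np.corrcoef(norm.iloc[1], mito_frac)[0, 1]
        assert abs(r) < 0.05

    def test_zero_count_cell_rejected(self):
        counts = np.zeros((10, 2), dtype=np.int64)
        counts[:, 0] = 1
        with pytest.raises(ValueError, match="zero-count"):
            normalize(_count_matrix(counts))


class TestCLR:
    def test_equal_counts_map_to_zero(self):
        out = clr_normalize(np.full((8, 5), 12))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_per_cell_values_sum_to_zero(self):
        rng = np.random.default_rng(5)
        out = clr_normalize(rng.integers(0, 100, size=(8, 200)))
        np.testing.assert_allclose(out.sum(axis=0), 0.0, atol=1e-10)

    def test_two_tag_hand_computation(self):
        out = clr_normalize(np.array([[3], [7]]))
        mean = (np.log(4) + np.log(8)) / 2
        np.testing.assert_allclose(
            out[:, 0], [np.log(4) - mean, np.log(8) - mean], atol=1e-12
        )


class TestWilcoxonDE:
    def _planted(self, seed, fold=4.0, n=200):
        cm, _ = bl.generate_citeseq_counts(
            n_cells=(n, n), n_genes=400,
            de_spec=[bl.DESpec("G0100", fold, base_mean=5.0)], seed=seed,
        )
        return normalize(cm), cm.groups

    def test_planted_gene_detected(self):
        norm, groups = self._planted(seed=0)
        res = wilcoxon_de(norm, groups)
        assert bool(res.loc["G0100", "significant"])
        # planted in "relapse" (second sorted group) -> negative log2 fc
        assert res.loc["G0100", "log2_fold_change"] < -1.0

    def test_permuted_labels_give_no_signal(self):
        hits = 0
        for seed in range(10):
            norm, groups = self._planted(seed=seed)
            rng = np.random.default_rng(seed)
            res = wilcoxon_de(norm, rng.permutation(groups))
            hits += int(res["significant"].sum() > 0)
        assert hits <= 1

    def test_low_fraction_gene_never_tested(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 10, size=(30, 100))
        counts[0] = 0
        counts[0, :4] = 3          # 8% in one group, 0% in the other
        norm = normalize(_count_matrix(counts), regress_mito=False)
        groups = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
        res = wilcoxon_de(norm, groups)
        assert not res.loc["g0", "tested"]
        assert res.loc["g0", "reason"] == "frac"
        assert np.isnan(res.loc["g0", "pvalue"])

    def test_pvalue_matches_exact_permutation_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.6, 1, 20).clip(0)
        y = rng.normal(0.0, 1, 20).clip(0)
        norm = pd.DataFrame(np.r_[x, y][None, :], index=["gene"])
        groups = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        res = wilcoxon_de(norm, groups, min_frac=0.0)
        # Monte-Carlo permutation distribution of the rank-sum statistic
        ref = stats.permutation_test(
            (x, y),
            lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided").statistic,
            permutation_type="independent",
            n_resamples=20000,
            alternative="two-sided",
            random_state=0,
        )
        mc_err = 4 * np.sqrt(ref.pvalue * (1 - ref.pvalue) / 20000)
        assert res.loc["gene", "pvalue"] == pytest.approx(
            ref.pvalue, abs=max(mc_err, 0.02)
        )

    def test_group_swap_symmetry(self):
        norm, groups = self._planted(seed=8, n=50)
        res1 = wilcoxon_de(norm, groups)
        swapped = np.where(groups == "CR", "ZZ", "AA")
        res2 = wilcoxon_de(norm, swapped)
        np.testing.assert_allclose(
            res1["log2_fold_change"], -res2["log2_fold_change"], atol=1e-10
        )
        np.testing.assert_allclose(res1["pvalue"], res2["pvalue"], atol=1e-12)

    def test_bonferroni_bounds(self):
        norm, groups = self._planted(seed=9, n=50)
        res = wilcoxon_de(norm, groups)
        tested = res[res["tested"]]
        assert (tested["pvalue_adj"] >= tested["pvalue"] - 1e-15).all()
        assert (tested["pvalue_adj"] <= 1.0).all()

    def test_tiny_group_rejected(self):
        norm = pd.DataFrame(np.ones((5, 6)))
        groups = np.array(["a"] * 2 + ["b"] * 4, dtype=object)
        with pytest.raises(ValueError, match="3 cells"):
            wilcoxon_de(norm, groups)


class TestModuleScore:
    def _norm(self, seed=10, n_genes=500, n_cells=300):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(
            rng.lognormal(0, 1, size=n_genes)[:, None], size=(n_genes, n_cells)
        )
        return normalize(_count_matrix(counts + 1), regress_mito=False)

    def test_random_signature_scores_near_zero(self):
        norm = self._norm(n_cells=1000)
        rng = np.random.default_rng(11)
        genes = list(rng.choice(norm.index, size=25, replace=False))
        score = module_score(norm, genes, seed=0)
        assert abs(score.mean()) < 0.05

    def test_singleton_signature_definition(self):
        norm = self._norm()
        score = module_score(norm, [norm.index[5]], seed=1)
        ctrl = score.attrs["control_genes"]
        expected = norm.iloc[5] - norm.loc[ctrl].mean(axis=0)
        np.testing.assert_allclose(score, expected, atol=1e-12)

    def test_planted_signature_recovered(self):
        sig = tuple(f"G{j:04d}" for j in range(50, 60))
        cm, _ = bl.generate_citeseq_counts(
            n_cells=(300, 300), n_genes=500,
            signature_spec=bl.SignatureSpec(genes=sig, fold=2.0, base_mean=3.0),
            seed=12,
        )
        norm = normalize(cm)
        score = module_score(norm, list(sig), seed=2)
        a = score[cm.groups == "relapse"]
        b = score[cm.groups == "CR"]
        p = stats.ranksums(a, b, alternative="greater").pvalue
        assert p < 1e-6

    def test_invariant_to_permuting_uninvolved_gene(self):
        norm = self._norm()
        genes = [norm.index[5], norm.index[50]]
        score = module_score(norm, genes, seed=3)
        involved = set(score.attrs["control_genes"]) | set(genes)
        other = next(g for g in norm.index if g not in involved)
        # permute that gene's cells: bin averages and control draws unchanged
        perm = norm.copy()
        perm.loc[other] = np.random.default_rng(4).permutation(perm.loc[other].values)
        score2 = module_score(perm, genes, seed=3)
        np.testing.assert_allclose(score, score2, atol=1e-12)

    def test_empty_intersection_rejected(self):
        norm = self._norm()
        with pytest.raises(ValueError, match="missing"):
            module_score(norm, ["NOT_A_GENE"], seed=0)


class TestIndependentCrossChecks:
    def test_wilcoxon_pvalues_match_scanpy(self):
        """Rank-sum p-values agree with scanpy's tie-corrected Wilcoxon."""
        import scanpy as sc

        cm, _ = bl.generate_citeseq_counts(
            n_cells=(100, 100), n_genes=200,
            de_spec=[bl.DESpec("G0050", 3.0, base_mean=5.0)], seed=13,
        )
        norm = normalize(cm, regress_mito=False)
        res = wilcoxon_de(norm, cm.groups, min_frac=0.0, min_fc=1.0)

        import anndata

        ad = anndata.AnnData(
            X=norm.to_numpy().T,
            obs=pd.DataFrame({"group": pd.Categorical(cm.groups)},
                             index=cm.cell_ids),
            var=pd.DataFrame(index=cm.gene_ids),
        )
        sc.tl.rank_genes_groups(
            ad, "group", groups=["CR"], reference="relapse",
            method="wilcoxon", tie_correct=True, pts=False,
        )
        sc_p = pd.Series(
            ad.uns["rank_genes_groups"]["pvals"]["CR"],
            index=[g for g in ad.uns["rank_genes_groups"]["names"]["CR"]],
        )
        ours = res["pvalue"].reindex(sc_p.index)
        # scanpy's z omits the continuity correction scipy applies, which
        # perturbs p by ~1% at this sample size
        np.testing.assert_allclose(ours, sc_p, rtol=0.03, atol=1e-12)
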