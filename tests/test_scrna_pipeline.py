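"""Tests of the single-cell QC, differential-expression and hub-filter stages."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctcmd import scrna_pipeline as sp
from ctcmd import synthio


def adata_from_counts(X, gene_prefix="G", mt_last=True):
    n_cells, n_genes = X.shape
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    if mt_last:
        genes[-1] = "MT-0"
    return ad.AnnData(
        X=np.asarray(X, dtype=np.int64),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )


class TestCellQC:
    @pytest.mark.parametrize(
        "total, genes, mt_frac, keep, reason",
        [
            (3999, 2000, 0.10, False, "low_counts"),
            (4000, 2000, 0.10, True, ""),
            (50_000, 999, 0.10, False, "low_genes"),
            (50_000, 8000, 0.10, False, "high_genes"),
            (50_000, 2000, 0.80, False, "high_mt"),
            (50_000, 2000, 0.75, True, ""),
        ],
    )
    def test_threshold_rules(self, total, genes, mt_frac, keep, reason):
        n_genes = 8001
        X = np.zeros((1, n_genes), dtype=np.int64)
        mt = int(round(total * mt_frac))
        rest = total - mt
        n_nonmt = genes - 1
        base = rest // n_nonmt
        X[0, :n_nonmt] = base
        X[0, : rest - base * n_nonmt] += 1
        X[0, -1] = mt
        adata = adata_from_counts(X)
        _, qc = sp.qc_filter_cells(adata, mt_genes=["MT-0"])
        assert bool(qc["keep"].iloc[0]) is keep
        if reason:
            assert reason in qc["removal_reason"].iloc[0]

    def test_permuting_cells_keeps_same_set(self, small_counts, rng):
        _, qc = sp.qc_filter_cells(small_counts)
        order = rng.permutation(small_counts.n_obs)
        _, qc_perm = sp.qc_filter_cells(small_counts[order].copy())
        kept_a = set(qc.index[qc["keep"]])
        kept_b = set(qc_perm.index[qc_perm["keep"]])
        assert kept_a == kept_b

    def test_unknown_mt_gene_rejected(self, small_counts):
        with pytest.raises(ValueError):
            sp.qc_filter_cells(small_counts, mt_genes=["NOT-A-GENE"])


class TestLognormalize:
    def test_zero_count_maps_to_zero(self):
        X = np.array([[0, 10], [5, 5]])
        out = sp.lognormalize(X)
        assert out[0, 0] == 0.0

    def test_depth_invariance(self):
        X = np.array([[1, 2, 3], [2, 4, 6]])  # second cell = doubled first
        out = sp.lognormalize(X)
        np.testing.assert_allclose(out[0], out[1])

    def test_equal_counts_give_equal_values(self):
        out = sp.lognormalize(np.array([[7, 7, 7, 7]]))
        assert np.ptp(out) == 0.0

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            sp.lognormalize(np.array([[0, 0], [1, 1]]))


class TestComposition:
    def test_confounded_balanced_table(self):
        labels = [0] * 20 + [1] * 20
        covariate = ["a"] * 20 + ["b"] * 20
        table, res = sp.composition_association(labels, covariate)
        assert res.statistic == pytest.approx(40.0)

    def test_transpose_invariance(self, rng):
        labels = rng.integers(0, 2, 60)
        cov = rng.choice(["x", "y", "z"], 60)
        _, a = sp.composition_association(labels, cov)
        _, b = sp.composition_association(cov, labels)
        assert a.statistic == pytest.approx(b.statistic)

    def test_null_labels_calibrated(self):
        """Independent labels: rejection near the nominal rate over seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 2, 80)
            cov = rng.integers(0, 2, 80)
            _, res = sp.composition_association(labels, cov)
            hits += res.p_value < 0.05
        assert hits / n_seeds < 0.2

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError):
            sp.composition_association([0, 1, 0, 1], ["a", "a", "a", "a"])


class TestDGE:
    def build_norm(self, rng, n_cells=40, n_genes=30):
        X = rng.negative_binomial(2, 0.1, size=(n_cells, n_genes)) + 1
        return sp.lognormalize(X)

    def test_identical_gene_not_significant(self, rng):
        norm = self.build_norm(rng)
        norm[:, 0] = 1.0  # identical in both clusters
        labels = np.repeat([0, 1], 20)
        dge = sp.dge_wilcoxon(norm, labels, [f"g{i}" for i in range(norm.shape[1])])
        row = dge.iloc[0]
        assert row["log2fc"] == 0.0
        assert not row["significant"]

    def test_padj_is_bonferroni(self, rng):
        norm = self.build_norm(rng)
        labels = np.repeat([0, 1], 20)
        dge = sp.dge_wilcoxon(norm, labels, [f"g{i}" for i in range(norm.shape[1])])
        np.testing.assert_allclose(
            dge["p_adj"], np.minimum(1.0, dge["p_raw"] * norm.shape[1])
        )

    def test_pvalues_match_reference_implementation(self, rng):
        """Per-gene p-values cross-checked against scipy's asymptotic
        Mann-Whitney on the same matrix."""
        norm = self.build_norm(rng, n_cells=30, n_genes=12)
        labels = np.repeat([0, 1], 15)
        dge = sp.dge_wilcoxon(norm, labels, [f"g{i}" for i in range(12)])
        for j in range(12):
            ref = sps.mannwhitneyu(
                norm[labels == 0, j], norm[labels == 1, j],
                alternative="two-sided", method="asymptotic",
            )
            assert dge["p_raw"].iloc[j] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_planted_fold_change_recovered(self):
        """A planted 4-fold gene at 60 cells/cluster is recovered with the
        right sign and magnitude in >=90% of 20 seeds."""
        hits_fc = hits_sig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            adata = synthio.simulate_counts(
                synthio.CountSimConfig(
                    n_genes=200, n_deg=10, deg_log2fc_range=(2.0, 2.0),
                    mt_stress_fraction=0.0, library_size_range=(3e4, 3e5),
                    seed=300 + seed,
                )
            )
            norm = sp.lognormalize(adata)
            labels = adata.obs["true_cluster"].to_numpy()
            dge = sp.dge_wilcoxon(norm, labels, list(adata.var_names))
            truth = adata.var["true_log2fc"]
            gene = truth.abs().idxmax()
            row = dge.set_index("gene").loc[gene]
            hits_fc += abs(row["log2fc"] - truth.loc[gene]) <= 0.5
            hits_sig += bool(row["significant"])
        assert hits_fc / n_seeds >= 0.9
        assert hits_sig / n_seeds >= 0.9

    def test_single_cluster_rejected(self, rng):
        norm = self.build_norm(rng)
        with pytest.raises(ValueError):
            sp.dge_wilcoxon(norm, np.zeros(norm.shape[0], dtype=int),
                            [f"g{i}" for i in range(norm.shape[1])])


class TestFilterAndRank:
    def records(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "log2fc": [0.9, 2.0, -1.5, 3.0],
                "p_raw": [1e-5, 1e-4, 1e-4, 0.9],
                "p_adj": [0.001, 0.01, 0.02, 1.0],
            }
        )

    def test_fold_change_rule_and_score(self):
        out = sp.filter_and_rank_degs(self.records())
        sig = set(out["significant"]["gene"])
        assert sig == {"b", "c"}  # 'a' fails the 2-fold rule, 'd' fails p
        b = out["records"].set_index("gene").loc["b"]
        assert b["rank_score"] == pytest.approx(2.0 * 2.0)  # 2 * -log10(0.01)

    def test_up_down_counts(self):
        out = sp.filter_and_rank_degs(self.records())
        assert (out["n_up"], out["n_down"]) == (1, 1)

    def test_matches_brute_force_rescan(self, rng):
        rec = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "log2fc": rng.normal(0, 2, 200),
                "p_raw": rng.uniform(size=200),
                "p_adj": np.minimum(1.0, rng.uniform(size=200) * 3),
            }
        )
        out = sp.filter_and_rank_degs(rec)
        expected = {
            r["gene"]
            for _, r in rec.iterrows()
            if r["p_adj"] < 0.05 and abs(r["log2fc"]) >= 1.0
        }
        assert set(out["significant"]["gene"]) == expected


class TestHub:
    def norm_df(self, rng, n_cells=60, n_genes=5):
        X = rng.negative_binomial(2, 0.05, size=(n_cells, n_genes)) + 1
        return pd.DataFrame(
            sp.lognormalize(X),
            index=[f"c{i}" for i in range(n_cells)],
            columns=[f"g{i}" for i in range(n_genes)],
        )

    def test_monotone_score_gives_rho_one(self, rng):
        norm = self.norm_df(rng)
        scores = {
            m: pd.DataFrame({"SET": np.exp(norm["g0"])}, index=norm.index)
            for m in ("A", "B")
        }
        rec = sp.hub_correlations(norm, scores, ["g0"])
        np.testing.assert_allclose(rec["rho"], 1.0)

    def test_independent_scores_mostly_below_threshold(self):
        hits = total = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            norm = self.norm_df(rng, n_cells=300, n_genes=2)
            scores = {
                m: pd.DataFrame(
                    {"SET": rng.standard_normal(300)}, index=norm.index
                )
                for m in ("A", "B")
            }
            rec = sp.hub_correlations(norm, scores, ["g0"])
            hits += int((rec["rho"].abs() < 0.2).all())
            total += 1
        assert hits / total >= 0.95

    def test_cell_mismatch_rejected(self, rng):
        norm = self.norm_df(rng)
        scores = {
            "A": pd.DataFrame({"SET": [1.0]}, index=["other"]),
            "B": pd.DataFrame({"SET": [1.0]}, index=["other"]),
        }
        with pytest.raises(ValueError):
            sp.hub_correlations(norm, scores, ["g0"])

    def hub_records(self):
        return pd.DataFrame(
            [
                # gene, geneset, method, rho, p
                ("hub", "S1", "A", 0.25, 0.01),
                ("hub", "S1", "B", 0.30, 0.02),
                ("one_method", "S2", "A", 0.4, 0.001),
                ("one_method", "S2", "B", 0.05, 0.8),
                ("not_deg", "S3", "A", 0.5, 0.001),
                ("not_deg", "S3", "B", 0.5, 0.001),
            ],
            columns=["gene", "geneset", "method", "rho", "p_spearman"],
        )

    def test_three_criterion_rule(self):
        hubs, rec = sp.filter_hub_genes(self.hub_records(), {"hub", "one_method"})
        assert hubs == ["hub"]
        assert rec.loc[rec["gene"] == "hub", "is_hub"].all()

    def test_order_invariance(self, rng):
        rec = self.hub_records()
        shuffled = rec.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a, _ = sp.filter_hub_genes(rec, {"hub"})
        b, _ = sp.filter_hub_genes(shuffled, {"hub"})
        assert a == b

    def test_membership_restricts_pairs(self, rng):
        norm = self.norm_df(rng)
        scores = {
            m: pd.DataFrame(
                {"S1": rng.standard_normal(len(norm)), "S2": rng.standard_normal(len(norm))},
                index=norm.index,
            )
            for m in ("A", "B")
        }
        rec = sp.hub_correlations(
            norm, scores, ["g0", "g1"], geneset_members={"S1": ["g0"], "S2": ["g1"]}
        )
        assert set(map(tuple, rec[["gene", "geneset"]].to_numpy())) == {
            ("g0", "S1"),
            ("g1", "S2"),
        }
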