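"""Moderated linear model, two-part test, BH control, and clustering."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ftlipid.diffabund import (
    DifferentialAbundanceModel,
    bh_adjust,
    cluster_samples,
    differential_features,
    fit_moderated_linear_model,
    log2_fold_changes,
    two_part_test,
)

NA = float("nan")


def make_metadata(n_cancer, n_non, instruments=None):
    ids = [f"c{i}" for i in range(n_cancer)] + [f"n{i}" for i in range(n_non)]
    total = n_cancer + n_non
    instruments = instruments or ["Fusion 1" if i % 2 == 0 else "Fusion 2" for i in range(total)]
    return pd.DataFrame(
        {
            "sample_id": ids,
            "patient_id": ids,
            "class": ["cancer"] * n_cancer + ["non-cancer"] * n_non,
            "instrument": instruments,
        }
    )


@pytest.fixture(scope="module")
def gaussian_matrix():
    rng = np.random.default_rng(11)
    meta = make_metadata(10, 10)
    vals = rng.normal(8, 1, (50, 20))
    vals[:10, :10] += 1.0  # ten shifted features
    values = pd.DataFrame(vals, columns=meta["sample_id"], index=[f"f{i}" for i in range(50)])
    return values, meta


class TestModeratedModel:
    def test_identical_values_give_null_result(self):
        meta = make_metadata(3, 3)
        values = pd.DataFrame(
            np.full((2, 6), 5.0), columns=meta["sample_id"], index=["f0", "f1"]
        )
        out = fit_moderated_linear_model(values, meta)
        assert np.allclose(out["effect"], 0.0)
        assert np.allclose(out["p_value"], 1.0)

    def test_prior_zero_equals_ordinary_ols_t(self, gaussian_matrix):
        values, meta = gaussian_matrix
        out = fit_moderated_linear_model(values, meta, prior_df=0)
        import statsmodels.api as sm

        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "cancer": (meta["class"] == "cancer").astype(float).to_numpy(),
                "instrument": (meta["instrument"] == "Fusion 2").astype(float).to_numpy(),
            }
        )
        for fid in values.index[:10]:
            fit = sm.OLS(values.loc[fid].to_numpy(), X).fit()
            assert out.loc[fid, "effect"] == pytest.approx(fit.params["cancer"], abs=1e-10)
            assert out.loc[fid, "t"] == pytest.approx(fit.tvalues["cancer"], abs=1e-8)
            assert out.loc[fid, "p_value"] == pytest.approx(fit.pvalues["cancer"], abs=1e-10)

    def test_effect_identical_with_and_without_shrinkage(self, gaussian_matrix):
        values, meta = gaussian_matrix
        plain = fit_moderated_linear_model(values, meta, prior_df=0)
        shrunk = fit_moderated_linear_model(values, meta)
        assert np.allclose(plain["effect"], shrunk["effect"], atol=1e-12)
        assert shrunk["df_prior"].iloc[0] > 0

    def test_moderated_approaches_ordinary_as_prior_shrinks(self, gaussian_matrix):
        values, meta = gaussian_matrix
        plain = fit_moderated_linear_model(values, meta, prior_df=0)
        tiny = fit_moderated_linear_model(values, meta, prior_df=1e-9)
        assert np.allclose(plain["t"], tiny["t"], atol=1e-6)

    def test_rank_deficient_design_rejected(self):
        meta = make_metadata(3, 3, instruments=["Fusion 1"] * 6)
        # all cancer samples on Fusion 1 and all non-cancer on Fusion 2
        meta["instrument"] = ["Fusion 1"] * 3 + ["Fusion 2"] * 3
        values = pd.DataFrame(np.ones((2, 6)), columns=meta["sample_id"])
        with pytest.raises(ValueError):
            fit_moderated_linear_model(values, meta)

    def test_instrument_covariate_absorbs_batch_effect(self):
        # planted instrument shift, no class effect: with the covariate the
        # type-I error stays nominal; without it, it inflates
        rng = np.random.default_rng(42)
        meta = make_metadata(10, 10)
        # unbalance instrument vs class so omitting the covariate biases tests
        meta["instrument"] = ["Fusion 1"] * 9 + ["Fusion 2"] * 1 + ["Fusion 1"] * 1 + [
            "Fusion 2"
        ] * 9
        shift = (meta["instrument"] == "Fusion 2").to_numpy(dtype=float)
        vals = rng.normal(8, 0.5, (800, 20)) + 1.5 * shift[None, :]
        values = pd.DataFrame(vals, columns=meta["sample_id"])
        with_cov = fit_moderated_linear_model(values, meta)
        rate_with = (with_cov["p_value"] <= 0.05).mean()
        no_cov_meta = meta.copy()
        no_cov_meta["instrument"] = "Fusion 1"
        without_cov = fit_moderated_linear_model(values, no_cov_meta)
        rate_without = (without_cov["p_value"] <= 0.05).mean()
        assert 0.02 <= rate_with <= 0.08
        assert rate_without > 0.3

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_oracle(self, gaussian_matrix, tmp_path):
        values, meta = gaussian_matrix
        values.to_csv(tmp_path / "y.csv")
        meta.to_csv(tmp_path / "meta.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            y <- as.matrix(read.csv(args[1], row.names=1, check.names=FALSE))
            meta <- read.csv(args[2])
            design <- cbind(1, as.integer(meta$class=="cancer"),
                            as.integer(meta$instrument=="Fusion 2"))
            fit <- eBayes(lmFit(y, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s2post=fit$s2.post)
            write.csv(out, args[3])
            """
        )
        out_path = tmp_path / "limma.csv"
        subprocess.run(
            ["Rscript", str(script), str(tmp_path / "y.csv"), str(tmp_path / "meta.csv"), str(out_path)],
            check=True,
            capture_output=True,
        )
        oracle = pd.read_csv(out_path, index_col=0)
        ours = fit_moderated_linear_model(values, meta)
        assert np.allclose(ours["t"], oracle["t"], atol=1e-6)
        assert np.allclose(ours["p_value"], oracle["p"], atol=1e-8)
        assert ours["df_prior"].iloc[0] == pytest.approx(oracle["d0"].iloc[0], rel=1e-4)
        assert np.allclose(ours["s2_post"], oracle["s2post"], rtol=1e-6)


class TestTwoPartTest:
    @staticmethod
    def _classes(n1, n2):
        cols = [f"c{i}" for i in range(n1)] + [f"n{i}" for i in range(n2)]
        return cols, pd.Series(["cancer"] * n1 + ["non-cancer"] * n2, index=cols)

    def test_identical_fully_observed_values(self):
        cols, classes = self._classes(5, 5)
        values = pd.DataFrame([np.full(10, 3.0)], columns=cols)
        out = two_part_test(values, classes)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_complete_separation_binary_part(self):
        cols, classes = self._classes(10, 10)
        row = [5.0] * 10 + [NA] * 10
        values = pd.DataFrame([row], columns=cols)
        out = two_part_test(values, classes)
        # closed-form two-proportion score z: (1-0)/sqrt(0.5*0.5*(2/10))
        z = 1.0 / np.sqrt(0.25 * 0.2)
        assert out["statistic"].iloc[0] == pytest.approx(z**2)
        assert out["df"].iloc[0] == 1
        assert out["p_value"].iloc[0] == pytest.approx(sps.chi2.sf(z**2, 1))
        assert out["p_value"].iloc[0] < 0.01

    def test_continuous_part_matches_rank_sum(self):
        rng = np.random.default_rng(8)
        cols, classes = self._classes(12, 12)
        values = pd.DataFrame(rng.normal(size=(5, 24)), columns=cols)
        out = two_part_test(values, classes)
        for i in range(5):
            x1 = values.iloc[i, :12]
            x2 = values.iloc[i, 12:]
            # fully observed -> binary part degenerate, df = 1
            assert out["df"].iloc[i] == 1
            z = out["z_continuous"].iloc[i]
            # compare against scipy's tie-corrected normal approximation
            u = sps.mannwhitneyu(x1, x2, method="asymptotic", use_continuity=False)
            assert out["p_value"].iloc[i] == pytest.approx(sps.chi2.sf(z**2, 1), abs=1e-12)
            assert 2 * sps.norm.sf(abs(z)) == pytest.approx(u.pvalue, abs=1e-10)

    def test_all_missing_gives_p_one(self):
        cols, classes = self._classes(3, 3)
        values = pd.DataFrame([[NA] * 6], columns=cols)
        out = two_part_test(values, classes)
        assert out["df"].iloc[0] == 0
        assert out["p_value"].iloc[0] == 1.0


class TestBHAdjust:
    def test_hand_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_step_up_oracle(self):
        def oracle(ps):
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m - 1, -1, -1):
                i = order[rank]
                prev = min(prev, ps[i] * m / (rank + 1))
                adj[i] = prev
            return adj

        rng = np.random.default_rng(4)
        for _ in range(25):
            ps = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(ps), oracle(ps), atol=1e-14)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(6)
        ps = rng.uniform(size=30)
        adj = bh_adjust(ps)
        assert (adj >= ps - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestUnionAndFoldChanges:
    def test_union_with_provenance(self):
        idx = ["f0", "f1", "f2", "f3"]
        mod = pd.DataFrame({"p_value": [0.0001, 0.5, 0.0001, 0.9]}, index=idx)
        tp = pd.DataFrame({"p_value": [0.0001, 0.0001, 0.9, 0.9]}, index=idx)
        out = differential_features(mod, tp, alpha=0.01)
        assert out.loc["f0", "provenance"] == "both"
        assert out.loc["f1", "provenance"] == "two-part"
        assert out.loc["f2", "provenance"] == "moderated"
        assert not out.loc["f3", "significant"]
        assert set(out.index[out["significant"]]) >= set(
            out.index[out["sig_moderated"]]
        )

    def test_different_universes_rejected(self):
        mod = pd.DataFrame({"p_value": [0.5]}, index=["a"])
        tp = pd.DataFrame({"p_value": [0.5]}, index=["b"])
        with pytest.raises(ValueError):
            differential_features(mod, tp)

    def test_fold_change_hand_values(self):
        cols = ["c0", "c1", "n0", "n1"]
        classes = pd.Series(["cancer", "cancer", "non-cancer", "non-cancer"], index=cols)
        values = pd.DataFrame([[4.0, 4.0, 3.0, 3.0], [2.0, 2.0, 2.0, 2.0]], columns=cols)
        fc = log2_fold_changes(values, classes)
        assert fc.iloc[0] == pytest.approx(1.0)
        assert fc.iloc[1] == pytest.approx(0.0)

    def test_fold_change_requires_complete_data(self):
        cols = ["c0", "n0", "n1", "c1"]
        classes = pd.Series(["cancer", "non-cancer", "non-cancer", "cancer"], index=cols)
        values = pd.DataFrame([[1.0, NA, 1.0, 1.0]], columns=cols)
        with pytest.raises(ValueError):
            log2_fold_changes(values, classes)

    def test_cancer_only_feature_reproduces_extreme_fold_change(self):
        # feature observed only in cancer: after imputation the non-cancer
        # side sits at its class threshold minus one
        from ftlipid.preprocess import impute_missing

        cols = [f"c{i}" for i in range(4)] + [f"n{i}" for i in range(4)]
        classes = pd.Series(["cancer"] * 4 + ["non-cancer"] * 4, index=cols)
        vals = np.array(
            [[9.0, 9, 9, 9, NA, NA, NA, NA], [8.0, 8, 8, 8, 2.0, 2, 2, 2]]
        )
        values = pd.DataFrame(vals, columns=cols)
        imputed, thresholds = impute_missing(values, classes, q=0.0)
        fc = log2_fold_changes(imputed, classes)
        assert fc.iloc[0] == pytest.approx(9.0 - (thresholds["non-cancer"] - 1.0))


class TestClusterSamples:
    @staticmethod
    def _two_block_distance():
        labels = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        dist = np.full((8, 8), 1.0)
        dist[:4, :4] = 0.1
        dist[4:, 4:] = 0.1
        np.fill_diagonal(dist, 0.0)
        return pd.DataFrame(dist, index=labels, columns=labels)

    def test_planted_partition_recovered(self):
        from scipy.cluster.hierarchy import fcluster

        dist = self._two_block_distance()
        Z, leaves = cluster_samples(dist)
        labels = fcluster(Z, 2, criterion="maxclust")
        groups = {}
        for name, lab in zip(dist.index, labels):
            groups.setdefault(lab, set()).add(name)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset({"a0", "a1", "a2", "a3"}),
            frozenset({"b0", "b1", "b2", "b3"}),
        }

    def test_leaf_order_is_permutation(self):
        dist = self._two_block_distance()
        _, leaves = cluster_samples(dist)
        assert sorted(leaves) == sorted(dist.index)

    def test_identical_samples_zero_height(self):
        labels = list("abc")
        dist = pd.DataFrame(np.zeros((3, 3)), index=labels, columns=labels)
        Z, _ = cluster_samples(dist)
        assert np.allclose(Z[:, 2], 0.0)

    def test_asymmetric_rejected(self):
        dist = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_samples(dist)


class TestModelResults:
    def test_fit_summary_and_flags(self, default_study):
        from ftlipid.preprocess import impute_missing

        mat = default_study.latent_matrix()
        classes = default_study.metadata.set_index("sample_id")["class"]
        imputed, _ = impute_missing(mat, classes)
        model = DifferentialAbundanceModel.from_matrices(
            imputed, mat, default_study.metadata
        )
        results = model.fit()
        text = results.summary()
        assert "significant, union" in text
        t = results.table
        assert ((t["adj_p_moderated"] >= t["p_moderated"] - 1e-15).all())
        sig = t["significant"]
        assert (t.loc[sig & (t["log2fc"] > 0), "direction"] == "more").all()
        assert set(results.significant_features) == set(t.index[sig])

    def test_mismatched_matrices_rejected(self, default_study):
        mat = default_study.latent_matrix()
        with pytest.raises(ValueError):
            DifferentialAbundanceModel.from_matrices(
                mat.iloc[:-1], mat, default_study.metadata
            )
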