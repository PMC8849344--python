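"""The seven correction methods: worked examples, equivalences, invariants."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from tmabatch.correct import (
    correct_combat,
    correct_ipw_means,
    correct_quantile_norm,
    correct_quantile_reg,
    correct_simple_means,
    correct_standardized_means,
    correct_uncorrected,
)
from tmabatch.datamodel import BiomarkerTable, CovariateTable, GLEASON_LEVELS
from tmabatch.errors import DesignError
from tmabatch.synthdata import StudyDesign, generate_study

from conftest import make_biomarker, make_covariates

COVS = ["gleason_group", "stage_category", "diagnosis_year"]


class TestSimpleMeans:
    def test_worked_example(self):
        bm = make_biomarker({"A": [1, 2, 3], "B": [4, 5, 6]})
        res = correct_simple_means(bm, "m")
        np.testing.assert_allclose(
            res.values.df["value"], [2.5, 3.5, 4.5, 2.5, 3.5, 4.5]
        )
        effects = res.batch_effects.set_index("batch_id")["location"]
        np.testing.assert_allclose(effects[["A", "B"]], [-1.5, 1.5])

    def test_single_batch_identity(self):
        bm = make_biomarker({"A": [1.0, 5.0, 9.0]})
        res = correct_simple_means(bm, "m")
        np.testing.assert_array_equal(res.values.df["value"], bm.df["value"])

    def test_equal_batch_means_identity(self):
        bm = make_biomarker({"A": [1.0, 3.0], "B": [0.0, 4.0]})
        res = correct_simple_means(bm, "m")
        np.testing.assert_allclose(res.values.df["value"], bm.df["value"])

    def test_post_correction_means_equal(self, small_study):
        bm, _, _ = small_study
        res = correct_simple_means(bm, "marker1")
        means = res.values.df.groupby("batch_id")["value"].mean()
        np.testing.assert_allclose(means, means.iloc[0], atol=1e-10)


class TestStandardizedMeans:
    def test_empty_covariates_equals_simple_means(self, small_study):
        bm, cov, _ = small_study
        a = correct_standardized_means(bm, cov, "marker1", [])
        b = correct_simple_means(bm, "marker1")
        np.testing.assert_array_equal(a.values.df["value"], b.values.df["value"])

    def test_covariate_driven_differences_retained(self):
        # batch means differ only through Gleason composition: no batch
        # effect should be estimated, corrected ~= uncorrected
        rng = np.random.default_rng(3)
        rows, glist = [], []
        for b, p_high in [("A", 0.15), ("B", 0.7)]:
            for i in range(400):
                g = 5 if rng.uniform() < p_high else 1
                rows.append((f"{b}t{i}", "c1", b, "m", 0.5 * g + rng.normal(0, 0.5)))
                glist.append((f"{b}t{i}", GLEASON_LEVELS[g - 1]))
        bm = BiomarkerTable(
            pd.DataFrame(rows, columns=["tumor_id", "core_id", "batch_id", "marker_id", "value"])
        )
        cov = make_covariates(bm)
        cov.df["gleason_group"] = [g for _, g in glist]
        res = correct_standardized_means(bm, cov, "m", ["gleason_group"])
        effects = res.batch_effects.set_index("batch_id")["location"]
        assert np.abs(effects).max() < 0.1
        assert np.abs(res.values.df["value"] - bm.df["value"]).max() < 0.2

    def test_pure_offsets_with_balanced_covariates_match_simple_means(self):
        rng = np.random.default_rng(4)
        bm = make_biomarker({b: j * 0.8 + rng.normal(0, 1, 60) for j, b in enumerate("ABC")})
        cov = make_covariates(bm)  # cycled levels: identical per batch
        a = correct_standardized_means(bm, cov, "m", COVS)
        b = correct_simple_means(bm, "m")
        np.testing.assert_allclose(a.values.df["value"], b.values.df["value"], atol=1e-8)


class TestIPWMeans:
    def test_balanced_covariates_equal_simple_means(self):
        rng = np.random.default_rng(0)
        bm = make_biomarker({b: j + rng.normal(0, 1, 40) for j, b in enumerate("AB")})
        cov = make_covariates(bm)
        a = correct_ipw_means(bm, cov, "m", ["gleason_group"], truncation=(0, 100))
        b = correct_simple_means(bm, "m")
        assert np.abs(a.values.df["value"].to_numpy() - b.values.df["value"].to_numpy()).max() < 1e-6

    def test_hand_computed_stabilized_weights(self):
        # two batches, binary covariate with known cell counts:
        # A: 30 low, 10 high; B: 10 low, 30 high (n=80, P(A)=P(B)=1/2)
        rng = np.random.default_rng(1)
        rows, levels = [], []
        for b, n_low, n_high in [("A", 30, 10), ("B", 10, 30)]:
            for i in range(n_low + n_high):
                level = "5-6" if i < n_low else "9-10"
                rows.append((f"{b}t{i}", "c1", b, "m", rng.normal()))
                levels.append(level)
        bm = BiomarkerTable(
            pd.DataFrame(rows, columns=["tumor_id", "core_id", "batch_id", "marker_id", "value"])
        )
        cov = make_covariates(bm)
        cov.df["gleason_group"] = levels
        res = correct_ipw_means(bm, cov, "m", ["gleason_group"], truncation=(0, 100))
        w = res.diagnostics["weights"]
        # P(A|low)=3/4 -> w=0.5/0.75=2/3; P(A|high)=1/4 -> w=0.5/0.25=2
        np.testing.assert_allclose(w[:30], 2 / 3, atol=1e-4)
        np.testing.assert_allclose(w[30:40], 2.0, atol=1e-4)
        assert np.mean(w) == pytest.approx(1.0, abs=1e-4)

    def test_truncation_clips_weight_tails(self):
        rng = np.random.default_rng(2)
        bm, cov, _ = generate_study(
            StudyDesign(n_batches=4, tumors_per_batch=(60, 60), n_markers=1, seed=14)
        )
        res = correct_ipw_means(bm, cov, "marker1", COVS, truncation=(10, 90))
        w, w_raw = res.diagnostics["weights"], res.diagnostics["weights_untruncated"]
        assert w.min() == pytest.approx(np.percentile(w_raw, 10))
        assert w.max() == pytest.approx(np.percentile(w_raw, 90))


class TestQuantileReg:
    def test_identical_batches_nearly_identity(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 80)
        bm = make_biomarker({"A": base, "B": base.copy()})
        res = correct_quantile_reg(bm, None, "m", [])
        out = res.values.df
        # both batches receive the identical transform ...
        np.testing.assert_allclose(
            out.loc[out["batch_id"] == "A", "value"].to_numpy(),
            out.loc[out["batch_id"] == "B", "value"].to_numpy(),
            atol=1e-10,
        )
        # ... which deviates from identity only by the gap between the
        # regression quartile (an order statistic) and the interpolated
        # sample quartile
        assert np.abs(out["value"].to_numpy() - bm.df["value"].to_numpy()).max() < 0.2

    def test_location_scale_batches_align_quartiles(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 300)
        bm = make_biomarker({"A": base, "B": 2.0 * base + 1.0, "C": 0.5 * base - 1.0})
        res = correct_quantile_reg(bm, None, "m", [])
        out = res.values.df
        overall = np.quantile(out["value"], [0.25, 0.75])
        for b in "ABC":
            q = np.quantile(out.loc[out["batch_id"] == b, "value"], [0.25, 0.75])
            np.testing.assert_allclose(q, overall, atol=0.12)

    def test_constant_batch_is_degenerate(self):
        rng = np.random.default_rng(7)
        bm = make_biomarker({"A": rng.normal(0, 1, 20), "B": np.full(20, 2.0)})
        with pytest.raises(DesignError, match="B"):
            correct_quantile_reg(bm, None, "m", [])

    def test_small_batch_guard(self):
        bm = make_biomarker({"A": np.arange(20.0), "B": np.arange(5.0)})
        with pytest.raises(DesignError, match="minimum size"):
            correct_quantile_reg(bm, None, "m", [])


class TestQuantileNorm:
    def test_worked_two_batch_example(self):
        bm = make_biomarker({"A": [1, 2, 3], "B": [2, 4, 6]})
        res = correct_quantile_norm(bm, "m")
        np.testing.assert_array_equal(
            res.values.df["value"], [1.5, 3.0, 4.5, 1.5, 3.0, 4.5]
        )

    def test_identical_batches_identity(self):
        bm = make_biomarker({"A": [1.0, 2.0, 5.0], "B": [1.0, 2.0, 5.0]})
        res = correct_quantile_norm(bm, "m")
        np.testing.assert_allclose(res.values.df["value"], bm.df["value"])

    def test_within_batch_ranks_preserved(self, small_study):
        bm, _, _ = small_study
        res = correct_quantile_norm(bm, "marker1")
        merged = bm.subset_marker("marker1").assign(
            corrected=res.values.df["value"].to_numpy()
        )
        for _, sub in merged.groupby("batch_id"):
            rho = spearmanr(sub["value"], sub["corrected"]).statistic
            assert rho == pytest.approx(1.0)

    def test_batch_distributions_equalized(self, small_study):
        bm, _, _ = small_study
        out = correct_quantile_norm(bm, "marker1").values.df
        stats = out.groupby("batch_id")["value"].agg(["mean", "var"])
        assert stats["mean"].max() - stats["mean"].min() < 0.05
        assert stats["var"].max() / stats["var"].min() < 1.1

    def test_single_batch_rejected(self):
        bm = make_biomarker({"A": [1.0, 2.0]})
        with pytest.raises(DesignError):
            correct_quantile_norm(bm, "m")


class TestComBat:
    @staticmethod
    def _shifted_scaled_study(seed=8, n_markers=20, n=80):
        # marker-specific batch artifacts: the across-marker heterogeneity
        # the empirical-Bayes model assumes (shared artifacts would be
        # shrunk toward the common pattern instead of removed per marker)
        return generate_study(
            StudyDesign(
                n_batches=4, tumors_per_batch=(n, n), n_markers=n_markers,
                cores_per_tumor=1, batch_shift_sd=0.8, batch_scale_log_sd=0.3,
                marker_specific_effects=True, seed=seed,
            )
        )

    def test_removes_location_and_scale_effects(self):
        bm, cov, _ = self._shifted_scaled_study()
        res = correct_combat(bm, cov, covariates=["gleason_group"], adjust_variance=True)
        for marker in bm.markers:
            raw = bm.subset_marker(marker)
            out = res.values.df[res.values.df["marker_id"] == marker]
            means = out.groupby("batch_id")["value"].mean()
            var_raw = raw.groupby("batch_id")["value"].var()
            var_out = out.groupby("batch_id")["value"].var()
            # location artifacts (raw spread ~1.5-2 SD) essentially removed;
            # scale artifacts (raw ratios up to ~5) reduced toward 1, with
            # the ~10% residual the empirical-Bayes prior pull leaves
            assert means.max() - means.min() < 0.2
            assert var_out.max() / var_out.min() < 1.7
            assert var_out.max() / var_out.min() < var_raw.max() / var_raw.min()

    def test_null_stability(self, null_study):
        bm, cov, _ = null_study
        res = correct_combat(bm, cov, adjust_variance=True)
        diff = np.abs(res.values.df["value"].to_numpy() - bm.df["value"].to_numpy())
        assert np.median(diff) < 0.1  # EB shrinkage keeps null data nearly unchanged

    def test_requires_multiple_markers(self):
        bm = make_biomarker({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        with pytest.raises(DesignError, match="markers"):
            correct_combat(bm, None)

    def test_coverage_groups_corrected_independently_keys_preserved(self):
        bm, cov, _ = self._shifted_scaled_study()
        # markers 5-6 absent from batch D: separate coverage group
        df = bm.df[
            ~(bm.df["marker_id"].isin(["marker5", "marker6"]) & (bm.df["batch_id"] == "TMAD"))
        ].reset_index(drop=True)
        bm2 = BiomarkerTable(df)
        res = correct_combat(bm2, cov)
        assert res.diagnostics["n_groups"] == 2
        key = ["tumor_id", "core_id", "marker_id"]
        pd.testing.assert_frame_equal(
            res.values.df[key].sort_values(key).reset_index(drop=True),
            df[key].sort_values(key).reset_index(drop=True),
        )

    def test_matches_bioconductor_sva_reference(self, tmp_path):
        bm, cov, _ = generate_study(
            StudyDesign(
                n_batches=3, tumors_per_batch=(25, 30), n_markers=4, cores_per_tumor=1,
                batch_shift_sd=0.8, batch_scales=np.array([0.7, 1.0, 1.4]), seed=8,
            )
        )
        mine = correct_combat(bm, None, adjust_variance=True).values.df.pivot_table(
            index="marker_id", columns="tumor_id", values="value"
        )
        wide = bm.df.pivot_table(index="marker_id", columns="tumor_id", values="value")
        batch = (
            bm.df.drop_duplicates("tumor_id").set_index("tumor_id")["batch_id"]
            .reindex(wide.columns)
        )
        wide.to_csv(tmp_path / "y.csv")
        batch.to_frame("batch").to_csv(tmp_path / "b.csv")
        script = (
            'suppressMessages(library(sva));'
            f'y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1, check.names=FALSE));'
            f'b <- read.csv("{tmp_path}/b.csv", row.names=1)$batch;'
            'out <- ComBat(dat=y, batch=b, par.prior=TRUE, mean.only=FALSE);'
            f'write.csv(out, "{tmp_path}/out.csv")'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:
            pytest.fail(f"reference ComBat run failed: {proc.stderr[-500:]}")
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        ref.columns.name = "tumor_id"
        diff = (mine - ref.reindex(index=mine.index, columns=mine.columns)).abs()
        assert diff.to_numpy().max() < 1e-4


@pytest.fixture(scope="module")
def corrections(small_study):
    bm, cov, _ = small_study
    return bm, {
        "uncorrected": correct_uncorrected(bm, "marker1"),
        "simple_means": correct_simple_means(bm, "marker1"),
        "standardized_means": correct_standardized_means(bm, cov, "marker1", COVS),
        "ipw_means": correct_ipw_means(bm, cov, "marker1", COVS),
        "quantile_norm": correct_quantile_norm(bm, "marker1"),
    }


class TestSharedInvariants:
    def test_keys_preserved_and_values_finite(self, corrections):
        bm, results = corrections
        key = ["tumor_id", "core_id", "marker_id"]
        expected = bm.subset_marker("marker1")[key].reset_index(drop=True)
        for res in results.values():
            got = res.values.df[key].reset_index(drop=True)
            pd.testing.assert_frame_equal(got, expected)
            assert np.isfinite(res.values.df["value"]).all()

    def test_rank_preserving_methods_keep_within_batch_order(self, corrections):
        bm, results = corrections
        raw = bm.subset_marker("marker1")
        for name in ["simple_means", "standardized_means", "ipw_means", "quantile_norm"]:
            out = raw.assign(corrected=results[name].values.df["value"].to_numpy())
            for _, sub in out.groupby("batch_id"):
                assert spearmanr(sub["value"], sub["corrected"]).statistic == pytest.approx(1.0)
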