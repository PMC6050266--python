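import numpy as np
import pandas as pd
import pytest

from ksvar import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    chi_square_2x2,
    direction_contingency,
    log_transform,
    pca_signature,
    risk_gene_profile,
    simulate_matrix,
    spearman_clinical,
)


class TestChiSquare2x2:
    def test_monocyte_microglia_direction_table(self):
        """A 2x2 direction contingency with cells 10/3/11/15 gives
        chi-square 4.18, p 0.041 without continuity correction."""
        res = chi_square_2x2([[10, 3], [11, 15]])
        assert res.chi2 == pytest.approx(4.18, abs=0.01)
        assert res.p == pytest.approx(0.041, abs=0.001)
        assert res.df == 1

    def test_perfect_independence(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_diagonal_table_closed_form(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 40*(400)^2/(20*20*20*20)
        assert chi_square_2x2([[20, 0], [0, 20]]).chi2 == pytest.approx(40.0)

    def test_invariant_to_transpose_and_label_swap(self):
        t = np.array([[7, 2], [4, 9]])
        base = chi_square_2x2(t).chi2
        assert chi_square_2x2(t.T).chi2 == pytest.approx(base)
        assert chi_square_2x2(t[::-1, ::-1]).chi2 == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2([[0, 0], [3, 4]])


class TestDirectionContingency:
    def test_reconstructed_39_gene_labeling(self):
        """Counts built to give margins 13 up / 26 down in cases and
        21 up / 18 down versus the comparator cell type."""
        pd_dir, ct_dir = {}, {}
        layout = [("up", "up", 10), ("up", "down", 3), ("down", "up", 11), ("down", "down", 15)]
        i = 0
        for d1, d2, count in layout:
            for _ in range(count):
                pd_dir[f"g{i}"] = d1
                ct_dir[f"g{i}"] = d2
                i += 1
        table = direction_contingency(pd_dir, ct_dir)
        assert table.tolist() == [[10, 3], [11, 15]]
        assert table.sum(axis=1).tolist() == [13, 26]
        assert table.sum(axis=0).tolist() == [21, 18]

    def test_single_cell_when_all_agree(self):
        table = direction_contingency({"a": "up", "b": "up"}, {"a": "up", "b": "up"})
        assert table.tolist() == [[2, 0], [0, 0]]

    def test_ties_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            table = direction_contingency(
                {"a": "up", "b": "tie"}, {"a": "down", "b": "up"}
            )
        assert table.sum() == 1

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValidationError):
            direction_contingency({}, {})
        with pytest.raises(ValidationError):
            direction_contingency({"a": "up"}, {"b": "up"})


def _log_matrix(values, sample_groups):
    m = ExpressionMatrix(pd.DataFrame(values), units="log2TPM1p")
    meta = SampleMetadata(
        pd.DataFrame({"group": sample_groups}, index=m.sample_ids)
    )
    return m, meta


class TestPcaSignature:
    def test_separated_groups_split_on_pc1(self):
        matrix, meta, truth = simulate_matrix(
            300, frac_mean_shift=0.1, frac_var_shift=0, lfc=4.0, sigma=0.3, seed=21
        )
        logm = log_transform(matrix)
        sig = truth.genes_of_class("mean_shift")
        proj, evr = pca_signature(logm.subset_genes(sig), meta)
        pc1_case = proj.loc[meta.case_ids, "PC1"]
        pc1_ctrl = proj.loc[meta.control_ids, "PC1"]
        assert max(pc1_case.max(), pc1_ctrl.max()) * min(pc1_case.min(), pc1_ctrl.min()) < 0
        assert (pc1_case.max() < pc1_ctrl.min()) or (pc1_ctrl.max() < pc1_case.min())
        assert evr[0] > 0.5

    def test_explained_variance_ratios_valid(self, small_cohort):
        matrix, meta, _ = small_cohort
        logm = log_transform(matrix)
        genes = list(logm.gene_ids[:20])
        _, evr = pca_signature(logm.subset_genes(genes), meta, n_components=5)
        assert evr.sum() <= 1 + 1e-9
        assert (np.diff(evr) <= 1e-12).all()

    def test_projections_centred(self, small_cohort):
        matrix, meta, _ = small_cohort
        logm = log_transform(matrix)
        proj, _ = pca_signature(logm.subset_genes(list(logm.gene_ids[:15])), meta)
        assert np.allclose(proj[["PC1", "PC2"]].mean(), 0, atol=1e-9)

    def test_zero_variance_gene_dropped_with_warning(self):
        vals = {
            "s1": [1.0, 5.0, 2.0],
            "s2": [2.0, 5.0, 1.0],
            "s3": [3.0, 5.0, 4.0],
            "s4": [0.5, 5.0, 3.0],
        }
        m, meta = _log_matrix(vals, ["case", "case", "control", "control"])
        with pytest.warns(UserWarning, match="zero-variance"):
            proj, _ = pca_signature(m, meta)
        assert proj.shape[0] == 4

    def test_deterministic_sign_convention(self, small_cohort):
        matrix, meta, _ = small_cohort
        logm = log_transform(matrix).subset_genes(list(matrix.gene_ids[:12]))
        p1, _ = pca_signature(logm, meta)
        p2, _ = pca_signature(logm, meta)
        pd.testing.assert_frame_equal(p1, p2)


class TestSpearmanClinical:
    def _cohort(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.lognormal(3, 1, size=(5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        m = ExpressionMatrix(expr, units="TPM")
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "group": ["case"] * 6 + ["control"] * 6,
                    "cov_mono": np.log2(expr.loc["g0"] + 1) * 3 + 1,  # monotone in g0
                    "cov_const": 5.0,
                    "cov_sparse": [1.0, 2.0, np.nan] + [np.nan] * 9,
                },
                index=expr.columns,
            )
        )
        return m, meta

    def test_monotone_covariate_perfect_rho(self):
        m, meta = self._cohort()
        rho, npairs = spearman_clinical(m, ["g0"], meta, ["cov_mono"])
        assert rho.loc["g0", "cov_mono"] == pytest.approx(1.0)
        assert npairs.loc["g0", "cov_mono"] == 12

    def test_reversed_covariate_negates_rho(self):
        m, meta = self._cohort()
        base = spearman_clinical(m, ["g1"], meta, ["cov_mono"])[0].iloc[0, 0]
        meta.table["cov_mono"] = -meta.table["cov_mono"]
        flipped = spearman_clinical(m, ["g1"], meta, ["cov_mono"])[0].iloc[0, 0]
        assert flipped == pytest.approx(-base)

    def test_constant_and_sparse_covariates_reported_missing(self):
        m, meta = self._cohort()
        rho, npairs = spearman_clinical(m, ["g0"], meta, ["cov_const", "cov_sparse"])
        assert rho.isna().all().all()
        assert npairs.loc["g0", "cov_sparse"] == 2

    def test_independent_noise_uncorrelated_on_average(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.lognormal(3, 1, size=(200, 10)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(10)],
        )
        m = ExpressionMatrix(expr, units="TPM")
        meta = SampleMetadata(
            pd.DataFrame(
                {"group": ["case"] * 5 + ["control"] * 5, "noise": rng.normal(size=10)},
                index=expr.columns,
            )
        )
        rho, _ = spearman_clinical(m, list(expr.index), meta, ["noise"])
        assert abs(rho["noise"].mean()) < 0.2


class TestRiskGeneProfile:
    def _matrices(self):
        genes = ["g_mono", "g_mg", "g_shared", "g_low"]
        def mk(means, n=10, prefix="s"):
            vals = pd.DataFrame(
                {f"{prefix}{i}": means for i in range(n)}, index=genes, dtype=float
            )
            return ExpressionMatrix(vals, units="TPM")
        return {
            "monocyte_control": mk([20.0, 5.0, 10.0, 0.5]),
            "monocyte_case": mk([18.0, 6.0, 11.0, 0.4], prefix="c"),
            "microglia": mk([5.0, 40.0, 12.0, 0.6], prefix="m"),
        }

    def test_categories(self):
        profile = risk_gene_profile(self._matrices(), ["g_mono", "g_mg", "g_shared", "g_low"])
        assert profile.category["g_mono"] == "monocyte_enriched"  # 20 vs 5: >2-fold
        assert profile.category["g_mg"] == "microglia_enriched"
        assert profile.category["g_shared"] == "shared"

    def test_low_expression_kept_in_categories_dropped_from_table(self):
        profile = risk_gene_profile(self._matrices(), ["g_mono", "g_low"])
        assert "g_low" in profile.category.index
        assert profile.below_min_tpm == ["g_low"]
        assert "g_low" not in set(profile.table["gene_id"])

    def test_constant_samples_zero_ci_width(self):
        profile = risk_gene_profile(self._matrices(), ["g_mono"])
        row = profile.table.query("gene_id == 'g_mono' and cell_type == 'monocyte_control'").iloc[0]
        assert row["ci_low"] == pytest.approx(row["mean_log2"])
        assert row["ci_high"] == pytest.approx(row["mean_log2"])

    def test_missing_gene_excluded_with_warning(self):
        mats = self._matrices()
        mats["microglia"] = mats["microglia"].subset_genes(["g_mono", "g_mg"])
        with pytest.warns(UserWarning, match="missing"):
            profile = risk_gene_profile(mats, ["g_mono", "g_shared"])
        assert profile.missing == ["g_shared"]
        assert list(profile.category.index) == ["g_mono"]

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            risk_gene_profile(self._matrices(), [])
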