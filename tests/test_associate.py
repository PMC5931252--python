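"""Differential profiles, miRNA filter, nested OLS + residual-bootstrap F."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ccmirnet.associate import (
    bootstrap_f_pvalue,
    filter_mirnas,
    fit_linear,
    gene_level_fdr,
    make_differential_profiles,
)
from ccmirnet.containers import MiRNAMatrix
from ccmirnet.errors import DegenerateInputError, ValidationError


def make_meta(entries):
    """entries: list of (sample, subject, tissue)."""
    idx = pd.Index([e[0] for e in entries], name="sample_id")
    return pd.DataFrame(
        {"subject_id": [e[1] for e in entries], "tissue": [e[2] for e in entries]},
        index=idx,
    )


class TestDifferentialProfiles:
    def test_hand_computed_differences(self):
        meta = make_meta([("a", "s1", "carcinoma"), ("b", "s1", "normal"),
                          ("c", "s2", "carcinoma"), ("d", "s2", "normal"),
                          ("e", "s3", "carcinoma"), ("f", "s3", "normal")])
        mat = pd.DataFrame([[5.0, 2.0, 7.0, 7.0, 0.0, 4.0]], index=["G1"],
                           columns=list("abcdef"))
        prof = make_differential_profiles(mat, meta)
        assert prof.loc["G1"].tolist() == [3.0, 0.0, -4.0]

    def test_equal_tissues_give_zero_profile(self):
        meta = make_meta([("a", "s1", "carcinoma"), ("b", "s1", "normal")])
        mat = pd.DataFrame([[9.0, 9.0]], index=["G1"], columns=["a", "b"])
        assert (make_differential_profiles(mat, meta).loc["G1"] == 0).all()

    def test_incomplete_subject_dropped_with_warning(self, caplog):
        meta = make_meta([("a", "s1", "carcinoma"), ("b", "s1", "normal"),
                          ("c", "s2", "carcinoma")])
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            prof = make_differential_profiles(mat, meta)
        assert list(prof.columns) == ["s1"]
        assert "dropping 1 subject" in caplog.text

    def test_duplicate_tissue_is_ambiguity_error(self):
        meta = make_meta([("a", "s1", "carcinoma"), ("b", "s1", "carcinoma"),
                          ("c", "s1", "normal")])
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=["a", "b", "c"])
        with pytest.raises(ValidationError):
            make_differential_profiles(mat, meta)


class TestMirnaFilter:
    @staticmethod
    def matrix_with_detection(n_detected: int, n_subjects: int = 100) -> MiRNAMatrix:
        entries = []
        for i in range(n_subjects):
            entries += [(f"S{i}_C", f"S{i}", "carcinoma"), (f"S{i}_N", f"S{i}", "normal")]
        meta = make_meta(entries)
        sig = pd.DataFrame(0.0, index=["miR-x"], columns=meta.index)
        sig.loc["miR-x", [f"S{i}_N" for i in range(n_detected)]] = 3.0
        sig.loc["miR-x", [f"S{i}_C" for i in range(n_subjects)]] = 1.0
        return MiRNAMatrix(sig, meta)

    def test_21_of_100_kept(self):
        assert filter_mirnas(self.matrix_with_detection(21)) == ["miR-x"]

    def test_exactly_20_of_100_dropped(self):
        assert filter_mirnas(self.matrix_with_detection(20)) == []

    def test_all_zero_dropped(self):
        assert filter_mirnas(self.matrix_with_detection(0)) == []


class TestFitLinear:
    def test_exact_fit_zero_residual(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = 2.0 * x
        age = np.full(6, 65.0)
        sex = np.zeros(6)
        fit = fit_linear(y, x, age, sex)
        assert fit.beta == pytest.approx(2.0, abs=1e-10)
        assert np.abs(fit.null_resid - (y - fit.null_fitted)).max() < 1e-12

    def test_matches_statsmodels_to_1e10(self):
        rng = np.random.default_rng(7)
        n = 6
        x = rng.normal(size=n)
        age = rng.normal(65, 8, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = 0.7 * x + 0.02 * age + rng.normal(size=n)
        fit = fit_linear(y, x, age, sex)
        X_full = sm.add_constant(np.column_stack([x, age - age.mean(), sex]))
        X_null = sm.add_constant(np.column_stack([age - age.mean(), sex]))
        full = sm.OLS(y, X_full).fit()
        null = sm.OLS(y, X_null).fit()
        f_oracle = (null.ssr - full.ssr) / (full.ssr / full.df_resid)
        assert fit.beta == pytest.approx(full.params[1], abs=1e-10)
        assert fit.f_obs == pytest.approx(f_oracle, abs=1e-10)

    def test_null_f_has_f_distribution_moment(self):
        rng = np.random.default_rng(3)
        n = 24
        fs = []
        for _ in range(2000):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            age = rng.normal(65, 8, n)
            sex = (rng.random(n) < 0.5).astype(float)
            fs.append(fit_linear(y, x, age, sex).f_obs)
        df2 = n - 4
        assert np.mean(fs) == pytest.approx(df2 / (df2 - 2), rel=0.1)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_linear(np.arange(6.0), np.ones(6), np.arange(6.0), np.zeros(6))


class TestBootstrapF:
    def test_constant_y_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        fit = fit_linear(np.full(6, 3.0), x, np.full(6, 65.0), np.zeros(6))
        assert fit.f_obs == 0.0
        assert bootstrap_f_pvalue(fit, 500) == 1.0

    def test_close_to_parametric_f_under_gaussian_errors(self):
        rng = np.random.default_rng(5)
        n = 50
        x = rng.normal(0, 1, n)
        age = rng.normal(65, 8, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = 0.35 * x + rng.normal(0, 1, n)
        fit = fit_linear(y, x, age, sex)
        p_param = stats.f.sf(fit.f_obs, 1, fit.df2)
        p_boot = bootstrap_f_pvalue(fit, 10000, rng=np.random.default_rng(8))
        assert abs(p_boot - p_param) < 0.02

    def test_affine_invariance_of_p(self):
        rng = np.random.default_rng(9)
        n = 40
        x = rng.normal(size=n)
        age = rng.normal(65, 8, n)
        sex = (rng.random(n) < 0.5).astype(float)
        y = 0.2 * x + rng.normal(size=n)
        p1 = bootstrap_f_pvalue(fit_linear(y, x, age, sex), 2000,
                                rng=np.random.default_rng(1))
        p2 = bootstrap_f_pvalue(fit_linear(5 * y + 3, 0.1 * x - 2, age, sex), 2000,
                                rng=np.random.default_rng(1))
        assert p1 == p2

    def test_plus_one_floor_and_determinism(self):
        rng = np.random.default_rng(11)
        n = 30
        x = rng.normal(size=n)
        y = 3.0 * x + rng.normal(0, 0.1, n)
        fit = fit_linear(y, x, rng.normal(65, 8, n), (rng.random(n) < 0.5).astype(float))
        p1 = bootstrap_f_pvalue(fit, 999, rng=np.random.default_rng(2))
        p2 = bootstrap_f_pvalue(fit, 999, rng=np.random.default_rng(2))
        assert p1 == p2 == pytest.approx(1 / 1000)

    def test_invalid_n_boot_rejected(self):
        fit = fit_linear(np.arange(6.0), np.arange(6.0) ** 2,
                         np.full(6, 65.0), np.zeros(6))
        with pytest.raises(ValidationError):
            bootstrap_f_pvalue(fit, 0)


class TestGeneLevelFdr:
    def test_single_mirna_gene_unchanged(self):
        rec = pd.DataFrame({"gene": ["A"], "mirna": ["m1"], "p_boot": [0.03]})
        assert gene_level_fdr(rec)["fdr_gene"].iloc[0] == pytest.approx(0.03)

    def test_hand_bh_within_gene(self):
        rec = pd.DataFrame({"gene": ["A", "A"], "mirna": ["m1", "m2"],
                            "p_boot": [0.01, 0.04]})
        assert np.allclose(gene_level_fdr(rec)["fdr_gene"], [0.02, 0.04])

    def test_genes_adjusted_independently(self):
        rec = pd.DataFrame({
            "gene": ["A", "A", "B", "B"],
            "mirna": ["m1", "m2", "m1", "m2"],
            "p_boot": [0.01, 0.04, 0.01, 0.04],
        })
        out = gene_level_fdr(rec)
        a = out[out.gene == "A"]["fdr_gene"].to_numpy()
        b = out[out.gene == "B"]["fdr_gene"].to_numpy()
        assert np.allclose(a, b)

    def test_global_scope_flag(self):
        rec = pd.DataFrame({"gene": ["A", "B"], "mirna": ["m", "m"],
                            "p_boot": [0.01, 0.04]})
        out = gene_level_fdr(rec, scope="global")
        assert np.allclose(out["fdr_gene"], [0.02, 0.04])


class TestNullPipelineCalibration:
    def test_all_null_profiles_give_nominal_rejections_and_no_fdr_hits(self):
        """With no planted effects, ~5% of pairs reject at p<0.05 and
        essentially none survive the gene-level FDR."""
        from ccmirnet.associate import associate_all, make_differential_profiles
        from ccmirnet.normalize import rpmpcg
        from ccmirnet.simulate import (
            SimConfig, generate_cohort, generate_mirna_signal, generate_paired_counts,
        )
        cfg = SimConfig(n_subjects=100, n_genes=20, n_mirnas=10, rng_seed=31)
        cohort = generate_cohort(cfg)
        expr = generate_paired_counts(cfg, cohort)
        y = make_differential_profiles(rpmpcg(expr).values, expr.sample_meta)
        matrix, _ = generate_mirna_signal(cfg, cohort)
        x = make_differential_profiles(matrix.signal, matrix.sample_meta)[y.columns]
        records = associate_all(y, x, cohort, n_boot=400, rng_seed=31)
        assert len(records) == 200
        frac = (records["p_boot"] < 0.05).mean()
        assert 0.005 <= frac <= 0.12  # binomial tolerance around 0.05
        assert (records["fdr_gene"] < 0.05).sum() <= 3
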