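"""Generator contracts: determinism, planted-parameter recovery, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest

from ccmirnet.associate import fit_linear, make_differential_profiles
from ccmirnet.errors import DegenerateInputError, InvalidConfigError, ReferenceError_
from ccmirnet.normalize import rpmpcg
from ccmirnet.simulate import (
    AssocEffect,
    SeedSite,
    SimConfig,
    generate_cohort,
    generate_mirna_signal,
    generate_paired_counts,
    generate_sequences,
    generate_survival,
)


class TestCohort:
    def test_population_moments_match_study_defaults(self):
        cohort = generate_cohort(SimConfig(n_subjects=10_000, rng_seed=0))
        assert abs(cohort["age"].mean() - 64.8) < 0.5
        assert abs((cohort["sex"] == "male").mean() - 0.544) < 0.02
        assert cohort["age"].between(30, 79).all()
        stage_freq = cohort["ajcc_stage"].value_counts(normalize=True)
        assert abs(stage_freq[3] - 0.336) < 0.02

    def test_same_seed_gives_identical_tables(self):
        cfg = SimConfig(n_subjects=50, rng_seed=11)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_nonpositive_subjects_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_cohort(SimConfig(n_subjects=0))


class TestPairedCounts:
    def test_null_genes_have_unit_fold_change(self):
        cfg = SimConfig(n_subjects=400, n_genes=10, rng_seed=5)
        expr = generate_paired_counts(cfg, generate_cohort(cfg))
        values = rpmpcg(expr).values
        meta = expr.sample_meta
        carc = values[meta.index[meta["tissue"] == "carcinoma"]].mean(axis=1)
        norm = values[meta.index[meta["tissue"] == "normal"]].mean(axis=1)
        assert np.allclose(carc / norm, 1.0, atol=0.12)

    def test_planted_fold_change_recovered_empirically(self):
        cfg = SimConfig(n_subjects=500, n_genes=3,
                        planted_log_fc=(("G0001", np.log(2.0)),), rng_seed=2)
        expr = generate_paired_counts(cfg, generate_cohort(cfg))
        values = rpmpcg(expr).values
        meta = expr.sample_meta
        ratio = (
            values.loc["G0001", meta.index[meta["tissue"] == "carcinoma"]].mean()
            / values.loc["G0001", meta.index[meta["tissue"] == "normal"]].mean()
        )
        assert 1.9 <= ratio <= 2.1

    def test_determinism_and_new_genes_do_not_perturb_old(self):
        cfg = SimConfig(n_subjects=20, n_genes=4, rng_seed=9)
        expr1 = generate_paired_counts(cfg, generate_cohort(cfg))
        expr2 = generate_paired_counts(cfg, generate_cohort(cfg))
        pd.testing.assert_frame_equal(expr1.counts, expr2.counts)
        # per-feature sub-streams: widening the panel keeps existing genes' draws
        bigger = SimConfig(n_subjects=20, n_genes=6, rng_seed=9)
        expr3 = generate_paired_counts(bigger, generate_cohort(bigger))
        pd.testing.assert_frame_equal(expr3.counts.loc[expr1.counts.index], expr1.counts)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_subjects=5, nb_dispersion=0.0).validate()


class TestMiRNASignal:
    def test_planted_slope_recovered_by_ols(self):
        cfg = SimConfig(
            n_subjects=500, n_genes=3, n_mirnas=3, rng_seed=4,
            assoc_effects=(AssocEffect("G0001", "miR-0001", beta=0.30, noise_sd=1.0),),
        )
        cohort = generate_cohort(cfg)
        matrix, profiles = generate_mirna_signal(cfg, cohort)
        x = make_differential_profiles(matrix.signal, matrix.sample_meta)
        age = cohort.set_index("subject_id").loc[x.columns, "age"].to_numpy()
        sex = (cohort.set_index("subject_id").loc[x.columns, "sex"] == "male").to_numpy(float)
        fit = fit_linear(profiles.loc["G0001", x.columns].to_numpy(),
                         x.loc["miR-0001"].to_numpy(), age, sex)
        assert abs(fit.beta - 0.30) < 0.03

    def test_unknown_feature_reference_rejected(self):
        cfg = SimConfig(n_subjects=10, n_genes=2, n_mirnas=2,
                        assoc_effects=(AssocEffect("G0099", "miR-0001", 0.2),))
        with pytest.raises(ReferenceError_):
            generate_mirna_signal(cfg, generate_cohort(cfg))

    def test_low_expression_tail_fails_inclusion_filter(self):
        from ccmirnet.associate import filter_mirnas
        cfg = SimConfig(n_subjects=100, n_genes=2, n_mirnas=10,
                        low_expression_fraction=0.3, rng_seed=6)
        matrix, _ = generate_mirna_signal(cfg, generate_cohort(cfg))
        kept = filter_mirnas(matrix, 0.20)
        assert set(kept) == set(cfg.mirna_ids()[:7])

    def test_same_seed_identical(self):
        cfg = SimConfig(n_subjects=30, n_genes=2, n_mirnas=4, rng_seed=3)
        cohort = generate_cohort(cfg)
        m1, _ = generate_mirna_signal(cfg, cohort)
        m2, _ = generate_mirna_signal(cfg, cohort)
        pd.testing.assert_frame_equal(m1.signal, m2.signal)


class TestSurvival:
    def test_zero_horizon_censors_everyone(self):
        from ccmirnet.survival import build_survival_frame
        from ccmirnet._coxph import CoxModel
        cfg = SimConfig(n_subjects=30, censor_horizon_months=0.0, rng_seed=8)
        cohort = generate_survival(cfg, generate_cohort(cfg))
        assert (cohort["vital_status"] == "alive").all()
        frame = build_survival_frame(cohort)
        with pytest.raises(DegenerateInputError):
            CoxModel(frame["time"].to_numpy(), frame["event"].to_numpy())

    def test_death_cause_consistent_with_vital_status(self):
        cfg = SimConfig(n_subjects=300, rng_seed=12)
        cohort = generate_survival(cfg, generate_cohort(cfg))
        alive = cohort["vital_status"] == "alive"
        assert ((cohort["death_cause"] == "none") == alive).all()
        assert (cohort["survival_months"] >= 0).all()
        assert cohort.loc[~alive, "death_cause"].isin(["crc", "other"]).all()


class TestSequences:
    def test_planted_site_recorded_and_present(self):
        cfg = SimConfig(n_subjects=5, n_genes=2, n_mirnas=2, utr_length=300,
                        seed_sites=(SeedSite("G0001", "miR-0002", 7, position=101),),
                        rng_seed=1)
        seqs = generate_sequences(cfg)
        [site] = seqs.planted
        assert site["position"] == 101 and site["seed_length"] == 7
        seed = seqs.mirna["miR-0002"][1:8]
        target = seed.replace("U", "T").translate(str.maketrans("ACGT", "TGCA"))[::-1]
        utr = seqs.utrs["G0001|GRCh38"]
        assert utr[100:107] == target

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        from ccmirnet import io
        cfg = SimConfig(n_subjects=5, n_genes=3, n_mirnas=3, rng_seed=2)
        for run in ("a", "b"):
            seqs = generate_sequences(cfg)
            io.write_fasta(seqs.utrs, tmp_path / f"{run}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_background_six_mer_rate_matches_binomial_expectation(self):
        from ccmirnet.seedmatch import extract_seeds, match_string
        cfg = SimConfig(n_subjects=5, n_genes=2000, n_mirnas=1, utr_length=50,
                        rng_seed=13)
        seqs = generate_sequences(cfg)
        total = 0
        for mi, mseq in enumerate(seqs.mirna.values()):
            target = match_string(extract_seeds("m", mseq).seeds[6])
            for utr in seqs.utrs.values():
                start = utr.find(target)
                while start != -1:
                    total += 1
                    start = utr.find(target, start + 1)
        n_pairs = len(seqs.utrs)
        expected = n_pairs * 45 * 4.0**-6
        assert abs(total - expected) <= 3 * np.sqrt(expected) + 3

    def test_too_small_utr_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_subjects=5, utr_length=8).validate()
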