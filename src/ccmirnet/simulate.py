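"""Synthetic paired tumor/normal cohorts with planted, recoverable effects.

Every downstream stage of the pipeline (normalization, paired NB differential
expression, bootstrap-F association, permutation Cox survival, seed matching)
is exercised against data produced here, where the ground truth — per-gene
log fold changes, gene-miRNA regression slopes, log hazard ratios per IQR,
and seed-site insertion positions — is known exactly.

Defaults mirror the study population the pipeline was designed for: 217
paired subjects, age ~ Normal(64.8, 10.1) truncated to the 30-79 eligibility
window, 54.4% male, AJCC stage frequencies (27.1, 28.5, 33.6, 10.8)%.

Randomness: one `numpy` Generator per (generator, feature) pair, derived
deterministically from ``rng_seed`` via ``SeedSequence`` so that adding genes
or miRNAs never perturbs the draws of existing ones, and identical configs
give bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io
from .containers import CARCINOMA, NORMAL, MiRNAMatrix, PairedExpressionSet
from .errors import InvalidConfigError, ReferenceError_

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AssocEffect:
    """Planted linear association: mrna_diff = beta * mirna_diff + covariates + noise."""

    gene: str
    mirna: str
    beta: float
    noise_sd: float = 1.0


@dataclass(frozen=True)
class SeedSite:
    """Planted seed-complementary site for (gene UTR, miRNA) at a known position."""

    gene: str
    mirna: str
    seed_length: int
    position: int | None = None  # 1-based start in the UTR; None -> drawn


@dataclass(frozen=True)
class SimConfig:
    """All planted parameters and cohort-level defaults for one simulation."""

    n_subjects: int = 217
    n_genes: int = 20
    n_mirnas: int = 20
    planted_log_fc: tuple[tuple[str, float], ...] = ()  # natural-log scale, per gene
    nb_dispersion: float = 20.0  # NB size: Var = mu + mu^2 / nb_dispersion
    subject_sd: float = 0.5  # SD of the per-subject log-scale random intercept
    assoc_effects: tuple[AssocEffect, ...] = ()
    planted_log_hr_per_iqr: tuple[tuple[str, float], ...] = ()
    seed_sites: tuple[SeedSite, ...] = ()
    utr_length: int = 500
    rng_seed: int = 0

    # cohort composition (study-population defaults, overridable)
    age_mean: float = 64.8
    age_sd: float = 10.1
    age_min: float = 30.0
    age_max: float = 79.0
    male_fraction: float = 0.544
    stage_probs: tuple[float, float, float, float] = (0.271, 0.285, 0.336, 0.108)

    # expression scale
    mean_pc_total: float = 2.0e6  # mean protein-coding library size
    pc_total_log_sd: float = 0.15
    base_rpm_range: tuple[float, float] = (5.0, 500.0)  # baseline RPMPCG, log-uniform

    # miRNA signal
    mirna_base_range: tuple[float, float] = (20.0, 2000.0)
    mirna_diff_sd: float = 20.0
    mirna_sample_noise_sd: float = 5.0
    low_expression_fraction: float = 0.0  # fraction of miRNAs made rarely detected
    low_expression_detect_rate: float = 0.10
    assoc_age_coef: float = 0.05  # covariate effects entering planted associations
    assoc_sex_coef: float = 0.5

    # survival process
    censor_horizon_months: float = 120.0
    baseline_hazard: float = 0.003  # CRC-death hazard per month at covariate baseline
    other_cause_hazard: float = 0.002
    age_log_hr: float = 0.03  # per year, age centered at its mean
    male_log_hr: float = 0.10
    stage_log_hr: tuple[float, float, float, float] = (0.0, 0.3, 0.7, 1.2)

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_genes <= 0 or self.n_mirnas <= 0:
            raise InvalidConfigError("n_subjects, n_genes, n_mirnas must be positive")
        if self.nb_dispersion <= 0:
            raise InvalidConfigError("nb_dispersion must be > 0")
        if self.subject_sd < 0:
            raise InvalidConfigError("subject_sd must be >= 0")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("stage_probs must sum to 1")
        if self.utr_length <= 8:
            raise InvalidConfigError("utr_length must exceed 8")
        for site in self.seed_sites:
            if site.seed_length not in (6, 7, 8):
                raise InvalidConfigError(f"seed_length must be 6, 7 or 8: {site}")
            last_start = self.utr_length - site.seed_length + 1
            if site.position is not None and not (1 <= site.position <= last_start):
                raise InvalidConfigError(f"seed site does not fit in the UTR: {site}")
        for eff in self.assoc_effects:
            if eff.noise_sd <= 0:
                raise InvalidConfigError(f"noise_sd must be > 0: {eff}")

    # --- id helpers -----------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_mirnas)]

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.n_subjects)]

    def log_fc_vector(self) -> pd.Series:
        lf = pd.Series(0.0, index=self.gene_ids())
        for gene, value in self.planted_log_fc:
            if gene not in lf.index:
                raise ReferenceError_(f"planted_log_fc refers to unknown gene {gene!r}")
            lf[gene] = value
        return lf


def _rng(config: SimConfig, *tags) -> np.random.Generator:
    """Deterministic sub-stream keyed by (rng_seed, tags)."""
    digest = hashlib.sha256(repr(tags).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed % (2**31), *words]))


def sample_ids_for(subject: str) -> tuple[str, str]:
    """(carcinoma, normal) sample ids for one subject."""
    return f"{subject}_C", f"{subject}_N"


def _sample_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for s in config.subject_ids():
        carc, norm = sample_ids_for(s)
        rows.append((carc, s, CARCINOMA))
        rows.append((norm, s, NORMAL))
    meta = pd.DataFrame(rows, columns=["sample_id", "subject_id", "tissue"])
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Subject table: age (truncated normal), sex, AJCC stage.

    Survival columns are appended later by :func:`generate_survival`.
    """
    config.validate()
    rng = _rng(config, "cohort")

    # 64.8 / 10.1 describe the observed (eligibility-truncated) ages, so the
    # latent normal's location is solved such that the truncated mean matches
    def trunc_mean(loc: float) -> float:
        a = (config.age_min - loc) / config.age_sd
        b = (config.age_max - loc) / config.age_sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=config.age_sd)

    from scipy.optimize import brentq

    lo, hi = config.age_min, config.age_max + 3 * config.age_sd
    if trunc_mean(lo) < config.age_mean < trunc_mean(hi):
        loc = brentq(lambda m: trunc_mean(m) - config.age_mean, lo, hi, xtol=1e-6)
    else:
        loc = config.age_mean
    a = (config.age_min - loc) / config.age_sd
    b = (config.age_max - loc) / config.age_sd
    ages = stats.truncnorm.rvs(
        a, b, loc=loc, scale=config.age_sd,
        size=config.n_subjects, random_state=rng,
    )
    sex = np.where(rng.random(config.n_subjects) < config.male_fraction, "male", "female")
    stage = rng.choice([1, 2, 3, 4], size=config.n_subjects, p=config.stage_probs)
    return pd.DataFrame(
        {
            "subject_id": config.subject_ids(),
            "age": ages,
            "sex": sex,
            "ajcc_stage": stage,
        }
    )


# ---------------------------------------------------------------------------
# paired RNA-seq counts
# ---------------------------------------------------------------------------

def generate_paired_counts(
    config: SimConfig,
    cohort: pd.DataFrame,
    mirna_diffs: pd.DataFrame | None = None,
) -> PairedExpressionSet:
    """NB counts for paired samples with subject random intercepts.

    count[g, sample] ~ NB(mean = pc_total_s * rate_g * exp(a_i + log_fc_g * carcinoma),
                          size = nb_dispersion)
    with a_i ~ Normal(0, subject_sd).  ``rate_g`` is the baseline expression
    expressed as a fraction of the protein-coding library (RPMPCG / 1e6).

    When ``mirna_diffs`` (miRNA x subject differential signal) is supplied,
    each planted :class:`AssocEffect` shifts the gene's carcinoma mean by
    ``(beta * mirna_diff + covariate terms + noise) * pc_total / 1e6`` so the
    RPMPCG differential profile computed downstream carries the planted
    slope against the miRNA profile.
    """
    config.validate()
    meta = _sample_meta(config)
    n_samples = len(meta)

    totals_rng = _rng(config, "pc_totals")
    pc_totals = np.rint(
        np.exp(
            totals_rng.normal(np.log(config.mean_pc_total), config.pc_total_log_sd, n_samples)
        )
    ).astype(np.int64)
    pc_totals = np.maximum(pc_totals, 1)

    subject_rng = _rng(config, "subject_intercepts")
    a = pd.Series(
        subject_rng.normal(0.0, config.subject_sd, config.n_subjects),
        index=config.subject_ids(),
    )

    base_rng = _rng(config, "gene_baselines")
    lo, hi = config.base_rpm_range
    base_rpm = np.exp(base_rng.uniform(np.log(lo), np.log(hi), config.n_genes))

    log_fc = config.log_fc_vector()
    is_carc = (meta["tissue"] == CARCINOMA).to_numpy(dtype=float)
    subj_effect = a.loc[meta["subject_id"]].to_numpy()

    # per-subject carcinoma-mean shifts (RPMPCG units) planting associations
    rpm_shift: dict[str, np.ndarray] = {}
    if mirna_diffs is not None and config.assoc_effects:
        age_c = cohort.set_index("subject_id").loc[config.subject_ids(), "age"].to_numpy()
        age_c = age_c - config.age_mean
        male = (
            cohort.set_index("subject_id").loc[config.subject_ids(), "sex"] == "male"
        ).to_numpy(float)
        for ei, eff in enumerate(config.assoc_effects):
            if eff.mirna not in mirna_diffs.index:
                raise ReferenceError_(f"assoc effect refers to unknown miRNA {eff.mirna!r}")
            x = mirna_diffs.loc[eff.mirna, config.subject_ids()].to_numpy(float)
            erng = _rng(config, "assoc_noise", ei)
            delta = (
                eff.beta * x
                + config.assoc_age_coef * age_c
                + config.assoc_sex_coef * male
                + erng.normal(0.0, eff.noise_sd, config.n_subjects)
            )
            rpm_shift[eff.gene] = rpm_shift.get(eff.gene, 0.0) + delta

    subj_pos = {s: i for i, s in enumerate(config.subject_ids())}
    subj_idx = np.array([subj_pos[s] for s in meta["subject_id"]])

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    theta = config.nb_dispersion
    for gi, gene in enumerate(config.gene_ids()):
        mu = (
            pc_totals
            * (base_rpm[gi] / 1e6)
            * np.exp(subj_effect + log_fc[gene] * is_carc)
        )
        if gene in rpm_shift:
            mu = mu + is_carc * rpm_shift[gene][subj_idx] * pc_totals / 1e6
            mu = np.maximum(mu, 0.01)
        grng = _rng(config, "counts", gi)
        counts[gi] = grng.negative_binomial(theta, theta / (theta + mu))

    counts_df = pd.DataFrame(counts, index=config.gene_ids(), columns=meta.index)
    totals = pd.Series(pc_totals, index=meta.index, name="pc_total")
    return PairedExpressionSet(counts_df, totals, meta)


# ---------------------------------------------------------------------------
# miRNA signal with planted linear associations
# ---------------------------------------------------------------------------

def generate_mirna_signal(
    config: SimConfig,
    cohort: pd.DataFrame,
    mrna_profiles: pd.DataFrame | None = None,
) -> tuple[MiRNAMatrix, pd.DataFrame]:
    """miRNA signal matrix plus mRNA differential profiles carrying planted slopes.

    For each planted :class:`AssocEffect` the miRNA differential profile is
    drawn first and the gene's differential profile is then constructed as
    ``beta * mirna_diff + age/sex covariate terms + Normal(0, noise_sd)`` so
    that the downstream least-squares stage regressing the mRNA profile on
    the miRNA profile recovers ``beta`` consistently.  Genes without a
    planted edge keep their incoming profile (or i.i.d. noise when no
    profile is supplied).

    A ``low_expression_fraction`` tail of the miRNA panel is generated with
    signal detected in only ``low_expression_detect_rate`` of normal samples,
    to exercise the >20%-of-normal-samples inclusion filter.

    Returns ``(mirna_matrix, mrna_profiles)`` where profiles are indexed
    gene x subject.
    """
    config.validate()
    mirnas = config.mirna_ids()
    genes = config.gene_ids()
    for eff in config.assoc_effects:
        if eff.gene not in genes:
            raise ReferenceError_(f"assoc effect refers to unknown gene {eff.gene!r}")
        if eff.mirna not in mirnas:
            raise ReferenceError_(f"assoc effect refers to unknown miRNA {eff.mirna!r}")

    subjects = config.subject_ids()
    n = config.n_subjects
    meta = _sample_meta(config)

    if mrna_profiles is None:
        mrna_profiles = pd.DataFrame(0.0, index=genes, columns=subjects)
    else:
        mrna_profiles = mrna_profiles.copy()

    n_low = int(round(config.low_expression_fraction * config.n_mirnas))
    low_set = set(mirnas[config.n_mirnas - n_low:]) if n_low else set()

    base_rng = _rng(config, "mirna_baselines")
    lo, hi = config.mirna_base_range
    base = np.exp(base_rng.uniform(np.log(lo), np.log(hi), config.n_mirnas))

    diffs = pd.DataFrame(0.0, index=mirnas, columns=subjects)
    signal = pd.DataFrame(0.0, index=mirnas, columns=meta.index)
    carc_cols = [sample_ids_for(s)[0] for s in subjects]
    norm_cols = [sample_ids_for(s)[1] for s in subjects]

    for mi, mirna in enumerate(mirnas):
        mrng = _rng(config, "mirna", mi)
        if mirna in low_set:
            detected = mrng.random(n) < config.low_expression_detect_rate
            normal = np.where(detected, mrng.uniform(1.0, 5.0, n), 0.0)
            carcinoma = np.where(mrng.random(n) < config.low_expression_detect_rate,
                                 mrng.uniform(1.0, 5.0, n), 0.0)
            diffs.loc[mirna] = carcinoma - normal
        else:
            diff = mrng.normal(0.0, config.mirna_diff_sd, n)
            normal = base[mi] + mrng.normal(0.0, config.mirna_sample_noise_sd, n)
            carcinoma = normal + diff
            # keep the planted difference exact while staying nonnegative
            shift = np.minimum(np.minimum(normal, carcinoma), 0.0)
            normal = normal - shift
            carcinoma = carcinoma - shift
            diffs.loc[mirna] = diff
        signal.loc[mirna, carc_cols] = carcinoma
        signal.loc[mirna, norm_cols] = normal

    age_c = cohort.set_index("subject_id").loc[subjects, "age"].to_numpy() - config.age_mean
    male = (cohort.set_index("subject_id").loc[subjects, "sex"] == "male").to_numpy(float)
    for ei, eff in enumerate(config.assoc_effects):
        erng = _rng(config, "assoc_noise", ei)
        x = diffs.loc[eff.mirna].to_numpy()
        y = (
            eff.beta * x
            + config.assoc_age_coef * age_c
            + config.assoc_sex_coef * male
            + erng.normal(0.0, eff.noise_sd, n)
        )
        mrna_profiles.loc[eff.gene] = y

    matrix = MiRNAMatrix(signal, meta, scaled=False)
    return matrix, mrna_profiles


# ---------------------------------------------------------------------------
# survival outcomes
# ---------------------------------------------------------------------------

def generate_survival(
    config: SimConfig,
    cohort: pd.DataFrame,
    profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach survival outcome columns to the cohort.

    CRC-death times are exponential with log-hazard
    ``sum_f (planted_log_hr_f / IQR_f) * x_f + covariate terms``; deaths from
    other causes arrive as an independent exponential and censor the subject
    at the death time; everyone still alive at the administrative horizon is
    censored there.
    """
    config.validate()
    subjects = config.subject_ids()
    n = config.n_subjects
    rng = _rng(config, "survival")

    eta = np.zeros(n)
    eta += config.age_log_hr * (cohort["age"].to_numpy() - config.age_mean)
    eta += config.male_log_hr * (cohort["sex"] == "male").to_numpy(float)
    stage_lhr = np.asarray(config.stage_log_hr)
    eta += stage_lhr[cohort["ajcc_stage"].to_numpy() - 1]

    for feature, log_hr in config.planted_log_hr_per_iqr:
        if profiles is None or feature not in profiles.index:
            raise ReferenceError_(f"planted_log_hr refers to unknown feature {feature!r}")
        x = profiles.loc[feature, subjects].to_numpy(dtype=float)
        q75, q25 = np.percentile(x, [75, 25])
        iqr = q75 - q25
        if iqr <= 0:
            raise InvalidConfigError(f"feature {feature!r} has zero IQR; cannot scale log-HR")
        eta += (log_hr / iqr) * x

    t_crc = rng.exponential(1.0 / (config.baseline_hazard * np.exp(eta)))
    t_other = rng.exponential(1.0 / config.other_cause_hazard, n)
    horizon = config.censor_horizon_months

    months = np.minimum(np.minimum(t_crc, t_other), horizon)
    crc_death = (t_crc <= t_other) & (t_crc < horizon)
    other_death = (t_other < t_crc) & (t_other < horizon)

    out = cohort.copy()
    out["survival_months"] = months
    out["vital_status"] = np.where(crc_death | other_death, "dead", "alive")
    out["death_cause"] = np.select([crc_death, other_death], ["crc", "other"], default="none")
    return out


# ---------------------------------------------------------------------------
# sequences with planted seed sites
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Simulated mature miRNA and 3'-UTR sequences plus planted-site log."""

    mirna: dict[str, str]  # id -> RNA sequence 5'->3'
    utrs: dict[str, str]   # "GENE|BUILD" -> DNA sequence
    planted: list[dict]    # gene, mirna, build, seed_length, position (1-based)
    build: str = "GRCh38"


def _revcomp_dna_of_rna(seed_rna: str) -> str:
    return seed_rna.replace("U", "T").translate(_DNA_COMPLEMENT)[::-1]


def generate_sequences(config: SimConfig, build: str = "GRCh38") -> SequenceSet:
    """Random miRNA (RNA, 20-24 nt) and UTR (DNA) sequences with planted sites.

    For each planted :class:`SeedSite` the reverse complement of the miRNA's
    seed (positions 2..1+seed_length) is written into the gene's UTR at a
    recorded 1-based position.  Sites for distinct (gene, miRNA) pairs are
    placed in disjoint windows so planted sites never overwrite one another.
    """
    config.validate()
    mirna_seqs: dict[str, str] = {}
    for mi, mirna in enumerate(config.mirna_ids()):
        rng = _rng(config, "mirna_seq", mi)
        length = int(rng.integers(20, 25))
        mirna_seqs[mirna] = "".join(rng.choice(list(RNA_ALPHABET), length))

    utrs: dict[str, str] = {}
    gene_seqs: dict[str, list[str]] = {}
    for gi, gene in enumerate(config.gene_ids()):
        rng = _rng(config, "utr_seq", gi)
        gene_seqs[gene] = list("".join(rng.choice(list(DNA_ALPHABET), config.utr_length)))

    planted: list[dict] = []
    sites_by_gene: dict[str, list[SeedSite]] = {}
    for site in config.seed_sites:
        sites_by_gene.setdefault(site.gene, []).append(site)
    for gene, sites in sites_by_gene.items():
        if gene not in gene_seqs:
            raise ReferenceError_(f"seed site refers to unknown gene {gene!r}")
        # disjoint windows so several planted sites can coexist in one UTR
        slot_width = config.utr_length // len(sites)
        if slot_width < 8:
            raise InvalidConfigError(
                f"utr_length {config.utr_length} too small for {len(sites)} sites in {gene}"
            )
        for si, site in enumerate(sites):
            if site.mirna not in mirna_seqs:
                raise ReferenceError_(f"seed site refers to unknown miRNA {site.mirna!r}")
            seed = mirna_seqs[site.mirna][1:1 + site.seed_length]  # positions 2..L+1
            target = _revcomp_dna_of_rna(seed)
            if site.position is not None:
                pos = site.position
            else:
                rng = _rng(config, "seed_pos", gene, si)
                lo = si * slot_width + 1
                hi = lo + slot_width - site.seed_length
                pos = int(rng.integers(lo, hi + 1))
            gene_seqs[gene][pos - 1:pos - 1 + site.seed_length] = list(target)
            planted.append(
                {
                    "gene": gene,
                    "mirna": site.mirna,
                    "build": build,
                    "seed_length": site.seed_length,
                    "position": pos,
                }
            )

    for gene, chars in gene_seqs.items():
        utrs[f"{gene}|{build}"] = "".join(chars)
    return SequenceSet(mirna_seqs, utrs, planted, build=build)


# ---------------------------------------------------------------------------
# dataset writer (CLI entry)
# ---------------------------------------------------------------------------

def write_dataset(config: SimConfig, outdir: str | Path) -> Path:
    """Generate every input the pipeline consumes and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    from .normalize import rpmpcg
    from .associate import make_differential_profiles

    cohort = generate_cohort(config)
    mirna, _profiles = generate_mirna_signal(config, cohort)
    mirna_diffs = make_differential_profiles(mirna.signal, mirna.sample_meta)
    # associations are planted through the counts so the written dataset
    # carries them end to end
    expr = generate_paired_counts(config, cohort, mirna_diffs=mirna_diffs)
    seqs = generate_sequences(config)

    # survival planted on normalized mRNA differential profiles
    norm = rpmpcg(expr)
    profiles = make_differential_profiles(norm.values, expr.sample_meta)
    all_profiles = pd.concat([profiles, mirna_diffs])
    cohort = generate_survival(config, cohort, all_profiles)

    io.write_matrix_tsv(expr.counts, outdir / "counts.tsv", index_label="gene")
    io.write_matrix_tsv(expr.pc_totals.to_frame().T, outdir / "pc_totals.tsv",
                        index_label="field")
    io.write_matrix_tsv(mirna.signal, outdir / "mirna_signal.tsv", index_label="mirna")
    io.write_table_tsv(expr.sample_meta.reset_index(), outdir / "samples.tsv")
    io.write_table_tsv(cohort, outdir / "subjects.tsv")
    io.write_fasta(seqs.mirna, outdir / "mirna.fa")
    io.write_fasta(seqs.utrs, outdir / "utrs.fa")

    truth = {
        "config": asdict(config),
        "planted_seed_sites": seqs.planted,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, default=str) + "\n")
    return outdir
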