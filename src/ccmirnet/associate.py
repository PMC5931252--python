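"""Gene-miRNA association on subject-level differential profiles.

The regression unit is the differential profile: for each subject,
carcinoma expression minus normal-mucosa expression (RPMPCG for genes,
scaled signal for miRNAs).  For a candidate (gene, miRNA) pair we fit

    full:  mrna_diff ~ 1 + mirna_diff + age + sex
    null:  mrna_diff ~ 1 + age + sex

and test the miRNA term with the nested-model F statistic.  P-values come
from a residual bootstrap under the null: resample the null model's raw
residuals with replacement, rebuild y* = null fit + resampled residuals,
recompute F on each replicate, and report the plus-one-corrected tail
fraction (1 + #{F* >= F_obs}) / (n_boot + 1).  Covariate columns are held
fixed across replicates.

Multiple-testing adjustment is made at the gene level: BH across each gene's
tested miRNAs, independently per gene (a global BH variant is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CARCINOMA, NORMAL, MiRNAMatrix
from .de import bh_fdr
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# differential profiles
# ---------------------------------------------------------------------------

def make_differential_profiles(
    matrix: pd.DataFrame, sample_meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-subject (carcinoma - normal) values, features x subjects.

    Subjects lacking either tissue are dropped with a logged count; a
    duplicated tissue for a subject is an error.
    """
    meta = sample_meta
    by_subj: dict[str, dict[str, str]] = {}
    for sample, row in meta.iterrows():
        slot = by_subj.setdefault(row["subject_id"], {})
        if row["tissue"] in slot:
            raise ValidationError(
                f"subject {row['subject_id']!r} has more than one {row['tissue']} sample"
            )
        slot[row["tissue"]] = sample

    complete = {s: t for s, t in by_subj.items() if CARCINOMA in t and NORMAL in t}
    dropped = len(by_subj) - len(complete)
    if dropped:
        logger.warning("dropping %d subject(s) lacking a tissue pair", dropped)
    if not complete:
        raise ValidationError("no subject has both a carcinoma and a normal sample")

    subjects = list(complete)
    carc_cols = [complete[s][CARCINOMA] for s in subjects]
    norm_cols = [complete[s][NORMAL] for s in subjects]
    diffs = matrix[carc_cols].to_numpy(float) - matrix[norm_cols].to_numpy(float)
    return pd.DataFrame(diffs, index=matrix.index, columns=subjects)


def filter_mirnas(m: MiRNAMatrix, min_fraction: float = 0.20) -> list[str]:
    """miRNAs with signal > 0 in strictly more than ``min_fraction`` of normal samples."""
    normal_cols = m.sample_meta.index[m.sample_meta["tissue"] == NORMAL]
    if len(normal_cols) == 0:
        raise ValidationError("no normal-tissue samples present")
    frac = (m.signal[normal_cols] > 0).mean(axis=1)
    return list(frac.index[frac > min_fraction])


# ---------------------------------------------------------------------------
# nested OLS and bootstrap F
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    """Nested least-squares fit of one (gene, miRNA) pair."""

    beta: float
    f_obs: float
    df2: int
    n: int
    null_fitted: np.ndarray
    null_resid: np.ndarray
    _q_full: np.ndarray
    _q_null: np.ndarray


def _rss(q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares via an orthonormal column basis of the design."""
    proj = q.T @ y
    return (y * y).sum(axis=0) - (proj * proj).sum(axis=0)


def fit_linear(
    y: np.ndarray, x: np.ndarray, age: np.ndarray, sex: np.ndarray
) -> LinearFit:
    """OLS of y on [1, x, age, sex]; nested F for the x term with (1, n-4) df.

    ``sex`` is a 0/1 indicator; age is centered internally (affects neither
    the slope of interest nor F).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.shape[0]
    if not (x.shape[0] == age.shape[0] == sex.shape[0] == n):
        raise ValidationError("profile and covariate lengths differ")
    if n < 5:
        raise ValidationError("need at least 5 subjects for the 4-parameter model")
    if np.ptp(x) == 0:
        raise DegenerateInputError("miRNA differential profile has zero variance")

    age_c = np.asarray(age, float) - np.mean(age)
    ones = np.ones(n)
    x_null = np.column_stack([ones, age_c, np.asarray(sex, float)])
    x_full = np.column_stack([ones, x, age_c, np.asarray(sex, float)])

    q_null, _ = np.linalg.qr(x_null)
    q_full, _ = np.linalg.qr(x_full)

    coef, *_ = np.linalg.lstsq(x_full, y, rcond=None)
    rss_full = float(_rss(q_full, y[:, None])[0])
    rss_null = float(_rss(q_null, y[:, None])[0])
    df2 = n - x_full.shape[1]
    denom = rss_full / df2
    f_obs = 0.0 if denom == 0 else max(rss_null - rss_full, 0.0) / denom

    null_coef, *_ = np.linalg.lstsq(x_null, y, rcond=None)
    null_fitted = x_null @ null_coef
    return LinearFit(
        beta=float(coef[1]),
        f_obs=float(f_obs),
        df2=df2,
        n=n,
        null_fitted=null_fitted,
        null_resid=y - null_fitted,
        _q_full=q_full,
        _q_null=q_null,
    )


def bootstrap_f_pvalue(
    fit: LinearFit,
    n_boot: int = 10000,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Residual-bootstrap p-value for the nested F test (plus-one corrected)."""
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = fit.n
    idx = rng.integers(0, n, size=(n, n_boot))
    y_star = fit.null_fitted[:, None] + fit.null_resid[idx]
    rss_full = _rss(fit._q_full, y_star)
    rss_null = _rss(fit._q_null, y_star)
    denom = rss_full / fit.df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = np.where(denom > 0, (rss_null - rss_full) / denom, 0.0)
    return float((1 + np.count_nonzero(f_star >= fit.f_obs)) / (n_boot + 1))


# ---------------------------------------------------------------------------
# batch association + gene-level FDR
# ---------------------------------------------------------------------------

def associate_all(
    mrna_profiles: pd.DataFrame,
    mirna_profiles: pd.DataFrame,
    cohort: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    n_boot: int = 10000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap-F association for every candidate (gene, miRNA) pair.

    ``pairs`` defaults to the full cross of the supplied profile indexes.
    Each pair draws from its own deterministic RNG sub-stream, so results do
    not depend on the order in which pairs are evaluated.
    """
    subjects = list(mrna_profiles.columns)
    if list(mirna_profiles.columns) != subjects:
        mirna_profiles = mirna_profiles[subjects]
    cohort_idx = cohort.set_index("subject_id").loc[subjects]
    age = cohort_idx["age"].to_numpy(float)
    sex = (cohort_idx["sex"] == "male").to_numpy(float)

    if pairs is None:
        pairs = [(g, m) for g in mrna_profiles.index for m in mirna_profiles.index]

    gene_pos = {g: i for i, g in enumerate(mrna_profiles.index)}
    mirna_pos = {m: i for i, m in enumerate(mirna_profiles.index)}
    rows = []
    for gene, mirna in pairs:
        y = mrna_profiles.loc[gene].to_numpy(float)
        x = mirna_profiles.loc[mirna].to_numpy(float)
        fit = fit_linear(y, x, age, sex)
        rng = np.random.default_rng(
            np.random.SeedSequence([rng_seed % (2**31), gene_pos[gene], mirna_pos[mirna]])
        )
        p_boot = bootstrap_f_pvalue(fit, n_boot=n_boot, rng=rng)
        direction = "positive" if fit.beta > 0 else ("negative" if fit.beta < 0 else "none")
        rows.append(
            {
                "gene": gene,
                "mirna": mirna,
                "beta": fit.beta,
                "f_obs": fit.f_obs,
                "p_boot": p_boot,
                "n_boot": n_boot,
                "direction": direction,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=["gene", "mirna", "beta", "f_obs", "p_boot", "n_boot", "direction"],
    )
    return gene_level_fdr(records)


def gene_level_fdr(records: pd.DataFrame, scope: str = "gene") -> pd.DataFrame:
    """BH adjustment of bootstrap p-values.

    ``scope='gene'`` (default) adjusts within each gene across its tested
    miRNAs; ``scope='global'`` adjusts across all records at once.
    """
    if "p_boot" not in records.columns:
        raise ValidationError("records need a p_boot column")
    out = records.copy()
    if len(out) == 0:
        out["fdr_gene"] = pd.Series(dtype=float)
        return out
    if scope == "global":
        out["fdr_gene"] = bh_fdr(out["p_boot"].to_numpy())
    elif scope == "gene":
        out["fdr_gene"] = np.nan
        for gene, grp in out.groupby("gene"):
            if len(grp) == 0:
                logger.warning("empty record group for gene %r", gene)
                continue
            out.loc[grp.index, "fdr_gene"] = bh_fdr(grp["p_boot"].to_numpy())
    else:
        raise ValidationError(f"unknown FDR scope {scope!r}")
    return out
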