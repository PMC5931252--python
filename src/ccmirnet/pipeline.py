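"""End-to-end orchestration: normalize -> DE -> band filter -> associate ->
seed match -> classify -> survival -> edge list.

Stage contracts are files (TSV / FASTA / JSON manifest) inside a run
directory, so every stage is independently inspectable and a rerun with the
same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .associate import associate_all, filter_mirnas, make_differential_profiles
from .containers import MiRNAMatrix, PairedExpressionSet
from .de import banded_significant_genes, round_fc, run_de
from .errors import ConsistencyError, InvalidConfigError
from .normalize import rpmpcg, scale_mirna
from .seedmatch import classify_interaction, report_table, scan_pairs
from .survival import survival_analysis

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths to the input files plus every analysis threshold."""

    counts: str
    pc_totals: str
    samples: str
    subjects: str
    mirna_signal: str
    mirna_fasta: str
    utr_fasta: str
    fc_low: float = 0.67
    fc_high: float = 1.50
    de_alpha: float = 0.05
    assoc_fdr: float = 0.05
    n_boot: int = 10000
    n_perm: int = 10000
    mirna_min_fraction: float = 0.20
    rng_seed: int = 0
    subset: str = "all"  # all | msi | mss (uses subjects.msi_status when present)

    def validate(self) -> None:
        if not (0 < self.fc_low < 1 < self.fc_high):
            raise InvalidConfigError("need 0 < fc_low < 1 < fc_high")
        for name in ("de_alpha", "assoc_fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidConfigError(f"{name} must be in (0, 1)")
        if self.n_boot < 1 or self.n_perm < 1:
            raise InvalidConfigError("n_boot and n_perm must be positive")
        if not (0 <= self.mirna_min_fraction < 1):
            raise InvalidConfigError("mirna_min_fraction must be in [0, 1)")
        if self.subset not in ("all", "msi", "mss"):
            raise InvalidConfigError("subset must be one of all/msi/mss")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """File values overridden by CLI keyword arguments (CLI > file > defaults)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    counts = io.read_matrix_tsv(config.counts)
    totals_df = io.read_matrix_tsv(config.pc_totals)
    totals = totals_df.iloc[0].astype(np.int64)
    totals.name = "pc_total"
    samples = io.read_table_tsv(config.samples).set_index("sample_id")
    subjects = io.read_table_tsv(config.subjects)
    mirna_signal = io.read_matrix_tsv(config.mirna_signal)

    if list(counts.columns) != list(samples.index):
        raise ConsistencyError("counts columns and sample table ids differ")
    if list(counts.columns) != list(totals.index):
        raise ConsistencyError("counts columns and pc_totals ids differ")
    if set(samples["subject_id"]) != set(subjects["subject_id"]):
        raise ConsistencyError("sample table and subject table disagree on subjects")
    if list(mirna_signal.columns) != list(samples.index):
        raise ConsistencyError("miRNA signal columns and sample table ids differ")

    if config.subset != "all":
        if "msi_status" not in subjects.columns:
            raise ConsistencyError("subset analysis requested but subjects lack msi_status")
        keep_subjects = set(
            subjects.loc[subjects["msi_status"] == config.subset, "subject_id"]
        )
        keep_samples = [s for s in samples.index if samples.loc[s, "subject_id"] in keep_subjects]
        logger.info("subset=%s keeps %d subjects", config.subset, len(keep_subjects))
        counts = counts[keep_samples]
        totals = totals.loc[keep_samples]
        samples = samples.loc[keep_samples]
        mirna_signal = mirna_signal[keep_samples]
        subjects = subjects[subjects["subject_id"].isin(keep_subjects)]

    expr = PairedExpressionSet(counts, totals, samples)
    mirna = MiRNAMatrix(mirna_signal, samples, scaled=False)
    mirna_seqs = io.read_fasta(config.mirna_fasta)
    utr_seqs = io.read_fasta(config.utr_fasta)
    return expr, mirna, subjects, mirna_seqs, utr_seqs


def build_edge_list(
    assoc: pd.DataFrame,
    reports: dict,
    survival_records: pd.DataFrame,
) -> pd.DataFrame:
    """One row per tested (gene, miRNA) pair with classification and survival flags."""
    surv = survival_records.set_index("feature") if len(survival_records) else pd.DataFrame()

    def flags(feature: str) -> tuple[bool, bool]:
        if feature not in getattr(surv, "index", []):
            return False, False
        row = surv.loc[feature]
        return bool(row["p_perm"] < 0.05), bool(row["fdr"] < 0.05)

    rows = []
    for _, rec in assoc.iterrows():
        key = (rec["gene"], rec["mirna"])
        if key not in reports:
            raise ConsistencyError(f"association {key} was never seed-scanned")
        cls = classify_interaction(rec["beta"], reports[key])
        g_p, g_f = flags(rec["gene"])
        m_p, m_f = flags(rec["mirna"])
        rows.append(
            {
                "gene": rec["gene"],
                "mirna": rec["mirna"],
                "beta_sign": "positive" if rec["beta"] > 0 else
                             ("negative" if rec["beta"] < 0 else "none"),
                "interaction_class": cls,
                "gene_survival_p05": g_p,
                "gene_survival_fdr05": g_f,
                "mirna_survival_p05": m_p,
                "mirna_survival_fdr05": m_f,
            }
        )
    columns = ["gene", "mirna", "beta_sign", "interaction_class",
               "gene_survival_p05", "gene_survival_fdr05",
               "mirna_survival_p05", "mirna_survival_fdr05"]
    return pd.DataFrame(rows, columns=columns)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage, writing per-stage TSVs and a JSON manifest to ``outdir``."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr, mirna, subjects, mirna_seqs, utr_seqs = _load_inputs(config)
    summary: dict = {}

    # 1. normalization
    norm = rpmpcg(expr)
    io.write_matrix_tsv(norm.values, out / "normalized_mrna.tsv", index_label="gene")
    mirna_scaled = scale_mirna(mirna)
    io.write_matrix_tsv(mirna_scaled.signal, out / "scaled_mirna.tsv", index_label="mirna")

    # 2. differential expression + band filter
    de_table = run_de(expr, fc_low=config.fc_low, fc_high=config.fc_high)
    report = de_table.copy()
    report["fc_ratio"] = [round_fc(v) if np.isfinite(v) else np.nan for v in report["fc_ratio"]]
    io.write_table_tsv(report.reset_index(), out / "de.tsv")
    banded = banded_significant_genes(
        de_table, alpha=config.de_alpha, fc_low=config.fc_low, fc_high=config.fc_high
    )
    summary["genes_tested"] = int(len(de_table))
    summary["genes_banded_significant"] = int(len(banded))

    # 3. differential profiles + miRNA inclusion filter
    mrna_profiles = make_differential_profiles(norm.values, expr.sample_meta)
    kept_mirnas = filter_mirnas(mirna_scaled, config.mirna_min_fraction)
    summary["mirnas_kept"] = int(len(kept_mirnas))
    summary["mirnas_dropped_low_expression"] = int(len(mirna.signal) - len(kept_mirnas))
    mirna_profiles = make_differential_profiles(
        mirna_scaled.signal.loc[kept_mirnas], mirna_scaled.sample_meta
    )
    io.write_matrix_tsv(mrna_profiles, out / "mrna_profiles.tsv", index_label="gene")
    io.write_matrix_tsv(mirna_profiles, out / "mirna_profiles.tsv", index_label="mirna")

    # 4. association (banded genes x kept miRNAs)
    assoc = associate_all(
        mrna_profiles.loc[banded],
        mirna_profiles,
        subjects,
        n_boot=config.n_boot,
        rng_seed=config.rng_seed,
    )
    io.write_table_tsv(assoc, out / "associations.tsv")
    sig = assoc[assoc["fdr_gene"] < config.assoc_fdr]
    summary["pairs_tested"] = int(len(assoc))
    summary["pairs_significant"] = int(len(sig))

    # 5. seed matching + classification for every tested pair
    pairs = list(zip(assoc["gene"], assoc["mirna"]))
    reports = scan_pairs(mirna_seqs, utr_seqs, pairs)
    io.write_table_tsv(report_table(reports), out / "seed_matches.tsv")
    sig_match = {
        (g, m): reports[(g, m)].any_match for g, m in zip(sig["gene"], sig["mirna"])
    }
    summary["significant_with_seed_match_positive_beta"] = int(
        sum(1 for (_, rec) in sig.iterrows()
            if sig_match[(rec["gene"], rec["mirna"])] and rec["beta"] > 0)
    )
    summary["significant_with_seed_match_negative_beta"] = int(
        sum(1 for (_, rec) in sig.iterrows()
            if sig_match[(rec["gene"], rec["mirna"])] and rec["beta"] < 0)
    )

    # 6. survival: DE-significant banded mRNAs + miRNAs with a significant association
    surv_mirnas = sorted(set(sig["mirna"]))
    surv_features = pd.concat(
        [mrna_profiles.loc[banded], mirna_profiles.loc[surv_mirnas]]
    )
    classes = {f: "mrna" for f in banded}
    classes.update({m: "mirna" for m in surv_mirnas})
    surv = survival_analysis(
        surv_features, subjects, B=config.n_perm,
        rng_seed=config.rng_seed, feature_class=classes,
    )
    io.write_table_tsv(surv, out / "survival.tsv")
    summary["survival_features_tested"] = int(len(surv))

    # 7. edge list
    edges = build_edge_list(assoc, reports, surv)
    io.write_table_tsv(edges, out / "edges.tsv")

    io.write_manifest(
        out / "manifest.json",
        inputs={
            "counts": config.counts,
            "pc_totals": config.pc_totals,
            "samples": config.samples,
            "subjects": config.subjects,
            "mirna_signal": config.mirna_signal,
            "mirna_fasta": config.mirna_fasta,
            "utr_fasta": config.utr_fasta,
        },
        config=dataclasses.asdict(config),
        seed=config.rng_seed,
        summary=summary,
    )
    return out
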