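"""In-memory containers shared across pipeline stages.

The analysis operates on paired samples: each subject contributes exactly one
carcinoma and one normal-mucosa sample.  Sample metadata is a DataFrame
indexed by sample id with columns ``subject_id`` and ``tissue``
(``carcinoma`` / ``normal``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

CARCINOMA = "carcinoma"
NORMAL = "normal"
TISSUES = (CARCINOMA, NORMAL)


def validate_sample_meta(sample_meta: pd.DataFrame) -> None:
    """Every subject must appear with exactly one sample of each tissue."""
    if not {"subject_id", "tissue"}.issubset(sample_meta.columns):
        raise ValidationError("sample_meta needs 'subject_id' and 'tissue' columns")
    bad = set(sample_meta["tissue"]) - set(TISSUES)
    if bad:
        raise ValidationError(f"unknown tissue labels: {sorted(bad)}")
    counts = sample_meta.groupby(["subject_id", "tissue"]).size().unstack(fill_value=0)
    for t in TISSUES:
        if t not in counts.columns:
            counts[t] = 0
    off = counts[(counts[CARCINOMA] != 1) | (counts[NORMAL] != 1)]
    if len(off):
        raise ValidationError(
            f"subjects without exactly one carcinoma and one normal sample: "
            f"{list(off.index[:5])}"
        )


@dataclass
class PairedExpressionSet:
    """Gene x sample counts with per-sample protein-coding totals.

    ``counts`` holds nonnegative integers; ``pc_totals`` the per-sample total
    protein-coding read count used as the exposure offset in the paired
    negative-binomial model and as the RPMPCG denominator.
    """

    counts: pd.DataFrame
    pc_totals: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.pc_totals.index):
            raise ValidationError("counts columns and pc_totals index differ")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValidationError("counts columns and sample_meta index differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        nonpos = self.pc_totals[self.pc_totals <= 0]
        if len(nonpos):
            raise ValidationError(
                f"non-positive protein-coding totals for samples {list(nonpos.index[:5])}"
            )
        validate_sample_meta(self.sample_meta)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, samples: list[str]) -> "PairedExpressionSet":
        return PairedExpressionSet(
            self.counts[samples],
            self.pc_totals.loc[samples],
            self.sample_meta.loc[samples],
        )


@dataclass
class NormalizedMatrix:
    """Gene x sample matrix of nonnegative normalized values."""

    values: pd.DataFrame
    method: str = "rpmpcg"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite normalized values")
        if (arr < 0).any():
            raise ValidationError("negative normalized values")


@dataclass
class MiRNAMatrix:
    """miRNA x sample signal matrix (Agilent-style total gene signal)."""

    signal: pd.DataFrame
    sample_meta: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if (self.signal.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative miRNA signal")
        if list(self.signal.columns) != list(self.sample_meta.index):
            raise ValidationError("signal columns and sample_meta index differ")
        validate_sample_meta(self.sample_meta)
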