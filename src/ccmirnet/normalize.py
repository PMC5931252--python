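"""Normalization: RPMPCG for RNA-seq counts, 75th-percentile scaling for miRNA.

RPMPCG ("reads per million protein-coding genes") divides each gene's count
by the sample's total protein-coding count and multiplies by 1e6, so values
are comparable across libraries of different depth.

miRNA total gene signal is rescaled per sample by
``median over samples of q75 / q75 of the sample`` so that after scaling
every sample shares the same 75th percentile.  Percentiles use linear
interpolation between order statistics (numpy's default), and the median of
an even number of samples is the mean of the two central values.
"""

from __future__ import annotations

import numpy as np

from .containers import MiRNAMatrix, NormalizedMatrix, PairedExpressionSet
from .errors import NormalizationError


def rpmpcg(expr: PairedExpressionSet) -> NormalizedMatrix:
    """value[g, s] = counts[g, s] / pc_total[s] * 1e6."""
    totals = expr.pc_totals.astype(float)
    bad = totals[totals <= 0]
    if len(bad):
        raise NormalizationError(
            f"non-positive protein-coding total for sample(s) {list(bad.index[:5])}"
        )
    values = expr.counts.astype(float).div(totals, axis=1) * 1e6
    return NormalizedMatrix(values, method="rpmpcg")


def scale_mirna(m: MiRNAMatrix) -> MiRNAMatrix:
    """75th-percentile scaling; idempotent up to float tolerance.

    factor_s = median_s'(q75_s') / q75_s, applied columnwise.
    """
    q75 = m.signal.quantile(0.75, axis=0)
    bad = q75[q75 <= 0]
    if len(bad):
        raise NormalizationError(
            f"non-positive 75th percentile for sample(s) {list(bad.index[:5])}"
        )
    factors = np.median(q75.to_numpy()) / q75
    scaled = m.signal.mul(factors, axis=1)
    return MiRNAMatrix(scaled, m.sample_meta, scaled=True)
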