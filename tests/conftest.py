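import numpy as np
import pandas as pd
import pytest

from ccmirnet.containers import PairedExpressionSet


def make_paired_set(counts: np.ndarray, totals=None, genes=None) -> PairedExpressionSet:
    """PairedExpressionSet from a genes x (2*n_subjects) array laid out as
    [S1_C, S1_N, S2_C, S2_N, ...]."""
    counts = np.atleast_2d(np.asarray(counts))
    n_pairs = counts.shape[1] // 2
    samples, rows = [], []
    for i in range(n_pairs):
        subj = f"S{i + 1:04d}"
        samples += [f"{subj}_C", f"{subj}_N"]
        rows += [(subj, "carcinoma"), (subj, "normal")]
    meta = pd.DataFrame(rows, columns=["subject_id", "tissue"],
                        index=pd.Index(samples, name="sample_id"))
    genes = genes or [f"G{i + 1:04d}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=genes, columns=samples)
    if totals is None:
        totals = np.full(len(samples), 1_000_000)
    tot = pd.Series(np.asarray(totals), index=samples, name="pc_total")
    return PairedExpressionSet(df, tot, meta)


@pytest.fixture
def toy_expr() -> PairedExpressionSet:
    """5 pairs x 3 genes with identical counts in both tissues of each pair."""
    per_subject = np.array([[10, 40, 25, 60, 15],
                            [100, 80, 120, 90, 110],
                            [3, 0, 7, 2, 5]])
    counts = np.repeat(per_subject, 2, axis=1)  # C and N identical per pair
    return make_paired_set(counts)
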