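"""TSV / FASTA / manifest helpers used by every stage.

All tabular interchange is tab-delimited UTF-8 with a header row; feature
matrices carry the feature id in the first column and one column per sample.
Missing values are written as ".".
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = "."


def read_matrix_tsv(path: str | Path, index_col: int = 0) -> pd.DataFrame:
    """Read a feature x sample matrix (first column = feature id)."""
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[MISSING])


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, na_rep=MISSING)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns in insertion order."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, *, inputs: dict[str, str | Path],
                   config: dict, seed: int | None, summary: dict) -> None:
    """Record input hashes, the echoed configuration, and stage summaries."""
    manifest = {
        "inputs": {k: sha256_file(v) for k, v in inputs.items()},
        "config": config,
        "seed": seed,
        "summary": summary,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
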