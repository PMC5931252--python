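"""miRNA seed extraction and 3'-UTR seed-match scanning.

Seeds are taken from the 5' end of the mature miRNA at positions 2-7
(6-mer), 2-8 (7-mer) and 2-9 (8-mer) — the canonical seed family anchored
at nucleotide 2; the anchor is configurable.  A candidate binding site is
the reverse complement of the seed (with U -> T) occurring on the sense
strand of the gene's 3' UTR.  All, possibly overlapping, occurrences are
reported with 1-based start positions; 'N' bases never match.  Matching is
case-insensitive.

A significant gene-miRNA association whose pair also has a seed match (in
any scanned genome build, any isoform) is classified "direct":
repression-consistent when the regression slope is negative, a
feedback/feed-forward candidate when positive.  Pairs without a match are
"indirect".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

SEED_LENGTHS = (6, 7, 8)
SEED_ANCHOR = 2  # 1-based position of the first seed nucleotide
_RNA_LETTERS = set("ACGU")
_DNA_LETTERS = set("ACGTN")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DIRECT_NEGATIVE = "direct_negative"
DIRECT_POSITIVE = "direct_positive"
INDIRECT = "indirect"


@dataclass(frozen=True)
class SeedSet:
    """Seeds of one mature miRNA, keyed by length."""

    mirna: str
    sequence: str
    seeds: dict[int, str]


@dataclass(frozen=True)
class UTRRecord:
    gene: str
    build: str
    sequence: str
    isoform: str = ""


@dataclass
class SeedMatchReport:
    """Match positions for one (gene, miRNA) pair, by build and seed length."""

    gene: str
    mirna: str
    # (build, isoform, seed_length) -> sorted 1-based start positions
    positions: dict[tuple[str, str, int], list[int]] = field(default_factory=dict)

    @property
    def any_match(self) -> bool:
        return any(self.positions.values())


def extract_seeds(
    mirna: str, sequence: str,
    anchor: int = SEED_ANCHOR, lengths: tuple[int, ...] = SEED_LENGTHS,
) -> SeedSet:
    """Seeds at positions ``anchor .. anchor+L-1`` (1-based) for each length."""
    seq = sequence.upper().replace("T", "U")
    if set(seq) - _RNA_LETTERS:
        raise ValidationError(
            f"{mirna}: invalid RNA characters {sorted(set(seq) - _RNA_LETTERS)}"
        )
    if len(seq) < anchor - 1 + max(lengths):
        raise ValidationError(
            f"{mirna}: sequence of length {len(seq)} too short for an "
            f"{max(lengths)}-nt seed at position {anchor}"
        )
    seeds = {L: seq[anchor - 1:anchor - 1 + L] for L in lengths}
    return SeedSet(mirna, seq, seeds)


def match_string(seed: str) -> str:
    """DNA target-site string: reverse complement of the seed, U -> T."""
    return seed.upper().replace("U", "T").translate(_DNA_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) 1-based occurrences of ``needle`` in ``haystack``."""
    positions = []
    start = haystack.find(needle)
    while start != -1:
        positions.append(start + 1)
        start = haystack.find(needle, start + 1)
    return positions


def scan_utr(utr: UTRRecord, seeds: SeedSet) -> SeedMatchReport:
    """All seed-complementary sites of one miRNA in one UTR record."""
    seq = utr.sequence.upper()
    bad = set(seq) - _DNA_LETTERS
    if bad:
        raise ValidationError(f"{utr.gene}: invalid UTR characters {sorted(bad)}")
    if seq and seq.count("N") / len(seq) > 0.10:
        logger.warning("%s (%s): more than 10%% N bases, skipping", utr.gene, utr.build)
        return SeedMatchReport(utr.gene, seeds.mirna)
    report = SeedMatchReport(utr.gene, seeds.mirna)
    for L, seed in seeds.seeds.items():
        target = match_string(seed)
        # an all-N or N-containing window can never equal the target (target has no N)
        report.positions[(utr.build, utr.isoform, L)] = _find_all(seq, target)
    return report


def parse_utr_header(header: str) -> tuple[str, str, str]:
    """UTR FASTA header grammar: ``GENE|BUILD`` or ``GENE|BUILD|ISOFORM``."""
    parts = header.split("|")
    if len(parts) == 2:
        return parts[0], parts[1], ""
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    raise ValidationError(f"cannot parse UTR header {header!r} (want GENE|BUILD[|ISOFORM])")


def scan_pairs(
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    pairs: list[tuple[str, str]],
) -> dict[tuple[str, str], SeedMatchReport]:
    """Scan every (gene, miRNA) pair against all isoforms/builds of the gene's UTR."""
    utr_records: dict[str, list[UTRRecord]] = {}
    for header, seq in utr_seqs.items():
        gene, build, isoform = parse_utr_header(header)
        utr_records.setdefault(gene, []).append(UTRRecord(gene, build, seq, isoform))

    seed_cache = {m: extract_seeds(m, s) for m, s in mirna_seqs.items()}
    reports: dict[tuple[str, str], SeedMatchReport] = {}
    for gene, mirna in pairs:
        if mirna not in seed_cache:
            raise ValidationError(f"no mature sequence for miRNA {mirna!r}")
        if gene not in utr_records:
            raise ValidationError(f"no UTR sequence for gene {gene!r}")
        merged = SeedMatchReport(gene, mirna)
        for rec in utr_records[gene]:
            merged.positions.update(scan_utr(rec, seed_cache[mirna]).positions)
        reports[(gene, mirna)] = merged
    return reports


def classify_interaction(beta: float, report: SeedMatchReport) -> str:
    """direct_negative / direct_positive (feedback candidate) / indirect.

    Tie-break: a zero slope with a seed match is classified by the match
    alone and returned as ``direct_none``.
    """
    if not report.any_match:
        return INDIRECT
    if beta < 0:
        return DIRECT_NEGATIVE
    if beta > 0:
        return DIRECT_POSITIVE
    return "direct_none"


def report_table(reports: dict[tuple[str, str], SeedMatchReport]) -> pd.DataFrame:
    """Long-format match table: gene, mirna, build, isoform, seed_length, position."""
    rows = []
    for (gene, mirna), rep in reports.items():
        for (build, isoform, L), positions in rep.positions.items():
            for pos in positions:
                rows.append(
                    {
                        "gene": gene,
                        "mirna": mirna,
                        "build": build,
                        "isoform": isoform,
                        "seed_length": L,
                        "position": pos,
                    }
                )
    return pd.DataFrame(rows, columns=["gene", "mirna", "build", "isoform",
                                       "seed_length", "position"])
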