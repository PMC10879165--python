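"""Read-count tables and alignment counting.

The canonical input is a tab-separated table with one row per sample::

    sample  protocol  chr1  chr2 ... chr22  chrX  chrY

Counts can also be derived directly from a SAM/BAM file with the same
filters used for ancient-DNA shotgun screening (minimum read length 35,
minimum mapping quality 25); the table remains the unit of exchange.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .chromosomes import AUTOSOMES, CHROMOSOMES, normalize_chromosome

__all__ = [
    "CountTableError",
    "TableDialect",
    "ReadCountProfile",
    "CohortTable",
    "read_count_table",
    "write_count_table",
    "count_reads_from_alignment",
]


class CountTableError(ValueError):
    """Malformed or inconsistent read-count input."""


@dataclass(frozen=True)
class TableDialect:
    """Column naming for count tables.

    ``chrom_prefix`` is prepended to bare chromosome names to form column
    headers (``"chr"`` gives ``chr1`` .. ``chrY``; ``""`` gives ``1`` .. ``Y``).
    """

    sample_col: str = "sample"
    protocol_col: str = "protocol"
    chrom_prefix: str = "chr"

    def chrom_col(self, chrom: str) -> str:
        return f"{self.chrom_prefix}{chrom}"


@dataclass
class ReadCountProfile:
    """Per-chromosome read counts for one sample.

    ``counts`` must contain every chromosome ``"1"``..``"22"``, ``"X"``, ``"Y"``
    (zero is allowed, absence is not). ``n_autosomal`` is always recomputed
    from the counts, never trusted from a file.
    """

    sample_id: str
    protocol: str
    counts: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in CHROMOSOMES if c not in self.counts]
        if missing:
            raise CountTableError(
                f"sample {self.sample_id!r}: missing chromosome(s) {missing}"
            )
        bad = {c: v for c, v in self.counts.items() if int(v) < 0}
        if bad:
            raise CountTableError(
                f"sample {self.sample_id!r}: negative count(s) {bad}"
            )
        self.counts = {c: int(self.counts[c]) for c in CHROMOSOMES}

    @property
    def n_autosomal(self) -> int:
        """Total reads on chromosomes 1-22 (recomputed)."""
        return sum(self.counts[c] for c in AUTOSOMES)

    @property
    def n_total(self) -> int:
        """Total reads on all 24 chromosomes."""
        return sum(self.counts.values())

    def autosomal_proportions(self) -> dict[str, float]:
        """k_c / n_autosomal for each autosome (NaN-free; requires reads)."""
        n = self.n_autosomal
        if n == 0:
            raise CountTableError(
                f"sample {self.sample_id!r} has no autosomal reads"
            )
        return {c: self.counts[c] / n for c in AUTOSOMES}


@dataclass
class CohortTable:
    """An ordered collection of profiles with unique sample ids."""

    profiles: list[ReadCountProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise CountTableError(f"duplicate sample id(s): {sorted(dupes)}")
        self._index = {p.sample_id: p for p in self.profiles}

    @property
    def protocols(self) -> set[str]:
        return {p.protocol for p in self.profiles}

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[ReadCountProfile]:
        return iter(self.profiles)

    def __getitem__(self, sample_id: str) -> ReadCountProfile:
        return self._index[sample_id]

    def subset(self, sample_ids: Iterable[str]) -> "CohortTable":
        wanted = set(sample_ids)
        return CohortTable([p for p in self.profiles if p.sample_id in wanted])

    def to_frame(self, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row: dict[str, object] = {
                dialect.sample_col: p.sample_id,
                dialect.protocol_col: p.protocol,
            }
            for c in CHROMOSOMES:
                row[dialect.chrom_col(c)] = p.counts[c]
            rows.append(row)
        return pd.DataFrame(rows)


def _resolve_columns(
    columns: Iterable[str], dialect: TableDialect
) -> dict[str, str]:
    """Map each chromosome to the header that holds it (dialect-tolerant)."""
    by_chrom: dict[str, str] = {}
    for col in columns:
        chrom = normalize_chromosome(col)
        if chrom is not None and chrom not in by_chrom:
            by_chrom[chrom] = col
    return by_chrom


def read_count_table(
    path: str | Path, dialect: TableDialect = TableDialect()
) -> CohortTable:
    """Parse a per-sample read-count TSV into a :class:`CohortTable`.

    Raises :class:`CountTableError` naming the offending column for a
    missing header, and the offending row numbers (0-based data rows) for
    unparseable or negative counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (dialect.sample_col, dialect.protocol_col):
        if col not in df.columns:
            raise CountTableError(f"missing required column {col!r} in {path}")
    chrom_cols = _resolve_columns(df.columns, dialect)
    missing = [c for c in CHROMOSOMES if c not in chrom_cols]
    if missing:
        raise CountTableError(
            f"missing chromosome column(s) {missing} in {path}"
        )

    profiles: list[ReadCountProfile] = []
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        counts: dict[str, int] = {}
        ok = True
        for chrom in CHROMOSOMES:
            raw = row[chrom_cols[chrom]]
            try:
                value = int(str(raw).strip())
            except (TypeError, ValueError):
                ok = False
                break
            if value < 0:
                ok = False
                break
            counts[chrom] = value
        if not ok:
            bad_rows.append(int(i))
            continue
        profiles.append(
            ReadCountProfile(
                sample_id=str(row[dialect.sample_col]),
                protocol=str(row[dialect.protocol_col]),
                counts=counts,
            )
        )
    if bad_rows:
        raise CountTableError(
            f"unparseable or negative counts in row(s) {bad_rows} of {path}"
        )
    return CohortTable(profiles)


def write_count_table(
    cohort: CohortTable,
    path: str | Path,
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write a cohort back to the same TSV dialect (round-trip safe)."""
    cohort.to_frame(dialect).to_csv(path, sep="\t", index=False)


def count_reads_from_alignment(
    path: str | Path,
    sample_id: str | None = None,
    protocol: str = "unknown",
    min_len: int = 35,
    min_mapq: int = 25,
) -> tuple[ReadCountProfile, int]:
    """Count primary mapped alignments per chromosome from a SAM/BAM file.

    Alignments are kept when the aligned read is at least ``min_len`` bases
    long (inclusive) and has mapping quality at least ``min_mapq``
    (inclusive). Secondary and supplementary alignments are never counted.
    Returns the profile plus the number of passing alignments that mapped
    to contigs other than the 24 nuclear chromosomes (ignored).
    """
    import pysam

    if sample_id is None:
        sample_id = Path(path).stem
    counts = {c: 0 for c in CHROMOSOMES}
    n_ignored = 0
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            length = read.query_length or read.infer_read_length() or 0
            if length < min_len:
                continue
            chrom = normalize_chromosome(read.reference_name)
            if chrom is None:
                n_ignored += 1
                continue
            counts[chrom] += 1
    profile = ReadCountProfile(sample_id=sample_id, protocol=protocol, counts=counts)
    if profile.n_total == 0:
        warnings.warn(
            f"no alignments in {path} passed the filters "
            f"(min_len={min_len}, min_mapq={min_mapq})",
            stacklevel=2,
        )
    return profile, n_ignored
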