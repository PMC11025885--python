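"""Readers and writers for the external formats the tool touches.

Dialect rules, stated once:

* FASTA — transcript (cDNA) records; only sequence *lengths* are used.
  The transcript ID is the first whitespace-delimited token of the header;
  version suffixes are **not** stripped, so joins against BED files are
  exact-match only.
* BED — tab-separated, 0-based half-open coordinates, exactly as produced
  by ``bedtools bamtobed``.  Three columns are required; column 6 (strand)
  is optional and defaults to ``+``.  Transcript-relative coordinates are
  assumed (no spliced genome features).
* Gene lists — plain text, one transcript ID per line, ``#`` comments.
* Summary / per-bin tables — TSV, numbers at full precision with 4-decimal
  display columns for the two rates.

``.gz`` inputs are transparently decompressed for FASTA, BED and gene
lists.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .regression import DropoffEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptCatalog",
    "ReadAlignment",
    "BedStats",
    "SummaryRow",
    "read_transcript_lengths",
    "read_bed",
    "read_gene_list",
    "write_summary",
    "write_bins",
    "SUMMARY_COLUMNS",
]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass(frozen=True)
class TranscriptCatalog:
    """Transcript IDs with their nucleotide lengths.

    The catalog is the coordinate frame for all binning: a read only
    counts if its transcript is present here and its 3' end falls inside
    the recorded length.
    """

    entries: dict[str, int]

    def __post_init__(self) -> None:
        for tid, length in self.entries.items():
            if length < 1:
                raise ValueError(f"transcript {tid!r} has non-positive length {length}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.entries

    def length(self, transcript_id: str) -> int:
        """Nucleotide length of one transcript."""
        return self.entries[transcript_id]

    def codon_length(self, transcript_id: str) -> int:
        """Length in codons, ``floor(nt / 3)``."""
        return self.entries[transcript_id] // 3

    def ids(self) -> list[str]:
        return list(self.entries)

    def subset(self, ids: Iterable[str]) -> "TranscriptCatalog":
        """Catalog restricted to ``ids`` (silently drops unknown IDs)."""
        keep = {tid: L for tid, L in self.entries.items() if tid in set(ids)}
        return TranscriptCatalog(keep)


class ReadAlignment(NamedTuple):
    """One aligned read interval on a transcript (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class BedStats:
    """Tally of what happened while parsing a BED file."""

    n_lines: int = 0
    n_yielded: int = 0
    n_bad_interval: int = 0


def read_transcript_lengths(fasta_path: str | Path) -> TranscriptCatalog:
    """Build a :class:`TranscriptCatalog` from a transcript FASTA file.

    The ID is the first whitespace-delimited header token; the length is
    the number of sequence characters.  Duplicate IDs and empty sequences
    are hard errors; an empty file yields an empty catalog with a warning.
    """
    entries: dict[str, int] = {}
    with _open_text(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            tid = record.id
            if tid in entries:
                raise ValueError(f"duplicate transcript ID in {fasta_path}: {tid!r}")
            length = len(record.seq)
            if length == 0:
                raise ValueError(f"empty sequence for transcript {tid!r} in {fasta_path}")
            entries[tid] = length
    if not entries:
        warnings.warn(f"no FASTA records found in {fasta_path}", stacklevel=2)
    return TranscriptCatalog(entries)


def read_bed(bed_path: str | Path, stats: BedStats | None = None) -> Iterator[ReadAlignment]:
    """Stream :class:`ReadAlignment` records from a BED3/BED6 file.

    Coordinates are taken verbatim (0-based half-open).  A missing strand
    column defaults to ``+``.  Records with ``start >= end`` are skipped
    and tallied in ``stats.n_bad_interval``; non-integer coordinates are a
    hard error naming the offending line.
    """
    if stats is None:
        stats = BedStats()
    with _open_text(bed_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            stats.n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            if start >= end or start < 0:
                stats.n_bad_interval += 1
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            stats.n_yielded += 1
            yield ReadAlignment(fields[0], start, end, strand)
    if stats.n_bad_interval:
        logger.warning(
            "%s: skipped %d record(s) with invalid intervals", bed_path, stats.n_bad_interval
        )


def read_gene_list(path: str | Path, catalog: TranscriptCatalog | None = None) -> set[str]:
    """Read a plain-text gene list (one ID per line, ``#`` comments).

    Returns the de-duplicated set.  If a catalog is given, IDs absent from
    it are reported (count plus a sample) but retained — the caller decides
    whether that matters.  An empty result is a hard error: a subset
    analysis needs at least one gene.
    """
    ids: set[str] = set()
    with _open_text(path) as handle:
        for line in handle:
            token = line.split("#", 1)[0].strip()
            if token:
                ids.add(token)
    if not ids:
        raise ValueError(f"gene list {path} contains no IDs")
    if catalog is not None:
        missing = sorted(tid for tid in ids if tid not in catalog)
        if missing:
            sample = ", ".join(missing[:5])
            logger.warning(
                "%s: %d ID(s) not in the transcript catalog (e.g. %s)",
                path, len(missing), sample,
            )
    return ids


SUMMARY_COLUMNS = [
    "dataset",
    "subset",
    "bin_size",
    "n_bins_used",
    "r_b",
    "r_c",
    "rmse",
    "r_squared",
    "se",
    "ci_low",
    "ci_high",
    "t_score",
    "p_value",
    "r_b_display",
    "r_c_display",
]


@dataclass
class SummaryRow:
    """One row of the per-dataset / per-subset results table.

    ``estimate`` is ``None`` for subsets where the fit degenerated (too few
    usable bins); those become NA rows with the failure reason.
    """

    dataset: str
    subset: str
    bin_size: int
    estimate: "DropoffEstimate | None"
    reason: str = ""
    extra: dict = field(default_factory=dict)


def _display(x: float) -> str:
    # round-half-even at 4 decimals, matching how the rates are usually printed
    return f"{round(x, 4):.4f}"


def summary_frame(rows: Iterable[SummaryRow]) -> pd.DataFrame:
    """Assemble summary rows into a DataFrame with the canonical columns."""
    rows = list(rows)
    if not rows:
        raise ValueError("no summary rows to write")
    records = []
    for row in rows:
        est = row.estimate
        if est is None:
            rec = dict.fromkeys(SUMMARY_COLUMNS, float("nan"))
            rec.update(dataset=row.dataset, subset=row.subset, bin_size=row.bin_size,
                       r_b_display="NA", r_c_display="NA")
            rec["reason"] = row.reason
        else:
            rec = {
                "dataset": row.dataset,
                "subset": row.subset,
                "bin_size": row.bin_size,
                "n_bins_used": est.n_bins_used,
                "r_b": est.r_b,
                "r_c": est.r_c,
                "rmse": est.rmse,
                "r_squared": est.r_squared,
                "se": est.se,
                "ci_low": est.ci[0],
                "ci_high": est.ci[1],
                "t_score": est.t_score,
                "p_value": est.p_value,
                "r_b_display": _display(est.r_b),
                "r_c_display": _display(est.r_c),
                "reason": row.reason,
            }
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=SUMMARY_COLUMNS + ["reason"])


def write_summary(rows: Iterable[SummaryRow], path: str | Path) -> pd.DataFrame:
    """Write the summary TSV; returns the DataFrame that was written."""
    frame = summary_frame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_bins(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the per-bin export (columns: bin, Y, weight, n_genes, ribo_count, rna_count)."""
    expected = ["bin", "Y", "weight", "n_genes", "ribo_count", "rna_count"]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"per-bin frame is missing columns: {missing}")
    frame.to_csv(path, sep="\t", index=False, columns=expected)
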