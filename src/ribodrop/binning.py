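"""Metagene binning of read 3' ends and construction of the density vector.

Every transcript is divided into consecutive bins of ``l`` nucleotides,
numbered from 1.  For each aligned read we take the strand-aware 3'-end
position and count it into the bin that contains it.  Per-bin counts are
then averaged over the genes that cover the bin — fractionally, for genes
whose last bin is only partially covered — and optionally normalized by
RNA-seq counts binned the same way.  The result is the mean density vector
``Y`` indexed by bin number ``X`` that the exponential drop-off model is
fitted to.

Conventions (fixed here, used everywhere):

* 3' end of a ``+`` read = ``end - 1``; of a ``-`` read = ``start``
  (0-based nucleotide on the transcript).
* bin index ``X = floor(position / l) + 1`` (1-based).
* a gene of length ``L`` contributes ``min(1, max(0, (L - (b-1)*l)/l))``
  genes' worth of coverage to bin ``b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ReadAlignment, TranscriptCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedProfile",
    "DensityVector",
    "three_prime_position",
    "bin_index",
    "coverage_weights",
    "bin_counts",
    "build_density",
]


def three_prime_position(read: ReadAlignment) -> int:
    """0-based transcript position of the read's 3' end."""
    return read.start if read.strand == "-" else read.end - 1


def bin_index(position: int, bin_size_nt: int) -> int:
    """1-based bin number holding a 0-based nucleotide position."""
    if position < 0:
        raise ValueError(f"negative position {position}")
    if bin_size_nt < 1:
        raise ValueError(f"bin size must be >= 1, got {bin_size_nt}")
    return position // bin_size_nt + 1


@dataclass
class BinnedProfile:
    """Per-bin 3'-end counts plus the effective gene coverage of each bin."""

    bin_size_nt: int
    counts: np.ndarray          # shape (N,), bin b stored at index b-1
    coverage: np.ndarray        # effective number of genes covering each bin
    n_genes: int
    n_reads_used: int = 0
    n_reads_skipped: int = 0
    skip_reasons: dict = field(default_factory=dict)
    per_gene: pd.DataFrame | None = None   # columns: transcript_id, bin, count

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.counts.shape != self.coverage.shape:
            raise ValueError("counts and coverage must have identical length")

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class DensityVector:
    """The regression input: mean normalized density per bin.

    ``included`` marks bins usable for the log-linear fit: positive density,
    enough gene support, a valid RNA denominator, and outside any excluded
    leading (ramp) bins.
    """

    X: np.ndarray
    Y: np.ndarray
    weights: np.ndarray
    included: np.ndarray
    bin_size_nt: int

    def __post_init__(self) -> None:
        n = len(self.X)
        if not (len(self.Y) == len(self.weights) == len(self.included) == n):
            raise ValueError("X, Y, weights, included must have identical length")
        if np.any(self.Y[self.included] <= 0):
            raise ValueError("included bins must have positive density")

    @property
    def n_included(self) -> int:
        return int(np.count_nonzero(self.included))


def coverage_weights(
    catalog: TranscriptCatalog,
    subset: Iterable[str] | None,
    bin_size_nt: int,
) -> np.ndarray:
    """Effective per-bin gene coverage for a gene subset.

    Fractional for the last, partially covered bin of each gene; the vector
    runs to the last bin any subset gene reaches.  Coverage is therefore
    non-increasing in the bin number.
    """
    ids = catalog.ids() if subset is None else [t for t in subset if t in catalog]
    if not ids:
        raise ValueError("subset has no genes in common with the catalog")
    lengths = np.array([catalog.length(t) for t in ids], dtype=float)
    l = float(bin_size_nt)
    n_bins = int(np.ceil(lengths.max() / l))
    starts = np.arange(n_bins, dtype=float) * l            # nt start of each bin
    frac = np.clip((lengths[None, :] - starts[:, None]) / l, 0.0, 1.0)
    return frac.sum(axis=1)


def _reads_frame(reads: Iterable[ReadAlignment] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    frame = pd.DataFrame(list(reads), columns=["transcript_id", "start", "end", "strand"])
    return frame


def bin_counts(
    reads: Iterable[ReadAlignment] | pd.DataFrame,
    catalog: TranscriptCatalog,
    bin_size_nt: int,
    subset: Iterable[str] | None = None,
    plus_only: bool = False,
    keep_per_gene: bool = False,
) -> BinnedProfile:
    """Count read 3' ends into bins for the genes of ``subset``.

    Reads are dropped (and tallied, never fatal) when their transcript is
    not in the catalog, not in the subset, on the minus strand with
    ``plus_only``, or when the 3' end lies at or beyond the recorded
    transcript length (soft-clipping artifacts are not clamped into the
    last bin).
    """
    frame = _reads_frame(reads)
    coverage = coverage_weights(catalog, subset, bin_size_nt)
    n_bins = len(coverage)
    subset_ids = set(catalog.ids()) if subset is None else {
        t for t in subset if t in catalog
    }
    n_genes = len(subset_ids)
    skip: dict[str, int] = {"unknown_gene": 0, "outside_subset": 0,
                            "beyond_length": 0, "minus_strand": 0}
    if frame.empty:
        return BinnedProfile(bin_size_nt, np.zeros(n_bins), coverage, n_genes,
                             0, 0, skip,
                             per_gene=pd.DataFrame(columns=["transcript_id", "bin", "count"])
                             if keep_per_gene else None)

    n_total = len(frame)
    known = frame["transcript_id"].isin(catalog.entries.keys()).to_numpy()
    skip["unknown_gene"] = int((~known).sum())
    frame = frame[known]
    if subset is not None:
        in_sub = frame["transcript_id"].isin(subset_ids).to_numpy()
        skip["outside_subset"] = int((~in_sub).sum())
        frame = frame[in_sub]
    strand = frame["strand"].to_numpy()
    if plus_only:
        plus = strand == "+"
        skip["minus_strand"] = int((~plus).sum())
        frame = frame[plus]
        strand = strand[plus]

    pos = np.where(strand == "-", frame["start"].to_numpy(), frame["end"].to_numpy() - 1)
    lengths = frame["transcript_id"].map(catalog.entries).to_numpy()
    inside = pos < lengths
    skip["beyond_length"] = int((~inside).sum())
    pos = pos[inside]

    bins = pos // bin_size_nt           # 0-based bin slot
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    per_gene = None
    if keep_per_gene:
        pg = pd.DataFrame({
            "transcript_id": frame["transcript_id"].to_numpy()[inside],
            "bin": bins + 1,
        })
        per_gene = (pg.groupby(["transcript_id", "bin"], sort=True)
                      .size().rename("count").reset_index())

    n_used = int(inside.sum())
    n_skipped = n_total - n_used
    return BinnedProfile(bin_size_nt, counts, coverage, n_genes,
                         n_used, n_skipped, skip, per_gene=per_gene)


def _per_gene_normalized(ribo: BinnedProfile, rna: BinnedProfile,
                         pseudocount: float) -> np.ndarray:
    """Sum over genes of per-gene ribo/RNA bin ratios (sensitivity mode)."""
    if ribo.per_gene is None or rna.per_gene is None:
        raise ValueError("per_gene normalization requires profiles built with keep_per_gene=True")
    merged = ribo.per_gene.merge(rna.per_gene, on=["transcript_id", "bin"],
                                 how="left", suffixes=("_ribo", "_rna"))
    denom = merged["count_rna"].fillna(0.0) + pseudocount
    ok = denom > 0
    ratios = merged.loc[ok, "count_ribo"] / denom[ok]
    out = np.zeros(ribo.n_bins)
    sums = ratios.groupby(merged.loc[ok, "bin"]).sum()
    out[sums.index.to_numpy() - 1] = sums.to_numpy()
    return out


def build_density(
    ribo: BinnedProfile,
    rna: BinnedProfile | None = None,
    *,
    min_coverage_genes: float = 1.0,
    rna_pseudocount: float = 0.0,
    normalization_mode: str = "aggregate",
    leading_bins_excluded: int = 0,
) -> DensityVector:
    """Assemble the mean normalized density vector from binned profiles.

    Without RNA, the per-bin ribosome count is averaged over the genes
    covering the bin: ``Y[b] = ribo[b] / coverage[b]``.

    With RNA in ``aggregate`` mode (default), *both* the ribosome and the
    RNA bin totals are averaged per covering gene before taking the ratio;
    since the coverage cancels, ``Y[b] = ribo[b] / rna[b]``.  Dividing the
    raw ratio by the coverage once more would count the gene average twice
    — an RNA bin total from uniform coverage is itself proportional to the
    bin's effective gene coverage — and would imprint the coverage decline
    of long-gene bins onto the density as a spurious extra decay.

    ``per_gene`` mode instead forms each gene's own ribo/RNA bin ratio,
    sums over genes and divides by the coverage (a sensitivity mode:
    per-gene ratios are noisy wherever per-gene RNA counts are small).

    Bins whose RNA denominator is zero are excluded, not pseudocounted,
    unless ``rna_pseudocount`` > 0.  Regression weights are the coverage
    rescaled to a maximum of 1: bins supported by more genes weigh more in
    the fit.
    """
    if rna is not None:
        if rna.bin_size_nt != ribo.bin_size_nt:
            raise ValueError("ribo and rna profiles have different bin sizes")
        if rna.n_bins != ribo.n_bins:
            raise ValueError("ribo and rna profiles have different bin counts")

    coverage = ribo.coverage
    n_bins = ribo.n_bins
    rna_valid = np.ones(n_bins, dtype=bool)
    safe_cov = np.where(coverage > 0, coverage, 1.0)
    if rna is None:
        Y = np.where(coverage > 0, ribo.counts / safe_cov, 0.0)
    elif normalization_mode == "aggregate":
        denom = rna.counts + rna_pseudocount
        rna_valid = denom > 0
        # per-covering-gene averages of numerator and denominator: the
        # coverage cancels and the ratio of bin totals remains
        Y = np.zeros(n_bins)
        Y[rna_valid] = ribo.counts[rna_valid] / denom[rna_valid]
    elif normalization_mode == "per_gene":
        normalized = _per_gene_normalized(ribo, rna, rna_pseudocount)
        rna_valid = (rna.counts + rna_pseudocount) > 0
        Y = np.where(coverage > 0, normalized / safe_cov, 0.0)
    else:
        raise ValueError(f"unknown normalization_mode {normalization_mode!r}")
    weights = coverage / coverage.max() if coverage.max() > 0 else coverage.copy()
    X = np.arange(1, n_bins + 1)
    included = (
        (Y > 0)
        & (weights > 0)
        & (coverage >= min_coverage_genes)
        & rna_valid
        & (X > leading_bins_excluded)
    )
    return DensityVector(X=X, Y=Y, weights=weights, included=included,
                         bin_size_nt=ribo.bin_size_nt)


def bins_frame(density: DensityVector, ribo: BinnedProfile,
               rna: BinnedProfile | None = None) -> pd.DataFrame:
    """Per-bin table for export/plotting (see :func:`ribodrop.io.write_bins`)."""
    return pd.DataFrame({
        "bin": density.X,
        "Y": density.Y,
        "weight": density.weights,
        "n_genes": ribo.coverage,
        "ribo_count": ribo.counts,
        "rna_count": rna.counts if rna is not None else np.full(len(density.X), np.nan),
        "included": density.included,
    })
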