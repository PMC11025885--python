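"""Gene-subset definitions and per-subset orchestration.

Drop-off rates can be estimated on any subset of the transcript catalog:
gene-length windows (to test whether processivity depends on CDS length),
externally supplied gene lists (e.g. a GO category exported to a plain
file), single genes, or everything.  Each subset is binned and fitted
independently; a subset whose density cannot support a fit (fewer than
three usable bins — typical for very short genes) degrades to an NA row
instead of aborting the whole partition report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .binning import BinnedProfile, bin_counts, bins_frame, build_density
from .config import RunConfig
from .io import ReadAlignment, SummaryRow, TranscriptCatalog
from .regression import ComparisonResult, DropoffEstimate, fit_dropoff, welch_compare

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetSpec",
    "SubsetResult",
    "partition_by_length",
    "run_subsets",
    "compare_subsets",
    "DEFAULT_LENGTH_BOUNDARIES",
]

DEFAULT_LENGTH_BOUNDARIES = (500, 1000, 2000, 3000, 4000, 5000)


@dataclass(frozen=True)
class SubsetSpec:
    """A named set of transcript IDs with the definition that produced it.

    ``definition`` is one of ``all``, ``length_window(low, high]``,
    ``gene_list(<path>)`` or ``single_gene(<id>)``.
    """

    name: str
    member_ids: frozenset[str]
    definition: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"subset {self.name!r} is empty")

    @classmethod
    def all_genes(cls, catalog: TranscriptCatalog) -> "SubsetSpec":
        return cls("all", frozenset(catalog.ids()), "all")

    @classmethod
    def from_gene_list(cls, name: str, ids: Iterable[str],
                       catalog: TranscriptCatalog) -> "SubsetSpec":
        members = frozenset(t for t in ids if t in catalog)
        if not members:
            raise ValueError(f"gene list {name!r} shares no IDs with the catalog")
        return cls(name, members, f"gene_list({name})")

    @classmethod
    def single_gene(cls, gene_id: str, catalog: TranscriptCatalog) -> "SubsetSpec":
        if gene_id not in catalog:
            raise ValueError(f"gene {gene_id!r} not in the catalog")
        return cls(gene_id, frozenset([gene_id]), f"single_gene({gene_id})")


@dataclass
class SubsetResult:
    """Outcome of one subset's estimation: an estimate or an NA reason."""

    spec: SubsetSpec
    estimate: DropoffEstimate | None
    reason: str = ""
    bins: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return self.estimate is not None


def partition_by_length(
    catalog: TranscriptCatalog,
    boundaries: Sequence[int] = DEFAULT_LENGTH_BOUNDARIES,
) -> list[SubsetSpec]:
    """Partition the catalog into half-open length windows ]low, high].

    Lengths are nucleotides.  The windows are ]0, b1], ]b1, b2], ...,
    ]bk, inf); every gene lands in exactly one window by its length, and
    empty windows are dropped with a warning.
    """
    if len(catalog) == 0:
        raise ValueError("cannot partition an empty catalog")
    bounds = list(boundaries)
    if any(b <= 0 for b in bounds) or bounds != sorted(set(bounds)):
        raise ValueError(f"boundaries must be positive and strictly increasing: {boundaries}")
    edges = [0] + bounds + [None]
    windows: list[SubsetSpec] = []
    for low, high in zip(edges[:-1], edges[1:]):
        if high is None:
            members = [t for t, L in catalog.entries.items() if L > low]
            name = f">{low}"
            definition = f"length_window({low}, inf)"
        else:
            members = [t for t, L in catalog.entries.items() if low < L <= high]
            name = f"]{low},{high}]"
            definition = f"length_window({low}, {high}]"
        if not members:
            logger.warning("length window %s is empty; dropped", name)
            continue
        windows.append(SubsetSpec(name, frozenset(members), definition))
    return windows


def _estimate_one(
    ribo_frame: pd.DataFrame,
    rna_frame: pd.DataFrame | None,
    catalog: TranscriptCatalog,
    spec: SubsetSpec,
    config: RunConfig,
) -> SubsetResult:
    keep_pg = config.normalization_mode == "per_gene" and rna_frame is not None
    ribo = bin_counts(ribo_frame, catalog, config.bin_size, subset=spec.member_ids,
                      plus_only=config.plus_only, keep_per_gene=keep_pg)
    rna: BinnedProfile | None = None
    if rna_frame is not None:
        rna = bin_counts(rna_frame, catalog, config.bin_size, subset=spec.member_ids,
                         plus_only=config.plus_only, keep_per_gene=keep_pg)
    density = build_density(
        ribo, rna,
        min_coverage_genes=config.min_coverage_genes,
        rna_pseudocount=config.rna_pseudocount,
        normalization_mode=config.normalization_mode if rna is not None else "aggregate",
        leading_bins_excluded=config.leading_bins_excluded,
    )
    bins = bins_frame(density, ribo, rna)
    try:
        estimate = fit_dropoff(density, alpha=config.alpha)
    except ValueError as exc:
        logger.warning("subset %s: %s", spec.name, exc)
        return SubsetResult(spec, None, reason=str(exc), bins=bins)
    return SubsetResult(spec, estimate, bins=bins)


def run_subsets(
    reads_ribo: Iterable[ReadAlignment] | pd.DataFrame,
    reads_rna: Iterable[ReadAlignment] | pd.DataFrame | None,
    catalog: TranscriptCatalog,
    subsets: Sequence[SubsetSpec],
    config: RunConfig | None = None,
) -> list[SubsetResult]:
    """Estimate the drop-off rate independently on each subset.

    Reads may be any iterable of alignments or a pre-built DataFrame; they
    are materialised once and re-binned per subset.  Per-subset failures
    become NA results, never exceptions.
    """
    if not subsets:
        raise ValueError("no subsets to run")
    config = config or RunConfig()
    ribo_frame = reads_ribo if isinstance(reads_ribo, pd.DataFrame) else pd.DataFrame(
        list(reads_ribo), columns=["transcript_id", "start", "end", "strand"])
    rna_frame = None
    if reads_rna is not None:
        rna_frame = reads_rna if isinstance(reads_rna, pd.DataFrame) else pd.DataFrame(
            list(reads_rna), columns=["transcript_id", "start", "end", "strand"])
    return [_estimate_one(ribo_frame, rna_frame, catalog, spec, config)
            for spec in subsets]


def results_to_rows(results: Sequence[SubsetResult], dataset: str,
                    bin_size: int) -> list[SummaryRow]:
    """Convert subset results to summary-table rows (NA rows carry reasons)."""
    return [SummaryRow(dataset=dataset, subset=res.spec.name, bin_size=bin_size,
                       estimate=res.estimate, reason=res.reason)
            for res in results]


def compare_subsets(
    estimates: dict[str, DropoffEstimate],
    pairs: Sequence[tuple[str, str]],
    tail: str = "one_sided",
) -> list[tuple[str, str, ComparisonResult]]:
    """Welch comparison for each labelled pair of estimates."""
    out = []
    for a, b in pairs:
        for label in (a, b):
            if label not in estimates:
                raise KeyError(
                    f"unknown label {label!r}; available: {sorted(estimates)}")
        out.append((a, b, welch_compare(estimates[a], estimates[b], tail=tail)))
    return out
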