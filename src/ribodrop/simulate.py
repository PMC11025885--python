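"""Synthetic Ribo-seq / RNA-seq data with a known ground-truth drop-off rate.

The generator emulates the steady-state picture behind the estimator: with
constant elongation speed and asynchronous initiation, the expected
ribosome density at codon j of a transcript is proportional to the
probability that a ribosome's run reaches codon j.  If the per-codon
drop-off probability is r_c, runs are geometric (P(run = k) =
(1-r_c)^(k-1) * r_c, k >= 1), the reach probability is (1-r_c)^(j-1), and
a sequencing snapshot of footprints therefore samples 3'-end codons from
the *truncated geometric* distribution

    P(j) ∝ (1 - r_c)^(j-1),   j = 1 .. L_codons.

(Equivalently: in a snapshot a ribosome is observed with probability
proportional to its residence time, i.e. its run length, and uniformly
along its realised run; the size-bias and the uniform position cancel into
the reach probability.)  r_c = 0 degenerates to uniform coverage.

RNA-seq reads are positionally uniform.  Everything is deterministic under
the spec's seed: the same spec writes byte-identical FASTA/BED files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TranscriptCatalog

__all__ = [
    "FixedLengths",
    "LognormalLengths",
    "LengthClass",
    "SimulationSpec",
    "GroundTruth",
    "simulate_catalog",
    "simulate_footprints",
    "simulate_rna",
    "simulate_dataset",
]


@dataclass(frozen=True)
class FixedLengths:
    """All genes share one nucleotide length."""

    length_nt: int


@dataclass(frozen=True)
class LognormalLengths:
    """Lognormal nucleotide lengths clipped to [min_nt, max_nt].

    ``mean_nt`` and ``sd_nt`` are on the natural (nucleotide) scale; the
    underlying normal parameters are derived from them.
    """

    mean_nt: float
    sd_nt: float
    min_nt: int
    max_nt: int


@dataclass(frozen=True)
class LengthClass:
    """One class of genes: a length model plus its true per-codon rate."""

    name: str
    proportion: float
    lengths: FixedLengths | LognormalLengths
    r_c: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_c < 1:
            raise ValueError(f"true r_c must be in [0, 1), got {self.r_c}")
        if self.proportion <= 0:
            raise ValueError("class proportion must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic dataset.

    ``footprints_per_gene_mean`` is the *library-average* footprint count
    per gene; individual genes receive footprints in proportion to their
    expected total occupancy (equal initiation rates across genes), so at
    equal rates longer genes yield proportionally more footprints.  This
    keeps the per-codon footprint density equal across genes, which is
    exactly the steady-state picture the estimator assumes.  Likewise
    ``rna_reads_per_gene_mean`` is the library average, with per-gene
    means proportional to transcript length (uniform per-nucleotide RNA
    coverage).  The default footprint length of 28 nt is the typical
    yeast monosome footprint — it only shapes the BED intervals, never
    the 3'-end counts.
    """

    n_genes: int
    classes: tuple[LengthClass, ...]
    footprints_per_gene_mean: float = 500.0
    footprint_length_nt: int = 28
    rna_reads_per_gene_mean: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.classes:
            raise ValueError("at least one length class is required")
        for cls in self.classes:
            min_nt = (cls.lengths.length_nt if isinstance(cls.lengths, FixedLengths)
                      else cls.lengths.min_nt)
            if min_nt < self.footprint_length_nt:
                raise ValueError(
                    f"class {cls.name!r}: minimum length {min_nt} nt is shorter "
                    f"than the footprint ({self.footprint_length_nt} nt)")

    @classmethod
    def single(cls, n_genes: int, lengths: FixedLengths | LognormalLengths,
               true_r_c: float, **kwargs) -> "SimulationSpec":
        """Convenience constructor for a one-class simulation."""
        return cls(n_genes=n_genes,
                   classes=(LengthClass("all", 1.0, lengths, true_r_c),),
                   **kwargs)


@dataclass
class GroundTruth:
    """Per-gene truth of a simulation, for parameter-recovery checks."""

    gene_ids: list[str]
    lengths_nt: np.ndarray
    class_names: list[str]
    r_c: np.ndarray
    seed: int
    footprint_counts: np.ndarray | None = None
    rna_counts: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "transcript_id": self.gene_ids,
            "length_nt": self.lengths_nt,
            "class": self.class_names,
            "true_r_c": self.r_c,
        })
        if self.footprint_counts is not None:
            frame["n_footprints"] = self.footprint_counts
        if self.rna_counts is not None:
            frame["n_rna_reads"] = self.rna_counts
        return frame

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible streams per stage
    return np.random.default_rng([stream, seed])


def _draw_lengths(model: FixedLengths | LognormalLengths, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    if isinstance(model, FixedLengths):
        return np.full(n, model.length_nt, dtype=np.int64)
    mean, sd = model.mean_nt, model.sd_nt
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    lengths = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    return np.clip(np.round(lengths), model.min_nt, model.max_nt).astype(np.int64)


def simulate_catalog(
    spec: SimulationSpec,
    fasta_path: str | Path | None = None,
) -> tuple[TranscriptCatalog, GroundTruth]:
    """Draw the gene catalog (IDs, classes, lengths) and optionally write FASTA.

    Sequence content is uniform random A/C/G/T — the estimator is
    sequence-agnostic, only lengths matter.
    """
    rng = _rng(spec.seed, stream=1)
    props = np.array([c.proportion for c in spec.classes], dtype=float)
    props /= props.sum()
    # deterministic class sizes (largest-remainder), genes then shuffled by ID order
    sizes = np.floor(props * spec.n_genes).astype(int)
    for i in np.argsort(-(props * spec.n_genes - sizes))[: spec.n_genes - sizes.sum()]:
        sizes[i] += 1
    gene_ids, lengths, class_names, r_cs = [], [], [], []
    counter = 0
    for cls, size in zip(spec.classes, sizes):
        L = _draw_lengths(cls.lengths, size, rng)
        for j in range(size):
            gene_ids.append(f"g{counter:05d}")
            counter += 1
        lengths.append(L)
        class_names.extend([cls.name] * size)
        r_cs.extend([cls.r_c] * size)
    lengths = np.concatenate(lengths) if lengths else np.array([], dtype=np.int64)
    truth = GroundTruth(gene_ids=gene_ids, lengths_nt=lengths,
                        class_names=class_names, r_c=np.array(r_cs), seed=spec.seed)
    catalog = TranscriptCatalog(dict(zip(gene_ids, (int(x) for x in lengths))))
    if fasta_path is not None:
        bases = np.array(list("ACGT"))
        with open(fasta_path, "w") as out:
            for tid, L in zip(gene_ids, lengths):
                seq = "".join(bases[rng.integers(0, 4, size=int(L))])
                out.write(f">{tid}\n")
                for i in range(0, len(seq), 60):
                    out.write(seq[i:i + 60] + "\n")
    return catalog, truth


def _truncated_geometric(r_c: np.ndarray, l_codons: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Sample codons j in 1..L with P(j) proportional to (1-r_c)^(j-1).

    Inverse-CDF per footprint; r_c = 0 falls back to a uniform draw.
    """
    u = rng.random(len(r_c))
    j = np.empty(len(r_c), dtype=np.int64)
    zero = r_c == 0
    j[zero] = np.floor(u[zero] * l_codons[zero]).astype(np.int64) + 1
    nz = ~zero
    if nz.any():
        log_q = np.log1p(-r_c[nz])
        # CDF(j) = (1 - q^j) / (1 - q^L); invert at u
        tail = -np.expm1(l_codons[nz] * log_q)        # 1 - q^L
        j[nz] = np.floor(np.log1p(-u[nz] * tail) / log_q).astype(np.int64) + 1
    return np.minimum(j, l_codons)


def _bed_frame(ids: np.ndarray, starts: np.ndarray, ends: np.ndarray,
               prefix: str) -> pd.DataFrame:
    n = len(ids)
    return pd.DataFrame({
        "transcript_id": ids,
        "start": starts,
        "end": ends,
        "name": [f"{prefix}{i}" for i in range(n)],
        "score": np.zeros(n, dtype=np.int64),
        "strand": ["+"] * n,
    })


def _write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False)


def simulate_footprints(
    spec: SimulationSpec,
    catalog: TranscriptCatalog,
    truth: GroundTruth,
    bed_path: str | Path | None = None,
) -> pd.DataFrame:
    """Draw Ribo-seq footprints whose 3'-end codons follow the decay law.

    Per gene the footprint count is Poisson with mean proportional to the
    gene's expected total occupancy Z_g = sum_{j<=L_c} (1-r_c)^(j-1)
    (scaled so the library average equals ``footprints_per_gene_mean``);
    each footprint's 3'-end codon j is truncated-geometric as derived in
    the module docstring.  Jointly this makes the codon-level counts
    independent Poisson with mean proportional to (1-r_c)^(j-1), the same
    amplitude for every gene.  The 3' nucleotide is the last base of codon
    j (0-based position 3j - 1), so the BED interval is
    [3j - footprint_length, 3j), clipped at 0, on the ``+`` strand.
    Updates ``truth.footprint_counts`` and optionally writes a 6-column
    BED.
    """
    rng = _rng(spec.seed, stream=2)
    n_genes = len(truth.gene_ids)
    l_cod = truth.lengths_nt // 3
    with np.errstate(divide="ignore", invalid="ignore"):
        occupancy = np.where(
            truth.r_c > 0,
            -np.expm1(l_cod * np.log1p(-truth.r_c)) / np.where(truth.r_c > 0, truth.r_c, 1.0),
            l_cod.astype(float),
        )
    lam = spec.footprints_per_gene_mean * occupancy / occupancy.mean()
    counts = rng.poisson(lam, size=n_genes)
    truth.footprint_counts = counts
    gene_idx = np.repeat(np.arange(n_genes), counts)
    l_codons = (truth.lengths_nt // 3)[gene_idx]
    r_c = truth.r_c[gene_idx]
    j = _truncated_geometric(r_c, l_codons, rng)
    three_prime = 3 * j - 1                       # 0-based nt of the 3' end
    ends = three_prime + 1
    starts = np.maximum(0, ends - spec.footprint_length_nt)
    ids = np.array(truth.gene_ids, dtype=object)[gene_idx]
    frame = _bed_frame(ids, starts, ends, "fp")
    if bed_path is not None:
        _write_bed(frame, bed_path)
    return frame


def simulate_rna(
    spec: SimulationSpec,
    catalog: TranscriptCatalog,
    truth: GroundTruth,
    bed_path: str | Path | None = None,
) -> pd.DataFrame:
    """Draw RNA-seq reads with positionally uniform 3' ends over [0, L).

    Per-gene read counts are Poisson with mean proportional to transcript
    length (library average = ``rna_reads_per_gene_mean``), i.e. uniform
    per-nucleotide RNA coverage across genes, as fragment counting of
    equally abundant transcripts produces.
    """
    rng = _rng(spec.seed, stream=3)
    n_genes = len(truth.gene_ids)
    lam = (spec.rna_reads_per_gene_mean
           * truth.lengths_nt / truth.lengths_nt.mean())
    counts = rng.poisson(lam, size=n_genes)
    truth.rna_counts = counts
    gene_idx = np.repeat(np.arange(n_genes), counts)
    lengths = truth.lengths_nt[gene_idx]
    three_prime = np.floor(rng.random(len(gene_idx)) * lengths).astype(np.int64)
    ends = three_prime + 1
    starts = np.maximum(0, ends - spec.footprint_length_nt)
    ids = np.array(truth.gene_ids, dtype=object)[gene_idx]
    frame = _bed_frame(ids, starts, ends, "rna")
    if bed_path is not None:
        _write_bed(frame, bed_path)
    return frame


def simulate_dataset(
    spec: SimulationSpec,
    out_dir: str | Path | None = None,
    with_rna: bool = True,
) -> tuple[TranscriptCatalog, GroundTruth, pd.DataFrame, pd.DataFrame | None]:
    """One-call generation of catalog + footprints (+ RNA), optionally on disk.

    With ``out_dir`` set, writes ``transcripts.fa``, ``ribo.bed``,
    ``rna.bed`` and ``truth.tsv`` there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    catalog, truth = simulate_catalog(spec, out / "transcripts.fa" if out else None)
    ribo = simulate_footprints(spec, catalog, truth, out / "ribo.bed" if out else None)
    rna = None
    if with_rna:
        rna = simulate_rna(spec, catalog, truth, out / "rna.bed" if out else None)
    if out is not None:
        truth.write(out / "truth.tsv")
    return catalog, truth, ribo, rna
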