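"""Run configuration shared by the library orchestration and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All knobs of an estimation run, with their defaults.

    ``bin_size`` is in nucleotides (default 50, the reference setting for
    whole-transcriptome runs); ``alpha`` is the confidence/test level;
    ``leading_bins_excluded`` optionally drops the first bins (the ramp
    region near the start codon) from the regression.
    """

    bin_size: int = 50
    alpha: float = 0.05
    normalization_mode: str = "aggregate"   # or "per_gene"
    rna_pseudocount: float = 0.0
    min_coverage_genes: float = 1.0
    leading_bins_excluded: int = 0
    plus_only: bool = False
    welch_tail: str = "one_sided"
    seed: int = 0
    output_prefix: str = "ribodrop"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size < 3:
            raise ValueError(f"bin_size must be >= 3 nt, got {self.bin_size}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)} - {"extra"}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def describe(self) -> str:
        return ", ".join(f"{f.name}={getattr(self, f.name)!r}"
                         for f in fields(self) if f.name != "extra")
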