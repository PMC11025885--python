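# Methods

## Model and assumptions

A ribosome initiating on a CDS either completes elongation or detaches
prematurely. With a constant per-codon detachment probability `r_c`, the
number of codons a ribosome traverses is geometric,
`P(run = k) = (1 − r_c)^(k−1) · r_c`, and the probability of reaching
codon `j` is `(1 − r_c)^(j−1)`. Under asynchronous initiation at a
steady rate and roughly constant elongation speed, the expected ribosome
density at codon `j` is proportional to that reach probability, so the
mean footprint density decays exponentially along the CDS. Averaged over
genes in bins of `l` nucleotides, this gives the working model
`Y = A · exp(−r_b · X)` with `X` the 1-based bin number; the per-bin and
per-codon rates are linked by `r_b = 1 − (1 − r_c)^(l_c)` with
`l_c = l/3` codons per bin.

The estimator assumes: (i) drop-off is homogeneous along the CDS within
the analysed gene set (no position dependence beyond the exponential);
(ii) per-codon footprint amplitude is exchangeable across genes, so the
coverage average is meaningful; (iii) the elevated density near the start
codon (the "ramp") either is negligible at the bin scale or is removed
with `leading_bins_excluded`.

## Binning conventions

* 3′ end of a `+` read = `end − 1`; of a `−` read = `start` (0-based,
  half-open BED as `bedtools bamtobed` writes it). Transcript-space
  alignments are normally `+`; a `plus_only` switch discards `−` reads.
* Bin index `X = floor(position / l) + 1`.
* Effective gene coverage of bin `b`: each gene of length `L` contributes
  `min(1, max(0, (L − (b−1)·l)/l))`, so a gene's final, partially covered
  bin counts fractionally. Coverage is non-increasing in `b` and doubles
  as the regression weight (rescaled to max 1): bins supported by more
  genes are trusted more.
* Reads whose 3′ end lies at or beyond the recorded transcript length are
  tallied and skipped, not clamped (they are soft-clipping or annotation
  artifacts, and clamping would inflate the last bin).

## RNA-seq normalization

With matched RNA-seq, each bin's ribosome count is normalized by the RNA
count in the same bin to cancel transcript-abundance and library effects.
Two modes exist:

* `aggregate` (default): numerator and denominator are both understood as
  per-covering-gene averages of the subset totals; since the same
  effective coverage divides both, it cancels and
  `Y[b] = ribo[b] / rna[b]`. Dividing this ratio by the coverage again
  would count the gene average twice — an RNA bin total under uniform
  per-nucleotide coverage is itself proportional to the bin's effective
  gene coverage — and would imprint the coverage decline of long-gene
  bins onto `Y` as a spurious extra decay.
* `per_gene`: each gene's own ribo/RNA bin ratio is formed, summed over
  genes, and divided by the coverage. This follows the "normalize, then
  average per covering gene" reading literally but is noisy wherever
  per-gene RNA counts are small; it is provided as a sensitivity check.

Bins with zero RNA are excluded from the fit rather than pseudocounted
(`rna_pseudocount`, default 0, can override): a density with an
unobserved denominator is not evidence.

## Regression and inference

`fit_dropoff` performs weighted least squares of `ln Y` on `X` over the
included bins (positive density, coverage at least `min_coverage_genes`,
valid RNA denominator, past any excluded leading bins) and reports
`r_b = −slope`. All statistics use the same `N` = number of included
bins:

* `S_E` = sqrt(weighted RSS / (N−2)) / sqrt(weighted Σ(x−x̄_w)²); with
  equal weights this is exactly the classical simple-regression slope SE.
  The overall weight scale cancels, so weights matter only relatively.
* CI: `r_b ± t_{α/2, N−2} · S_E` (default α = 0.05).
* Slope test: `t = r_b / S_E`, one-sided upper-tail p on N−2 df
  (alternative: positive drop-off).
* RMSE is the unweighted root mean square of the log-scale residuals —
  the regression's own scale; `R²` uses the regression weights.
* A flat density returns `r_b = 0`, `p = 0.5` with a `degenerate` flag
  instead of failing; an exact fit with nonzero slope reports `p = 0`
  and the same flag. A fitted decay steeper than one event per bin
  (`r_b ≥ 1`) leaves the probability model's domain: the per-bin rate is
  reported, `r_c` is NaN.

`welch_compare` refers `t = (r_b1 − r_b2)/√(SE₁² + SE₂²)` to a standard
normal: the per-dataset bin counts are in the hundreds, where Student-t
and normal agree to the third decimal, and a Welch–Satterthwaite df would
require per-group sizes that add nothing at that scale. The default tail
is `one_sided`, defined as `P(Z ≥ |t|)` — the convention under which the
published comparison values of this method's reference analyses are
reproduced; `two_sided` doubles it and is the calibrated choice for
null-hypothesis error control (under the null, `P(Z ≥ |t|) < α` occurs
with probability 2α).

`survival_probability` evaluates `(1 − r_c)^L` exactly or `exp(−r_c·L)`
in the small-rate limit; the two agree within `r_c²·L`.

## Synthetic data generator

`simulate_dataset` produces FASTA + BED fixtures with known truth:

* **Catalog**: gene lengths fixed, lognormal (clipped), or a mixture of
  classes each with its own length model and true `r_c`. Sequence content
  is uniform random — the estimator only uses lengths.
* **Footprints**: the 3′-end codon of each footprint is drawn from the
  truncated geometric `P(j) ∝ (1 − r_c)^(j−1)`, `j = 1..L_c` — the
  snapshot distribution of ribosome positions (a ribosome is observed
  with probability proportional to its residence time, i.e. its run
  length, uniformly along its realised run; size-bias and uniform
  position cancel into the reach probability). Per-gene footprint totals
  are Poisson with mean proportional to the gene's expected occupancy
  `Σ_j (1−r_c)^(j−1)`, scaled so the library average per gene equals
  `footprints_per_gene_mean`. Jointly the codon-level counts are
  independent Poisson with a gene-independent amplitude, which is what
  equal initiation rates give at steady state; forcing equal totals per
  gene instead would make short genes artificially dense per codon and
  bend the coverage-averaged profile away from the exponential.
* **RNA-seq**: 3′ ends uniform over the transcript; per-gene totals
  Poisson with mean proportional to length (uniform per-nucleotide
  coverage, as fragment counting of equally abundant transcripts gives).
* The 3′ nucleotide of codon `j` is `3j − 1` (0-based) and the BED
  interval is `[3j − 28, 3j)` clipped at zero — the default 28 nt is a
  typical yeast monosome footprint and only shapes the intervals, never
  the 3′-end counts. Everything is reproducible: one integer seed feeds
  separate catalog/footprint/RNA streams, and reruns are byte-identical.

What the generator does **not** emulate: expression variation between
genes, the start-codon ramp, codon-specific dwell times, ribosome
collisions, sequence or ligation biases, and nucleotide-level scatter of
digestion around the codon boundary. Passing recovery tests therefore
show the estimator is correct *under its own model*, not that real
libraries satisfy that model.

### Codon-grid quantization

Because simulated 3′ ends sit exactly on the codon grid, a bin size that
is not a multiple of 3 holds alternately ⌈l/3⌉ and ⌊l/3⌋ codon slots
(16/17 for l = 50), which superimposes a sawtooth on `ln Y`. The sawtooth
is nearly orthogonal to the linear trend — rate estimates and bin-size
invariance are essentially unaffected (measured spread across bins
25/50/100 is ~0.3%) — but it inflates the residual variance and hence the
slope SE, making CIs conservative. Real libraries spread 3′ ends over
nucleotide offsets and do not show this artifact. Calibration analyses on
synthetic data (type-I error of the Welch comparison) therefore use a
codon-aligned bin size of 48 nt, where the statistic is correctly
calibrated (|t| sd ≈ 0.99).

### Pooling across length classes

In a mixture of length classes with different rates, the pooled
coverage-averaged profile follows the density-weighted average of the
class rates only while several classes cover the bins. Once the short
class's coverage ends, its accumulated extra log-drop is exactly
cancelled by the upward composition step of the coverage average, and the
pooled profile thereafter follows the surviving class's line; a straight
fit across the transition can land outside the class-rate range. The
pooled "combination of length-dependent rates" is therefore evaluated on
the common support — via `min_coverage_genes` set so only bins covered by
all classes enter the fit — where the pooled estimate falls strictly
between the class rates. For the same reason, per-length-window analyses
are the reliable way to resolve length dependence in real data, and the
long-gene tail of a pooled profile (few covering genes) should be viewed
with suspicion or trimmed with `min_coverage_genes`.

## Defaults and problem sizes

| parameter | default | meaning |
|---|---|---|
| `bin_size` | 50 nt | reference setting for whole-transcriptome runs |
| `alpha` | 0.05 | CI level and test size |
| `min_coverage_genes` | 1 | any covered bin is eligible |
| `rna_pseudocount` | 0 | zero-RNA bins are excluded, not imputed |
| `normalization_mode` | `aggregate` | see above |
| `leading_bins_excluded` | 0 | no ramp trimming |
| `welch_tail` | `one_sided` | reporting convention; `two_sided` for calibration |
| `footprint_length_nt` | 28 | BED interval shaping only |

The simulation-based validation in the test suite uses 2000 genes with
lognormal lengths (mean 1350 nt, sd 800, clipped to [300, 8000] —
a realistic budding-yeast-like CDS distribution) and ~10⁶ footprints for
parameter recovery (50 replicates, CI coverage ≥ 90%, relative error
< 15%), 300 fixed-length genes × 2 × 200 replicates for type-I
calibration, and a two-class mixture (1200 nt at 2×10⁻³ vs 3600 nt at
2×10⁻⁴ per codon) for the length-dependence checks.

## Known limitations

* No P-site offsetting: the method is defined on raw 3′ ends; rates are
  insensitive to a constant offset, but codon-resolution questions are
  out of scope.
* The start-codon ramp is not modelled, only optionally excluded.
* `R²` on real data is expected to be modest; the exponential is a
  first-order description and the test only asks whether the slope is
  nonzero.
* No multiple-testing correction across subsets; callers comparing many
  windows or gene lists should correct externally.
* Genome-coordinate BED files with spliced features are not supported;
  alignments must be transcript-relative.
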