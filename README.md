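# ribodrop

Estimation of the **ribosome drop-off rate** — the per-codon probability
that a translating ribosome detaches from the mRNA before reaching the
stop codon — from ribosome-profiling (Ribo-seq) alignments.

Ribosome drop-off limits translational processivity: even a small
per-codon rate compounds over a long coding sequence, so the fraction of
initiating ribosomes that finish a protein falls with CDS length. The
package quantifies this from standard Ribo-seq data, optionally normalized
by matched RNA-seq, and is aimed at anyone studying translation dynamics,
protein output, or stress effects on elongation.

## The model

Transcripts are divided into bins of *l* nucleotides. Footprint 3′ ends
are counted per bin and averaged over the genes covering each bin
(fractionally for partially covered last bins), giving a mean density
*Y* per bin number *X* = 1…*N*. At steady state, constant drop-off makes
the density decay exponentially:

```
Y = A · exp(−r_b · X)
```

A weighted log-linear regression of ln *Y* on *X* (weights = per-bin
effective gene coverage) estimates the per-bin rate *r_b*; the per-codon
rate follows from the complement rule with *l_c* = *l*/3 codons per bin:

```
r_c = 1 − (1 − r_b)^(1/l_c)
```

The fit carries a full inferential suite: the slope standard error
*S_E* (classical simple-regression formula, weighted analog), the margin
of error *M_E* = *t*<sub>α/2</sub>·*S_E* and 95% CI on *N*−2 degrees of
freedom, a one-sided *t*-test of *r_b* > 0, log-scale RMSE and weighted
*R*², Welch's test *t* = (*r_b₁* − *r_b₂*)/√(SE₁² + SE₂²) for comparing
conditions, and the survival probability *P_S* = (1 − *r_c*)^*L* that a
ribosome completes an *L*-codon CDS.

## Worked example

A synthetic dataset with a known truth of *r_c* = 4×10⁻⁴ per codon
(1000 genes, lognormal lengths, ~5×10⁵ footprints, matched RNA-seq):

```python
import ribodrop as rd

spec = rd.SimulationSpec.single(
    n_genes=1000,
    lengths=rd.LognormalLengths(mean_nt=1350, sd_nt=800, min_nt=300, max_nt=8000),
    true_r_c=4e-4,
    footprints_per_gene_mean=500,
    rna_reads_per_gene_mean=500,
    seed=42,
)
catalog, truth, ribo, rna = rd.simulate_dataset(spec)

ribo_prof = rd.bin_counts(ribo, catalog, bin_size_nt=50)
rna_prof = rd.bin_counts(rna, catalog, bin_size_nt=50)
density = rd.build_density(ribo_prof, rna_prof)
est = rd.fit_dropoff(density)

print(f"r_b = {est.r_b:.4f}  (per 50 nt bin)")
print(f"r_c = {est.r_c:.2e}  (per codon; truth 4.0e-04)")
print(f"95% CI for r_b: [{est.ci[0]:.4f}, {est.ci[1]:.4f}]")
print(f"t = {est.t_score:.1f}, one-sided p = {est.p_value:.2e}")
print(f"RMSE = {est.rmse:.3f}, R^2 = {est.r_squared:.3f}, bins used = {est.n_bins_used}")
print(f"P(reach stop codon | 450-codon CDS) = {rd.survival_probability(est.r_c, 450):.3f}")
```

prints

```
r_b = 0.0065  (per 50 nt bin)
r_c = 3.93e-04  (per codon; truth 4.0e-04)
95% CI for r_b: [0.0061, 0.0069]
t = 31.7, one-sided p = 2.11e-60
RMSE = 0.170, R^2 = 0.893, bins used = 122
P(reach stop codon | 450-codon CDS) = 0.838
```

The fitted per-codon rate lands within 2% of the simulated truth and the
CI covers it; the strongly positive *t* says the decay is real, and the
survival probability shows what such a rate means for a long CDS: about
16% of initiating ribosomes never finish a 450-codon protein.

The same analysis from the shell:

```sh
ribodrop simulate --out-dir sim --n-genes 1000 --true-r-c 4e-4 \
    --length-nt 1500 --footprints-per-gene 500 --seed 42
ribodrop estimate -t sim/transcripts.fa -r sim/ribo.bed --rna sim/rna.bed \
    -o run --dataset sim
ribodrop windows -t sim/transcripts.fa -r sim/ribo.bed -o win   # per length window
ribodrop compare runA.summary.tsv runB.summary.tsv               # Welch test
```

`estimate` writes a summary TSV (one row per subset: *r_b*, *r_c*, SE,
CI, *t*, *p*, RMSE, *R*²) and a per-bin TSV (bin, *Y*, weight, coverage,
raw counts) for plotting. Subset analyses (`-s` gene lists, `--gene`
single genes, `windows` length partitions) run the identical pipeline per
subset and degrade to NA rows where a subset cannot support a fit.

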