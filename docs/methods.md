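# Methods

## Generative model

The synthetic-data generator is the package's test surface: every
downstream claim is checked against data whose ground truth is known.

Each gene g carries, per condition, a synthesis rate κ_g > 0, a degradation
rate δ_g > 0 and a pausing fraction π_g ∈ (0, 1) — the fraction of nascent
signal falling in the TSS window. At steady state the mature-RNA abundance
is κ/δ; nascent signal is proportional to κ. For sample j with depth scalar
d_j and capture efficiency c_j, expected counts are

    TT arm:   TSS ~ NB(d_j c_j κ_g π_g, α),  body ~ NB(d_j c_j κ_g (1-π_g), α)
    RNA arm:  gene ~ NB(d_j c_j κ_g / δ_g, α)
    spikes:   species i ~ NB(d_j c_j a_i, α_spike)

with the NB parameterized as Var = μ + αμ² (α = 0 falls back to Poisson).
The same factor d_j c_j scales genes and spike-ins — that identity is the
assumption spike-in normalization exploits, and it is what makes the
neutrality checks exact on expected counts.

Effect classes are disjoint random gene subsets. Between conditions the
transcription class multiplies κ by a fold, the stability class multiplies
δ, and the pausing class multiplies the *odds* π/(1−π) — the odds scale
keeps π inside (0, 1) for any positive fold.

Defaults describe a scaled two-condition, three-replicate design: 2000
genes of 1–20 kb, ~10⁶ gene-derived fragments per sample at capture 1,
α = 0.05, capture efficiencies uniform in (0.5, 2), 10% of genes per effect
class with 2-fold effects. The base rates (κ lognormal with median 10,
δ lognormal with median 1, π uniform in (0.1, 0.5)) are generator choices
giving realistic skewed count distributions; analyses in this repository
use smaller gene counts and depths where noted, purely as problem sizes.

### Spike-in noise

Spike counts use a separate dispersion α_spike (default 0.005) rather than
the genes' α. Spike material is purified exogenous RNA (a foreign whole
transcriptome for the steady-state arm, modelled as 20 species; in vitro
transcripts — three of six 4sU-labeled — for the nascent arm): it shares
each sample's capture/pipetting factor c_j, which the size factors are
meant to absorb, but not the biological replicate-to-replicate variance of
the genes. Giving spikes biological-scale dispersion would inject a noise
component *shared across all genes of a sample* into the size factors;
per-gene dispersion estimates then absorb it as if it were independent
noise, and the Wald tests become markedly over-conservative. With
technical-scale spike noise the tests are calibrated (see below).

### Fragments

Fragment intervals (default 150 bp, configurable) realise the count draws:
placed uniformly *inside* the generating window, so quantifying them
reproduces the count matrices exactly. Optional extras with recorded true
categories: boundary "straddlers" (overlapping TSS window and body — these
must be discarded by the counter) and intergenic fragments (must hit no
gene). There is no sequence content and no read-level error model; passing
tests say nothing about alignment or library artefacts in real data.

## Regions and counting

Coordinates are 0-based half-open. For a + strand gene [s, e) the TSS base
is s, the TSS window [s−250, s+251) (501 bp) and the body [s+251, e); the −
strand case mirrors this at e−1. The 501 bp reading is adopted because the
body starts at the +251st base, making the windows exactly adjacent.
Windows may extend beyond the gene upstream of the TSS; windows reaching
below coordinate 0 are clipped at 0 with a logged warning. Genes shorter
than 500 bp (strictly) are dropped before quantification; the ChIP-style
variant of the same filter uses 2 kb.

Overlap is ≥ 1 bp against the half-open windows; no minimum-overlap
fraction. The default strand mode is `same` (directional libraries);
`opposite` and `ignore` are available because upstream protocols differ. A
fragment overlapping windows of two genes counts for both — overlapping
genes are permitted and no ambiguity resolution is attempted. Counts are
fragment counts, not coverage; "signal" everywhere means size-factor-
normalized counts, without width normalization by default (a flag enables
width normalization for the stalling index).

## Normalization and filtering

RNA-arm raw factor: total spike count per sample. TT-arm raw factor:
median over labeled species of the per-species count (per-species counts,
not per-base coverage; the median is over the labeled set only). Factors
are divided by their geometric mean so normalized counts stay counts-like;
the anchoring is a convention — only ratios between samples matter.

The low-count filter acts on raw counts before normalization or testing: a
gene is removed iff some condition has every replicate strictly below 5
reads. The filter is monotone in the threshold.

## Differential testing

DESeq2-style GLM fitting (Cox–Reid dispersions, LFC shrinkage) is
deliberately replaced by a transparent moment-based NB Wald test with a
documented, testable contract: calibration and effect recovery, not
equality with any external tool's output.

Per-gene dispersions are method-of-moments, α̂ = (v − m)/m² on normalized
counts within each condition, averaged across conditions and floored at
1e-8. At n = 3 these have so few degrees of freedom that plugging them into
a normal-reference Wald statistic inflates the type-I error about 2.5-fold.
The testing path therefore *moderates* them: genes are grouped into 10
quantile bins of base mean and each gene receives its bin's average α̂
(a common/trended dispersion). Under dispersion heterogeneity within a bin
this under/over-corrects individual genes — a known limitation shared with
common-dispersion approaches; median-based recovery statistics are
insensitive to it.

The Wald variance is Var(ln μ̂_c) ≈ 1/(n_c μ̂_c s̄_c) + α/n_c per condition
(Poisson part evaluated on the raw scale through the mean size factor s̄_c,
overdispersion part α/n), converted to log2. Genes with a zero mean in
either condition get ±inf log2FC, are flagged untested, and excluded from
BH. BH is the standard step-up with monotonicity enforcement; calls use
|log2FC| ≥ 1 and adjusted p < 0.05 (both thresholds configurable).

The stalling index uses pseudocount 1 on normalized means in numerator and
denominator (zero handling; the choice is visible only for near-empty
genes). dSI combines four delta-method variance terms (TSS/body ×
ref/alt), each with its own moderated dispersion, evaluated at the
pseudocount-shifted means. The stability shift joins the two arms on gene
id (inner join; genes absent from either arm are dropped, not imputed).
Swapping ref and alt negates log2FC, dSI and Δ and leaves p-values
unchanged.

Measured behaviour (recomputed by `scripts/acceptance.py` and the test
suite): under a null simulation (2000 genes, 3v3, α = 0.05) the empirical
type-I error of the expression and stalling tests at nominal 0.05 falls in
[0.03, 0.07]; with 2-fold effects on 10% of 500 genes the recovery medians
land within ±0.2 of the generating log2 effects.

## Binding

The 1:1 isotherm is the exact quadratic root, not the hyperbola: with the
ligand at 90 nM and the tightest affinities below a micromolar, ligand
depletion shifts the curve by more than the fitting noise. Fits use
nonlinear least squares over (K_d, r_free, r_bound) with r_free/r_bound
initialised at the observed extremes and K_d at the half-range protein
concentration, with bounded multiplicative restarts on non-convergence.
Flat series are flagged non-identifiable and report no K_d; decreasing
series converge but carry a warning flag. Each replicate dilution series is
fit separately and K_d is reported as mean ± sd across replicates (the
convention for independent experiments), with a pooled fit for comparison.
Concentrations are converted to µM internally; K_d is reported in µM.

The %input computation adjusts the input Cq for the reserved chromatin
fraction (an explicit parameter, typically 5–10%) before the exponential
readout; each additional ChIP cycle halves the result exactly.

## Problem sizes and determinism

Every generator takes an explicit seed and uses independent RNG streams
per stage, so composing stages never perturbs earlier draws (fragments
reproduce the count draws bit-for-bit). The analysis scripts use 200-gene
designs; the calibration and recovery checks use 2000 and 500 genes — sizes
chosen so each stage's statistical claim is testable with stable medians.
The acceptance script derives all of its randomness from the single
`--seed` argument.

## Known limitations

- No read-level simulation (no sequences, no alignment, no multimapping),
  no isoforms, one TSS per gene.
- The moderated-dispersion Wald test assumes dispersion varies smoothly
  with expression; strong per-gene dispersion outliers are not shrunk
  individually.
- Stability inference is the difference of two log fold changes; it
  inherits both arms' biases and is only interpretable for genes tested in
  both.
- Binding fits assume a single binding site and no instrument corrections;
  ± values from replicate scatter do not capture systematic concentration
  errors.
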