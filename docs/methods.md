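# Methods

## Model and assumptions

The co-oscillation model assumes an unsynchronized but homogeneous
population: every cell s carries a latent circular phase θ_s ∈ [0, 2π),
drawn independently and uniformly, and an oscillatory gene g in group k
has pre-noise expression

    baseline + amplitude · sin(f_k · θ_s + φ_g),

i.e. genes within a group share a frequency (relative to the latent
cycle) and differ only in phase. The phase is a *circular* latent
variable, not an ordering — the pair statistic never uses cell order,
which is what makes the approach applicable to snapshot scRNA-seq.
Because absolute time is unobserved, the method cannot estimate the
period of the transcriptional cycle; it only identifies which genes
share one. Period estimation in hours is the job of the live-imaging
module, where real time stamps exist.

After linear rescaling of each gene to [−1, 1], a co-oscillating pair
(x, y) with phase shift ψ satisfies x² + y² − 2xy·cos ψ − sin²ψ = 0 in
every cell. The statistic ε is the mean squared violation of that
identity minimized over ψ ∈ [0, π]; restricting to [0, π] is exact
because the objective depends on ψ only through cos ψ.

### Numerical treatment of the ψ-minimization

With c = cos ψ and per-cell quantities b_s = x_s y_s,
d_s = x_s² + y_s² − 1, the summed squared residual is the quartic

    q(c) = S c⁴ − 4(Σb) c³ + (2Σd + 4Σb²) c² − 4(Σdb) c + Σd².

The five coefficients are cell-wise moments, so for the all-pairs scan
they come out of a handful of G × G matrix products and the per-cell
data are never touched again. q is evaluated on a 1000-point uniform ψ
grid (configurable) and the bracketing interval of the best grid point
is refined by ternary search to ~10⁻¹⁰ in ψ; a 10⁶-point brute-force
grid oracle agrees to better than 10⁻⁶ relative in the test suite.
Perfect fits can round to ε ≈ −10⁻¹⁶, so ε is clamped at 0. Constant
gene vectors cannot be rescaled and are rejected; the variance filter
removes them upstream.

## Significance

The null distribution of ε is obtained by permutation: a draw picks two
distinct genes and independently permutes each one's values across
cells, which destroys cross-cell alignment while preserving marginals.
The null is *pooled* across pairs within a cluster (default
n_perm = 1000), which keeps the cost linear in n_perm; p-values use the
add-one estimator p = (1 + #{null ≤ ε}) / (B + 1) and are adjusted by
Benjamini–Hochberg (step-up, implemented directly and cross-checked
against statsmodels in the tests). α defaults to 0.05.

The pooled null assumes the genes entering a cluster's scan are
exchangeable. That holds well when their rescaled marginals are
comparable, and degrades when very different marginal shapes are mixed:
a gene whose values form a compact blob plus a few rescale-stretching
outliers (the signature of technical zeros far below the expression
band) yields systematically smaller ε against *any* partner, biasing
its pooled p-values. The zero-filter (≥ 80% of cells non-zero,
inclusive boundary) exists precisely to keep such genes out; this is
also the mechanistic reading of the observation that zero inflation
hurts this family of methods. With one permutation pool of size 1000
and m pairs, no single pair can reach the BH threshold α/m under a
global null once m ≳ 60, so pure-noise matrices essentially never
produce calls — false-discovery control on the null is structural, not
statistical luck.

Communities: significant pairs form an undirected network; greedy
modularity maximization runs per connected component (1–2-node
components pass through), singleton communities are dropped, and the
union of the remaining communities is the oscillator call. Community
significance scores or linearity flags are deliberately not used for
filtering. Pairs are ordered lexicographically by symbol so seeded runs
are byte-reproducible.

## Filtering

"Expressed" means strictly positive; the 80% threshold is inclusive
("at least"). Variance is the n−1 sample variance across the cluster's
cells, computed over the zero-filtered candidates, and the threshold is
the *mean* of those variances with a strict ">" (sequential reading of
the cascade; the alternative — thresholding against all genes — is a
one-line change but is not the default). Both filters are invariant to
global positive rescaling of the matrix.

## Synthetic data: what it emulates and what it does not

The generator plants groups of phase-shifted sinusoids of a shared
latent frequency on a constant baseline, adds i.i.d. Gaussian noise,
clips at zero (clip rate reported in the ground truth), and applies
entrywise Bernoulli dropout. Defaults describe the regime the method
targets: 300 cells, one 20-gene group, 180 noise genes, amplitude 2,
noise SD 0.5 (SNR 4), dropout 0.1, baseline 2.5. The baseline is chosen
so the oscillator trough (baseline − amplitude = 0.5) sits one noise SD
above zero: strongly oscillating genes swing close to the detection
limit, as multi-fold ultradian oscillators do in TPM units, and
technical zeros then fall near the natural trough instead of stretching
the rescale. With a baseline far above the amplitude the rescale
distortion from zeros dominates and detection power collapses at much
lower dropout — the generator exposes both regimes via its parameters.

Deliberately not modelled: library-size variation, negative-binomial
UMI counts, gene–gene correlation outside the planted groups,
expression-dependent dropout (a magnitude-independent Bernoulli is the
default; the rate parameter is the dial). Passing tests therefore show
correctness of the inference machinery under the stated generative
model, not robustness to every artefact of real scRNA-seq.

Traces are offset + amplitude·sin(2πt/period) + trend + noise with
optional random thinning for uneven sampling; defaults mirror typical
acquisition (70 h at 20 min intervals, 17 h period, linear drift,
SNR 5).

## Periodicity analysis

QC drops traces shorter than 25 h (exactly 25 h is kept — strict "<")
and traces whose intensity variance exceeds the cohort mean by more
than 5 cohort SDs of trace variances. The variance rule is a
cohort-level outlier criterion; note a lone outlier among n traces can
reach at most (n−1)/√n SDs, so it only bites in reasonably large
cohorts. Detrending uses a Gaussian-weighted moving average with a 24 h
window, σ = window/5 and truncation at ±window/2 — slow drifts
(photobleaching, expression-level changes) are removed while sub-daily
fluctuation passes; trend + residual reconstructs the input exactly.
The Lomb–Scargle PSD (variance-normalized, so scale-invariant) is
evaluated on a frequency grid spanning periods 2–24 h at spacing
1/(4 × duration) (oversample 4); the short-period bound guards against
sampling artefacts and the long bound matches the detrending window.
Dominant power is the PSD maximum and dominant period its reciprocal
frequency; per-condition averages interpolate all periodograms linearly
onto the intersection band at the finest input resolution. Condition
contrasts (e.g. rank tests on dominant powers) are left to standard
statistics libraries on the emitted per-trace table.

## Problem sizes and determinism

Simulation-based checks run at 200 genes × 300 cells with 1000
permutations (one cluster: well under a second) and trace cohorts of
tens of traces; replicate counts of 10–50 give stable rates at these
sizes. Every stochastic step takes a `numpy` Generator seeded from the
run configuration, and identical config + seed reproduces all outputs
byte-for-byte.

## Known limitations

- ε is marginal-dependent; heavy marginal heterogeneity within a
  cluster weakens the pooled-null calibration (see above). A per-pair
  permutation scheme is the natural extension but costs O(pairs × B).
- Harmonically related frequencies (1:2) partially satisfy the ellipse
  identity, so distinct harmonic groups can share occasional edges;
  community detection still separates them in practice.
- The low-cycling classifier consumes an external enrichment table; it
  does not compute gene-set enrichment itself.
- Add-one p-values have resolution 1/(n_perm + 1); detecting subtle
  (non-planted-scale) co-oscillation requires raising n_perm.
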