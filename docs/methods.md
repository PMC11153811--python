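# Methods

This note documents the models, default parameters, numerical conventions
and design choices behind `lsopatch`, and states what the synthetic-data
generator does and does not emulate.

## Synthetic data

### Count model

Counts follow a negative binomial with per-gene baseline and per-cell
library size:

    counts[g, c] ~ NB(mean = s_c · b_g · 2^(lfc_g · 1[cluster_c = target_g]),
                      var  = mean + φ · mean²)

with dispersion φ = 0.3 by default, library sizes s_c ~ LogNormal(0, 0.3),
and independent Bernoulli dropout (rate 0.05) applied after sampling.
Gene blocks:

- **markers**: 250 genes up-regulated in cluster 1 and 100 in cluster 2,
  effect sizes log2FC = 1 + |N(0.5, 0.5)| (range ≈ 1–2.5), baselines
  b_g ~ LogNormal(ln 4, 1.3) — most genes are lowly expressed, as in real
  single-cell data;
- **housekeeping**: 50 genes at b_g ~ LogNormal(ln 300, 0.5), shared
  across all cells; they dominate the top-expressed ranking as
  mitochondrial/ribosomal/ATP-synthesis genes do in real neurons;
- **transmitter panel**: the 7 neurotransmitter-associated genes are
  modelled as a Bernoulli gate × NB magnitude.  Gate probabilities per
  class are set from the printed cohort percentages (e.g. vGLUT2 70/50/20%
  for Onset/Sustained/Delayed; CGRP 93% and urocortin 83% in LOCs), so the
  "% expressing" and combination-size statistics are directly
  controllable.  Their truth log2FC is the expected cluster-mean ratio
  implied by the gates.
- **negative controls**: 4 cells sampled at 1/8 of the neuronal depth and
  without class structure; they exist to exercise the QC filter and
  receive no recordings.

Cohort sizes default to 44 Onset + 12 Sustained + 30 Delayed (clusters of
56 and 30 cells).  Gene lengths are uniform integers in 0.5–5 kb.

### Trace model

Recordings are synthesized parametrically rather than by conductance-based
simulation, so ground truth is exactly recoverable.  Subthreshold voltage
follows the closed-form RC response V(t) = V_rest + I·R_in·(1 − e^(−t/τ_m))
with τ_m = R_in·C_m.  For suprathreshold steps the trajectory is clipped
at the AP threshold voltage (integrate-and-fire style) and Gaussian AP
templates (absolute peak = V_rest + amplitude; FWHM = configured
halfwidth) are inserted at rule-driven times:

- *Onset*: 1 AP at rheobase at latency ~N(2.9, 0.4) ms; a small burst at
  higher currents (≤ 4 APs);
- *Sustained*: regular train at rate 10 Hz + 0.3 Hz/pA·(I − rheobase),
  first AP at ~N(7.0, 0.8) ms;
- *Delayed*: train at 20 Hz + 0.2 Hz/pA·(I − rheobase) starting after a
  latency of 25 ms + Exp(4.4) (mean 29.4 ms, clipped to [25, 180] ms).

Hyperpolarizing steps in pLSO classes add a sag component with kernel
(1 − e^(−t/12 ms))⁴ · e^(−t/40 ms) — a sigmoid (I_h-like) activation whose
slow onset leaves the fast charging phase mono-exponential — plus a
post-offset rebound of the same shape.  The sag amplitude is calibrated at
generation time with the same peak-minus-steady-state rule the extractor
uses, so the stored truth is the measurable quantity.  The stored AP
threshold truth is likewise the value the dV/dt criterion reads off the
clean template, since a procedural definition has no other ground truth.

Spontaneous PSCs are Poisson-timed biexponential events (EPSCs inward,
IPSCs outward per the Cl⁻ reversal convention), 2 Hz per polarity, with
LOC kinetics slower than pLSO by default.  The printed record gives no PSC
amplitudes or time constants per class, so the defaults (pLSO EPSC 60 pA,
τ_rise 0.25 ms, τ_decay 1.5 ms; LOC EPSC 45 pA, 0.5/3.0 ms, etc.) are free
parameters chosen to be physiologically plausible and well-separated.

Sampling rates: 50 kHz current clamp, 20 kHz voltage clamp and PSC, 5 kHz
rest segment.  Additive Gaussian noise defaults to 0.5 mV / 3 pA.
Randomness derives from per-cell `SeedSequence` streams spawned from the
configuration seed, so any subset of cells regenerates byte-identically.

### What the generator does not emulate

No amplifier artifacts (bridge imbalance, capacitance transients, series
resistance drift), no biophysical AP shape variation with firing rate, no
gene–gene correlation beyond the cluster structure, no batch effects or
ambient RNA, no read-level (FASTQ) structure.  Passing recovery tests
therefore demonstrate correctness of the measurement and inference
procedures under the stated statistical model — not robustness to all
failure modes of real recordings or libraries.

## Feature extraction conventions

- **AP detection**: peaks above −10 mV with ≥ 1 ms refractory gap.
  Threshold voltage: Savitzky–Golay-smoothed dV/dt (0.5 ms window, order
  3); walking back from the peak, the threshold is placed just after the
  last *sustained* (≥ 0.2 ms) stretch below the 10 V/s criterion — single
  noisy dV/dt dips near the peak are not spike feet.  Amplitude is
  referenced to the pre-stimulus baseline; halfwidth is measured at
  baseline + half amplitude with linear interpolation.
- **τ_m**: mono-exponential least squares over a window from step onset to
  3× a coarse 63% estimate.  The short window keeps sag contamination
  below 1% on noiseless traces while retaining enough samples at 50 kHz.
- **R_s / R_in**: R_s = ΔV/I_peak from the capacitive transient (searched
  in the first 2 ms, unsmoothed — smoothing would destroy the ~0.15 ms
  transient); R_in = ΔV/I_ss − R_s with I_ss the mean over the last
  quartile of the step.  mV/pA is converted to MΩ (×1000).
- **C_m = τ_m / R_in** (ms/MΩ → nF, reported in pF).  Users comparing to
  amplifier capacitance-compensation readings should note the convention.
- **Sag**: steady state = mean of the last quartile of the step; the
  hyperpolarized peak is searched in the first 50 ms on a 1-ms
  moving-average smoothed trace (edge-replicated, not zero-padded).
  Rebound requires the post-offset voltage to exceed baseline by
  ≥ max(2× pre-stimulus noise SD, 0.1 mV) for ≥ 5 contiguous ms.
- **PSC detection**: per-polarity threshold at 4× the robust noise SD
  (1.4826·MAD).  An event must stay above threshold for ≥ 0.2 ms
  (tolerating isolated dips) and must rise from near baseline — the median
  over [−1, −0.25] ms before the crossing must sit below half the
  threshold — which rejects re-crossings inside a previous event's tail.
  The first 100 events per polarity are aligned on the steep 50%-of-peak
  rising crossing (peak alignment smears the rise because the
  biexponential peak is flat) and averaged; amplitude, 10–90% rise and
  100–37% decay are read from the average.  Fewer than 10 events flag the
  polarity low-confidence.
- **Firing classification**: Delayed if first-AP latency at rheobase
  ≥ 15 ms; otherwise Onset if the AP count at rheobase + 150 pA is ≤ 5,
  else Sustained.  The 15 ms/≤5 thresholds sit between the classes'
  printed statistics (2.9/7.0 vs 29.4 ms latency; 1–5 APs for Onset) and
  are configurable.
- Feature extraction is deterministic; missing protocols or failed fits
  yield NaN, never silent zeros.

## Preprocessing conventions

- **Cell QC**: log2(total counts + 1) and log2(detected genes + 1); remove
  below median − 3·MAD (1.4826 consistency constant, single pass).
- **Gene filter**: "detected (≥ 1 count) in ≥ 5% of cells", i.e.
  ⌈0.05·n⌉ cells.  The alternative reading (total count ≥ ⌈0.05·n⌉) is
  available as `mode="mean"`; the detection reading matches standard
  single-cell practice and is the default.
- **Size factors**: pooling deconvolution at desk scale — cells ordered on
  a ring by library size; pools of 21/26/31 consecutive cells; each pool's
  summed profile is compared against the average pseudo-cell by the median
  ratio over expressed genes; per-cell factors solve the pool-membership
  linear system by least squares with low-weight library-size anchor rows
  (weight 0.01) that fix the scale without influencing well-determined
  solutions.  Factors are rescaled to geometric mean 1; non-positive
  solutions fall back to library-size factors with a warning, as does the
  whole method below 20 cells.
- **TPM** is computed on the post-filter matrix: counts/kb, rescaled so
  every cell sums to 10⁶.
- **HVGs**: variance residual above a rolling-median (window 51)
  mean–variance trend on the normalized matrix; top 1000 by default.

## Clustering

For each k in 2..10, an ensemble over three cell–cell distances
(Euclidean, Pearson, Spearman) × spectral dimensions d ∈
⌈0.04 n⌉..⌈0.07 n⌉ (4..7 at n = 86): the distance matrix's leading
eigenvectors (by |eigenvalue|) form the embedding; k-means (10 restarts,
seeded per ensemble member) clusters it.  The consensus matrix is the
co-assignment frequency; final labels cut an average-linkage tree of
(1 − consensus); the average silhouette width is computed on the same
(1 − consensus) distances so the selection criterion matches the
construction.  k = argmax silhouette, ties toward smaller k.  This is a
reduced but faithful desk-scale rendering of the consensus approach; the
full method's gene-wise transformations are omitted for runtime.

The cross-check is Leiden community detection (RB-configuration
modularity, resolution 0.5) on a symmetrized 15-NN graph of the top 10
principal components.  t-SNE (seeded, PCA initialization) is provided for
visualization only.

## Differential expression

- Welch t-test per gene on log2(count/size-factor + 1); fold change is the
  difference of cluster means on that scale (pseudocount 1).  A variance
  floor of 1e-8 prevents zero-division; genes with equal means and zero
  variance get p = 1.
- BH step-up FDR.  The DEG rule is |log2FC| ≥ 1 ∧ FDR ≤ 0.05, boundaries
  inclusive.  (Equivalently −log10 FDR ≥ 1.3.)
- AUROC is the tie-aware Mann–Whitney U / (n₁n₂) for "expression predicts
  cluster-1 membership".  DEGs are ranked by |AUROC − 0.5| descending
  within each direction — a down-regulated gene with AUROC 0.03 ranks as
  high as an up-regulated one with 0.97.
- Super DEG and Cluster similarity add the ≥ 10 TPM (in ≥ 1 cluster) gate
  with fold-change ≥ 4 and ≤ 2 respectively; similarity explicitly
  excludes DEGs so the boundary case |log2FC| = 1 ∧ FDR ≤ 0.05 is a DEG,
  not both.

### Overlapping index

Gaussian KDE per sample with Silverman's bandwidth; both densities are
evaluated on a shared 1024-point uniform grid spanning the pooled range
± 3× the larger bandwidth, renormalized to unit mass on the grid
(so a sample against itself yields exactly 1.0), and
OI = Σ min(f̂₁, f̂₂)·Δx.  Per-cell TPM vectors enter with their zeros —
the zero mass is part of the distribution being compared.  If either
sample has fewer than two distinct values, KDE is undefined and both
samples are compared as discrete point masses (Σ min of value
frequencies): two all-zero genes get OI = 1, a point mass against a
disjoint point mass gets 0.

## Multimodal analysis

Features are z-scored; missing values are mean-imputed for the PCA only
(with a logged count) so no cell drops out of the embedding, and never for
statistics.  Component signs are fixed by making each PC's
largest-|loading| entry positive.  Cohort comparisons use a
Kolmogorov–Smirnov normality gate (against a normal fitted per cohort,
α = 0.05 — acknowledged as anticonservative since parameters are
estimated) followed by Welch's t-test or Mann–Whitney U, with Šidák
correction over the family of the 3 pairwise cohort comparisons per
feature (family size configurable).  Congruence maps
{Onset, Sustained} → one cluster and {Delayed} → the other, trying both
assignments and keeping the better, so it is invariant to cluster
relabeling.

## Problem sizes and determinism

Default analyses run at the study scale (86 neurons + 4 controls, 2000
genes); the test suite also uses reduced configurations (~40 cells,
500–600 genes) chosen so planted effects remain comfortably detectable.
Every stochastic step takes an explicit seed; the pipeline manifest
records a SHA-256 hash of the full parameter set, which changes iff any
parameter changes.

## Known limitations

- The deconvolution solver uses dense least squares — adequate to a few
  thousand cells, not to atlas scale.
- The consensus ensemble (12 members per k) is smaller than production
  consensus-clustering tools use; silhouettes on clean synthetic data are
  near 1.0, which compresses the dynamic range of the k-selection table.
- KDE-based OI depends on bandwidth; with heavy zero-inflation and few
  cells the Silverman rule oversmooths, inflating OI for sparsely
  expressed genes.
- The t-SNE step delegates to scikit-learn and is not meant for
  quantitative inference.
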