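# Methods

`tdscreen` implements a transcriptional-disease-signature (TDS) screening
pipeline for probe-count assays of the NanoString nCounter type. The setting
is whole-animal drug screening: a disease model (e.g. a transgenic melanoma
fish line) and wild-type animals are profiled on a custom probe panel; a
weighted gene signature separating the two states is built and validated;
compounds are then scored by whether they push the signature toward the
disease state or back toward the healthy state.

## Normalization model

Raw probe counts for sample *s* are modeled as

    count ≈ h_s · r_s · expression + background_s + counting noise,

where `h_s` is a lane/cartridge hybridization-efficiency factor (measured by
spiked positive-control oligos that see `h_s` but not the sample RNA), `r_s`
is an RNA-input factor (measured by the geometric mean of housekeeper
genes), and the additive background is measured by spiked negative controls.

The chain is fixed: positive-control scaling, then housekeeper scaling, then
background subtraction.

* Positive-control scaling multiplies each sample by
  `grand mean of per-sample positive-control means / own mean` (arithmetic
  means), so factors average ~1 within a run and cartridge effects cancel.
* Housekeeper scaling does the same with per-sample *geometric* means of the
  housekeepers. Zero housekeeper counts enter the geometric mean as 0.5
  (factor computation only; stored counts are untouched). Positive controls
  are exempt from this scaling: they carry no RNA-input signal, and leaving
  them alone preserves the equal positive-control means from step 1 as a
  pipeline-exit QC invariant.
* Background is `mu + 2*sigma` of each sample's negative controls (sample
  standard deviation, n−1 denominator), subtracted from the scored signal
  probes (signature and pathway classes) and clamped at zero. Housekeepers
  have finished their role as scaling anchors and pass through unmodified,
  so their geometric means also remain exactly equal at pipeline exit.
  Factors are computed before any subtraction.

A consequence of using the grand mean as the reference level: perturbing one
sample's raw counts rescales the *whole* normalized table by one common
scalar (the grand mean moves), while all relative expression is preserved
exactly. The scale-invariance property is therefore stated, and tested, as
exact proportionality rather than identity.

## Signature construction

Per-gene two-group statistics for disease vs healthy: log2 fold change of
(normalized) count means with pseudocount 1; Welch's two-sided t-test on
`log2(count + 1)` values (variance stabilization — fold change and test
deliberately use different scales); Benjamini–Hochberg FDR across the tested
genes; ROC-AUC with disease as the positive class via the Mann–Whitney rank
identity. For gating and weighting the orientation-free `max(auc, 1−auc)` is
used so down-regulated markers are not penalized.

Gates (defaults, overridable): preliminary selection requires
`|log2FC| ≥ 0.7`, `FDR ≤ 0.05` and `AUC ≥ 0.7`; cross-validation over two
independent tests requires a consistent nonzero fold-change direction in
both and AUC > 0.7 in at least one. Weights: 2 when both tests' AUCs exceed
0.8, else `max(auc1, auc2)` — the published weighting is only given as AUC
bins in (0.7, 1]; the max-AUC rule reproduces those bins and is monotone in
marker quality. The reference log2FC is the mean of the two tests'
estimates (averaging reduces single-test noise; the sign is the reference
direction). Because a test can yield AUC exactly 1.0 with the other ≤ 0.8,
weights are validated as `w = 2 or 0.7 < w ≤ 1` (closed at 1).

## Compound scoring

Treatment-vs-vehicle differential expression uses the same statistics with
the screening thresholds `|log2FC| ≥ 0.6`, raw `p ≤ 0.05` (both arms n ≥ 2).

**Activation Z-score.** Each signature gene with a nonzero treatment log2FC
gets a state `x_i = +1` if its change matches the reference disease
direction, else −1. Unweighted, `Z = (N₊ − N₋)/√N`; weighted,
`Z = Σ w_i x_i / √(Σ w_i²)`, which keeps unit variance under independent
equiprobable states. `Z ≥ 2` reads as disease-activating, `Z ≤ −2` as
disease-repressing. Zero fold changes are excluded and reduce N; with N = 0
the score is an explicit no-evidence result (NaN), never 0. By default all
panel genes participate (`min_abs_lfc = 0`); a DEG-restricted variant is
available.

**KS drug score.** Signature genes are ranked by treatment log2FC
(descending; ties broken by gene name for determinism). For a tag set at
1-based positions `V(1) < … < V(t)` in a ranking of length n,
`a = max_j [j/t − V(j)/n]`, `b = max_j [V(j)/n − (j−1)/t]`, and
`ks = a` if `a > b`, else `−b` (an exact tie returns the positive value;
ties are measure-zero on continuous data). `ks_up` tags the reference
up-genes, `ks_down` the down-genes; `S = ks_up − ks_down`, zeroed when both
share a strict sign (a zero is treated as signless). Tags default to the
reference signature classes (the connectivity-map convention); restricting
tags to the compound's DEGs is available but degenerates for quiet
compounds (empty tag classes), so it is not the default.

A useful exact identity: reversing the ranking maps `a → b − 1/n` and
`b → a + 1/n`, so whenever the statistic is decisive (`|a − b| > 2/n`) the
reversed score is the negated original to exactly 1/n. When tags crowd both
extremes simultaneously, reversal does *not* negate the score — the
statistic is a signed maximum, not an odd function.

## Threshold calibration

Disease-pair lists: the per-gene log2FC of every (disease, healthy) sample
pair over the signature genes (a 20 + 20 cohort gives 400 lists). Null
lists: each gene's value is drawn with replacement from the pooled matrix
values, destroying the gene structure; by default each draw's sign is also
flipped with probability 1/2 ("symmetric" pooling), which makes the null
exactly directionless — the consistent/contradicting states are equiprobable
regardless of any up/down imbalance in the signature, so the null mean Z is
0 by construction rather than only approximately. Plain pooling is
available (`symmetric=False`).

False-positive rate: fraction of null lists whose score magnitude reaches
the threshold (defaults |Z| ≥ 2, |S| ≥ 0.27). False-negative rate: fraction
of disease pairs whose *signed* score falls below +threshold — a disease
list must read as activated. Two anchors bracket the range: the reference
signature's own log2FC list (all states consistent; Z = √N unweighted or
`Σw/√(Σw²)` weighted) and the "model compound", its exact negation.

For N = 97 equiprobable states the exact null exceedance
P(|Z| ≥ 2) = P(|2K − 97| ≥ 2√97), K ~ Binomial(97, ½), is ≈ 4.2–4.6%
depending on the lattice cutoff; the resampled nulls reproduce it.

## Synthetic cohorts

The generator emulates the assay: 97 signature probes, 108 pathway probes,
29 housekeepers, 6 positive controls on a 4-fold ladder (128 … 0.125 fM) and
8 negative controls. Per-gene log2 baselines are Normal(8, 2). Signature
genes get a random direction, an effect size δ ~ Uniform(0.7, 2.5) log2
units and a penetrance p ~ Uniform(0.6, 1): a diseased individual expresses
the effect with probability p. Incomplete penetrance is what makes per-gene
AUC vary and motivates the weighting. Per-sample lane factors are
2^Normal(0, 0.1) and input factors 2^Normal(0, 0.2). Endogenous counts are
negative binomial (dispersion 0.05; variance μ + 0.05 μ²) around
`h·r·2^(baseline+effect) + background` with background mean 12 counts;
positive controls are Poisson around `h · gain · conc` with gain 600
counts/fM (top spike ≈ 77k counts, typical of real spike-ins) and are
independent of the input factor; negative controls are Poisson(h·b). A drug
arm shifts every signature gene by `−ρ·δ` (ρ = 1 full reversal, 0 inert,
−1 disease mimic; default 8 treated individuals) and can perturb a random
fraction of pathway genes by ±Uniform(0.6, 1.5) as off-target activity.
`panel_from_truth` exposes the latent signature directly as an oracle
reference panel for benchmarks (weights mapped from penetrance).

What the generator does not emulate: gene–gene expression correlation,
batch-by-batch chemistry drift beyond a scalar lane factor, probe-specific
hybridization biases, and compound dose–response. Passing tests therefore
demonstrate the statistical machinery under a faithful but idealized noise
model, not performance on any specific real assay.

## Problem sizes used by the test-suite benchmarks

Null calibration uses 400 and 10,000 resampled lists on one default 20 + 20
cohort; the compound-recovery benchmark uses 50 independent studies (cohort
plus a full-reversal and an inert arm each); panel-recovery checks use 8–20
reduced cohorts. These sizes make every stochastic check reproducible in
seconds while keeping Monte-Carlo error well below the asserted margins.

## Known limitation: resampled-null calibration of the KS score

The S threshold (0.27 ≈ the 5% point of the resampled-list null) does not
transfer exactly to treated-vs-vehicle comparisons. Pooled resampling (and
equivalently, permuting which gene carries which value) erases each gene's
own fold-change distribution. In a real inert comparison those marginals
differ systematically *by tag class*: genes down in disease sit at lower
disease-state counts and their arm means are far more sensitive to which
individuals are penetrant, so the ranking extremes fill class-asymmetrically
and |S| exceeds 0.27 in roughly 30% of genuinely inert arms under the
generator's default conditions — several times the resampling-based 5%. The
Z-score is much less affected (its null exceedance stays near the binomial
4–5%). Practical reading: treat S as a ranking/effect-size companion to Z
rather than as an independently calibrated significance test, or calibrate S
against treated-arm replicates when such data exist.
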