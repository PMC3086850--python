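# Methods

## Model

The predictor treats the probesets of one chromosome, ordered by genomic
start coordinate, as a hidden Markov chain. The hidden state at position i
is the composite pair (b, α) of the discretized expression symbol
b ∈ {H, L, M} and the copy-number status α ∈ {+, −, o}; the canonical state
order is H+, L+, M+, H−, L−, M−, Ho, Lo, Mo. Emissions are structurally
degenerate — state (b, α) emits b with probability 1 — so the emission
matrix is fixed rather than estimated: composing training states by
superimposing the observed symbol makes the emission MLE identically
degenerate, and hard-coding it avoids 0/0 rows for states never visited in
training. Inter-probe genomic distances are ignored: the chain is a pure
sequence model, so transition probabilities absorb the average segment
length in probe units, not base pairs.

One HMM is trained per chromosome and decoding never mixes probes across
chromosomes. Chromosomes to exclude (e.g. small or sex chromosomes, which
some studies drop for technical reasons) are a configuration list,
defaulting to none: the exclusion is a study choice, not a property of the
method.

### Training

Training is fully supervised: with paired expression and CGH data the
hidden path of every training sample is known, so transitions and initial
probabilities are maximum-likelihood counts with additive smoothing
(default pseudocount 0.5 on both). Smoothing matters because unseen
transitions otherwise receive probability 0 and make some observation
sequences undecodable (−∞ everywhere); decoding raises an explicit error
suggesting a positive pseudocount if that happens. Baum–Welch is
deliberately not provided: with known paths it is unnecessary, and with 81
transition parameters per chromosome unsupervised estimation is poorly
constrained at realistic cohort sizes.

### Decoding

Viterbi and scaled forward–backward run in natural-log space (per-position
scaling for the forward pass). With degenerate emissions only the 3 states
compatible with the observed symbol are reachable at each position, and the
posterior marginal of CNA label α at position i equals the posterior of the
single compatible composite state — so thresholding the composite-state
posterior and the CNA marginal coincide, and the distinction needs no
configuration. Viterbi ties break toward the earlier state in canonical
order, for cross-platform determinism. The posterior cutoff is restricted
to [0.5, 1] so at most one label can pass it; an exact 0.5/0.5 tie at
cutoff 0.5 stays neutral.

## Discretization

Expression symbols use the ratio of a probe's intensity to its cohort
median: H above 1.5-fold, L below 1/1.5, M between, with boundary values
going to the neutral class (the thresholds are strict inequalities). The
per-probe median reference makes symbolization invariant to rescaling any
single probe's row, hence insensitive to probe-specific hybridization
efficiency. It also assumes each probe is aberrant in fewer than half of
the samples; hotspots approaching 50% population frequency shift the median
toward the aberrant level and compress the observable fold change — a known
failure mode of median-reference discretization, visible in the simulator
when hotspot frequency is pushed toward 0.5.

In cross-validation the median is computed on the training cohort only and
the held-out sample is symbolized against that training median, preventing
leakage of the held-out sample into its own reference.

CGH tumor/normal ratios discretize at the conventional 1.25 (gain) and 0.75
(loss) thresholds, strict, configurable. Segments are projected onto probes
by midpoint containment: a probe takes the label of the segment containing
its midpoint; with overlapping opposite-label segments the larger bp
overlap with the probe wins and exact ties go neutral. Midpoint containment
was chosen over any-overlap because a probe is atomic here — no partial
labels — and over start-position because it is symmetric under strand and
coordinate conventions.

## Cytoband smoothing

For each cytoband and sample, label counts (n+, n−, no) are compared with
the same sample's genome-wide counts (N+, N−, No) by the log10 ratio of two
multinomial likelihoods, the alternative using the cytoband's own MLE
proportions and the null the genome background; multinomial coefficients
cancel. The score is non-negative by construction, zero exactly when the
cytoband matches the background proportions, and +inf (flagged with a
warning) only when the background entirely lacks a label the cytoband
shows. The default call cutoff is LOD ≥ 2. The likelihood-ratio hypothesis
is omnibus ("this band is aberrant"), so the direction of a significant
band is decided by strict probe-label majority (n+ vs n−), with ties making
no call — conservative by design, and each band gets at most one call.
Background counts are per-sample, not pooled across the cohort, so a
globally noisy sample raises its own null rather than polluting others.

## Validation

Gain and loss are scored separately as one-vs-rest 2×2 tables over
probe × sample cells: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
accuracy (TP+TN)/total. Metrics with an empty denominator are marked
undefined and excluded from averages rather than imputed as 0. LOOCV
reports both per-fold mean ± sd (the fold is the held-out sample) and
pooled-cell metrics; the per-fold aggregation is the only reading of a
"mean ± sd" summary compatible with leave-one-out, but both views are
emitted since they answer different questions. The LOOCV run always stores
the posterior CNA marginals so calls at any cutoff in [0.5, 0.9] can be
re-thresholded without re-running folds, which is how the cutoff sweep
(specificity rises, sensitivity falls as the cutoff rises) is produced.
Chromosome/label pairs with fewer than a configurable minimum (default 3)
of aberrant training samples are reported as under-trained: infrequent
aberrations are the expected failure mode of a supervised per-chromosome
model.

The two baselines bound the contribution of each model component: rGEP is
elementwise symbol relabeling (no spatial information), sGEP adds LOD
smoothing (spatial pooling at band resolution but no learned transition
structure and no training cohort). For probe-level comparison, sGEP band
calls are broadcast back onto the band's probes.

## Association test

For a recurrent region and direction, samples split into aberrant,
wild-type, and excluded (samples carrying both a gain and a loss in the
region are excluded from both groups). Each region probe contributes a
one-sided two-sample t-test p-value in the dosage direction — Welch by
default, since equal variances between aberrant and wild-type groups is
exactly what a dosage effect violates; a flag restores the pooled-variance
test. The statistic is Σ ln p (the log base only rescales the statistic
monotonically and cannot change the permutation p-value, which is asserted
as a test). Group labels are permuted preserving group sizes; the empirical
p-value is (1 + #{permuted ≤ observed}) / (n_perm + 1), the add-one
correction that keeps p-values valid and strictly positive at finite
n_perm. Zero-variance probes get p = 1 with a log entry.

## Synthetic cohort generator

The generator emulates the paired-data regime the predictor targets: a
tumor cohort with recurrent per-chromosome CNA hotspots and a multiplicative
dosage coupling from copy number to expression. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| n_samples | 100 | mid-sized expression/CGH cohort |
| chromosomes | 4 × 400 probes | enough chains to train/decode per-chromosome models quickly |
| probes per cytoband | 40 | matches high-density array probeset counts per band |
| hotspots | gains on chr1 (bands 3–5, 30%), chr2 (bands 5–7, 25%); losses on chr3 (25%), chr4 (20%) | lymphoma-like recurrence: a handful of hotspots at 20–30% population frequency; frequencies are this package's choices, not measurements |
| segment jitter | ±20 probes (~half a band) | CGH breakpoints scatter around a recurrent region rather than snapping to band boundaries |
| dosage_effect | 2.0 | linear-scale fold change for a detectable gain; reciprocal under loss |
| concordance | 0.7 | fraction of probes inside a CNA that express the dosage effect; dosage coupling is strong but not universal |
| noise_sd | 0.3 | sd of ln-scale multiplicative noise, giving a ~9% spurious H/L rate per probe at the 1.5-fold threshold |
| baseline medians | log-normal(ln 100, 1) | right-skewed intensity distribution on a linear scale |

Each hotspot is independently present per sample with its frequency, as a
single contiguous segment; expression is baseline × dosage factor (if in a
CNA and a per-probe concordance coin succeeds) × log-normal noise. Opposite-
label hotspots may not overlap on a chromosome (config error).

What the generator does **not** model: copy-neutral events (uniparental
disomy), epigenetic silencing, tumor-purity dilution of the dosage effect,
correlated (batch) noise across probes, probe-specific variance, and
breakpoints shared across samples by mechanism. Passing tests on this
cohort therefore demonstrate correctness of the algorithms and the claimed
qualitative ordering of the methods under a clean dosage model, not
performance on real tumor data, where all of the above depress concordance
and the absolute metric values.

## Numerical choices and problem sizes

- All decoding in natural-log space; forward–backward with per-position
  scaling; posterior rows renormalized, asserted to 1e−9.
- Decoding exactness is checked against exhaustive enumeration of all 3^n
  compatible paths for n ≤ 8 (tolerance 1e−10); parameter recovery uses 200
  sampled chains of length 500, where the 0.02 tolerance is ~3 binomial
  standard errors on the worst-case transition estimate.
- The permutation-test calibration uses 200 replicate null datasets at 200
  permutations each; the acceptance band [0.022, 0.088] is the 95% binomial
  interval for a 5% rejection rate at 200 replicates.
- LOOCV on the default cohort (100 folds × 4 chromosomes × 400 probes) runs
  in seconds; these sizes were chosen as the smallest at which the binomial
  checks above are meaningful.
- Floating-point: LOD is clamped at 0 from below (the true value is
  provably ≥ 0; rounding can produce −1e−17); model JSON serialization
  round-trips float64 exactly.

## Known limitations

- Per-chromosome supervised training needs several aberrant training
  samples per chromosome and label; rare aberrations are flagged, not
  fixed.
- The median-reference discretization degrades as hotspot frequency
  approaches 50% (see above).
- Cytoband calls are single-valued per band; a band genuinely harboring
  both a gain and a loss in the same sample is reported as the majority
  direction or no call.
- The 3-symbol/3-status state space cannot represent amplitude (high-level
  amplification vs single-copy gain); a 5×5 variant would need 625
  transition parameters and correspondingly larger cohorts.
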