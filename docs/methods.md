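# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limits of what the test suite
demonstrates.  Notation: k regions, T timepoints, TR sampling interval;
groups are control (C), PTSD (P), and PCS+PTSD (CP).

## Effective connectivity

**Static.**  The order-p MVAR with zero-lag augmentation is fitted per
target column j by ordinary least squares with regressors {z_i(t), i≠j}
∪ {z_i(t−1..t−p), all i}.  Columns are standardized first (default; can
be disabled), which makes coefficients comparable across subjects but
shrinks them by the source/target sd ratio — recovery of generative
coefficients on their native scale therefore uses `standardize=False`.
The model order is fixed at p = 1: at fMRI-like sampling rates the
directional information of interest lives at lags at or below one TR.
GC_ij sums the lagged coefficients only; the zero-lag matrix M(0) exists
precisely so instantaneous correlation is *excluded* from GC (verified by
the compensation tests: purely instantaneous coupling yields mean
off-diagonal |GC| < 0.05).

**Dynamic.**  The same regression is estimated recursively: state = the
stacked coefficient vector, random-walk dynamics realized by inflating
the state covariance by 1/λ per step (λ = forgetting factor),
measurement update in recursive-least-squares form.  Initialization:
coefficients 0, state covariance I (κ = 1); prediction errors are
retained for diagnostics.  With λ = 1 the recursion converges to the
batch fit (tested within ±0.05 on stationary data); with λ < 1 it tracks
coefficient drift with an effective memory of ≈ 1/(1−λ) samples.  Two
numerical points matter:

* the covariance update loses symmetry in floating point and then
  diverges along weakly-excited directions (observed at k = 2);
  re-symmetrizing P each step eliminates this;
* the coefficient trajectory carries an irreducible noise floor with
  per-coefficient sd ≈ √((1−λ)/2)·σ_e/σ_x; at λ = 0.98 and standardized
  data this is ≈ 0.08–0.10.  This floor is load-bearing for the power
  discussion below.

The pipeline default is λ = 0.98: λ = 1 cannot express coupling
*variability* at all (the trajectory collapses onto the running batch
estimate), and λ near the tracking optimum N ≈ period/2π balances floor
noise against attenuation of the planted oscillations.  DEC variance
excludes a burn-in prefix of max(50, 5 % of T) (filter transient);
variances over time are population variances (ddof 0), which makes the
two-point-alternation identity exact.

## Blind deconvolution

Band-pass filtering is zero-phase (forward–backward Butterworth): a
causal filter would introduce lags that corrupt directionality.  Nuisance
regression is exact least-squares projection with intercept.

Pseudo-events are local maxima of excursions above 1 sd (threshold
configurable).  The HRF is estimated per region by FIR least squares on
the event train over a window from 12 s before to 24 s after the event
anchor — unlike a plain event-locked average this deconvolves overlapping
responses.  Because events are anchored at the BOLD peak, the absolute
hemodynamic delay is not directly observable; it is inferred from the
response *shape* by scoring a double-gamma template grid
(time-to-peak 2–12 s, 0.25 s steps) with two standardized criteria
summed: peak-aligned shape correlation over a common zero-padded window,
and kurtosis of the Wiener-deconvolved signal (a point-process prior:
the correct template width maximizes sparsity of the recovered signal;
kurtosis is width- but not shift-sensitive).  The FIR curve is
interpolated (cubic spline, dt/8) so the onset shift is not quantized to
whole samples.  Absolute time-to-peak carries a common bias of up to
~1 s; *relative* delays across regions — what directional analysis needs
— are recovered to within about half a sample.  Wiener regularization
defaults to 0.1·mean|H|².

The lagged-HRF demonstration pairs an identical point-process neural
signal with HRFs peaking 5 s and 7 s at TR = 2 s (so the delay is one
sample and is expressible by a first-order model), T = 2000 with 240
events and 15 % observation noise.  Blind deconvolution reduces the
spurious GC by ≥ 2× in ≈ 97 % of replicates (median factor ≈ 7).

## Graph measures

Connectivity matrices enter as |values|, zero diagonal, max-normalized
per graph.  Segregation uses the Fagiolo cube-root formulations
(transitivity global, clustering coefficient nodal, and the
weighted-directed neighborhood-efficiency form of local efficiency).
Integration uses edge length 1/weight: Dijkstra distances (unreachable →
+∞, contributing 0 to global efficiency), and edge betweenness as *raw
counts* of all tied shortest directed paths through an edge over ordered
source–target pairs (ties resolved with relative tolerance 1e−9), not
fractional Brandes shares.  All six measures are verified against
exhaustive enumeration oracles to 1e−10 on random graphs, and are
permutation-equivariant and scale-invariant by construction.  Dynamic
tensors are measured snapshot-by-snapshot with a configurable stride
(cohort default 5, trading runtime for temporal resolution; the variance
estimates are limited by the trajectory correlation time, not by the
stride).  Transitivity is undefined below three nodes (NaN sentinel).

## Group statistics

Each feature × pair comparison is a linear model
feature ~ group + age + education + race + motion on the two groups'
rows (two-sided test on the group dummy; adjusted means at covariate
grand means; race reference-coded with categories of < 2 subjects merged;
the implementation is a vectorized normal-equations solve verified
against statsmodels OLS to 1e−10).  Benjamini–Hochberg runs within each
(pair, flavor) family, with the raw-connectivity family corrected
separately from the network-measure family so the gate is an independent
check.  Trend conformance: strength features must be monotone in one
consistent direction across adjusted means (labelled inflation or
deflation; ties fail), variability features must strictly decrease
C > P > CP (rigidity).  Hypothesis-2 requires all six cells significant
plus trend; hypothesis-1 requires the four control-vs-clinical cells
significant, both P-vs-CP cells non-significant (absence of evidence, not
an equivalence test — a documented limitation), and both clinical groups
displaced from control in the same direction.  Node selections intersect
cc and local efficiency; edge selections intersect SPL and edge
betweenness and are then gated on the raw SEC / DGC-variance pattern.

## The synthetic cohort

The generator's default design *is* the study condition for all
end-to-end tests: k = 20, T = 500, TR = 1 s, 20 subjects per group.

* **Background**: dense weak couplings N(0, 0.09), self-coupling 0.3,
  unit innovation noise; one *shared* anatomical backbone per cohort
  (subject-specific backbones make shortest-path routing — and hence
  edge betweenness — noise-dominated).  A sparse strong-backbone /
  community variant exists as configuration.
* **Planted chain** (4 edges over regions 0–4): coupling *bursts* — a
  square-wave alternation between a floor of 0.35 and a high state, with
  burst amplitude 0.30 × {1.0, 0.5, 0.03} for C/P/CP and period 250
  samples with random phase.  Bursty coupling makes strength (time
  average) and variability deflate *together*, the
  deflation-plus-rigidity co-occurrence the framework is designed to
  detect, and it keeps all snapshot weights away from the 1/w blow-up
  region.  Multipliers were chosen once, by pilot power analysis, to
  produce subject-level standardized effects of d ≳ 1.5 between adjacent
  groups on the raw-connectivity features — mirroring the very large
  clinical separations such studies report on symptom scales.
* **Reference edge** (0.97, constant): anchors the per-graph
  max-normalization; without a stable strongest connection, uniform
  planted strength changes would cancel under normalization.
* **Hypothesis-1 edges** (2) with clinical groups planted equal, and
  **diffuse pathology edges** (12, acyclic bipartite block) with the
  graded signature: the disorder is not confined to one chain, and a
  realistic number of true effects keeps the multiple-comparison
  landscape honest.
* **Behavior**: PCL5 / NSI / NCI are linear in the subject's mean
  realized variability multiplier plus noise (sd 4–5), yielding control ≈
  20/9/108 through comorbid ≈ 54/40/78 — symptom scales worsen exactly as
  network variability rigidifies, so variability features correlate
  negatively with symptom load.
* **Observation**: by default the latent signals plus white noise
  (sd 0.02).  An HRF-confounded mode (per-region double-gamma HRFs with
  time-to-peak U[4.5, 7.5] s plus noise) exists for studying the
  deconvolution stage; the cohort analyses run on the latent mode so that
  connectivity power is not conflated with deconvolution fidelity, which
  is validated separately.
* Determinism: a cohort is a pure function of (design, seed); divergence
  is guarded at |Z| > 1e6; unstable subject draws are retried five times
  with fresh jitter.

What the generator does **not** emulate: physiological noise spectra,
head motion, spatial smoothness or volumetric structure, scanner drift,
non-linear neurovascular coupling, inter-regional HRF correlations, or
heavy-tailed innovations.  Passing tests therefore demonstrate the
*pipeline's* correctness and power under the stated generative story,
not performance on real recordings.

## Power of the full selection at this scale — a known limitation

The raw-connectivity stages recover the planted structure cleanly: SEC
contrasts reach p < 1e−4 in every cell, DGC-variance contrasts pass in
most cells, behavior correlations reach |r| ≈ 0.8, classification
worst-case accuracy exceeds 80 %, and symptom-score SVR reaches
R² ≈ 0.8.  The *full* hypothesis-2 edge selection — six significant cells
for SPL **and** edge betweenness **and** the raw gate, FDR-corrected over
~800-feature families — typically selects nothing at T = 500, n = 20.
Extensive piloting isolated why, and the obstacle is structural rather
than a tuning matter:

1. Snapshot-metric variance couples to metric *level* through estimator
   noise.  With coefficient-noise floor σ_w, the SPL variance of an edge
   scales like (∂(1/w)/∂w)²σ_w² = σ_w²/w⁴, so the group with the
   *weakest* coupling (CP) inherits the *largest* noise-driven SPL
   variance — opposing the planted rigidity ordering.  Edge betweenness
   shows the mirrored effect (stronger edges sit on more near-marginal
   routes, inflating count variance), so any monotone strength trend
   drives the two local integration measures' variances in *opposite*
   directions unless planted oscillation variance dominates the floor
   term in both.
2. The floor cannot be made small enough at T = 500: the optimum
   forgetting for an oscillation of period τ gives memory N ≈ τ/2π and
   floor variance ≈ π/τ, while stability bounds the plantable amplitude;
   for the middle group the oscillation signal lands at or below the
   floor, so the P-vs-CP variability cells — which hypothesis-2 strictly
   requires — remain at p ≈ 0.1–0.9 regardless of effect-multiplier
   choices we consider generatively defensible.

Doubling the record (T = 1000, λ = 0.99) lifts SEC/SPL-static cells to
p < 1e−9 and most betweenness cells past FDR, but the SPL-variance
P-vs-CP cell remains noise-bound.  We report the full-selection
sensitivity honestly (it is one of the quantities
`scripts/acceptance.py` recomputes) rather than weakening the selection
rule; the per-cell significance table printed by
`analysis/04_group_statistics.py` makes the bottleneck visible.  On real
data this caveat translates to: variability ("flexibility") differences
in *snapshot graph metrics* need either long records, variance
normalization against a subject-level noise floor, or confirmation on
the raw connectivity variability, which is far better behaved.

## Prediction stages

Linear kernels with unit cost throughout; no hyperparameter search.
RCE-SVM: per repetition, stratified 80/20 splits (six per repetition);
feature k-means (on training rows only) into the current cluster count;
clusters scored by 3-fold cross-validated SVM accuracy *within the
training set* (so elimination never sees held-out rows — verified by a
leakage test); the worst 20 % of clusters dropped per step from 40 down
to 2; held-out accuracy recorded at every step; worst-case accuracy is
the minimum over all repetitions × splits.  Multiclass handling is
one-vs-one voting.  Binomial significance uses the pooled held-out
correct count against chance = the largest class proportion
(conservative).  SVR pools held-out predictions per iteration and
reports the squared Pearson correlation with truth; the default
iteration count (hundreds to a thousand) is a compute choice —
estimates stabilize long before that.
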