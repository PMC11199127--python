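# Methods

This note documents the models, estimators and numerical choices behind
`ccmbn`, what the built-in simulators do and do not emulate, and the known
limitations.

## State-space reconstruction and simplex projection

A scalar series x is embedded into lagged-coordinate vectors
(x_t, x_{t−l}, …, x_{t−(E−1)l}).  Simplex projection predicts a quantity
co-registered with each state vector from the E+1 nearest library
neighbours (Euclidean distance), with weights exp(−d_i/d_1) normalized to
sum to one; if the nearest distance is zero, only zero-distance
neighbours are used, with equal weight; all-equal distances degenerate to
uniform weights.  A point is never its own neighbour: exact time matches
are excluded.  Prediction skill is the Pearson correlation between
predictions and observations (the CCM-literature standard), defined as 0
for degenerate (constant) inputs.  Degenerate local regressions in the
S-map are stabilized by a ridge term of 1e−8 on the normal-equation
diagonal.

**Embedding parameters.** E is chosen to maximize leave-one-out simplex
forecast skill over 1…20 (ties to the smaller E); the lag l is the first
minimum of the lagged self mutual information (2-D histogram estimator
with ⌈√(n/5)⌉ bins per axis), with defaults E=5, l=2 when no admissible
optimum exists.  The pipeline-level helper `select_embedding`
additionally caps the MI lag at the series' decorrelation time (the
first lag where the autocorrelation falls below 1/e).  Rationale: the
embedding lag exists to decorrelate coordinates.  On strongly chaotic
series the MI profile decays monotonically into the estimator's noise
floor without a real interior minimum, so the first-minimum rule lands
on a floor fluctuation (l ≈ 4–16) and produces embeddings whose stale
coordinates destroy window-level cross-map skill; such series
decorrelate within one step, and the cap yields l=1.  Smooth seasonal
series decorrelate slowly and keep their MI lag.  A forecast-skill
competition between lag candidates was tried and rejected: persistence
makes the unit lag win trivially on smooth data regardless of whether it
unfolds the attractor.  For windowed analyses the selection is further
restricted to embeddings spanning at most a quarter of the window, so
each window keeps enough state vectors.

**S-map nonlinearity test.**  Locally weighted linear forecasts with
weights exp(−θ·d/d̄) over θ ∈ {0, 0.1, …, 8}; θ=0 is the global linear
model.  The series is flagged nonlinear (state-dependent) when some θ>0
improves skill by more than 0.01 — the package-wide threshold for a
meaningful skill difference.

## Convergent cross mapping

To test X → Y, the *effect* Y is embedded and its manifold predicts the
concurrent values of the cause X.  Inside sliding windows the
chronological first 75% of state vectors form the library pool and the
last 25% are prediction targets, respecting temporal order.  Whole-frame
(single-frame) runs use the same chronological split.  The library at
size L is a random draw of L pool vectors, and the skill at each L is
averaged over 8 seeded draws: with a deterministic first-L library the
skill-vs-L curve of even independent noise is rough enough that
convergence testing becomes unreliable, while draw-averaging removes the
library-composition noise at negligible cost (draws are batched into a
single nearest-neighbour pass).  Library sizes follow a 15-point
log-spaced schedule from E+2 to the pool maximum.

**Convergence** is declared when (i) skill gains at least 0.05 from the
smallest to the largest library, (ii) the (L, skill) trend is positive by
a one-sided Kendall-τ test at the 5% level, and (iii) the final skill is
significantly positive by a one-sided Fisher-z test at the same level
given the held-out sample size.  Condition (iii) exists because a curve
drifting upward inside the sampling-noise band of the correlation
estimate — common for independent series — satisfies (i)–(ii) ~30% of
the time; with it, the white-noise false-convergence rate measured over
20 seeds is ≤10%.

**Sliding-window protocol.**  Windows of 100 samples advance by 10.
Each window is tested for a unit root (ADF, constant term, AIC lag
selection, α=0.05) and both series of the pair are differenced together
when either fails, keeping rows aligned.  The aggregate skill of a pair
is the mean final skill over *converged* windows only, and an edge
passes with ≥10 converged windows and mean skill ≥0.01.  Whole-series
runs replace the window-count filter by requiring convergence of the
single curve.

**Surrogate significance.**  Phase-randomized surrogates preserve the
periodogram exactly (DC kept, so the mean is preserved; the Nyquist bin
keeps its magnitude with a random sign).  Surrogates replace the cause
series only; since the effect manifold and hence the neighbour geometry
are unchanged, a thousand surrogates reduce to a thousand re-weightings
of the same neighbour table and are cheap.  Significance is the strict
comparison of the observed skill against the empirical 0.9 quantile of
the surrogate skills; the observed value is not pooled into the
surrogate distribution.  Under independent AR(1) pairs the test fires at
its nominal 10% level (calibration is part of the acceptance checks).

## Extended CCM and interaction classification

Skill is rescanned over shifts −20…+20 on the most recent 400-point
frame (shrunk with a warning, floor 100, for shorter series), with a
fixed maximum library of 200 vectors and leave-one-out prediction over
the frame.  Two lags are recorded per direction: the global argmax (ties
toward 0), which drives classification, and the best non-positive lag —
the "highest peak at lag ≤ 0" convention — which becomes the edge lag.

Classification (a total function; peaks below 0.01 count as
unsupported):

| pattern | class |
|---|---|
| neither direction supported | false_interaction |
| both optimal lags 0, peak skills within 0.05 | synchrony_common_force |
| both lags 0, dissimilar skills | unidirectional toward the stronger |
| lag_xy < 0 and lag_yx > 0 | synchrony_enslaved_xy (mirrored for yx) |
| both lags ≤ 0, both supported | bidirectional |
| one supported direction with lag ≤ 0 | unidirectional |
| otherwise (best lags strictly positive) | false_interaction |

The rows for dissimilar zero-lag skills and for mixed (0, <0) lags fill
combinations the enslavement/bidirectional rules leave open, keeping the
function total.  Network refinement drops false interactions and
common-force synchrony, keeps only the dominant direction of an
enslaved pair, and keeps both directions of a bidirectional pair, each
with its own lag.

## DAG conversion

Cycles are processed in a canonical order (each simple cycle rotated to
its lexicographically smallest node, cycles sorted by length then
names), making the procedure deterministic across runs and platforms.  A
cycle through the target loses the target's out-edge inside the cycle; a
cycle avoiding it loses the weakest (lowest mean skill) edge entering a
confounder — read as a node with ≥2 out-edges, i.e. a common cause — or,
with no confounder in the cycle, simply its weakest edge.  Non-target
sinks are then pruned repeatedly.  In-edges of the target are never
removed, the output is acyclic (verified against an independent
topological sort in the tests), and the conversion is idempotent.
Expert-knowledge edges can be appended afterwards (rejected if they
would close a cycle) and are exempt from the evidence filters.

## Discrete Bayesian network

Variables are categorized on the resampled raw scale — quantile codes
are scale invariant, and the stored cutoffs stay in physical units:
predictors into tertiles (codes 0/1/2, left-closed intervals, values at
a cutoff joining the upper category), the target binarized at its 0.75
quantile with the upper interval closed (high = value ≥ threshold).
Each cause column is advanced by its |lag| so cause and effect are
row-aligned; upstream variables accumulate the lag of their
maximum-skill out-edge along the path toward the target, and the leading
max-shift rows are dropped.  CPTs are maximum-likelihood with add-1
smoothing (unseen parent configurations become uniform) on the
chronological first 75% of rows; state support is checked against the
>20-cases rule and under-supported fits warn rather than fail.
Inference is exact variable elimination (eliminating hidden variables in
sorted order), equal to brute-force joint enumeration to 1e−9 on all
test networks.  Evaluation scores P(target=1 | parents) per held-out
row with a 0.5 cutoff; AUC is the rank statistic with half credit for
ties, using P(high) as the score.  The hill-climbing baseline greedily
adds/removes/reverses edges from the empty graph under the BIC score
with deterministic lexicographic move enumeration and a parent cap of 4.

## Sensitivity analysis

Up to 20,000 distinct uniform random category assignments over all
non-target nodes (exhaustive when the space is smaller) are pushed
through exact inference.  With residuals r_s = P_s − mean(P), the
maximizing side (P > 0.5) picks each variable's bloom-promoting category
(its modal category among those scenarios) and the variable's term is
the mean residual over *all* scenarios holding that category; the
minimizing side is analogous, and the contribution is the sum of the two
absolute terms.  Averaging over all scenarios with the category — not
only the side that chose it — is what makes the score discriminative: a
variable unrelated to the target mixes residuals from both sides and
scores ≈0, while restricting to one side would hand every variable that
side's mean residual.  This definition is canonical for this package.
Mean maximizing/minimizing scenarios are the per-variable mean category
over the P > 0.5 and P < 0.5 subsets (boundary scenarios belong to
neither), with subset sizes reported.

## The simulators

**Four-species coupled logistic system.**  Y1 is an autonomous chaotic
logistic map (growth 3.9); Y2, Y3, Y4 are logistic maps coupled each to
its predecessor (couplings 0.4, 0.4, 0.35), giving the ground-truth
chain Y1 → Y2 → Y3 → Y4 with indirect influences downstream.  Runs
discard a 100-step burn-in, are deterministic for a given initial
condition, and error out on divergence (|Y| > 10).  Replicates jitter
the default initial condition (0.4, 0.4, 0.4, 0.4) by ±0.05 under the
seed.  The heterogeneous regime keeps the first third of the series and
re-iterates the rest with Y2 and Y3 multiplied after each update by
i.i.d. Uniform(0.5, 1.0) attenuation factors, clipped to [0, 1].
Attenuation (multipliers ≤ 1) rather than symmetric noise is essential:
the coupled maps leave their feasible region when pushed upward, after
which clipping parks the species at the absorbing fixed point 0 and the
"weakened" regime would degenerate into extinction; any multiplier
ceiling above ~0.99 eventually triggers this.

**Lake-like generator.**  Root variables are phase-shifted sinusoids of
a configurable period (default 73 samples = one year at a 5-day step)
plus Gaussian noise; each child is a coefficient-weighted sum of its
lagged parents plus noise; the declared edges must form a DAG and are
returned as ground truth.  This fixture exercises the full pipeline —
seasonal synchrony produces a dense CCM network that the ECCM and DAG
stages must then prune — but it is linear apart from the shared
seasonality.

**What passing these tests does and does not show.**  The simulators
provide known causal structure, stationary sampling, no missing data and
no observation error.  Real monitoring data add irregular sampling,
measurement noise, regime shifts, aggregation over taxa and unobserved
confounders; recovery rates on the simulators are therefore an upper
bound on, not an estimate of, field performance.  Results on the
seasonal fixture in particular are dominated by how well the lag scan
separates shared seasonality from genuine coupling.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| window / gap | 100 / 10 samples | sliding-window CCM protocol |
| skill_min | 0.01 | minimum mean converged skill for an edge |
| min_windows | 10 | converged windows required per edge |
| split | 0.75 | chronological train fraction (CCM and BN) |
| surrogates / quantile | 1000 / 0.9 | phase-randomized significance test |
| ECCM frame / library / shifts | 400 / 200 / ±20 | lag-scan protocol |
| target quantile | 0.75 | bloom threshold for the binary target |
| probability cutoff | 0.5 | classification threshold in evaluation |
| scenarios | 20,000 | sensitivity permutation budget |

One global seed fans out to per-stage seeds through
`numpy.random.SeedSequence.spawn`; no stage consumes OS entropy, and a
fixed configuration and seed reproduce every artifact byte for byte.

## Problem sizes used in the validation suite

The shipped validation runs use 1000-step four-species series (20
homogeneous and 10 heterogeneous replicates), 400-point ECCM frames, a
200×200 surrogate calibration, and an 800-step lake-like fixture —
sizes at which every stage's behaviour (recovery rates, calibration,
determinism) is stable while the whole suite runs in minutes on a single
core.

## Known limitations

- The convergence criterion is this package's own operationalization;
  CCM literature offers no standard definition, and edge counts are
  sensitive to it.
- ECCM classification near the decision boundaries (similar-magnitude
  zero-lag peaks, shoulder peaks) inherits the ambiguity of the lag
  patterns themselves; the package resolves ties deterministically but
  cannot remove the underlying ambiguity.
- The surrogate test conditions on the cause's power spectrum only;
  nonlinear null structure (e.g. multiplicative noise) is outside its
  null class.
- The BN stage assumes the categorized, lag-aligned rows are i.i.d.
  draws from the conditional tables — temporal dependence within the
  training rows is ignored, as is feedback (removed at the DAG step).
- Categorization cutoffs (tertiles, 0.75 target quantile) materially
  affect CPTs; domain-specific thresholds, where known, should be passed
  explicitly.
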