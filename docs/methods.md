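# Methods

`dynafc` implements a multi-stage functional-connectivity analysis for
small pre/post treatment fMRI cohorts: temporal preprocessing of node
timeseries, static and dynamic connectivity estimation, connectome-based
predictive modeling (CPM) of behavior, and the univariate statistics used
to report treatment effects. A synthetic-cohort generator with recorded
ground truth makes every stage testable without access to patient data.

## Connectivity model

**Static FC.** For a cleaned T×N node matrix, the sFC matrix holds the
Fisher z-transform atanh(r) of the Pearson correlation between every node
pair. Perfect correlations (duplicated nodes) are capped at
atanh(0.999999) and flagged rather than propagated as infinities.

**Dynamic FC.** An edge's dFC is the sample variance over time of its
conditional-correlation path, estimated with the standard two-stage
dynamic conditional correlation (DCC) model:

1. Each node series (demeaned) is fitted with GARCH(1,1) by Gaussian
   quasi-maximum likelihood: σ²ₜ = ω + α ε²ₜ₋₁ + β σ²ₜ₋₁, with ω > 0,
   α, β ≥ 0, α + β ≤ 1 − 10⁻⁶, σ²₁ initialized at the sample variance.
2. For each node pair, the standardized residuals zₜ enter the DCC(1,1)
   recursion Qₜ = (1 − a − b)·S̄ + a·zₜ₋₁z′ₜ₋₁ + b·Qₜ₋₁ with Q₁ = S̄ (the
   residual sample correlation), ρₜ = Q₁₂,ₜ/√(Q₁₁,ₜQ₂₂,ₜ), and (a, b)
   maximize the stage-2 Gaussian quasi-likelihood.

Choices that were genuinely open, and how they were settled:

- **Bivariate per-edge DCC**, not one joint N-dimensional fit: correlations
  are estimated "for each edge", and the bivariate fit is tractable and the
  common practice at this dimensionality.
- **Gaussian innovations / quasi-likelihood**, the canonical two-stage
  estimator; the generator uses Gaussian innovations to match.
- **dFC variance on the raw ρₜ path**, not Fisher-transformed; the z
  transform is applied to sFC only.
- **Deterministic optimization**: constrained SLSQP from three fixed
  starting points per stage, best candidate kept; no random restarts, so a
  fixed input always yields the same fit.
- **Parsimony tie-break**: when candidates lie within 2 log-likelihood
  units of the optimum (roughly an AIC penalty for the two persistence
  parameters), the one with the smallest persistence sum wins. White noise
  leaves β unidentified and constant correlation leaves b unidentified;
  without the tie-break those directions drift to arbitrary values, with it
  they collapse onto the constant-variance / constant-correlation solution.
  Fits never fail hard: if no start converges, the constant-variance
  (GARCH) or constant-correlation (DCC) solution is returned flagged.
- **Degenerate edges** (|S̄| at the correlation cap, e.g. duplicated nodes)
  get a constant path, dFC 0, and a QC-table flag, so a full-connectome run
  survives pathological inputs.

Both recursions are evaluated as first-order IIR filters
(`scipy.signal.lfilter`), which is exact and fast; tests replay them with
naive Python loops and require agreement of the reported log-likelihood to
1e-6.

## Temporal preprocessing

Cleaning is a single least-squares projection: the design matrix stacks an
intercept, a linear trend, a cosine (DCT-II) basis column for every
frequency k/(2·T·TR) outside the 0.009–0.08 Hz pass band, any supplied
nuisance regressors (24 motion parameters and 5+5 tissue PCs in the
emulated design; their upstream computation is out of scope and they are
accepted as columns), and one indicator column per spike frame. A single
projection implements *simultaneous* bandpass filtering and nuisance
regression; scrubbing by spike regressors rather than frame deletion keeps
T constant for the DCC stage. Spikes are frames with |global-signal z| > 5
(scan's own mean/SD) or framewise displacement > 0.9 mm (both exclusive
inequalities at the printed thresholds). On 355-frame probes the projection
removes > 99.9% of stop-band power and keeps > 99% of mid-band power.

Parcellation averages voxels within a 10-mm sphere (Euclidean distance ≤
radius, continuous mm coordinates, no grid rounding) that pass a voxel
quality mask; per-node coverage is the passing fraction of in-sphere
voxels. A node is retained only if coverage ≥ 0.75 (inclusive) in *every*
scan. Nodes with no usable voxels yield NaN signal and coverage 0, never
silent zeros. Split-half reliability is the correlation across edges
between sFC computed on the two halves of a scan.

## Connectome-based predictive modeling

Within each leave-one-participant-out fold: edges whose Pearson
correlation with behavior passes p < threshold (two-tailed) are selected
and split by sign; the training-row feature is Σ(positive edges) −
Σ(negative edges); an OLS line maps the summary onto behavior; the model
predicts the held-out participant. Performance is the Pearson r between
observed and out-of-fold predictions. A fold selecting zero edges predicts
the training mean and is flagged. The sign-split *difference* summary is
the default (a two-predictor positive/negative variant is available via
`combine="two-predictor"`); sFC and dFC tables are concatenated without
rescaling in the "both" space because correlation-based selection is
scale-free. The threshold grid is 0.010–0.050 in steps of 0.005; ties for
the best model break toward the stricter threshold. Edges selected in ≥
75% of folds are the model's stable features. Node-subset models keep
edges with at least one endpoint in the subset.

`sign_reversal_report` compares, for edges stable in both the
baseline-predicting and the change-predicting models (each at its best
threshold), the dominant sign of the edge–behavior correlation in the two
directions. In the change direction the behavioral variable is the *signed*
change (post − baseline), matching how change is plotted against brain
features in this literature; `stats.delta_scores` separately provides the
improvement-positive convention (baseline − post) for clinical reporting.
An edge that is negatively related to the baseline score but positively
related to the signed change sits in a "reversed" cell: it marks
participants who start better but change less.

## Statistics

Paired t on differences d = pre − post (positive t = decrease =
improvement for symptom counts), df = n − 1, 95% CI of the mean
difference, and difference-score Cohen's d = t/√n — the only d definition
consistent with all printed (t, d) pairs at n = 20. One-way
repeated-measures ANOVA uses the within-participant decomposition, F =
MS_condition/MS_(condition×participant), df = (k−1, (k−1)(n−1)) with no
sphericity correction (printed dfs are uncorrected), and partial η² =
F·df1/(F·df1 + df2). The Bayes factor is the default JZS one-sample BF10
on difference scores with Cauchy prior scale √2/2, computed by adaptive
quadrature; tests cross-check it against a fine-grid trapezoid oracle and
`pingouin`. Listwise deletion handles missing timepoints.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: 24
participants by default (13 immediate / 11 delayed treatment), 355 TRs at
TR = 2 s, baseline and 1-week-post scans, integer behavior scores (a
HAMD-like depression scale, range 0–52, baseline mean 23; a PCET-like
perseverative-error count, range 0–30, baseline mean 14) at baseline, week
1 and week 4, plus a behavior-only pre-delay timepoint with zero planted
change for the delayed group (the practice-effect null check).

Node signals are GARCH(1,1) processes (defaults ω = 0.05, α = 0.10,
β = 0.85, unit long-run variance — persistence typical of slow BOLD
variance drift). Inactive node pairs share a constant background
correlation of 0.10; "active" edges (the treatment-target edge plus any
coupled edges) carry a DCC-generated correlation path whose deviations are
scaled by a per-participant amplitude (mean 1, SD 0.35 by default),
giving between-participant dFC heterogeneity with exactly recorded ground
truth: the true dFC of an edge is the variance of its recorded path. With
`amplitude_shared=True` all active edges share one per-participant
dynamics factor, emulating a node whose overall correlation dynamics scale
together. Innovations at each TR are drawn from the instantaneous
correlation matrix (eigenvalue-clipped to PSD; inert for node-disjoint or
single-node-star active sets such as the defaults).

Behavior scores are latent participant means (between-SD 4) plus
measurement noise (SD 4, implying test-retest r ≈ 0.5, configurable),
rounded and clipped to the instrument range. Planted treatment effects are
standardized against the pre/post difference SD (√2 × noise SD), so a
planted 0.8 is recovered as paired d ≈ 0.8. Baseline couplings add
sign × strength × standardized(feature) × between-SD score units to the
baseline score or to its change, where the feature is the participant's
true baseline sFC level (ρ̄) or dFC amplitude of a chosen edge.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamics and autocorrelated BOLD noise,
scanner drift and physiological artifacts, spatial structure beyond
spherical parcels, non-Gaussian innovations, heavy-tailed motion, item
structure of the behavioral instruments, and dropout mechanisms other than
listwise-deletable missingness.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make the statistical
properties sharp while keeping the full suite quick on a laptop: parameter
recovery at T = 2000 over 50 edges, ranking recovery over 20
graded-variance edges, CPM planted/null suites at n = 20 participants ×
200 edges with 50 replicates and 100 permutations, and the sign-reversal
cohort at 20 participants × 8 nodes × 355 TRs. Correlations are capped at
|r| = 0.999999 before atanh; dFC uses the ddof = 1 sample variance; all
randomness flows through `numpy.random.default_rng` seeds, and every
simulation, fit and CV routine is deterministic given its inputs.

## Known limitations

- At T = 355 (the emulated scan length), weak correlation dynamics are
  often indistinguishable from constant correlation, and the parsimony
  tie-break then reports dFC = 0; group-level dFC contrasts at this scan
  length need the planted dynamics to be moderately strong, which is a
  property of the method, not of the implementation.
- The DCC variant is the standard bivariate Gaussian two-stage estimator;
  toolbox-specific variations (targeting corrections, Student-t
  innovations) are not implemented.
- CPM here does not do nested tuning, external validation, or nonlinear
  models; the permutation null is the intended significance reference.
- The printed Bayes factors of the emulated study depend on its raw data
  and on the authors' (unnamed) BF implementation; only the JZS default is
  provided.
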