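# Methods

This note documents the models, conventions, and numerical choices behind
`netshift`, in the spirit of a package reference: what is computed, under
which assumptions, and where the genuinely open design decisions were made.

## Synthetic paired datasets

**Generative model.** Each subject contributes two multivariate Gaussian
time series (volumes × regions) drawn from target correlation matrices
with block structure: regions are partitioned into modules, within-module
correlations sit at `within_r` and between-module correlations at
`between_r`. White Gaussian draws with the target spatial covariance are
band-pass filtered (ideal frequency mask, 0.01–0.08 Hz at TR = 2 s by
default), which confines spectral content to the low-frequency range
typical of resting-state BOLD parcel signals while preserving the
cross-regional correlation structure in expectation. Pearson connectivity
of such data recovers the block structure, and proportional thresholding
of the block structure yields clustered, small-world-like graphs — the
regime the downstream analysis assumes.

**Defaults.** 36 paired subjects, 90 regions in standard AAL order, 230
retained volumes, TR 2 s, band 0.01–0.08 Hz, six contiguous modules of
fifteen regions, `within_r = 0.30`, `between_r = 0.05`. The module count
and correlation levels are this package's choice of a realistic operating
point: six modules echo the canonical large-scale system decomposition of
the cortex, 0.30/0.05 produce thresholded graphs whose clustering, path
length and small-world indices fall in the ranges typically reported for
parcel-level BOLD graphs at these costs (γ well above 1, λ near 1), and
the band-pass at 230 volumes leaves roughly 32 independent spectral bins,
so sample correlations carry realistic estimation noise (SE ≈ 0.11)
rather than being near-noiseless.

**Condition effects.** Condition B applies three perturbations to the
target matrix before sampling: `clustering_delta` (+0.10) on every
within-module correlation (drives the global clustering coefficient up),
`hub_delta` (+0.15) on all correlations of the hub node (region 24, right
superior medial frontal gyrus; drives degree centrality up), and
`degraded_delta` (−0.10) on all correlations of the degraded node (region
55, left fusiform gyrus; drives nodal efficiency down). Perturbed
matrices are repaired to positive definiteness by clipping eigenvalues
below 1e-8 and rescaling to unit diagonal — minimal, deterministic, and
structure-preserving; the emitted matrix is verified to have smallest
eigenvalue above 1e-10.

**Pairing.** Between-subject variation enters as Gaussian jitter of the
two target correlation levels on the Fisher-z scale (SD 0.10), keyed by
subject only and therefore shared between a subject's two conditions: the
pre-noise target matrices of conditions A and B differ exactly by the
implanted effects. The jitter SD is a free knob controlling test–retest
similarity, not an estimate of any empirical quantity; 0.10 makes
between-subject variance comparable to the sampling noise of a single
session.

**Behavior.** Four neuropsychological scores (DST, NCT-A, LTT, SDT) are
generated per condition as
`baseline + shift·[condition B] + coupling·(metric − mean) + noise`, with
baselines and condition shifts matching the rested-wakefulness summary
statistics and observed shift directions of the emulated design (DST
falls under deprivation; the three timed tests slow). The coupled metric
is a noiseless surrogate for the subject's clustering level (the mean
within-module target correlation), so metric–behavior correlations emerge
through the shared subject jitter; couplings are sized to yield moderate
(|ρ| ≈ 0.3–0.4) correlations at n = 36. Ages are normal(32, 4.3)
truncated to [26, 42]; sex is Bernoulli with the emulated cohort's male
fraction (21/36).

**Reproducibility.** All randomness derives from one master seed through
`numpy.random.SeedSequence` streams keyed by purpose and subject index:
identical configurations reproduce datasets bit for bit, and extending
the cohort never changes earlier subjects' draws.

**What the generator does not emulate.** No hemodynamic response,
head-motion or physiological artifacts, no spatial autocorrelation beyond
the block structure, no heavy-tailed marginals, and no empirically
calibrated test–retest reliability. Passing tests therefore demonstrate
that the pipeline recovers implanted effects of known size from data with
its assumed statistical structure — not performance on real fMRI.

## Connectivity

Pearson correlation of every pair of regional time series; zero-variance
regions are rejected by name. The Fisher transform z = arctanh(r) is
applied off-diagonal; the diagonal of z is fixed at 0 and excluded from
every analysis (arctanh(1) diverges). The seed-based contrast is
expressed at parcel level — the seed row of each subject's z matrix,
compared between conditions per target with the routed paired test and
BH-FDR across the 89 targets. This is a deliberate simplification of the
voxelwise seed analysis such studies usually report: voxel data are out
of scope, and the parcel-level contrast carries the same design. Region
indexing is 1-based atlas order in every user-facing interface; zero
difference vectors receive p = 1 (conservative, keeps FDR well defined)
rather than NaN.

## Graph construction and metrics

**Thresholding.** At cost s, the top `round(s·R(R−1)/2)` upper-triangle
entries by |z| are retained (half-to-even rounding at exact ties of the
edge-count arithmetic, so 0.10·4005 = 400.5 yields 400 edges). Ties in
|z| at the cut break deterministically: larger |z| first, then (row,
column) lexicographic order. Binary mode sets retained entries to 1;
weighted mode keeps |z| and normalizes by the maximum retained weight
inside the metric kernels.

**Binary metrics.** Clustering per node is 2tᵢ/(kᵢ(kᵢ−1)) via diag(A³),
zero when kᵢ < 2; Cp is the mean over all nodes. Shortest paths come from
`scipy.sparse.csgraph`; Lp averages finite off-diagonal distances only,
reporting the number of excluded (disconnected) ordered pairs, while all
efficiency metrics use the 1/∞ = 0 convention and are therefore
insensitive to disconnection. Local efficiency of node i is the global
efficiency of the subgraph induced by its neighbors (0 when kᵢ < 2).

**Weighted metrics.** Onnela clustering (geometric mean of normalized
triangle weights), inverse-weight shortest-path distances for Lp and the
efficiencies, strength (sum of normalized weights) for degree. With all
weights equal, every weighted metric reduces to its binary counterpart.

**Hierarchy.** The exponent b of c ∝ k^(−b), from the least-squares slope
of ln cᵢ on ln kᵢ over nodes with kᵢ ≥ 2 and cᵢ > 0 (at least three such
nodes and non-constant ln k required; otherwise the metric is undefined
and the error names the offending sparsity). Reported positive for
descending curves. The eligibility rule exists because ln 0 is undefined;
the log–log regression convention is this package's choice.

**Null models.** γ, λ, σ normalize by the means of degree-preserving
Maslov–Sneppen rewired ensembles: 100 nulls by default, 10·E swap
attempts each, rejection of swaps that would create self-loops or
multi-edges. Nulls achieving zero swaps (a star graph admits none) are
flagged and excluded; an all-failed ensemble is an error. Weighted
networks rewire their binary pattern and shuffle the retained weights
among the rewired edges, preserving the degree sequence and the weight
distribution. The rewiring was cross-checked against networkx's
implementation (ensemble clustering means agree within Monte-Carlo
error). Null-normalized metrics are meaningful only when nulls can carry
triangles; on very small or very sparse graphs (tens of edges) ensemble
mean clustering can be zero and the indices are undefined — the package
raises rather than reporting a vacuous γ.

**AUC.** Trapezoidal integration of each metric curve over the cost grid
(13 points at 0.10–0.22 step 0.01; the extended range 0.05–0.25 gives
21). AUC is linear in the curve, and a constant curve v integrates to
0.12·v over the primary grid.

## Statistics

Shapiro–Wilk on the paired differences routes each comparison: p ≥ 0.05
keeps the paired t test, otherwise (or for constant differences) the
Wilcoxon signed-rank test. The Wilcoxon convention is: zero differences
dropped, tie-corrected normal-approximation variance, no continuity
correction — deterministic and consistent with the z magnitudes such
studies print. Effect sizes are dz = t/√n and r = z/√n with the sign of
the B−A direction; their 95% CIs use dz ± 1.96·√(1/n + dz²/2n) and
r ± 1.96/√n truncated to [−1, 1] — normal-theory constructions chosen
because no standard exact form exists for paired designs; the point
estimates, not the CIs, are the quantities validated against external
references. BH-FDR is applied within each nodal metric (m = 90) and
within the seed-contrast target family (m = 89); global metrics and
behavior correlations are reported uncorrected and flagged exploratory,
matching the reporting convention of the emulated design. Spearman
correlations carry Fisher-transform CIs with SE 1/√(n−3). Regression is
ordinary least squares with an intercept; standardized betas come from
the z-scored refit, tolerance is 1 − R² of each predictor on the others,
VIF = 1/tolerance, and sex is coded 0/1 (F/M). Everything is two-tailed
at α = 0.05.

## Pipeline and problem sizes

`run_full` executes the primary analysis (binary, 0.10–0.22) plus two
robustness variants (binary over 0.05–0.25; weighted over 0.10–0.22),
reusing each subject's z matrix across variants, and emits
schema-stable CSV tables plus a JSON provenance record (config hash,
seed, version). Identical config and seed reproduce every table byte for
byte, independent of thread count.

The simulation harnesses — effect recovery (50 replicates) and null
calibration (200 replicates) — restrict each replicate to the metrics
under test (Cp and degree AUCs, no null ensembles), which keeps a full
calibration run to a few minutes on one CPU; this is a metric-subset
feature of the sweep, not an approximation, since neither harness tests a
null-normalized quantity. Measured operating characteristics at the
default conditions: type-I error of the Cp comparison 0.03 (200 null
replicates), recovery of the implanted clustering increase and of the hub
node's first-place degree ranking 50/50 replicates each — both recomputed
by `scripts/acceptance.py` and the acceptance test suite on every run.

## Known limitations

Voxel-level analyses (cluster inference, MNI coordinates) are out of
scope; the seed contrast is parcel-level. Weighted-mode values depend on
the maximum-weight normalization convention and are comparable only
within that convention. The hierarchy exponent is sensitive to the
eligibility rule on sparse graphs. The behavior generator couples all
four tests to a single clustering surrogate rather than to
test-specific circuits. CI constructions for effect sizes are
approximate normal-theory forms.
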