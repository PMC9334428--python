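# Methods

## The agreement index as an inter-subject synchronization measure

A voxel observed in M subjects over n volumes forms an n×M matrix X.
Two moment summaries drive everything:

* **S** (M×M) — the zero-lag cross-covariance of subject time courses
  over time; its off-diagonal mass measures pairwise synchronization.
* **V** (n×n) — the covariance of time rows across subjects; its total
  mass reflects between-subject differences in mean intensity.

Both use population-style divisors (S over n, V over M).  With these
divisors the agreement index

    Â = (M/(M−1)) [1'S1 − tr S] /
        { 1'S1 [ 1 + (n−1)Γ/(n(M−1)) − (M/(n(M−1)))·tr S/1'S1 + 1/(n(M−1)) ] }

with Γ = (1'V1/n²)/(1'S1/M²) is *exactly* the two-way random-effects
ICC(2,M) of the classical ANOVA decomposition (time points as targets,
subjects as raters), and the consistency index

    Ĉ = (M/(M−1)) (1'S1 − tr S)/1'S1

is exactly ICC(3,M).  This exact identity (verified to 1e-10 in the
test suite across n ∈ [10, 240], M ∈ [2, 49]) is why the divisor
convention is not negotiable: sample (count−1) divisors break it.

Ĉ is invariant to adding a constant to any subject's series; Â is not.
The gap is governed by Γ, estimated consistently by the ratio of the
mean element of V to the mean element of S, through

    Â ≈ Ĉ (M−1)/((M−1)+Γ) + O(1/(nM)).

Both indices range over (−∞, 1]; negative values are reported as-is,
never truncated.

## Asymptotic variance and the half-vectorization calculus

Under strict stationarity and ρ-mixing of the time courses, sample
covariances are asymptotically normal and the delta method gives

    Var(Ĉ) = (2/n) η' K_M (Σ⊗Σ) K_M' η,   evaluated at Σ = S,

where η is the derivative of ICC(C,M) with respect to vech Σ and K_M
maps vec to vech.  **Reading of K_M.**  Two standard matrices satisfy
vech Σ = K_M vec Σ: the 0/1 elimination matrix and the Moore–Penrose
inverse of the duplication matrix G_M.  They are *not* interchangeable
inside this quadratic form.  This package uses the Moore–Penrose
inverse, because only that choice reproduces the standard asymptotic
covariance of sample covariances, Cov(s_ij, s_kl) ≈ (σ_ik σ_jl +
σ_il σ_jk)/n, and collapses the formula to the equivalent closed form

    Var(Ĉ) = (2/n) tr(D Σ D Σ),   D = ∂Ĉ/∂Σ = c(tr Σ · J − 1'Σ1 · I),
    c = M/((M−1)(1'Σ1)²),

which needs only M×M products — no M²×M² Kronecker product is ever
materialized, keeping whole-brain maps at M = 49 cheap.  The dense
elimination/duplication route is retained as a test oracle.  Monte
Carlo calibration (5000 Gaussian replicates, n = 240, M ∈ {5, 10},
compound-symmetric correlations 0–0.6) agrees with this variance
within ~6%; the literal-elimination reading is off by a factor up to 2.

The agreement variance uses the shrinkage factor implied by the
approximation above,

    Var(Â) ≈ Var(Ĉ) ((M−1)/((M−1)+Γ))²  ≤ Var(Ĉ),

with the population ratio evaluated at the sample Γ, and the
standardized value is t_Â = Â/√Var(Â).  Variances that come out
negative by more than 1e-12 raise an error rather than being clamped;
within that tolerance they are set to 0.

## Surrogate null and weak FDR

The null hypothesis is absence of *inter-subject* synchronization, not
absence of temporal structure.  Fourier phase randomization respects
that: each subject's series keeps its amplitude spectrum (hence mean,
variance, and autocorrelation up to circularity) while phases of the
non-DC bins are redrawn independently per subject and voxel.  For even
n the Nyquist bin is real; its sign is randomized so surrogates stay
real.  Recomputing t_Â over 50 surrogate replicates and pooling across
in-mask voxels yields one brain-wide null distribution — pooled rather
than voxelwise because 50 values per voxel cannot support 0.1% tails.
Empirical p-values use the add-one rule p = (1+r)/(1+N) so p > 0.

Thresholding uses the Benjamini–Yekutieli step-up with
C(K) = Σ_{i≤K} 1/i, valid under arbitrary dependence between voxels
("weak" control).  The implementation is the explicit step-up (largest
rank i with p_(i) ≤ (i/K)·α/C(K), ties at the boundary all rejected)
and is cross-checked against statsmodels' `fdr_by` in the tests.

A known small-sample caveat, quantified in the tests: the surrogate Â
of voxels whose power concentrates in a few low-frequency bins carries
a negative ratio bias of order −0.01 to −0.02 at the default fixture
SNR.  It biases the null conservatively (the pooled tail still
dominates inference).

## Stationarity screen

KPSS (regression with deterministic trend; null = trend-stationarity)
and ADF (constant only, AIC lag selection; null = unit root) run per
voxel and subject.  Note the asymmetry this implies: a deterministic
trend is *stationary* for the trend-including KPSS but looks like a
unit root to the constant-only ADF — the two tests answer different
questions and are reported side by side, not combined.  A voxel counts
as consistently nonstationary when KPSS rejects in at least
ceil(f·M) subjects (f = 0.5/0.6/0.7 reported), optionally after
per-subject weak-FDR correction across voxels, which can only lower
the proportion.  The ρ-mixing diagnostic reports, per lag υ, the max
over (voxel, subject) of |corr(X_k, X_{k+υ})|; for mixing data it
decays to a max-statistic floor (the max of many near-zero sample
correlations is well above zero — ~0.3 for thousands of series of
length 240 — so the profile flattens rather than reaching 0).
Screening is reported, never used to excise voxels from the maps.

## ROI clustering

Supra-threshold voxels are averaged per ROI per subject.  ROIs whose
supra-threshold intersection has fewer than 4 voxels are dropped:
such remnants are usually FDR false positives and are too small for
the homogeneity split.  An ROI carrying two response shapes (checked
by K-means with K = 2 on z-scored voxel mean series) is split into two
sub-ROIs when the mean Silhouette width is ≥ 0.5, the bottom of the
"reasonable structure" band.  Group-level mean series are z-scored and
clustered by multi-restart (100) K-means over K = 2..6, keeping the K
with the largest mean Silhouette.  Z-scoring makes Euclidean distance
behave like a correlation (shape) distance, so clusters are response
types, not amplitudes.  Identical series raise an error instead of
returning an arbitrary K.

## Connectivity and cortisol

Pairwise connectivity is the Pearson correlation of subject-level mean
series over a window (full scan, or one 120-volume condition block),
Fisher Z-transformed and standardized as z·√n_window — the
1/√n-convention, deliberately not the Fisher-exact 1/√(n−3).  Group
significance per pair is a one-sample Student t on the subjects' Z
values with weak FDR over the single family of all pairs.  Temporal
autocorrelation makes √n an optimistic scale for any single subject's
z, but inference runs on between-subject variability, which is
unaffected.  Z values are averaged per subject within left/left,
right/right and mixed pair scopes (entries without an L/R label are
excluded); scope summaries are related to pre-/post-scan cortisol by
partial correlation controlling age, sex, trait anxiety (STAI-Trait)
and stress-symptom score (SQ-ISMA) — state anxiety is excluded by
default — with p from t on N−2−c degrees of freedom.

## Synthetic data

The generator reproduces the study conditions the analysis assumes:
n = 240 volumes at TR = 2 s, eyes-closed onset at volume 1, eyes-open
onset at volume 121, default M = 10 subjects on a 12×12×8 grid
(~1.1k voxels, sized for minutes-scale test runs; larger grids and
M up to 49 are supported).  A block atlas assigns four bilateral ROIs
to each of three response networks (positive-transient,
negative-transient, limbic-biphasic) and leaves the midline slab null.
Voxel series are

    offset(subject, voxel) + amplitude(subject, network)·template + AR(1) noise,

with offset sd 0.5 (this drives Γ > 0, separating Â from Ĉ), subject
amplitudes N(1, 0.3²), AR(1) coefficient 0.3 and unit innovations.
Templates are difference-of-exponentials bumps after each onset
(eyes-open bump twice the eyes-closed bump, decayed by 60 s) and, for
the limbic-biphasic type, a slow decline through the closed-eyes block
followed by a short dip and sustained rise after eyes open.  Every
template is normalized to unit temporal sd so `response_amplitude`
reads directly as shared-signal SNR and no response type dominates the
pooled surrogate null.  The default 0.45 was chosen so that (i) the
planted networks are recovered essentially perfectly by the full
pipeline, and (ii) the surrogate-Â ratio bias of strongly structured
series stays within ±0.02.  Both properties hold jointly over 20
seeds in the acceptance suite.

What the generator does *not* emulate: hemodynamic convolution,
cardiac/respiratory noise, head motion, scanner drift, and spatial
noise correlation beyond ROI-constant signals.  Passing tests
therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to real acquisition artifacts.

Cortisol simulation draws demographics with cohort-typical moments,
builds pre-scan cortisol as covariate effects plus a connectivity
summary plus noise scaled to hit a target partial correlation
(default 0.5), and couples post-scan to pre-scan cortisol at r = 0.417.

## Problem sizes and numerical choices

Default test/acceptance sizes: 2000-voxel global-null datasets and the
12×12×8 fixture, 50 surrogates, 20 replicate datasets/seeds; the
Monte-Carlo variance calibration uses 5000 replicates.  The pipeline's
stationarity screen subsamples to 200 voxels by default
(`stationarity_max_voxels`; set to None for all voxels) — the screen
is a diagnostic summary and ~2000 KPSS+ADF fits characterize it well.  The vectorized
map path (`icc_map`) computes S via a batched einsum and 1'V1 through
the identity 1'V1 = (n²/M)·Σ_i (colmean_i − grand mean)², avoiding the
n×n matrix entirely; it returns NaN for degenerate voxels so one bad
voxel cannot kill a whole-brain run, while the scalar path raises
typed errors.  Symmetry is enforced by averaging (A+A')/2; PSD checks
use 1e-8 relative tolerance.  Determinism: every stochastic step takes
a seed or Generator; the pipeline derives stage streams from one
master seed, and identical config + seed reproduces byte-identical
TSV outputs.

## Known limitations

* The surrogate null assumes (trend-)stationary, mixing series; the
  screen reports violations but nothing is excluded automatically.
* The pooled null trades voxelwise exactness for tail resolution; a
  voxel with an atypical spectrum is judged against the brain-wide
  null.
* Student's t on Fisher Z treats subjects as exchangeable; no
  mixed-effects or robust variants are provided.
* ADF acceptance is reported descriptively only; no aggregation rule
  is applied to it.
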