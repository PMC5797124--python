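# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic cohorts do and do not emulate, and the known
limitations of the package.

## Motion quantification and exclusion

Framewise displacement is the sum of absolute backward differences of the
six rigid-body parameters; rotational differences are converted to mm as
arc length on a sphere of radius `rotation_radius_mm` (default 50 mm, the
convention of the displacement-based scrubbing literature).  Passing a
radius of 0 sums the raw angular values instead, reproducing the bare
six-term formula for pipelines that report it that way.  FD of the first
volume is defined as 0 so censor masks align with the time grid.

Both thresholds are strict: a volume is censored when FD *exceeds* 0.5 mm,
and a run is excluded when the censored count reaches the smallest integer
*strictly greater* than 9% of the run length — 16 volumes for a 176-volume
run (the same limit whether computed on 176 retained or 180 acquired
volumes, which is why the ambiguity is harmless).

## Nuisance regression

All nuisance terms are removed in one regression per subject: Legendre
trends of orders 0–3, sine/cosine pairs at every DFT frequency of the run
outside the 0.01–0.1 Hz retention band (the regressor formulation of a
band-pass filter), six demeaned motion parameters and their backward
differences, tissue signals (white matter, ventricle), and optionally the
FEF mean signal.  Implementing the band-pass as regressors rather than a
filter is what makes censoring clean: censored volumes are simply omitted
from the least-squares fit (row deletion, not zero-weighting or
interpolation), and the residuals carry NaN at censored positions so that
downstream correlations drop them pairwise.  At 176 volumes and TR 2 s the
band-stop set alone has 111 columns and the full design ~130, leaving
~45 residual degrees of freedom per subject — the standard cost of
regression-based band-passing, and the reason estimability is checked
against the uncensored row count with the design condition number reported.

One consequence worth knowing: the generator's shared signal has some power
below 0.01 Hz, so full preprocessing attenuates pairwise correlations
relative to the raw-coupling oracle (≈ 0.26 observed vs 0.36 generated for
adults in the default cohort).  Tests that check the c_i·c_j oracle
therefore run on scaled-but-unfiltered data; the end-to-end acceptance
script reports the honest post-filtering values.

## Pairwise inter-SC

Per node, Pearson correlation between every subject pair over the volumes
kept in *both* subjects (pairwise-complete deletion — unbiased for r, at
the cost of slightly varying pair sample sizes, which are recorded).  Pairs
with fewer than `min_pair_volumes` (default 100 of 176) usable volumes are
flagged and propagate as missing, never as zeros.  Correlations are mapped
to Fisher z = atanh(r); |r| ≥ 1 − 1e-12 is clipped first because the mixed
model requires finite responses, and clipped pairs are flagged.

## The crossed random-effects model

A pairwise matrix violates independence: z_ij and z_ik share subject i.
The model

    z_ij = x_ij'β + a_i + a_j + e_ij,   a ~ N(0, τ²),  e ~ N(0, σ²)

absorbs that shared-subject covariance.  In matrix form V = σ²(I + λ ZZ')
with λ = τ²/σ² and Z the pair-by-subject incidence (two ones per row; for
child-to-adult blocks, two separate factors with one membership each and
V = σ²(I + λ_c Z_cZ_c' + λ_a Z_aZ_a')).

Estimation is profile REML over λ.  The Gram matrices ZZ' are symmetric
and, for the designs used here (a single factor, or a complete crossed
block), jointly diagonalizable; the solver eigendecomposes them once per
incidence structure and every per-node fit then reduces to scalar
reweighting inside a 1–2 dimensional bounded optimization.  Non-commuting
structures (incomplete crossed blocks) are rejected explicitly rather than
approximated.  σ² is profiled out analytically; λ is bounded at the zero
boundary, where the variance is pinned and the fit flagged.

The symmetric matrix is conventionally listed with both triangles so the
subject factor is balanced.  Duplicated rows carry no information, so the
fitter collapses them to unique unordered pairs before estimating;
doubled-triangle and single-triangle inputs give bit-identical estimates
and standard errors (fitting duplicates as independent data would halve the
standard errors).  The whole path is verified against an independent
dense-covariance REML oracle (explicit V, generic optimizer) to 1e-6 in
fixed effects and log-likelihood.

### Degrees of freedom

t statistics use Satterthwaite denominator df computed from the REML
information matrix of (σ², τ²_k) by the delta method, in closed form on the
eigenbasis.  For a balanced child × adult block the age-slope df lands on
the classical value C − 2 (44 for 46 children) exactly; intercept df track
the subject count, not the pair count, and can sit a few percent below
N − 1 depending on the realized τ²/σ².  When a variance component is pinned
at zero the information matrix is unreliable and the df falls back to the
conservative value min_k(n_subjects_k) − rank(X).

### Model builders

- *Within-group*: intercept-only over one group's pairs; the intercept is
  the group-average synchrony, also reported on the r scale via tanh.
- *Group contrast*: within-A plus within-B pairs with a ±½ affiliation
  code (β_affiliation = A − B) and a single subject factor spanning both
  groups.  Mixed (A, B) pairs are excluded by default — the contrast
  compares within-group synchrony levels — but can be included as a third
  affiliation level.
- *Child-to-adult age*: the child × adult block with crossed child and
  adult random intercepts and centered child age in months as the fixed
  effect of interest.  A constant age column raises an estimability error.

The calibration property that motivates all of this is tested directly:
under nulls with subject effects present, the crossed-RE group test holds
its 5% level (empirical type-I error ≈ 0.05 over 500 replicates) while a
naive independent-pairs t-test rejects at ≈ 0.4.

## Surface smoothing and cluster inference

Node areas are barycentric (one third of each incident triangle), an exact
partition of the total surface area.  Smoothing is an iterated
nearest-neighbor diffusion x ← (1−α)x + αWx with W the row-normalized
adjacency; α and the iteration count are calibrated so a delta function
spreads with the per-axis variance of a Gaussian of the requested FWHM
(σ² = FWHM²/(8 ln 2); one step adds ≈ α·E[edge²]/2 per tangent axis on a
2-D manifold).  The operator is linear and constant-preserving, and the
measured FWHM of a smoothed delta on a 1 mm grid is within a few percent of
target.  Accuracy degrades when the FWHM is less than ~2–3 edge lengths —
the regime coarser than any sensible analysis mesh (the 7 mm kernel on a
~1 mm FreeSurfer-density mesh is comfortably fine; a 3 mm toy grid is at
the edge).  Toy planar grids are triangulated with alternating diagonals;
a fixed diagonal direction would make diffusion anisotropic (dx–dy
correlation 0.5) and visibly narrow the kernel's axis profile.

Clusters are maximal connected components of supra-threshold nodes
(p < threshold, strict) under shared-edge adjacency, with component area
the sum of member node areas and an extent filter in mm².  Labeling is
verified against a union-find oracle on random Delaunay meshes.

Familywise-error control follows the Monte Carlo logic of the reference
pipeline with one structural change: null maps are generated directly on
mesh nodes (i.i.d. standard normal, smoothed at the analysis FWHM,
re-standardized per map) rather than in a voxel volume projected to the
surface, since no volume grid exists here.  This is an approximation — it
sets the null smoothness purely by the kernel, without any contribution
from intrinsic data smoothness; a smoothness-matching knob is available via
the config FWHM.  Because thresholds and their evaluation use the same
generative procedure, the realized familywise error is controlled by
construction (measured ≈ 0.05 on fresh nulls).  Primary thresholding is
two-sided on |z|.  The extent threshold is the conservative
next-order-statistic quantile: with the n null maxima sorted ascending,
the order statistic of rank floor((1−α)n) + 1.  Stricter nodewise p gives
smaller extents (e.g. 72 vs 30 mm² at p < .05 vs p < .01 on the test mesh),
the same ordering as the 315/150 mm² pairing used at full mesh scale.

## Synthetic cohorts

Subject i at node v is generated as

    y_iv(t) = c_iv · s_v(t) + sqrt(1 − c_iv²) · ε_iv(t)

- s_v: white Gaussian noise convolved with a temporal Gaussian (FWHM ≈ 3
  TRs, mimicking hemodynamic smoothness), standardized; shared by all
  subjects.
- ε_iv: a mixture of an idiosyncratic smooth signal (fraction
  `idiosyncratic_frac`, default 0.3) and AR(1) noise (lag-1 correlation
  0.3), orthogonalized against s_v per node and standardized — so the
  composite has exactly unit variance and the expected pairwise Pearson
  correlation is exactly c_iv·c_jv, the closed-form oracle used throughout
  the tests.
- c_iv: group coupling in the effect nodes (defaults 0.6 adult / 0.4
  child), `baseline_coupling` 0.4 elsewhere, plus 0.002/month × centered
  age for children in effect nodes, plus a per-subject spread
  (`coupling_subject_sd`, default 0.04).  The subject spread is what gives
  the cohort genuine crossed random effects at the ISC level; without it
  (and with noise orthogonalized against the shared signal) the pairwise
  matrix would be nearly independent across pairs and REML would correctly
  pin τ² at zero.  Its default is set below the group contrast (0.2 in
  coupling units) and comparable to the age-span effect (0.06), which
  makes the age effect reliably sign-recoverable but not overwhelming —
  the strength regime the method is designed for.  Realized couplings are
  recorded in the truth table, so the oracle remains exact under the
  spread.

Default cohort structure: 23 / 23 / 21 subjects (child4 / child6 / adult),
176 volumes at TR 2 s, child ages in two narrow bands (mean ± sd of
53.3 ± 3.5 and 78.6 ± 3.6 months; a uniform-age option covers the 48–84
month range).  Motion traces are slow random walks (translation step sd
0.03 mm, rotation 3e-4 rad) producing mean FD ≈ 0.14 mm, with transient
spikes of 0.6–1.2 mm injected at a rate of `motion_spike_rate`·n/2 so the
expected fraction of FD > 0.5 mm volumes matches the configured 5%.
Spikes affect only the motion parameters unless
`couple_spikes_to_signal` is set, which adds a large artifact to all nodes
at spike volumes for scrubbing-efficacy experiments.  Nuisance signals
(white matter, ventricle, FEF) are independent smooth noise; they exercise
the regression machinery but do not contaminate the data by default, so
removal neither helps nor hurts the oracle.

What the generator does **not** emulate: hemodynamic forward modeling (no
HRF convolution of event streams, no balloon model), volumetric imaging
and projection, spatially correlated noise across nodes, distance-dependent
motion artifacts, or heavier-tailed physiological noise.  Passing tests
therefore demonstrate the statistical machinery under the generative
assumptions — correct bookkeeping, calibrated inference, recoverable
effects — not robustness to every artifact of real EPI data.

## Numerical conventions

- Fisher clipping bound 1 − 1e-12 before atanh; round-trip tanh∘atanh is
  exact to 1e-14 over |r| ≤ 0.95.
- REML optimizer: bounded scalar search (single factor) or multi-start
  L-BFGS-B polished by Nelder-Mead (two factors), λ ∈ [0, 1e4]; the zero
  boundary is always evaluated explicitly.
- Constant responses short-circuit to the exact least-squares solution with
  zero variances (flagged) rather than failing in the log-likelihood.
- Residual orthogonality to the design is < 1e-8 (relative) on uncensored
  volumes; the regression matches an independent QR oracle to 1e-10.
- Degenerate meshes: smoothing on a disconnected mesh proceeds per
  component with a warning; isolated nodes keep their values.

## Problem sizes

Test and acceptance runs use toy meshes (4–256 nodes) with the full
study-sized cohort (67 subjects, 176 volumes), 500-replicate calibration
and null-threshold simulations, and 20-seed recovery sweeps; these sizes
give Monte Carlo standard errors comfortably inside the asserted bands
while keeping the suite fast.  All heavy linear algebra is shared: one
eigendecomposition per incidence structure serves every node's fit.

## Known limitations

- Incomplete child × adult blocks (missing pairs) with two random factors
  are not supported by the fast solver (non-commuting Gram matrices); rows
  with flagged pairs are dropped, which re-creates completeness in
  practice, and a genuinely incomplete design raises a clear error.
- The Monte Carlo null lacks a data-driven smoothness estimate (see above);
  on real data the extent thresholds should be interpreted relative to the
  chosen kernel.
- Satterthwaite df at the τ² = 0 boundary uses a deliberately conservative
  fallback rather than the OLS residual df.
- The per-node models are independent across nodes (as in the reference
  analysis); no spatial regularization is attempted.
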