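# Methods

This note records the models, numerical choices and known limitations of
`chromdecon` in the package's own terms. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Data model and I/O

A chromatogram is a dense scan-time × m/z matrix on a unit-spaced integer
m/z grid (default 50–450, the full-scan range of a quadrupole EI
instrument), with times in minutes throughout. ANDI/AIA netCDF files are
netCDF-3 classic, read and written with `scipy.io.netcdf_file`; sparse
per-scan centroid lists are binned by rounding m/z to the nearest integer
and summing collisions, which conserves total ion current exactly and
matches unit-mass library search. Negative raw intensities are clamped to
zero with a logged count, since every downstream step assumes non-negative
counts. MSP libraries follow the NIST text dialect; every spectrum is
normalized to base peak 999 on load (idempotent).

## Synthetic data generator

`simulate` produces chromatograms as sums of Gaussian elution peaks
(unit-area in time, so `amount` is the chromatographic area) outer-multiplied
with base-peak-normalized spectra, plus a constant baseline and i.i.d.
Gaussian noise clamped at zero. Defaults emulate a quadrupole full-scan
acquisition: 3.6 scans/s, m/z 50–450. Signal-to-noise is specified the way
chromatographers measure it — peak apex height over the noise SD of the TIC
trace; with J channels the per-cell noise SD is apex/(SNR·√J). Overloaded
matrix interferents can be approximated by wide, high-amount components with
flat-top clipping at a saturation level.

What the generator deliberately does not model: peak tailing (an
exponentially-modified-Gaussian option exists in the truth type but is off
by default), matrix-induced signal enhancement, drifting baselines, and
spectral skew across a peak. Passing tests on this generator therefore
demonstrate correctness of the deconvolution and identification machinery
under idealized peak shapes, not robustness to every instrumental artifact.

## Pseudo-replicate augmentation

Member k+1 of a replicate set is `shift_rt(multiply(original, m_k), d_k)`:
multipliers nominally in [0.5, 1.5] (values outside warn rather than fail —
documented usage includes factors near 2) and signed retention offsets in
[−0.003, 0.003] min. At 3.6 scans/s one scan is ≈0.0046 min, so these
offsets are sub-scan: the shift is realised by translating the signal and
resampling onto the original scan grid with per-channel linear
interpolation (edge values held), keeping all members co-registered for
cube construction. Interpolation conserves peak areas to <0.1 % but
attenuates ℓ2 norms by up to ~1.5 % at half-scan offsets; this is why
amount recovery is exact for multiplier-only sets and accurate to ~1 % once
shifts are included. The optional denoising filter is Savitzky–Golay
(window 5 scans, order 2) per m/z channel, clamped at zero; it reproduces
polynomials up to degree 2 exactly.

## Intervals

Retention intervals are half-open [start, end) in minutes so that tiling
configs partition every scan exactly once; overlapping configs are accepted
only behind an explicit flag (re-covering an unresolved region in several
intervals is a legitimate strategy when neighbouring compounds share
near-identical spectra). `suggest_intervals` is advisory: it places
boundaries at the deepest mean-TIC valleys (a valley must dip below at
least one neighbour; a flat TIC falls back to equal-width tiling). The
canonical path is a manually curated config.

## PARAFAC2 fitting

The direct-fitting parameterization X_k ≈ P_k H diag(c_k) Sᵀ with
orthonormal P_k is used throughout; elution profiles are B_k = P_k H and
satisfy the constant-cross-product constraint exactly in every reported
model. Non-negativity on S (spectra) and C (amounts) is imposed by
non-negative least squares; all NNLS subproblems are reduced through the
Gram/Cholesky identity to R×R active-set solves, with rows whose
unconstrained optimum is already feasible skipping the solver.

**Why the elution mode is constrained too.** A pseudo-replicate set scales
every component of member k by one multiplier, so C is rank one by
construction. Under the classic model (free H) any invertible non-negative
mixing W of the spectral columns can be absorbed: S→SW, H→HD W⁻ᵀ D′⁻¹, with
identical fit. The data cannot prefer pure spectra — unless elution
profiles are required to be non-negative, because mixing spectra forces
compensating negative elution contributions exactly in the scan regions
where only one compound elutes. The default path therefore:

1. seeds per-member profiles from the R purest m/z channels (greedy
   SIMPLISMA-style selection: purity = std/(mean + 3 % damping offset),
   weighted by the channel's norm orthogonal to already-chosen channels);
2. runs a flexible-coupling ALS, minimizing
   Σ_k‖X_k − B_k diag(c_k)Sᵀ‖² + μ‖B_k − P_kH‖² with B_k ≥ 0 and μ ramped
   geometrically (factor 1.03 per sweep, up to 1000 sweeps, initialized at
   the misfit/coupling ratio) until the profiles sit on the PARAFAC2
   manifold;
3. finishes with the exact-constraint ALS holding H frozen (Procrustes
   updates of P_k, NNLS updates of S and C). Freezing H matters: a free-H
   polish re-opens the rotational valley and drifts back toward mixed
   spectra.

This path is deterministic (no random start); multi-start best-of-SSE is
deliberately *not* applied here because mixed solutions can undercut pure
ones by a few parts in 10⁶ of SSE (they soak interpolation error), so an
SSE tie-break would systematically select the wrong basin. The classic
fit — SVD-seeded start plus seeded random restarts, best SSE, non-negativity
on S and C only — remains available as
`FitSettings(nonneg_elution=False)` and is the right choice for genuine
replicate injections whose amounts vary independently per component.

Convergence: relative SSE change below 1e-8 per sweep, at most 50,000
sweeps. SSE is tracked through the orthonormal-basis identity
‖X_k − P_kM_k‖² = ‖X_k‖² − ‖Y_k‖² + ‖Y_k − M_k‖², and the finish-stage
history is monotone non-increasing. Scale indeterminacy is fixed by
normalizing the columns of S and H to unit length and absorbing magnitude
into C.

## Core consistency

CORCONDIA is evaluated on the PARAFAC representation implied by PARAFAC2:
slabs Y_k = P_kᵀX_k with CP loadings (H, S, C).

* Sample mode informative (σ₂/σ₁ of C above 1e-3): the standard
  computation — least-squares Tucker core G via mode-wise pseudo-inverses,
  compared with the superdiagonal target, 100·(1 − ‖G−T‖²/R).
* Sample mode rank-one by design (pseudo-replicates): the standard core is
  undefined along C's null directions, and in floating point the diagnostic
  explodes to large negative values for *correct* models. The diagnostic is
  then computed on the sample-collapsed bilinear representation: project
  the Y_k onto the leading sample direction, form G₂ = H⁺ Ȳ (S⁺)ᵀ,
  normalize each column by its sample-loading norm, and compare with the
  identity. Components with numerically zero sample loadings cannot
  reproduce their superdiagonal entry and count as full misses, preserving
  overfactoring sensitivity: fitting R = 3 to one-component data yields
  values far below 90 (collapsed dead components give ≈33; duplicated
  components drive the informative-branch value strongly negative).

The two branches agree in behaviour wherever both are defined; for R = 1
the value is exactly 100 at any ALS fixed point (optimal per-component
scale). Values are capped above by 100 and may be negative.

## Model selection

Per interval, R sweeps 1–7 (configurable; badly overloaded peaks can need
more) and the smallest R passing all rules is chosen: fit > 90 %, core
consistency > 90, converged ALS, and balanced residuals. "Low residuals"
is operationalized as no member exceeding 3× the median member residual
norm — applied only when the total residual exceeds 0.01 % of the data,
since an essentially exact fit's leftover structure is numerical, not
chemical. Parsimony (smallest passing R, not best fit) is deliberate:
overfactoring splits genuine spectra. Baseline components are flagged when
the elution profile is nearly constant (coefficient of variation < 0.2) or
when ≥50 % of spectral intensity falls on configured background ions
(defaults 207/281/355, the common siloxane/column-bleed fragments); both
thresholds are configurable.

## Match factors

The forward match factor is the squared weighted cosine on the union
integer m/z grid with Stein–Scott identity-search weights m¹·I^0.5, scaled
to 0–999 and rounded. The reverse match factor applies the same score after
deleting query peaks at m/z absent from the library entry, so RMF ≥ MF
always. These scores follow the published weighting but are not the
proprietary composite of commercial library software, so absolute values
differ from vendor outputs; the 0–999 scale and quality bands carry over
(≥900 excellent, 800–900 good, 700–800 fair, <600 very poor; the unnamed
600–700 band is labelled "poor" here by convention). Ties in library
ranking break by RMF, then library order, for determinism.

## Aggregation

AMF/ARMF are per-compound means of MF/RMF across replicate analyses,
rounded half-up to integers. Study totals are means over compounds with at
least one hit; the ARMF−AMF difference is computed on the *unrounded* means
and rounded last (rounding the totals first can shift the difference by one
unit). The packaged 40-compound reference table reproduces, via exactly
this arithmetic, study totals of 874 (standard mixture) and 786 (pooled
real samples), a standard-mixture ARMF−AMF difference of 43 (and 62 for the
real samples), a minimum standard AMF of 664, and an 85 % share of standard
AMF values above 800. Two real-sample rows of the published table (Aldrin,
Chlorpyrifos) have ARMF < AMF; the package's own aggregation can never
produce that (it inherits RMF ≥ MF), so those rows are treated as data
facts, not invariants.

## Problem sizes

The validation scenario used by tests and the acceptance script is a
0.4 min run at 3.6 scans/s (86 scans × 401 m/z), a five-member set, and a
14-scan × 401-channel interval cube around the co-eluting pair — small
enough for exhaustive sweeps while exercising every code path at realistic
peak widths and scan rates.

## Known limitations

* Pseudo-replicates carry no new chemical information: amounts recovered
  from them estimate the applied multipliers, not independent
  concentrations, and compounds co-eluting with *identical* spectra remain
  unresolvable (as they are for any bilinear method).
* Spectral recovery accuracy degrades when true spectra share most of
  their fragment ions (the non-negativity cone then has width at the
  truth); the disjoint-spectrum tests are the sharp case.
* The match engine is scale-faithful but not numerically identical to
  proprietary search software; per-compound scores from other tools should
  not be compared to it at single-digit precision.
* Elution peaks are modelled per interval; compounds whose peaks straddle
  an interval boundary should be covered by overlapping intervals, which
  the config supports behind the explicit flag.
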