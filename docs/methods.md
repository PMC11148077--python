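# Methods

This note records the models implemented in `qmripls`, the conventions
and defaults chosen where several were defensible, and what the synthetic
phantoms do and do not establish about real data.

## MPM map estimation

**Signal model.** Each multi-echo FLASH train decays as
S_c(TE) = S0_c·exp(−R2\*·TE) with one effective transverse rate R2\*
shared across the three contrasts (T1w: TR 18 ms, FA 20°, 6 echoes
TE 2.16–14.81 ms; PDw: TR 27 ms, FA 6°, 8 echoes 2.04–22.20 ms; MTw:
TR 27 ms, FA 6°, 6 echoes 2.04–14.89 ms).  The joint log-linear fit
(ESTATICS) estimates per-contrast TE = 0 intercepts and the shared R2\*;
a single reweighting pass with weights equal to the squared predicted
signals ("WLS1") restores the efficiency the log transform loses at low
SNR.  Feeding R1/MTsat computation with TE = 0 intercepts rather than
echo averages removes R2\*-weighting bias from those maps.

**R1 and amplitude.** The spoiled steady state
S = A·sin α·(1−E1)/(1−cos α·E1), E1 = e^(−TR·R1), is inverted through its
small-angle rational approximation S ≈ A·α·TR·R1/(α²/2 + TR·R1), giving
the closed form R1 = ½(S_T1·α_T1/TR_T1 − S_PD·α_PD/TR_PD)/(S_PD/α_PD −
S_T1/α_T1) with α the B1-scaled flip angle; A follows by back-substitution.
The closed form is verified against direct root-finding of the 2 × 2
system in the test suite.  Over R1 ∈ [0.5, 1.2] s⁻¹ at the study's
TR/FA the approximation error is < 2% (measured ≈ 1.4% worst case).

**MTsat.** δ = (A·α_MT/S_MT − 1)·R1·TR_MT − α_MT²/2, reported ×100 in
percent units, with the empirical transmit-field correction
δ_corr = δ(1−C)/(1−C·f), C = 0.4 (configurable).  Noiseless round trips
recover δ to ≈ 1% (< 5% bound) across δ ∈ [0.005, 0.02].

**B1+ mapping.** Double-angle method at 60°/120°:
f = arccos(clamp(S_2α/2S_α)) / α_nominal, then a 3-D polynomial surface
of total degree 6 is least-squares fit to the raw map within the mask and
evaluated everywhere — polynomial smoothing suppresses the noise
amplification of the arccos at f ≈ 1.

**PD.** The amplitude map is scaled so its white-matter mean equals
69 p.u. (consistent with a pontine mean of ≈ 68.8 p.u. in the emulated
cohort).  Receive-field correction is assumed done or uniform; the
calibration target is a parameter.

## NODDI forward model and dictionary fit

Three compartments: Watson-dispersed sticks (intra-neurite, fraction
f_ic of the tissue), an axially symmetric extra-neurite tensor with
tortuosity coupling d⊥ = d∥(1−f_ic), and an isotropic ball (free-water
fraction f_iso).  Diffusivities are fixed at the canonical
d∥ = 1.7 µm²/ms, d_iso = 3.0 µm²/ms; ODI = (2/π)·arctan(1/κ).  Watson
averages use a deterministic 1000-point Fibonacci sphere; the Watson
normalization uses the same quadrature, so S(b=0) = 1 holds exactly and
the forward model is reproducible bit-for-bit.

The volume fit is dictionary-based in the spirit of AMICO: per voxel, the
neurite axis is taken from a DTI log-linear fit restricted to
b ≤ 1000 s/mm² (sign convention +z, falling back — flagged — to the
mean-signal gradient direction for degenerate tensors), a 12 × 12
(f_ic × ODI) lattice of tissue atoms plus one ball atom is assembled, and
non-negative least squares with a Tikhonov penalty λ on the weights is
solved.  NDI and ODI are weight-weighted lattice means; FW is the ball's
weight share.  Because every compartment is axially symmetric, each
atom's signal depends on the gradient only through (b, |g·μ|); atoms are
tabulated once per scheme on a 129-point |g·μ| grid and interpolated per
voxel, which makes the volume fit ≈ 1 ms/voxel.  An exact (quadrature)
dictionary path exists for verification; with the true orientation
supplied, on-lattice voxels are recovered to machine precision.

**Choice of λ.** λ defaults to 1e-4 on unit-normalized signals.  The
non-negativity constraint already regularizes strongly; a larger ridge
(1e-3) measurably biases the weighted-mean ODI (errors up to 0.11 on
noiseless off-lattice voxels, beyond one lattice spacing) while buying no
accuracy at SNR 30.  With 1e-4, noiseless off-lattice recovery is within
0.06 for ODI and 0.02 for NDI, and median errors at Rician SNR 30 are
≈ 0.02–0.05.

**Known limitation.** In nearly isotropic voxels (high ODI, low f_ic)
the per-voxel direction estimate is noisy and dispersion is
systematically overestimated under noise — a generic property of
orientation-dispersion estimation at low anisotropy.

## Region and voxel preprocessing

Probabilistic atlases are thresholded inclusively (prob ≥ thr; LC 10%,
VTA 25%, NbM 60%, pontine 50%) — the inclusive boundary makes behavior
deterministic where an atlas stores the threshold value exactly.  The
dorsal-raphe fallback ROI is a 3-mm sphere at MNI (0, −30, −13) built
from voxel centers through the grid affine (123 voxels on a 1-mm grid);
the published trimmed variant (~32 mm³) is not reproducible because its
trim shape is unpublished, so the pure sphere is the default and any
exclusion mask can be supplied.  The group white-matter mask keeps voxels
present in ≥ 95% of subjects (inclusive).  Voxelwise confound removal
regresses each voxel column on [1, age, 4 pontine MPM means, 3 pontine
NODDI means] by OLS; residuals come back mean-centered (harmless — PLS
z-scores columns), are exactly orthogonal to the covariates, and the
operation is idempotent.  Smoothing (σ = FWHM/√(8 ln 2), default FWHM
1 mm) follows residualization and renormalizes kernel mass over in-mask
voxels, so constants are preserved up to the mask edge.

## PLS correlation

Blocks are z-scored per column (SD with n−1), within group when a group
label is supplied.  Conditions (and groups) are stacked on the behavior
side — one shared voxel-salience map per LV with per-condition behavior
saliences, the only arrangement consistent with reporting per-condition
design-score contributions against a single voxel map per LV.  Sign
convention: each (u_l, v_l) pair is flipped so the largest-magnitude
voxel salience is positive; signs of downstream betas inherit this
convention and only magnitudes are comparable across runs.

*Permutation:* subject rows of the behavior block are permuted (within
group) against all conditions jointly; p_l = (#{s_l^perm ≥ s_l^obs}+1)/
(n_perm+1) — the add-one rule never returns zero.  Permuted singular
values come from eigenvalues of R·Rᵀ (exact, and much cheaper than a full
SVD when p ≫ rows); no procrustes alignment is applied inside the
permutation loop, which compares raw singular values (flagged in the
result metadata since toolboxes differ here).

*Bootstrap:* subjects are resampled with replacement (within group);
each resample's SVD is aligned to the original by the orthogonal
procrustes rotation of its U onto the original U — without alignment,
axis swapping between close LVs inflates the salience SD, which a
dedicated test demonstrates.  BSR = original salience / bootstrap SD
(±inf at zero SD, always suprathreshold); behavior-correlation CIs are
2.5/97.5 percentiles of corr(behavior, brain score) across resamples.
Resamples with < 3 distinct subjects (or a zero-variance column) are
redrawn and counted.  Reliable-voxel masks keep |BSR| > 2, label positive
and negative voxels separately with 26-connectivity, and drop clusters
< 32 voxels.  Condition contributions sum |behavior saliences| per
condition (signed sums could cancel).

## Downstream statistics

Partial correlations residualize both variables on [1, covariates] and
test r with t = r√(df/(1−r²)), df = n−2−k.  A variable whose residual
variance is numerically zero (fully explained by the covariates) yields
r = 0 rather than a spurious correlation of float noise.  Brain-score ~
biomarker regressions z-score all continuous variables (score, biomarker,
education) and keep sex binary, so the biomarker coefficient is a
standardized β; p-values are Bonferroni-corrected over m = 2 biomarkers
per score.  Age is never a covariate here because the voxel maps feeding
the scores were already age-residualized.  The CSF–MRI delay enters both
candidate models as a main effect; the biomarker × delay interaction is
kept only if it strictly lowers the AIC.

## The phantom: what it emulates and what it does not

The generator reproduces the *structure* of the cohort analysis:
n = 133 subjects by default; 16 nucleus metrics with the cohort's
per-nucleus means and SDs (e.g. LC R1 0.61 ± 0.03 s⁻¹); three voxelwise
condition maps on a 24 × 24 × 12 analysis grid (p = 6912, matching the
scale at which cluster logic is meaningful while staying desk-fast);
orthonormal smooth salience patterns; subject-level covariates (age
67.9 ± 5.3 y, 29% male, education 15.4 ± 3.5 y, positive CSF–MRI delays);
a pTau181 analog linearly linked to latent 2 and an independent Aβ42
analog; APOE4 carrier labels (fraction 50/132) with optional per-group
loading scales; and a native-space brainstem slab carrying exact
per-subject MPM truth in five disjoint ROIs, from which raw FLASH, DAM
and multi-shell DWI signals are simulated (Rician noise as magnitude of
complex Gaussian).

Condition maps are built as baseline + 0.1 × (Σ_l strength·z·vᵀ + noise)
and clipped to [0, 1]; the affine map into physical NODDI units is
immaterial to every correlation-based statistic, and with the default
scale the clip almost never binds (clipping, when forced by extreme
settings, slightly attenuates planted effects).  Default per-voxel noise
is 0.5 standardized units and behavior noise 0.5, giving metric–latent
correlations ≈ 0.4 — the magnitude of the cohort's reported bars.
Planted strengths ([[24, 3], [6, 12], [1, 0.5]] for NDI/ODI/FW × latent)
put the two planted singular values ≈ 3× above the random-matrix noise
edge at n = 150, p ≈ 6.9k, with a ≈ 2× gap between them: recoverability
of *each* latent (not just their span) requires separated singular
values, echoing the cohort's separated covariance shares (26.9% vs
10.2%).

Not emulated: spatial registration error, motion, susceptibility
distortion, bias fields, within-nucleus covariance beyond what the
shared latents induce (the source analysis reports none), non-Gaussian
biomarker distributions, and any spatial autocorrelation of the noise
(saliences are smooth; noise is white).  Passing recovery tests
therefore shows the *estimators* are correct under the stated model, not
that the acquisition-side pipeline stages excluded here are harmless.

## Problem sizes and determinism

Everything is a deterministic function of integer seeds.  The test suite
and acceptance script run the study-scale analyses at n = 150/p = 6912
(planted recovery, 20 seeds), 200 null replicates at n = 60/p = 1000 with
200 permutations, 100-voxel dictionary-recovery sweeps, and a full
133-subject end-to-end command-line run — sizes chosen so the complete
verification fits comfortably on a single desktop CPU core.
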