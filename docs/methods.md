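# Methods

## Dual regression

A subject's BOLD data are treated as an N-voxels × T-timepoints matrix
`Y`; the template networks as an M × N matrix `S` (used unthresholded —
the templates' scale is common to all subjects and cancels in group
comparisons). Stage 1 solves `Y = S' B_tc + E1` by pseudoinverse,
`B_tc = pinv(S') Y`, yielding one timecourse per network; stage 2 solves
`Y' = B_tc' B_sm + E2`, `B_sm = Y pinv(B_tc)`, yielding the
subject-specific spatial maps. Stage 2 always uses all M timecourses
jointly: the multivariate fit is what disentangles overlapping networks,
and it is never replaced by one-network-at-a-time regressions.

**Design normalization.** The stage-1 timecourse amplitudes
`a_i = std(B_tc[i])` differ across subjects, so raw stage-2 coefficients
are each estimated on a subject-specific scale. Dividing each timecourse
by its amplitude before stage 2 (`B_sm* = Y pinv(A⁻¹ B_tc)`,
`A = diag(a_i)`) puts every voxel and every subject in units of signal
change per unit standard deviation of the network timecourse. Raw `B_sm`
maps are algebraically invariant to any network-wide rescaling of a
timecourse (the amplitude cancels between the two stages), so they cannot
detect amplitude differences; worse, a node-level (within-network)
amplitude change rescales the shared timecourse and thereby shifts the
raw coefficients of *unaffected* voxels, mislocalizing the effect.
`B_sm*` is therefore the default statistic for group-level use; raw maps
require an explicit flag and emit a warning. The exact column identity
`B_sm* = B_sm · A` holds for any full-rank design and is enforced by
test.

**Demeaning.** Both stages mean-center the data (per voxel over time) and
the regressor columns (maps over voxels; timecourses over time). The
regression equations carry no intercept; centering the regressors makes
the fit orthogonal to the constant direction, which is equivalent to an
intercept and makes all coefficients invariant to voxelwise mean offsets.
The simulator adds a constant offset of 1000 to every voxel precisely to
exercise this path.

**Numerical choices.** Solutions use the SVD pseudoinverse with singular
values below `max(dim) · eps · s_max` treated as zero; a design whose
numerical rank is below M raises an error naming the most collinear
components rather than silently returning a minimum-norm solution, since
pinv on collinear templates mislocalizes connectivity. Amplitudes use the
sample standard deviation (divisor T−1) everywhere; the convention
cancels in all ratio-type results but must be single. A constant
(zero-amplitude) timecourse is an error: it cannot be normalized.
Voxel flattening is Fortran-order (first image axis fastest) through one
shared routine, so maps and data can never be misaligned; voxel
coordinates are 0-based indices, and world coordinates pass through
headers untouched.

## Cohort simulator

The simulator emulates a two-group resting-state study with known ground
truth. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| grid | 24 × 24 × 16 voxels, 3 mm | desk scale; all reported effects are coefficient ratios, hence grid-size-free |
| networks | 8 flat-top blob maps (MVN, LON, AUD, SMN, DMN, ECN, RFPN, LFPN roles) | flat weight 1 makes coefficient ratios directly interpretable |
| subjects | 18 per group | two-group design, df = 34 |
| timecourses | T = 178, TR = 2 s, band-limited 0.01–0.1 Hz | standard low-frequency resting-state regime |
| network amplitude | per subject ~ Uniform(0.8, 1.2), matched across groups | see below |
| noise | Gaussian, std 0.5 per voxel per timepoint | contrast-to-noise placing stage-1/ground-truth correlations near 1 |
| mean offset | 1000 everywhere | exercises demeaning only |

The DMN analog has four disjoint nodes so a "PCC" node exists; the ECN
analog has a large frontal blob plus a small basal-ganglia/thalamus node,
keeping the shape-swap region a minor fraction of the network, as it is
in real network maps. Timecourses are synthesized in the frequency
domain (independent complex Gaussian coefficients in the band, zero DC),
with the worst-correlated row redrawn until all pairwise |r| < 0.3.
Every draw flows from one seed; cohorts rebuild bit-identically.

Three manipulations are applied to Group B, all in a single default
cohort: (i) the MVN timecourse × 1.1 (network-wide amplitude), (ii) the
timecourse used at the DMN's PCC-node voxels × 1.5 (within-network
amplitude), (iii) the ECN's basal-ganglia node keeps its map weight but
receives the LFPN timecourse (shape swap; the donor timecourse is not
normalized, so a small residual amplitude difference accompanies the
shape change).

**Matched amplitudes.** Ground-truth network amplitudes vary across
subjects (needed for the amplitude-recovery slope to be a regression, and
a real feature of resting data), but the same set of amplitude draws is
assigned to both groups (subject i of each group shares one draw, with
independent timecourse realizations). With independent draws an 18-vs-18
split can produce an incidental multi-percent group amplitude difference
in an unmanipulated network; design-normalized maps would then correctly
report that real difference network-wide, confounding specificity checks
against the injected effects. The matched design encodes the study
condition that non-manipulated networks show no group amplitude
differences, so the injected manipulations are the only systematic group
effects.

**What the simulator does not model:** hemodynamic convolution,
physiological noise, head motion fields, and spatial variability of
network location across subjects. Passing tests therefore demonstrate the
estimator's algebraic and inferential behavior under the stated
spatiotemporal model, not robustness to misregistration or
subject-specific network topography.

## Group inference

Voxelwise unpaired pooled-variance t statistics (df = n_A + n_B − 2;
zero-pooled-variance voxels score t = 0, a common occurrence in synthetic
backgrounds) are converted to z by quantile matching
`z = Φ⁻¹(F_t(t; df))`, evaluated through the lower tail of |t| for
numerical stability. Clusters are the 26-connected components of
{z > 2.3}; cluster mass is Σz over members (an excess-mass variant,
Σ(z − threshold), is available behind a flag). Both one-sided contrasts
are tested at the stated level with no cross-contrast correction, and no
variance smoothing is applied.

The corrected p-value of each observed cluster is the fraction of
group-label permutations whose *maximum* cluster mass meets or exceeds
the cluster's mass, with the observed labeling always counted as one
permutation — the (1+b)/(1+m) convention, guaranteeing p ∈ (0, 1]. When
the number of distinct labelings C(n, n_A) is no larger than the
requested count the null is enumerated exactly; otherwise labelings are
sampled without replacement from a seeded generator. Cluster labeling is
deterministic: descending mass, ties broken by lowest peak-voxel index.

## Quality control

Stage-1 timecourses are the recommended place to catch motion that
mimics amplitude effects. The QC module tabulates per-subject
per-component amplitudes (same estimator as the regression module),
correlates timecourses against external references such as motion
parameter traces, and flags spikes by robust z-score
(median / 1.4826·MAD, cutoff 5 by default) — robust centering because a
spike inflates the ordinary standard deviation it would otherwise be
tested against. No automatic exclusion is applied: thresholds on motion
summaries are user policy.

## Problem sizes used in the shipped checks

The shipped tests and the acceptance script run the full default cohort
(36 subjects, N = 9216 voxels, T = 178) with 1,000 label permutations
for cluster inference, and calibrate the family-wise error rate over 200
null cohorts of 10 subjects on a 10 × 10 × 6 grid with exact enumeration
of the 252 labelings. These sizes were chosen so the whole pipeline —
simulation through corrected inference — reruns from scratch in minutes
on one CPU while keeping every quantity at its full-study interpretation
(all reported effects are ratios or p-values, not grid-dependent
magnitudes).

## Known limitations

* Templates are inputs; no group ICA estimation is provided.
* No preprocessing (motion correction, smoothing, filtering,
  registration): data are assumed analysis-ready and voxel-aligned to the
  templates.
* Two-group designs only; no covariates, F-tests, TFCE, or voxelwise
  FWE/FDR modes.
* Amplitude and shape effects cannot be disambiguated from `B_sm*` alone;
  that is a property of the method, not of this implementation.
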