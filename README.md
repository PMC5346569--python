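# dualreg

Dual regression for group analyses of resting-state functional
connectivity, with design normalization, a ground-truth cohort simulator,
and permutation cluster-mass inference.

## Who this is for

Resting-state fMRI studies commonly derive a set of group-level network
templates (e.g. from a group ICA) and then need subject-specific versions
of each network — both its *shape* (which voxels co-fluctuate) and its
*amplitude* (the standard deviation of its BOLD timecourse) — to compare
groups or conditions. `dualreg` implements the two-stage dual-regression
procedure for that purpose, emphasizing the normalization step that makes
the subject maps valid in the presence of amplitude effects, and ships a
simulator with known ground truth plus nonparametric group inference so
the whole pipeline can be validated end to end.

## The model

Let `S` (N voxels × M components) be the unthresholded template maps and
`Y` (N voxels × T timepoints) one subject's BOLD data.

**Stage 1 — spatial regression.** The network timecourses are the
multivariate least-squares solution

    B_tc = pinv(S) Y            (M × T)

Each row is that subject's timecourse for one network, after partialling
out all other networks. Its standard deviation `a_i = std(B_tc[i])` is the
network's amplitude; `A = diag(a_1, …, a_M)`.

**Stage 2 — temporal regression.** The subject-specific spatial maps are

    B_sm  = Y pinv(B_tc)        (N × M, raw coefficients)
    B_sm* = Y pinv(A⁻¹ B_tc)    (N × M, design-normalized)

Dividing each stage-1 timecourse by its amplitude before stage 2
("design normalization") yields semi-standardized coefficients in units of
signal change per unit standard deviation of the network timecourse.
`B_sm*` — and only `B_sm*` — retains network-wide amplitude information
and correctly localizes within-network amplitude effects (including
motion-induced ones), so it is the default group-level statistic here;
raw `B_sm` maps are produced only on explicit request and with a warning.

Group comparisons use voxelwise unpaired t-tests converted to z, clusters
formed at Z > 2.3 under 26-connectivity, and family-wise-error-corrected
cluster p-values from the permutation null distribution of the maximum
cluster mass (sum of z over the cluster).

Both stages mean-center data and regressors (the standard dual-regression
convention), data are 2-D matrices over a fixed voxel flattening (first
image axis fastest), and outputs follow the FSL `dr_stage1_subject#####.txt`
/ `dr_stage2_subject#####.nii.gz` naming so they drop into existing
toolchains.

## Worked example

```python
import numpy as np
from dualreg import DualRegression, GroupDesign, TwoGroupPermutationTest
from dualreg.simulate import simulate_cohort, synthesize_subject

cohort = simulate_cohort(seed=1)          # 18 + 18 subjects, 8 networks
results = [
    DualRegression(synthesize_subject(cohort, i), cohort.maps).fit(design_norm=True)
    for i in range(cohort.n_subjects)
]

# amplitude recovery for the network with a 10% Group-B amplitude boost
mvn = cohort.maps.component_names.index("MVN")
b = cohort.subjects_in_group("B")
truth = np.array([cohort.timecourses[i][mvn].std(ddof=1) for i in b])
rec = np.array([results[i].amplitudes[mvn] for i in b])
print(f"slope: {truth @ rec / (truth @ truth):.4f}")

# group inference on the within-network (node) manipulation
dmn = cohort.maps.component_names.index("DMN")
test = TwoGroupPermutationTest(
    [r.maps for r in results], GroupDesign(labels=cohort.group_labels)
).fit(component=dmn, n_perms=1000, cluster_z=2.3, seed=1)
print(test.summary())
```

This prints `slope: 1.1015` — stage 1 recovers Group B's injected 10%
network-wide amplitude boost as a slope of ~1.1 between recovered and
ground-truth timecourse standard deviations — and a cluster summary whose
only significant cluster (B > A, 33 voxels, corrected p = 0.001)
coincides with the node whose timecourse was multiplied by 1.5:

```
Two-group permutation test (component 4)
  groups: A (n=18) vs B (n=18), df=34
  cluster-forming Z > 2.3, mass = sum(z), 1000 permutations
  181 supra-threshold cluster(s), 1 significant at corrected p <= 0.05
  * B>A      cluster 1: 33 voxels, mass 212.6, peak z 6.84 at (11, 9, 10), corrected p = 0.001
```

The same pipeline is available from the shell: `drtool simulate`,
`drtool dualreg`, `drtool glm`, `drtool qc` (see `drtool --help`).

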