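# Methods

This note documents the models, conventions, and design choices behind
`boldgraph`, and what its synthetic-data tests do and do not establish about
real data.

## Synthetic BOLD model

ROI time series are drawn from a zero-mean stationary Gaussian AR(1) process:
innovations at each time step carry cross-ROI covariance `(1 − φ²) Σ`, and
`x_t = φ x_{t−1} + e_t` with `x_0 ~ N(0, Σ)`. Because spatial mixing and
temporal autocorrelation factorize, the stationary cross-ROI covariance equals
the target `Σ` exactly, which keeps the ground truth analytic: the expected
Fisher-z difference between groups on a planted edge is exactly the planted
`Δz` (up to the positive-definiteness repair below).

The target correlation matrix is block structured: `r_within` (default 0.3)
inside a functional network, `r_between` (default 0.05) across networks —
magnitudes typical of empirical resting-state ROI correlations. Group
differences are planted symmetrically on the z scale (`±Δz/2` around the
baseline) on chosen edges. After editing, the matrix is repaired to a valid
correlation matrix by clipping eigenvalues at 1e-6 and rescaling to unit
diagonal; the *realized* post-repair `Δz` per edge is recorded in the ground
truth so recovery tests compare against what was actually planted. Arbitrary
edge edits can otherwise break positive definiteness.

Defaults mirror the emulated study design: 17 + 18 subjects, 330 recorded
volumes at TR = 1.46 s (10 dropped, 320 usable), AR coefficient 0.3 (a
mid-range value for bandpassed BOLD at this TR), unit voxel noise. ADHD score
distributions default to patient 35.82 (SD 10.58) / control 26.11 (SD 7.65)
for the ADHD-RS-IV and 96.82 (42.15) / 64.17 (23.21) for the ASRS; age is
drawn independently of group (matched design) and gender is Bernoulli(½)
per subject.

Motion traces are a small-amplitude random walk (translation steps SD
0.01 mm, rotation steps SD 2×10⁻⁴ rad) whose framewise displacement is kept
strictly below 0.4 mm, plus Poisson-count sustained steps of 0.7–1.2 mm that
exceed the 0.5 mm scrubbing threshold exactly at their injection index. Spike
steps are signed toward zero cumulative offset so several spikes do not drift
a subject across the 2.5 mm whole-run exclusion limit by construction —
exclusion still occurs when the walk plus spikes happen to exceed it.

What the generator does **not** emulate: hemodynamic response shape, scanner
drift and physiological noise spectra, spatial autocorrelation beyond ROI
blocks, anatomy, or inter-subject variance in connectivity beyond sampling
noise (all subjects in a group share one covariance). Passing recovery tests
therefore demonstrates correctness of the estimators and calibration of the
permutation procedures under the stated model — not robustness to the many
nuisance structures of real BOLD.

## Preprocessing conventions

Stage order: drop initial volumes → nuisance regression (6 motion parameters
+ WM + CSF + intercept) → spatial smoothing → temporal bandpass → scrubbing.
Regression-before-filtering is enforced and covered by a regression test; the
two orders do not commute.

- Framewise displacement is the Power convention: sum of absolute backward
  differences of the six rigid-body parameters, rotations converted to arc
  length on a 50 mm sphere. FD(0) = 0 so vector lengths stay aligned.
- Scrubbing censors strictly `FD > 0.5` mm, plus 1 volume before and 2 after,
  clipped at the series boundaries; censored volumes are deleted, not
  interpolated, and downstream correlations use the shortened series.
- The bandpass default is a zero-phase (forward-backward) order-4 Butterworth,
  0.01–0.08 Hz; an ideal FFT brick-wall filter is available as a dialect.
  Correctness is defined by gain contracts (≥ 0.9 at 0.05 Hz, ≤ 0.1 at
  0.2 Hz for TR 1.46 s), not by filter coefficients.
- Constant confound columns are dropped (they duplicate the intercept); any
  other rank deficiency is an error naming the collinear columns.
- Subject exclusion: any translation > 2.5 mm or rotation > 2.5° relative to
  the first volume.

## Degree centrality and ReHo

Degree counts **positive** suprathreshold correlations only (r > 0.25), the
one-sided reading of the binarization rule; an absolute-value mode exists
behind a flag. The "z-transform" of a degree map is standardization across
in-mask voxels within subject (population-SD convention), the imaging-toolbox
convention — Fisher-z of a count is not meaningful.

ReHo uses Kendall's W over a voxel and its cubic neighborhood. The default
neighborhood is 27 voxels (center + 26): the commonly cited "24 neighbors"
matches no standard 7/19/27 scheme and is treated as a configurable choice
rather than silently mapped to one. Ties get midranks; the tie-correction
term of W is off by default (continuous data make ties measure-zero) but
available. At mask edges the neighborhood shrinks to its in-mask members;
voxels with fewer than 2 members are marked invalid and excluded from the
whole-brain normalization mean.

## Group inference

The voxel-wise model is OLS per voxel on (intercept, group, age, gender);
the group-coefficient t is reported with its model df (n − 4). With 35
subjects this gives df = 31; published tables in this literature sometimes
print df = 33 (the covariate-free value) — the package always reports the
model-implied df.

Cluster correction: the reference analyses in this literature use
random-field-theory "topological FDR" (SPM). RFT smoothness estimation is
deliberately out of scope; the package substitutes a permutation
cluster-extent null (group labels permuted, covariates fixed; the full
GLM + clustering pipeline rerun per permutation; maximal extent over both
tails recorded) with BH applied across the observed clusters of both tails.
This changes the calibration mechanism, not the structure of the claim; the
null simulation in the test suite verifies the realized family-wise rate.
Cluster connectivity defaults to 18 (face + edge), the SPM convention; the
two contrast directions are analyzed as separate one-sided cluster sets at
cluster-defining p = 0.001. Permutation p-values use the `(1 + b) / (1 + B)`
convention, so they live in `[1/(1+B), 1]`.

Gender enters as one binary column; education is assumed matched by design
and not modeled.

## Network analysis and NBS

Edge-wise tests are plain pooled-variance two-sample t tests on Fisher-z
values, df = n₁ + n₂ − 2, **without** covariates — deliberately inconsistent
with the voxel-wise GLM, mirroring the analysis convention this pipeline
emulates (its reported edge df equals the covariate-free value). NBS
permutations relabel groups only.

`|r|` is capped at 1 − 10⁻⁷ before atanh so degenerate correlations stay
finite. The NBS primary threshold is specified on the p scale (default
two-sided 10⁻⁴) and converted to a |t| cutoff at the pooled df; each tail
(increases, decreases) is analyzed separately. Component extent is the edge
count; the FWER p-value of a component is the `(1+b)/(1+B)` tail probability
of its extent under the permutation distribution of the maximal extent, the
+1 standing for the observed labeling. The permutation loop uses a
group-sum formulation evaluated by blocked matrix products, so study-scale
problems (392 ROIs ≈ 77k edges, thousands of permutations) run in seconds
without materializing a permutation × edge matrix of unbounded size.

Calibration and discreteness: NBS is a permutation test, so it never exceeds
its nominal family-wise level, but at a very sparse primary threshold (the
analysis default, two-sided 10⁻⁴) the null suprathreshold graph of a
100-ROI problem is almost always empty and the maximal-extent statistic
nearly degenerate — the realized null rejection rate is then far *below*
0.05 (strong conservatism), which is a property of extent-based inference,
not a fault. The null-calibration experiment therefore uses a denser
suprathreshold graph (primary p = 0.005) so that the realized rate is
informative in both directions, and measures the sparse-threshold regime
separately.

Known behavior at high node counts: because all edges incident to one ROI
share that ROI's subject-level fluctuations, the null distribution of the
maximal component extent develops "chance hubs" — at 392 nodes, null maxima
of ~5 edges are common. A 5-edge planted component at Δz = 0.5 is then
recovered exactly but sits near the 0.05 FWER boundary; at 60 nodes the same
effect is detected with p_fwer < 0.05 essentially always. This is a property
of component-extent inference, not of the implementation.

## Behavioral statistics

The two-sample test is Welch's (unequal variance) by default: evaluated from
the published demographic table's printed means/SDs at n = 17/18, Welch
reproduces the printed p-values (0.0043, 0.0094) to four decimals while the
pooled-variance test does not (0.0037, 0.0073) — fixing the unstated variant
empirically. The summary-statistic path and the raw-data path agree to
machine precision by construction. The gender test is Pearson χ² without
continuity correction (df = 1), which reproduces the printed 0.8767. The
table's age p-value (0.6207) is not reproducible from its own printed
summaries under either variant (both give ≈ 0.78 at n = 17/18); it was
plausibly computed on the full recruited sample before exclusions. The
package computes, never transcribes.

Spearman p-values use the t approximation with n − 2 df, adequate at the
study's n; brain values are residualized on (intercept, age, gender) before
correlation.

## Problem sizes used in tests and the acceptance script

Simulation studies run at the study's subject and time dimensions (17 + 18,
320 usable volumes) with ROI/voxel dimensions chosen for desk-scale runs:
100-ROI matrices and 500 permutations for NBS null calibration (200 replicate
datasets), 60 ROIs for NBS power (20 runs), 12³ voxel maps and 200
permutations for cluster-FDR calibration and power, and a 20³ grid carrying a
392-ROI box parcellation for the end-to-end run. The end-to-end voxel graph
(8000 voxels) is computed exactly — degree centrality uses blocked
correlation products rather than subsampling.

## Reproducibility

Every stochastic function is a pure function of (spec, seed); the pipeline
derives per-stage substreams from a single config seed via seed sequences,
and the run manifest records config hash, seed, per-file checksums,
per-subject censored-volume counts and motion exclusions. Re-running with the
same config reproduces identical outputs.
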