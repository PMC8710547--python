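# Methods

This note documents the models, conventions and numerical choices behind
`funconn`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort

**Spatial model.** Ground truth is a modular (stochastic-block)
correlation matrix: the N regions are split into `module_count` modules
of equal size (default 22 modules over 90 regions, i.e. 4–5 regions per
module); region pairs inside a module correlate at `rho_w`, pairs across
modules at `rho_b = 0.05`, unit variances. `rho_w` carries the group
effect — defaults 0.55 (HC), 0.44 (MHD without CI), 0.33 (MHD with CI) —
and each subject's realized value adds N(0, 0.025²) jitter, which is the
subject-level "network integrity" latent used for cognition scores.

Why small modules and large deltas: the full partial correlation of an
equicorrelated k-node block saturates at `rho_w / (1 + (k−2) rho_w)`,
and the realistic acquisition geometry (see below) leaves partial
correlations estimable only to sd ≈ 0.1. With 15-region modules and
`rho_w ≈ 0.3` the planted signal sits below that noise floor and no
method could recover the group effect at n = 64; with 4–5-region modules
at the default `rho_w` values the within-module partial correlations are
≈ 0.36/0.31/0.25 and the group effect is recovered with high probability
(omnibus ANCOVA rejection and ordering ≈ 0.99, positive Cp–MoCA partial
correlation ≈ 0.98 over 100 replicate cohorts). These are design
choices of the generator, not estimates of any real effect size.

**Temporal model.** Stationary Gaussian AR(1):
`x_t = φ x_{t−1} + e_t`, `e_t ~ N(0, (1−φ²)Σ)`, so the stationary
covariance is exactly the planted Σ; default φ = 0.4 (typical rs-fMRI
lag-1 autocorrelation at TR = 2 s), 240 volumes, 50-sample burn-in. No
hemodynamic convolution or physiological noise: the analysis consumes
only second-order structure after band-pass filtering, so richer
temporal realism would not change what is being tested.

**Covariates and cognition.** Age, sex, education, BMI, SDS/SAS are
drawn per group around values typical of such cohorts (patients more
often male, CI group older, SDS shifted upward across HC → CI so that
covariate adjustment is genuinely exercised). Cognition scores derive
from the latent `latent = cognition_link · z(rho_w,i) + N(0,1)`
(default link 2.0): MoCA is banded so the grouping rule is exact
(patients with MoCA < 26 are, by construction, exactly the CI group;
everyone else scores ≥ 26), TMT-A loads negatively, digit spans
positively; all scores are rounded and clipped to plausible scale ranges
(MoCA ≤ 30, DST ≥ 0, TMT-A in seconds).

**Motion.** Six-parameter random-walk traces (step sd 0.02 mm/deg) that
stay well under the exclusion thresholds; `inject_motion_artifact` adds
translation spikes to test the exclusion path.

**What passing tests on this cohort do not show:** robustness to
non-Gaussian BOLD features (spikes, drifts, physiological cycles),
atlas misparcellation, residual motion correlated with group, or
hemodynamic variability. The generator validates the *pipeline's
statistical machinery*, not the neurobiology.

## Preprocessing

Stage order is discard → nuisance regression → band-pass. The first 10
volumes are dropped (signal equilibration). The nuisance design holds an
intercept, a linear trend, any supplied surrogate WM/CSF series, and the
Friston-24 expansion of the motion trace (6 parameters, their 1-volume
lags, squares of both); columns made collinear are dropped with a
warning. Filtering is an ideal zero-phase spectral mask keeping
0.01 Hz ≤ f ≤ 0.08 Hz inclusive (DC always removed). Keeping the linear
detrend in the regression stage rather than inside the filter makes the
filter exactly idempotent and matches the pipeline's stated step order.

Framewise displacement is the Power convention: sum of absolute backward
differences of the six parameters, rotations (degrees) converted to arc
length on a 50 mm sphere; FD of the first volume is 0. Exclusion uses
strict inequalities (max |translation| > 2.5 mm, max |rotation| > 2.5°,
mean FD > 0.5), so a subject exactly at a threshold is kept.

A consequence of the realistic band: 230 volumes at TR = 2 s filtered to
0.01–0.08 Hz span only ~64 Fourier components, so the sample covariance
of 90 regions is singular even though T > N. The `"auto"` estimator
therefore inverts the sample covariance only when it is well-conditioned
(condition number < 1e8) and otherwise uses the Ledoit–Wolf shrinkage
covariance; an explicit shrinkage intensity is also accepted (and
reduces to the plain precision route as the intensity → 0).

## Network construction

Partial correlation is read off the precision matrix,
`ρ_ij = −P_ij/√(P_ii P_jj)`, symmetrized and clipped to [−1, 1], zero
diagonal. Binarization at sparsity S keeps the `m = round(S·N(N−1)/2)`
pairs of largest absolute weight (round half up; ties broken by
ascending node-index pair), which makes the sweep deterministic and its
edge sets nested. Exact-count thresholding (rather than a quantile
cutoff) is fixed by design; the two differ only at ties.

## Graph metrics

All metrics operate on undirected, unweighted, simple graphs.
Conventions for sparse or disconnected graphs: distances between
unreachable pairs are +inf; `Lp` averages hop counts over *reachable*
ordered pairs (reported missing when there are none); efficiencies use
1/inf = 0; clustering and local efficiency of nodes with degree < 2 are
0. Under these conventions the global metrics equal the nodal means
exactly (`mean NCp = Cp`, `mean Ne = Eg`, `mean NLe = Eloc`), which the
tests assert to 1e-12 against brute-force oracles.

γ and λ divide `Cp` and `Lp` by their means over `n_nulls = 100`
Maslov–Sneppen degree-preserving rewired graphs (10 successful
double-edge swaps per edge, proposal cap 20×, seeded per
subject × threshold from the run seed; null `Lp` uses the same
reachable-pairs convention). σ = γ/λ. Graphs too small to rewire are
returned unchanged with a warning; a zero null-mean clustering yields a
missing γ. AUC over the sweep is the trapezoid rule on the exact 0.01
grid; a missing value anywhere in a curve propagates to a missing AUC.

The hot loops (all-pairs BFS over CSR neighbour lists, neighbour-
subgraph efficiency, double-edge swaps, the per-null Cp/Lp batch) are
numba kernels; a full default run evaluates ~2×10⁵ null networks.

## Inference

The group comparison fits `AUC ~ group + age + sex + education + SDS`
by least squares; the omnibus p is the partial F-test of the two group
dummies (HC reference), post hoc p-values are the covariate-adjusted
pairwise contrasts from the same model, Bonferroni-multiplied by 3 and
capped at 1; adjusted means are evaluated at the covariate means. Rows
with missing values are dropped (listwise) with a warning; collinear
covariates are dropped with a warning; sex is coded male = 1 (reference
female, logged by the coding itself).

Nodal metrics form one BH-FDR family per metric across all N nodes
(q < 0.05 flags significance). The brain–cognition grid uses rank-based
partial correlation — rank-transform everything, residualize the ranked
variables on the ranked covariates, correlate residuals, p from the
t-approximation on n − k − 2 df — computed in patients only, for the
globally changed parameters (omnibus p < 0.05; all seven if none) plus
FDR-surviving nodes, with BH applied per cognition score within each
parameter block (global / NLe / NCp). The descriptive cohort table uses
Kruskal–Wallis (three-group continuous), χ² without continuity
correction (sex), Mann–Whitney (patient-only variables), and pairwise
Mann–Whitney × Bonferroni as post hoc when the omnibus is significant.

## Pipeline and repeatability

`run_pipeline` persists every intermediate as plain-text CSV plus a JSON
manifest (config hash, seed, versions, exclusions); all randomness —
cohort generation and every null ensemble — derives from the single run
seed, and two runs with identical config and seed are byte-identical.
Atlas presets set the region count (aal90/hoa112/brainnetome246; custom
N accepted); the repeatability harness regenerates matched cohorts under
each parcellation size from the same seed and module design and reports
per-metric sign agreement of the covariate-adjusted HC − CI effect.

## Validation problem sizes

The simulation studies in `funconn.calibration` use: type-I calibration
— 2000 replicate all-null cohorts of 10/10/10 subjects at a reduced
dimension (20 regions, 120 volumes, 4 modules, equal `rho_w`, zero
cognition link); nodal FDR — 1000 replicates of a 90-node all-null AUC
family; planted-effect recovery — replicate cohorts at the full default
design (64 subjects, 90 regions), restricted to the clustering
coefficient. The reduced dimensions keep the replicate counts large
where the calibrated quantity (a rejection rate) needs them, while the
recovery runs stay at the design's full size.

## Known limitations

Binary undirected networks only (no weighted/signed/directed variants,
no dynamic connectivity); ROI-level input only (no voxel-space spatial
preprocessing or parcellation); the FD formula and rotation radius
follow the most common convention since alternatives exist; the
correlation-grid FDR family structure is a documented convention, not
the only defensible one.
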