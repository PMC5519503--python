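# Methods

This note documents the models, numerical conventions and design choices
behind `phasegraph`, in the order the pipeline applies them.

## Regional time series and PET covariates

The pipeline's unit of analysis is the brain region of an integer-label
parcellation. ROI extraction is the unweighted arithmetic mean of all
labelled voxels (no partial-volume weighting, no grey-matter masking);
label 0 is background, negative labels are rejected, and regions are
ordered by ascending label everywhere — the manifest records this order and
every artifact of a run shares it. PET covariates are per-region means of
the tracer image: rCPS in nmol/g/min (protein synthesis) and SUV
(dimensionless, glucose uptake). Non-positive regional PET means are
retained with a warning rather than dropped, since they indicate upstream
problems the user should see.

## Hilbert-wavelet-pair design

Instantaneous phase is only meaningful for a band-limited analytic signal.
We obtain one per dyadic band with two parallel MODWTs whose filter banks
form an approximate Hilbert wavelet pair, built by the common-factor
construction: both scaling filters share F(z) = (1+z⁻¹)ᴷ Q(z) and differ by
a degree-L maximally flat (Lagrange) fractional-delay factor D(z),

    H0(z) = F(z) D(z),   G0(z) = F(z) z⁻ᴸ D(1/z),

so G0 is H0 delayed by half a sample to within the flatness of D. Q is
found by solving the orthonormality (halfband) condition, which is linear
in the autocorrelation of Q, then spectrally factorizing. Consequences,
all verified by the test suite:

* both banks are exactly orthonormal (perfect reconstruction to machine
  precision) and their magnitude responses are identical by construction;
* `design_order` (= K = L; supported 2, 3, 4; default 3, filter length 12)
  trades filter length against phase-approximation flatness;
* analyticity of the complex combination w_h + i·w_g is approximate and is
  a property of the *iterated* filter bank. The half-sample-delay phase
  relation cannot hold at the Nyquist frequency (a 2π-periodic frequency
  response cannot equal e^{iω/2} at ±π), so the depth-1 equivalent filter
  is necessarily two-sided (~30% of its energy at negative frequencies,
  for every order). The negative-frequency fraction falls rapidly with
  cascade depth — for order 3: 8.5% at depth 2, 2.0% at depth 3, 0.4% at
  depth 4 — which is why the package reports quality per depth and the
  shallowest scales are flagged rather than trusted.

## Scale indexing and band labels

With fs = 1/TR, scale j of J is labelled (fs/2ʲ, fs/2ʲ⁻¹) and scale J is
(0, fs/2ᴶ⁻¹); the labels tile (0, fs]. The coefficients behind the labels:
scales 2..J−1 are the wavelet details at levels 1..J−2, scale J is the
level-(J−2) smooth, and scale 1 — whose labelled band lies above the
Nyquist frequency — is the anti-analytic combination w_h − i·w_g of the
level-1 detail, i.e. the aliased image of the top octave. Scale 1 and the
deepest scales are computed for completeness and flagged (`above_nyquist`,
boundary masks); inference should rest on the interior scales. A pure
0.06 Hz tone sampled at TR = 0.72 s concentrates its energy at scale 5
(0.043–0.087 Hz), which the tests assert across scales 2–8. The maximal
J for a length-T series is floor(log₂ T) + 1, i.e. 11 for 1200 volumes.

Boundary handling is circular (the MODWT convention); the first
(2ˡ−1)(L_f−1) coefficients of level l (filter length L_f) are flagged as
boundary-affected but retained. Phase decimation (default factor 4) runs a
linear-phase FIR lowpass (order 8·factor, cutoff 0.8/factor of Nyquist)
forward-backward over e^{iθ} — filtering the unit-circle representation
rather than raw angles avoids wrap artefacts — then subsamples and re-takes
the argument.

## Phase-synchrony connectivity

The pairwise Kuramoto order parameter R_xy(t) = |cos((Θx−Θy)/2)| is used
as the connectivity weight: 1 for identical phases, 2/π ≈ 0.637 on average
for independent uniformly drifting phases (the null baseline the tests
check by Monte Carlo), 0 in antiphase. The modulus makes R a nonnegative
weight, as the downstream graph analysis requires; no variance-stabilizing
transform is applied. Static FC is the temporal mean of R; the diagonal is
stored as 1 and zeroed before any graph computation.

## Thresholding and node metrics

Thresholds maximize cost-efficiency: for each cost k in a grid (default
0.05–0.50, step 0.01) the FC matrix is binarized at the weight quantile
retaining fraction k of edges, binary global efficiency E is computed, and
E − k is maximized with ties resolved toward the sparser graph. In
`group_mean` mode (the default) per-subject thresholds from a designated
threshold cohort are averaged and applied to everyone; `per_subject` and
`fixed` modes exist for sensitivity analyses. Metrics are computed on the
thresholded *weighted* graph:

* **strength** — sum of incident weights;
* **clustering** — Onnela geometric-mean triangle intensity on weights
  max-normalized per graph, denominator k(k−1) with k the binary degree;
* **local efficiency** — weighted global efficiency of the subgraph
  induced by a node's (binary) neighbours;
* **betweenness** — unnormalized Brandes counts with fractional credit for
  ties.

Shortest-path lengths are reciprocal weights throughout (strong synchrony =
short distance). The weighted-variant and path-length choices are
conventions the literature leaves open; they are fixed here and the brute
force oracles in the test suite pin them down exactly. Timepoints whose
thresholded graph is empty yield zero metrics and a logged warning.

## Temporal stability

Stability of a node metric is its coefficient of variation across dynamic
FC timepoints, using the *population* standard deviation (the ~300
decimated timepoints make the sample/population distinction negligible;
fixing it matters only for bit-reproducibility). CVs with |mean| < 1e-12
are flagged as missing (NaN) and ignored — with a count — by the
across-subject average. Boundary-affected timepoints are excluded by
default; if that would discard half a scale's samples or more (the deepest
scales), all timepoints are kept for that scale instead, since an estimate
from edge-dominated data is still better than one from almost nothing.

## Repeated-measures association model

For each metric, the population-mean regions × scales matrix is the
response; regions are the units, scale the within factor, and one or two
z-scored PET covariates the between-unit continuous predictors (Type III
sums of squares; z-scoring leaves F statistics unchanged). The covariate
main effect is the OLS partial F on the region means, df (1, n−1−p) — 80
for one covariate and 79 for two at n = 82. Within effects use orthonormal
scale contrasts: interaction F = (SSH/(k−1)) / (SSE/((k−1)(n−1−p))), with
Greenhouse-Geisser ε = tr(S)²/((k−1)·tr(S²)) on the residual contrast
covariance and Mauchly's W with the Box chi-square approximation on the
same matrix. Both uncorrected and ε-corrected tests are always reported;
the corrected one is headline whenever Mauchly rejects at 0.05. Under a
Gaussian null the main-effect test is exactly calibrated, which the suite
verifies by simulation (2000 replicates, rejection rate within
[0.04, 0.06] at α = 0.05).

Post-hoc localization uses per-scale Pearson correlations, or first-order
partial correlations r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))
when a covariate of no interest is controlled, with two-sided t tests on
n−2−g df and Bonferroni correction over the scales × metrics family
(default 11 × 4 = 44).

Degenerate inputs are handled explicitly: collinear covariates raise; a
response with no within-scale variation reports all within effects as F = 0
with ε = W = 1; a control perfectly correlated with an input raises.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
haemodynamics. Kuramoto phase oscillators on a planted-hub coupling matrix
are integrated by Euler-Maruyama at dt = TR/10 (an explicit stability
check rejects K·max-degree·dt > 0.5), with intrinsic frequencies uniform
in 0.04–0.08 Hz (so planted structure concentrates at scale 5 of the
TR = 0.72 s ladder), and emitted as sin(θ) plus white observation noise
(sd 0.3). Defaults: 82 regions, 1200 volumes, TR = 0.72 s.

Chosen-once condition parameters: the background network is sparse (edge
density 0.15, weights ≈ 0.1), hub-incident edges are three times denser and
three times stronger; global coupling K = 0.1 and phase-diffusion
0.4 rad/√s put the system in partial synchrony (mean scale-5 FC ≈ 0.7) —
strong enough that hub structure imprints on FC, weak enough that it is not
erased by global locking, which is the regime where hub recovery is
informative. PET vectors come from a Gaussian copula on rank-normal scores
of ground-truth hubness: corr(rCPS, hubness) = ρ_hub (default 0.6) and
corr(rCPS, SUV) = ρ_between (default 0.63), mapped affinely to positive
physiological ranges (correlations are preserved exactly).

What passing tests show — and don't: hub recovery, the hub-stability sign
(hubs' strength-CV below the non-hub median) and detection of the planted
rCPS association demonstrate that the pipeline's estimators recover the
structure they target under band-limited oscillatory dynamics with planted
topology. They do not validate haemodynamic convolution, scanner noise
spectra, motion artefacts, or inter-subject anatomical variability, none of
which the generator models. The end-to-end association check averages
metric tables over 4 simulated subjects before regression — the pipeline's
own population-mean design — because a single subject's FC estimation noise
leaves the α = 0.01 check underpowered at the margins.

## Problem sizes used by the validation suite

Test and acceptance runs use the full default conditions (82 regions, 1200
volumes, 11 scales) for everything except the dynamic-metric stage, which
is evaluated at the intrinsic scale with node strength — the hub-recovery
and stability questions are strength questions, and per-timepoint
betweenness/efficiency at all scales adds cost without adding evidence.
Recovery fractions use 20 independent seeds. The pipeline itself computes
whatever scales and metrics the configuration requests.

## Known limitations

* Scale 1 is an alias image and scales ≥ 9 of a 15-minute run contain at
  most a few cycles; both are computed but flagged, and conclusions should
  not rest on them.
* The cost-efficiency optimum can leave the graph disconnected (a warning
  is emitted); unreachable pairs contribute zero efficiency.
* The RM-GLM treats regions as exchangeable units; spatial autocorrelation
  between neighbouring regions is not modelled, matching the analysis it
  implements rather than improving on it.
* The generator's observable is sin(θ) + noise; an optional lowpass stands
  in for haemodynamic smoothing but is off by default.
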