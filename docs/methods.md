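# Methods

`tauspread` tests whether inter-regional covariance of tau pathology follows
functional connectivity. This note documents the models and procedures, the
synthetic study conditions the package is validated on, the numerical
choices, and the limits of what those validations show.

## Analysis model

### Tracer harmonization

Regional SUVR samples (patients and controls pooled, baseline scans) are
modelled per tracer and ROI as a two-component Gaussian mixture, fitted by
EM (scikit-learn: k-means initialization with a fixed seed, tolerance 1e-6
on the log-likelihood, at most 500 iterations, variance floored at 1e-4
SUVR²). Components are ordered by mean; the positivity probability of a
value is 100 × the posterior probability of the higher-mean component,
computed in log space so far-tail values neither overflow nor underflow.

Low-tau ROIs are often genuinely unimodal, and a two-component fit of a
unimodal sample merely splits the noise. A fit is accepted as a real
negative/positive split only when (a) its Ashman separation
`D = √2 (μ₊ − μ₋)/√(σ₋² + σ₊²)` is at least 5 (a 2-GMM fit of a single
Gaussian lands near D ≈ 2.5, and fits up to D ≈ 4 are usually within-ROI
severity spread, not a control/patient split), and (b) both component
weights are at least 0.10 (fits that isolate one or two outliers as a
component would otherwise pin the ROI at 0% or 100% for every subject).
Rejected fits are flagged and fall back to the tracer-level mixture fitted
on all ROI values pooled. The fallback is deliberately *shared* across
ROIs: any per-ROI rescaling (rank or min-max) maps every noise-dominated
ROI to the same mean and destroys the cross-ROI ordering that the
downstream covariance and gradient analyses measure. The per-ROI versus
per-tracer choice is exactly the axis on which published pipelines differ;
this package uses per-ROI where the data support it and per-tracer
otherwise.

The two-Gaussian posterior is strictly increasing in SUVR when the
component spreads are comparable (the regime accepted fits live in); with
strongly unequal variances it is non-monotone far outside the data range.
The implementation reports the exact Bayes posterior rather than a
monotonized version.

### Connectome and functional distance

Frame-wise displacement above 0.5 mm removes that frame plus one preceding
and two following (windows clipped at the series boundary); a subject is
usable with ≥ 300 s retained. FC is the Fisher z of Pearson correlations
(r clipped to ±0.999999 so duplicated series stay finite); zero-variance
ROIs are set missing. The group matrix is the entry-wise mean across
subjects (missing entries ignored pairwise), averaged *before*
thresholding. Density thresholding keeps the ⌈density·P⌉ largest of the P
positive off-diagonal pairs (ceiling so that 30% of 9 positive edges keeps
3); boundary ties break toward the lexicographically smaller ROI pair.
Distance is the all-pairs shortest path (Dijkstra) with edge length
1/weight — the standard convention making strong connections short; path
lengths are not renormalized. Disconnected pairs carry `inf`, are counted,
logged, and excluded from regressions rather than imputed.

### Trajectories, epicentres, gradients

Per subject and ROI, `SUVR = β₀ + β₁·t` by OLS over follow-up years (first
scan shifted to t = 0 if needed); relative change is `100·β₁/β₀` percent
per year, with the *fitted* intercept as denominator — the model value at
time 0 is robust to baseline noise; the observed first scan is available
via `baseline="observed"`. Subjects with one scan are excluded; ROIs with
β₀ ≤ 0 are set missing; both counts are logged.

Epicentres are the top `round_half_away(0.05·n_roi)` ROIs (10 of 200) by
baseline SUVR — ties toward the lower ROI index — and accumulation
epicentres the same on percent change. Epicentre distance of a
non-epicentre ROI is its mean shortest-path distance to the epicentre ROIs
(finite entries only).

### Covariance and its association with distance

Tau covariance is the across-subject partial correlation per ROI pair:
values are residualized per ROI against an intercept + age + sex + site
design (categoricals dummy-coded against a reference level; a
rank-deficient design raises an error naming the dependent columns),
correlated, clipped, and Fisher z-transformed. Partial Spearman = Pearson
on per-ROI ranks taken before residualization. The Euclidean-distance
sensitivity variant residualizes the *pairwise* z values against pairwise
Euclidean distance (the pair-level reading; the alternative — adding
Euclidean distance to the subject-level design — is not implemented).

The association is a simple regression of pairwise z on pairwise distance,
both z-scored, so the slope is the standardized β (equal to the Pearson r
of the pair vectors). Network-scoped regressions restrict to pairs with
both ROIs in the network, using the whole-brain distances (the subgraph is
not re-solved). Null calibration rewires the thresholded FC graph by
Maslov–Sneppen pairwise edge swaps (10·|E| accepted swaps per replicate,
preserving the binary degree sequence exactly) and then redistributes the
original edge-weight multiset over the rewired edges by random permutation;
distances are recomputed per null and the regression re-run. The exact
test is one-sided on |β| with the add-one rule, `p = (1 + #{|β_null| ≥
|β|})/(B + 1)`, matching the qualitative statement that no null β exceeds
the actual one when p = 1/(B+1). B defaults to 1000.

Quartile gradients: per subject, non-epicentre ROIs are sorted by
epicentre distance (ties toward the lower ROI index and hence the lower
quartile) and assigned quartile `⌊4·rank/m⌋`, giving sizes 48/47/48/47 for
m = 190; per-quartile means are compared with all six paired two-sided
Wilcoxon signed-rank tests, reported uncorrected at α = 0.05 per
comparison (matching the per-comparison reporting convention of the
analyses this mirrors).

## Synthetic study conditions

The generator emulates what the restricted multicentre data look like to
this analysis:

- **Atlas**: 200 ROIs in 7 near-equal canonical networks; centroids cluster
  around random network centres (SD 8 mm).
- **Connectome**: block structure with within-network weight 0.7 and
  between-network weight 0.3, per-network-pair jitter ±0.12 (real
  inter-network coupling is graded, and this heterogeneity is what spreads
  shortest-path distances over a usable range), ROI-pair noise SD 0.02,
  then projection to a valid correlation structure (eigenvalue clipping +
  diagonal renormalization) so BOLD can be sampled from it exactly. The
  planted epicentre (the first 10 ROIs of the first network) forms a
  tightly coupled sub-cluster (mutual weight 0.95) — epicentres sit in
  strongly interconnected tissue. The template is redrawn (deterministic
  sub-seeds) until the 30%-thresholded graph is connected, as a real group
  template is.
- **BOLD**: frames are iid multivariate normal draws from the connectome
  correlation — FC estimation only needs the cross-sectional target, so no
  autocorrelation or haemodynamics are modelled. The default template
  sample is 42 control subjects × 400 frames (TR 2 s). FD traces stay
  below the scrubbing threshold except at explicitly injected spike frames.
- **Tau**: patient ROI *i* at time *t* has
  `SUVR = tracer_scale·[b + A_s·e_i·(1 + ρ_acc·t·e_i)] + site + age/sex + ε`,
  with `e_i = exp(−λ·d_i/d̄)`, `d_i` the mean shortest-path distance of ROI
  *i* to the epicentre set and `d̄` the mean inter-ROI distance. Decay per
  *mean* distance keeps λ portable across connectomes (raw path-length
  units depend on the weight scale and threshold), and using the *mean*
  set-distance makes the planted field monotone in exactly the quantity
  the quartile analysis ranks by. `A_s` is the subject's severity:
  amplitude × a mean-preserving lognormal factor — real cohorts are
  heterogeneous in progression, and this heterogeneity is what gives
  intermediate regions intermediate positivity rates instead of a binary
  map. The regional noise ε has SD 0.15 SUVR of which a fraction ρ = 0.8
  is shared along the connectome (ε = σ[√(1−ρ)·z + √ρ·L·z'] with L the
  Cholesky factor of the connectome correlation): connected regions
  accumulate together, the generative converse of the
  covariance-vs-distance inference. Controls have A_s = 0.
- **Defaults**: baseline 1.0, amplitude 2.5 (epicentre SUVR ≈ 3.5, the top
  of the range seen in severe atypical AD), λ = 2, accumulation 0.10/year,
  severity σ = 0.35, three sites with offsets {0, +0.03, −0.03}, age slope
  0.002 SUVR/year (centred at 70), sex offset 0.02, ages uniform 55–85,
  sex Bernoulli(0.5). These values were fixed once, chosen so the planted
  effect sizes sit in the regime the corresponding multicentre analyses
  report (whole-brain β ≈ −0.4…−0.6), and verified as a set across 12
  independent seeds.
- **Post-mortem**: a latent burden per subject/ROI around the expected tau
  map; ordinal 0–3 ratings are its bin index among three increasing cuts,
  quantitative density is the nonnegative burden × 25 tangles/mm² per SUVR
  unit.

What the generator does **not** emulate: spatial autocorrelation of the
noise beyond the connectome coupling, tracer-specific off-target binding
patterns, per-subject epicentre heterogeneity (a shared epicentre per
scenario; per-subject variation enters only through severity and noise),
atrophy-related partial-volume effects, and longitudinal dropout. Passing
the end-to-end checks therefore shows the *pipeline* is correct and
well-calibrated under these conditions; it does not certify effect sizes on
real data.

## Numerical choices

- Correlations clipped to ±0.999999 before `atanh`; covariance diagonal
  undefined (NaN).
- The exact test is valid by construction only if the null replicates are
  exchangeable with the data-generating connectome under H₀; the
  calibration check (tau simulated independently of the connectome, 200
  replicates at 50 ROIs) confirms the rejection rate stays at or below the
  nominal 5%.
- Rewiring aborts (with an error) if accepted swaps stall at 100× the swap
  budget — only degenerate graphs trigger this.
- `identify_epicentre` never selects NaN values and fails below k finite
  values; `round-half-away` keeps the 200 → 10 identity for any atlas size.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  configs; identical seeds give bit-identical cohorts, pipelines and
  reports.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at 50
patients + 30 controls × 200 ROIs with B = 100 null models, the calibration
study at 50 ROIs × 200 replicates (nulls precomputed once against the fixed
template), and mixture recovery at n = 2000 per ROI. These sizes put every
statistic well past its detection threshold while keeping a complete run in
the low minutes on one CPU; B = 1000 remains the default for real runs.

## Known limitations

- Positivity probabilities are a nonlinear rescaling of SUVR; in saturated
  regimes (clearly positive or clearly negative regions) they compress
  across-subject variance, which attenuates pairwise correlations relative
  to the SUVR scale at small n.
- No mixed-effects longitudinal model (plain OLS per subject×ROI), no
  spatial-autocorrelation-corrected inference (spin tests), no structural
  connectomes, no voxel-level processing.
- The leave-one-site-out check measures stability of mean positivity maps;
  it does not detect site effects that are constant across ROIs.
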