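# tauspread

Connectome-based analysis of tau-PET spread in Alzheimer's disease clinical
variants: does inter-regional covariance in tau pathology follow the brain's
functional connectivity architecture?

The package implements the full analytic chain used to answer that question
on multicentre tau-PET data — and, because such patient data are access
restricted, ships a synthetic multicentre cohort generator with the same
statistical structure, so every stage is testable and reproducible offline.

## Who this is for

Neuroimaging researchers studying pathology propagation along brain networks:
the same machinery applies to any ROI-level molecular-imaging measure paired
with a functional (or other) connectome.

## The analysis

1. **Tracer harmonization.** Regional tau-PET SUVRs from different tracers
   are not comparable. Per tracer and ROI, a two-component Gaussian mixture
   is fitted to the pooled patient + control SUVR sample; a scan's *tau
   positivity probability* for ROI *i* is the posterior probability of the
   higher-mean component,

   `P(tau+ | x) = w₊ N(x; μ₊, σ₊) / [w₋ N(x; μ₋, σ₋) + w₊ N(x; μ₊, σ₊)]`,

   reported on a uniform 0–100% scale.

2. **Functional distance.** From control resting-state BOLD series:
   motion-scrub frames with FD > 0.5 mm (plus one preceding, two following;
   ≥ 5 min retained), Fisher-z Pearson FC per subject, group average,
   density-threshold at 30% (strongest positive connections), then
   shortest-path lengths with edge length 1/weight. Strongly connected
   regions are "close".

3. **Epicentres.** Per subject, the top 5% of ROIs (10 of 200) by baseline
   SUVR; accumulation epicentres analogously by annual percent change
   `100 · β₁/β₀` from per-ROI OLS lines `SUVR = β₀ + β₁·t`.

4. **Covariance vs distance.** Tau covariance between ROIs *i, j* is the
   Fisher-z partial correlation of their tau values across subjects,
   adjusted for age, sex and site. Regressing pairwise covariance on
   functional distance (both z-scored) gives a standardized β; its exact
   p-value comes from 1000 degree- and weight-preserving connectome null
   models (`p = (1 + #{|β_null| ≥ |β|}) / (B + 1)`).

5. **Epicentre gradients.** Per subject, tau regressed on the functional
   distance of each non-epicentre ROI (n = 190) to the epicentre, and
   compared across distance quartiles (Q1 closest … Q4) with paired
   Wilcoxon signed-rank tests.

## Worked example

```bash
tauspread run --seed 7 --out runs/demo     # ~3 min with the default 1000 nulls
tauspread report runs/demo
```

or, faster, from Python with a reduced null count:

```python
import tauspread as ts
summary = ts.run_pipeline(ts.RunConfig(seed=7, n_nulls=100), "runs/demo")
```

whose summary (seed 7) contains:

```
beta_std_whole_brain    -0.409
p_exact_whole_brain      0.0099
epicentre_recovery_rate  1.00
quartile_means           [97.2, 94.6, 41.3, 16.9]
median_subject_beta     -0.900
```

Reading: tau covariance falls off sharply with functional distance
(standardized β = −0.41; none of the 100 rewired-connectome null models
produces a β as extreme, so p = 1/101); every synthetic subject's estimated
epicentre recovers at least 8 of the 10 planted epicentre ROIs; mean tau
positivity decreases monotonically from the quartile closest to the
epicentre (97%) to the most distant (17%); and within subjects, tau load
declines steeply with epicentre distance (median standardized slope −0.90).

`tauspread report` renders the covariance–distance scatter, the null-model β
distribution, the quartile gradient and the epicentre-probability map into
`report.md`.

Individual stages are also available as subcommands (`simulate`,
`harmonize fit/apply`, `connectome`, `trajectories`, `epicentres`,
`associate`) operating on tab-delimited artefacts.

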