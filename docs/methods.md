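# Methods

This note documents the models, conventions, and parameter defaults
behind each module, the design choices made where the procedure was
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Compression mechanics

A bead's load–strain curve is reduced to three descriptors.

**Linear (elastic) region.** Candidate windows are anchored at each
sample index at or after the first positive-load sample (keeping the
contact point immediately before it) and expanded greedily while the
least-squares line keeps R² ≥ `r2_min` (default 0.999, minimum window
5 points). The earliest qualifying start wins, and trailing points are
trimmed while their removal strictly improves R². The earliest-start
rule matters: the plastic plateau after yield fits a constant perfectly
(we define R² = 1 for a zero-variance response, which also makes the
all-zero curve well-posed), so a longest-window rule would
systematically return the plateau instead of the elastic region.
Detection is deterministic; identical input gives identical output.

**Stiffness** is the least-squares slope of load vs. strain on that
region. It is reported under the instrument-conventional label N/mm
although the denominator is dimensionless strain (mm/mm); the numeric
value is unaffected. Stiffness is invariant to constant load offsets.

**Fracture and maximum compression.** Fracture is flagged at the first
sample whose load falls below (1 − `drop_fraction`) × running maximum
(default drop 0.3); the reported fracture strain is the sample
immediately preceding that confirmed drop — the last strain at which
the bead still carried its load. This is exact for sharp drops and
robust when sensor noise places the literal load maximum anywhere along
a flat plateau. The deformation diameter D is taken as platen
displacement at the fracture point, so ε_max = D/d̄ equals the fracture
strain; for ductile beads that never fracture (PP-like), D is the
displacement at maximum applied strain and the summary is flagged
censored rather than treated as a true ε_max.

## Calorimetry

The melting enthalpy is the integral of the endothermic peak over a
user-chosen temperature window after subtracting the straight baseline
joining the signal at the window endpoints (the standard DSC
construction; no peak-shape model is assumed), divided by the heating
rate in °C/s to convert W·°C/g to J/g. Degree of crystallinity is
X_c = 100·ΔH_m/ΔH°_m with ΔH°_m = 293 J/g for PE and 207 J/g for PP;
PS is defined amorphous (X_c = 0). Integration is invariant to adding
any linear baseline. The second heating segment is the default for
X_c (the first heating carries thermal history); the segment and window
are configuration choices, not assertions about any particular
instrument run. A negative net area (no endotherm in the window) is
returned with a warning rather than silently clipped.

## Topography

Each AFM scan line is flattened independently by subtracting its
least-squares second-order polynomial in the column index (instrument
software convention), leaving every line with zero projection onto
{1, x, x²}. Roughness is computed on the flattened map only (enforced
by a flag): R_a is the mean absolute height and R_q the root of the
mean squared height, with n = number of sampled points, both in nm.
R_q ≥ R_a always (Jensen). A `rq_sqrt=False` variant reproduces the
no-square-root reading of the RMS formula sometimes seen in print; the
default takes the root so R_q has units of nm.

## Spectroscopy

All spectra live on strictly monotone wavenumber grids in
[400, 4000] cm⁻¹; resampling onto a common grid uses linear
interpolation at the coarsest spacing present. Residual CO₂ signal is
removed by subtracting a reference spectrum (CO₂ bands in 2390–2280 and
702–623 cm⁻¹, straight lines otherwise) scaled by the least-squares
factor fitted per spectrum on the 2390–2280 cm⁻¹ window. The
treatment-induced difference spectrum is `treated − c·control` with
c = ⟨treated, control⟩/⟨control, control⟩ on the 1500–1350 cm⁻¹
cancellation window — the ordinary least-squares operationalisation of
"scale the control so the polymer bands cancel"; it is exactly zero on
the window when treated is a scalar multiple of control, and the factor
is invariant to a common gain. No baseline correction is applied
anywhere. Replicate spots are averaged before differencing (a per-spot
mode exists for outlier inspection). Band positions are local minima of
the Savitzky–Golay second derivative (default window 9 points, order 3)
passing a prominence threshold; at 4 cm⁻¹ sampling a 9-point window
spans 36 cm⁻¹ and merges shoulders closer than ~15 cm⁻¹ to a strong
neighbour — use a 7-point window to resolve such shoulders. Located
band centres are accurate to one grid step.

## Resampling statistics

**Bootstrap difference of means.** Each of `n_boot` (default 10 000)
replicates resamples both groups independently, with replacement, at
their own sizes, and records the difference of resampled means. The CI
is the 2.5/97.5 percentile interval; the two-sided p-value is
2·min(P(diff\* ≤ 0), P(diff\* ≥ 0)) clipped to [2/n_boot, 1], so p < 0.05
coincides with the 95% CI excluding zero up to resampling discreteness.
Percentile CIs (not BCa) are the default reading of "95% confidence
interval"; BCa could be added but changes none of the worked examples.

*Known limitation (measured, not fixed):* with 3–6 observations per
group this test is anticonservative. At n = 5 per group its true size
at nominal α = 0.05 is ≈ 0.11 (measured over 1000 null simulations,
stable across seeds and across quantile conventions). Only a
pooled-under-H0 resampling scheme is well calibrated at this n, but
that is a different test from the one implemented here, which matches
the CI-excludes-zero decision rule this pipeline is defined around.
Treat borderline calls at these sample sizes accordingly.

**F-test.** F = s_a²/s_b² with (n_a−1, n_b−1) degrees of freedom and a
two-sided p from both tails of the F distribution; exchangeable in its
arguments.

**Monte-Carlo pairing.** Physicochemical variables measured on
different beads are unpaired; to correlate them, each (variable,
polymer, treatment) cell is represented by normal draws from its
observed mean and SD (normality is the minimal assumption — only the
first two moments are carried), paired by draw index within cell,
n = 3 draws per cell so pooling three polymers gives n = 9 rows per
treatment. Pearson's r on the paired rows gets a percentile bootstrap
CI over row resampling (degenerate zero-variance resamples are redrawn,
then dropped and counted). At n = 9 this CI under-covers slightly
(≈ 90% observed for a nominal 95%).

**Spearman's ρ** uses mid-ranks for ties; the p-value is an exact
enumeration over all n! pairings for n ≤ 9 (the screen's regime) and
the t-approximation above. The value 0.9487 = 54/√(54·60) is the exact
ceiling for a perfectly ordered screen of three polymers × three
samples with tied property ranks within each polymer.

## Community diversity

Rarefaction draws each sample down to a common depth without
replacement (multivariate hypergeometric) and averages each index over
`n_perm` permutations (default 999); the default depth is the minimum
row sum of the compared samples. Indices: Shannon–Wiener H in nats
(base-2 by flag); Fisher's α as the root of S = α·ln(1 + N/α) by
bracketed Brent iteration (residual < 1e−8); Chao1 in the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) by default with the
classic F1²/(2F2) form behind a flag (falling back to bias-corrected
when F2 = 0); ACE with the standard rare/abundant split at abundance 10
and the Chao1 fallback when every rare read is a singleton (C_ACE = 0).
Chao1 and ACE never fall below observed richness; all indices are
invariant to OTU order and zero-padding.

ANOVA across polymers is fitted factorially (polymer × index) to match
the two-factor layout diversity summaries are reported in, with a
one-way mode per index; Tukey HSD uses the studentized-range
distribution (statsmodels), and with exactly two groups reproduces the
classical equal-variance pairwise t-test (q = t√2). The
diversity–property screen pairs each sample's index value with its
polymer's mean property value (tied ranks within polymer) and reports
Spearman ρ and p per index × property; a polymer-means mode (n = 3)
is also provided since pairing "by polymer type" is ambiguous between
the two.

## Differential abundance

Counts are CSS-normalised: each sample is divided by the sum of its
counts at or below the q-th quantile (q = 0.5, linear-interpolation
definition — e.g. counts (1, 2, 10, 100) have nonzero median 6 and
factor 3) of its nonzero counts, rescaled by 1000, and
log2(x+1)-transformed. OTUs present in fewer samples than the OTU-wise
average ("effective samples" simplified to the nonzero-sample count)
are removed. Group means are fitted per OTU by least squares; residual
variances are shrunk toward an empirical-Bayes prior (d0, s0²)
estimated by method of moments on the log sample variances (trigamma
inversion by Newton), giving posterior variances
(d0·s0² + d·s²)/(d0 + d) and moderated t-statistics on d0 + d degrees
of freedom; log₂ fold-change is the difference of group means (already
log2 scale). p-values are BH-adjusted within contrast; significance at
adjusted p < 0.05. Setting the prior weight to 0 reproduces the
classical per-OTU t exactly (for a two-group design); infinite weight
pools all variances. The upstream zero-inflated Gaussian EM machinery
is deliberately *not* reimplemented: plain least squares on CSS-log2
values preserves the decision rule (moderated t + BH) while remaining
fully testable; this is the package's one prominent simplification and
it makes the per-OTU calls somewhat less robust to extreme
zero-inflation than a ZIG fit would be.

## Synthetic-data generator

Every generator is a pure function of (config, seed) and emits planted
ground truth beside the data; recovery tests read the truth, never
re-derive it. The default scenario mirrors the study shape: 3 polymers
× 3 replicates per treatment.

- Load–strain curves: linear elastic segment with the planted slope up
  to yield (0.1 mm/mm), plastic plateau, exponential densification
  above 0.4 mm/mm, optional sharp fracture at the planted strain,
  optional Gaussian load noise.
- Thermograms: Gaussian melting peak whose analytic area equals the
  planted enthalpy times the heating rate in °C/s, on a sloped linear
  baseline (25–190 °C, 10 °C/min).
- Height maps: per-line quadratic bow plus a white Gaussian roughness
  field of planted SD σ, so flattened R_q ≈ σ and R_a ≈ σ√(2/π).
- Spectra: polymer base bands including anchors at 1455/1375 cm⁻¹
  inside the cancellation window, lognormal per-spot gain, planted
  degradation bands at 3400/1730/1640/1000 cm⁻¹ on treated spots,
  optional planted CO₂ contamination; 4 cm⁻¹ grid.
- OTU tables: lognormal baseline relative abundances (σ = 1.5) shared
  across samples; negative-binomial counts with size 100 (mild
  overdispersion, CV ≈ 10% beyond Poisson); per-sample depths uniform
  on 15k–25k; abundance-dependent structural zeros
  P(zero) = 0.3·exp(−μ/10), concentrating zeros in rare OTUs as in real
  sparse tables; planted differential OTUs are drawn from the abundant
  tail (~1% relative abundance) with polymer-specific folds
  (5×, 5×, 3×, 2× on PE; 4× on PP and PS; one 4.1-log₂ OTU), mirroring
  that differentially abundant plastisphere taxa are dominant genera.
  With these defaults the planted 4.1-log₂ fold is recovered within
  ±0.3 in ≈95% of seeds at n = 3 per group.

What the generator does *not* emulate: taxon–taxon correlation,
compositional closure effects beyond the shared baseline, PCR/primer
bias, chimeras, overdispersion heterogeneity across taxa, instrument
drift, or ATR penetration-depth effects. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every artefact of real amplicon or
instrument data.

## Pipeline

`run_pipeline` executes simulate → physchem reductions → bootstrap
stats, and OTU table → diversity/diffabund, in fixed dependency order;
all randomness derives from the config seed (per-stage streams are
split off with CRC-labelled SeedSequences, so adding a stage never
shifts another stage's draws). Planted treatment effects default to a
crystallinity increase in PE, a 35 N/mm stiffness drop in PP, and a
higher fracture strain in PS, with roughness left null as a negative
control. Every output table is TSV with a fixed float format; the
summary embeds a hash of the config (excluding the output directory),
and identical configs produce byte-identical outputs. Problem sizes in
the bundled checks (e.g. 199 rarefaction permutations in the
determinism rerun, 100 seeds in recovery sweeps) are chosen to keep a
full verification run in the minutes range; all are configurable
upward.
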