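# plastisphere

Analysis pipeline for studying how biofilm formation changes the
physicochemical properties of microplastic beads, and how those
properties relate to the bacterial communities that colonise them.

When polyethylene (PE), polypropylene (PP), or polystyrene (PS) beads
are incubated in natural water, bacterioplankton form a biofilm (the
*plastisphere*) on the bead surface within days. Weathering under such
exposure shows up as shifts in polymer crystallinity, mechanical
stiffness and compressibility, surface roughness, and surface chemistry
— and the community structure of the biofilm in turn tracks those
substrate properties. This package implements the full measurement
chain from raw instrument traces and OTU count tables to the
statistical calls, with a seeded synthetic-data generator so every step
is testable against planted ground truth.

## What it computes

**Instrument-trace reduction**

- Compression curves → stiffness *k* = ΔF/Δε (slope of the elastic
  region of the load–strain curve), fracture detection, and maximum
  compression ε_max = D/d̄ (deformation diameter over initial diameter).
- DSC thermograms → heat of melting ΔH_m (baseline-corrected trapezoid
  integral of the melting peak divided by the heating rate) and degree
  of crystallinity X_c = 100·ΔH_m/ΔH°_m with ΔH°_m = 293 J/g (PE),
  207 J/g (PP); PS is treated as amorphous.
- AFM height maps → per-line second-order flattening, then arithmetic
  and root-mean-square roughness R_a = (1/n)Σ|y_i|,
  R_q = √((1/n)Σy_i²).
- ATR-FTIR spectra → CO₂-reference subtraction, difference spectra with
  the control scaled by the least-squares factor that cancels the
  polymer bands in the 1500–1350 cm⁻¹ window, and band localisation by
  Savitzky–Golay second-derivative minima.

**Statistics**

- Two-sample bootstrap difference-of-means test (10 000 resamples,
  percentile 95% CI, significant when the CI excludes zero) and the
  F-test for equality of variances.
- Monte-Carlo pairing of variables measured on different beads, with
  bootstrap Pearson CIs and Spearman's ρ (exact permutation p for
  n ≤ 9).
- Alpha diversity on rarefied OTU tables (Shannon–Wiener H, Fisher's α,
  Chao1, ACE; 999 rarefaction permutations), factorial ANOVA with Tukey
  HSD across polymers, and a Spearman screen of diversity against the
  polymer-level physicochemical means.
- Differential OTU abundance: cumulative-sum-scaling (CSS)
  normalisation, effective-samples filtering, moderated *t* contrasts
  with empirical-Bayes variance shrinkage, and Benjamini–Hochberg FDR
  (significant at adjusted p < 0.05).

## Worked example

```python
from plastisphere.synthgen import ScenarioConfig, gen_otu_table
from plastisphere import diffabund, calorimetry

xc = calorimetry.crystallinity(240.0, "PE")
print(f"PE crystallinity: Xc = {xc.Xc:.1f}% (dHm = {xc.delta_Hm:.0f} J/g, "
      f"dHm0 = {xc.delta_Hm0:.0f} J/g)")

table, truth = gen_otu_table(ScenarioConfig(seed=1))
res = diffabund.differential_abundance(
    table, [("PE", "PP"), ("PE", "PS"), ("PP", "PS")]
)
sig = res[res["significant"]].sort_values("fdr")
print(f"{sig['otu'].nunique()} differentially abundant OTUs "
      f"(of {len(truth)} planted)")
print(sig[["otu", "contrast", "log2_fc", "p", "fdr"]].head(5).to_string(index=False))
```

prints

```
PE crystallinity: Xc = 81.9% (dHm = 240 J/g, dHm0 = 293 J/g)
7 differentially abundant OTUs (of 7 planted)
       otu contrast   log2_fc            p      fdr
OTU_000347    PP-PS  4.154896 4.280321e-08 0.000029
OTU_000347    PE-PP -4.019857 5.608181e-08 0.000038
OTU_000981    PE-PP  2.320330 5.473512e-06 0.001864
OTU_000740    PE-PP  2.435911 1.012697e-05 0.002299
OTU_000981    PE-PS  2.211977 7.936333e-06 0.002786
```

A crushed PE sample with a 240 J/g melting enthalpy is 81.9%
crystalline. The synthetic OTU table (3 polymers × 3 replicates,
~1000 OTUs, sequencing depths 15k–25k) carries seven planted
polymer-specific fold changes; the moderated-t/FDR analysis recovers
all seven, with the strongest planted effect (4.1 log₂ fold on PP)
estimated at 4.15.

The same steps are available from the shell:

```sh
plastisphere simulate --seed 1 --out data/
plastisphere diffabund --otu data/otu.tsv --meta data/meta.tsv \
    --taxonomy data/taxonomy.tsv --out diffabund.tsv
plastisphere run --seed 1 --out run_out/   # full pipeline
```

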