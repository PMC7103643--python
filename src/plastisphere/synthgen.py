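"""Seeded generators for every input the pipeline consumes.

The generators emulate a bead-weathering study: 3 polymers (PE, PP, PS)
x 3 replicates, compared between a biofilm exposure and untreated
controls.  Every generator is a pure function of its config and seed
and returns the planted ground truth alongside the data, so recovery
tests always read truth from here rather than re-deriving it.

Planted defaults follow the study conditions: load-strain curves with a
linear elastic region, optional plastic plateau, densification above
0.4 mm/mm and brittle fracture near 0.18 mm/mm for PS-like beads;
DSC thermograms over 25-190 degC at 10 degC/min; FTIR spectra on a
4 cm-1 grid with polymer anchor bands in the 1500-1350 cm-1 window and
degradation bands near 3400/1730/1640/1000 cm-1; and zero-inflated
negative-binomial OTU tables (~1000 OTUs, depths 15k-25k) with
polymer-specific differential OTUs planted at known fold-changes
(defaults: 5x, 5x, 3x, 2x on PE and an average ~4.1 log2 fold split
across polymers).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .calorimetry import Thermogram
from .community import OtuTable
from .mechanics import LoadStrainCurve
from .spectroscopy import Spectrum
from .topography import HeightMap

__all__ = [
    "ScenarioConfig",
    "gen_load_strain",
    "gen_thermogram",
    "gen_heightmap",
    "gen_spectrum",
    "gen_co2_reference",
    "gen_otu_table",
]

POLYMERS = ("PE", "PP", "PS")

# Lineages observed as differentially abundant plastisphere taxa, plus
# common aquatic-biofilm fillers used to label the remaining OTUs.
TAXONOMY_POOL = [
    "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingobium",
    "Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Novosphingobium",
    "Planctomycetes;Planctomycetacia;Planctomycetales;Planctomycetaceae;uncultured",
    "Bacteroidetes;Sphingobacteriia;Sphingobacteriales;uncultured",
    "Bacteroidetes;Sphingobacteriia;Sphingobacteriales;Saprospiraceae;uncultured",
    "Proteobacteria;Alphaproteobacteria;Alphaproteobacteria_incertae_sedis;uncultured",
    "Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae",
    "Proteobacteria;Gammaproteobacteria;Alteromonadales;Alteromonadaceae",
    "Actinobacteria;Acidimicrobiia;Acidimicrobiales;uncultured",
    "Cyanobacteria;Cyanobacteria;SubsectionI;FamilyI;Synechococcus",
    "Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Verrucomicrobiaceae",
    "Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae",
]


@dataclass
class ScenarioConfig:
    """All planted parameters for one synthetic study scenario."""

    seed: int = 0
    polymers: Tuple[str, ...] = POLYMERS
    replicates: int = 3

    # mechanics
    slope: float = 120.0                 # N per unit strain
    fracture_strain: Optional[float] = 0.18  # mm/mm; None = ductile
    yield_strain: float = 0.1            # end of the elastic region
    max_strain: float = 0.5
    strain_step: float = 0.002
    load_noise_sd: float = 0.0           # N
    initial_diameter: float = 0.5        # mm

    # calorimetry
    enthalpy: float = 240.0              # planted delta_Hm, J/g
    heating_rate: float = 10.0           # degC/min
    temp_range: Tuple[float, float] = (25.0, 190.0)
    peak_center: float = 130.0           # degC
    peak_sigma: float = 4.0              # degC
    baseline_slope: float = 0.002        # W/g per degC
    baseline_offset: float = 0.05        # W/g
    dsc_noise_sd: float = 0.0            # W/g

    # topography
    map_shape: Tuple[int, int] = (64, 64)
    roughness_sd: float = 20.0           # nm, Gaussian height field
    bow_scale: float = 200.0             # nm, per-line quadratic bow

    # spectroscopy
    wn_step: float = 4.0                 # cm-1 grid (instrument resolution)
    wn_range: Tuple[float, float] = (400.0, 4000.0)
    degradation_bands: Tuple[float, ...] = (3400.0, 1730.0, 1640.0, 1000.0)
    degradation_amplitude: float = 0.05
    co2_amplitude: float = 0.0           # planted CO2 contamination factor
    spot_gain_sd: float = 0.1            # lognormal sd of per-spot gain
    spectrum_noise_sd: float = 0.0

    # OTU table
    n_otus: int = 1000
    depth_range: Tuple[int, int] = (15_000, 25_000)
    nb_size: float = 100.0               # NB size (inverse overdispersion)
    zero_inflation: float = 0.3          # max structural-zero probability
    zero_inflation_tau: float = 10.0     # mean count where zeros fade out
    lognormal_sigma: float = 1.5         # spread of baseline abundances
    # planted differential OTUs: (polymer with excess, linear fold)
    differential_otus: Tuple[Tuple[str, float], ...] = (
        ("PE", 5.0), ("PE", 5.0), ("PE", 3.0), ("PE", 2.0),
        ("PP", 4.0), ("PS", 4.0), ("PP", 17.148),  # 17.148x ~ 4.1 log2
    )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                val = raw[f.name]
                if isinstance(val, list):
                    val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
                kwargs[f.name] = val
        return cls(**kwargs)


def _rng(config: ScenarioConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32 is stable
    # across processes, unlike the builtin str hash)
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def gen_load_strain(
    config: ScenarioConfig, n_curves: Optional[int] = None
) -> Tuple[List[LoadStrainCurve], pd.DataFrame]:
    """Synthetic load-strain curves with planted slope and fracture.

    Shape: linear elastic region with the planted slope up to
    ``yield_strain``, a plastic plateau, exponential densification above
    0.4 mm/mm, and (if ``fracture_strain`` is set) a sharp drop to 5% of
    the peak load at the planted strain.  Gaussian noise optional.
    Returns the curves and a truth table (slope, fracture strain).
    """
    rng = _rng(config, "load_strain")
    n = n_curves if n_curves is not None else config.replicates
    strain = np.arange(0.0, config.max_strain + config.strain_step / 2,
                       config.strain_step)
    curves, truth = [], []
    for i in range(n):
        load = np.where(
            strain <= config.yield_strain,
            config.slope * strain,
            config.slope * config.yield_strain,
        )
        dens = strain > 0.4
        load = load + np.where(
            dens, config.slope * config.yield_strain *
            (np.exp(8.0 * (strain - 0.4)) - 1.0), 0.0
        )
        frac = config.fracture_strain
        if frac is not None:
            peak = config.slope * min(frac, config.yield_strain)
            load = np.where(strain <= frac, np.minimum(load, peak), 0.05 * peak)
            # make sure the planted fracture strain is on the grid
            k = int(round(frac / config.strain_step))
            frac_on_grid = float(strain[min(k, strain.size - 1)])
        else:
            frac_on_grid = None
        if config.load_noise_sd > 0:
            load = load + rng.normal(0.0, config.load_noise_sd, load.size)
        curves.append(
            LoadStrainCurve(
                strain=strain.copy(), load=load, bead_id=f"bead{i}",
                initial_diameter=config.initial_diameter,
            )
        )
        truth.append(
            {"bead_id": f"bead{i}", "slope": config.slope,
             "fracture_strain": frac_on_grid}
        )
    return curves, pd.DataFrame(truth)


def gen_thermogram(
    config: ScenarioConfig, n: Optional[int] = None
) -> Tuple[List[Thermogram], pd.DataFrame]:
    """Thermograms with a Gaussian melting peak of planted enthalpy.

    The peak's integrated area in W*degC/g equals
    ``enthalpy * (heating_rate in degC/s)`` on top of a sloped linear
    baseline, so integration recovers the planted delta_Hm in J/g.
    """
    rng = _rng(config, "thermogram")
    n = n if n is not None else config.replicates
    lo, hi = config.temp_range
    t = np.arange(lo, hi + 0.25, 0.5)
    beta_s = abs(config.heating_rate) / 60.0
    out, truth = [], []
    for i in range(n):
        area = config.enthalpy * beta_s  # W*degC/g
        peak = (
            area / (config.peak_sigma * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((t - config.peak_center) / config.peak_sigma) ** 2)
        )
        hf = config.baseline_offset + config.baseline_slope * t + peak
        if config.dsc_noise_sd > 0:
            hf = hf + rng.normal(0.0, config.dsc_noise_sd, hf.size)
        out.append(
            Thermogram(
                temperature=t.copy(), heat_flow=hf,
                heating_rate=config.heating_rate, segment="second heating",
            )
        )
        truth.append({"sample": i, "enthalpy": config.enthalpy,
                      "peak_center": config.peak_center,
                      "peak_sigma": config.peak_sigma})
    return out, pd.DataFrame(truth)


def gen_heightmap(
    config: ScenarioConfig, n: Optional[int] = None
) -> Tuple[List[HeightMap], pd.DataFrame]:
    """Height maps: per-line quadratic bow + Gaussian roughness field.

    After second-order flattening, Rq of the residual approaches the
    planted field sd (E|y| = sd * sqrt(2/pi) for the Gaussian field).
    """
    rng = _rng(config, "heightmap")
    n = n if n is not None else config.replicates
    rows, cols = config.map_shape
    x = np.linspace(-1.0, 1.0, cols)
    maps, truth = [], []
    for i in range(n):
        coef = rng.normal(0.0, config.bow_scale, size=(rows, 3))
        bow = coef[:, [0]] + coef[:, [1]] * x + coef[:, [2]] * x**2
        noise = rng.normal(0.0, config.roughness_sd, size=(rows, cols))
        maps.append(HeightMap(heights=bow + noise, pixel_size=10.0))
        truth.append({"map": i, "roughness_sd": config.roughness_sd})
    return maps, pd.DataFrame(truth)


def _gauss(wn: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2)


def gen_co2_reference(config: ScenarioConfig) -> Spectrum:
    """CO2 reference: bands in 2390-2280 and 702-623 cm-1, flat otherwise."""
    lo, hi = config.wn_range
    wn = np.arange(lo, hi + config.wn_step / 2, config.wn_step)
    ab = _gauss(wn, 2349.0, 12.0, 1.0) + _gauss(wn, 667.0, 8.0, 0.4)
    return Spectrum(wavenumber=wn, absorbance=ab, label="CO2 reference")


def gen_spectrum(
    config: ScenarioConfig,
    polymer: str = "PP",
    treated: bool = False,
    n_spots: Optional[int] = None,
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """ATR-FTIR spectra with planted degradation bands and CO2 signal.

    Each spot shares the polymer's base bands (including anchors at 1455
    and 1375 cm-1 inside the cancellation window) scaled by a random
    per-spot gain; treated spots additionally carry the planted
    degradation bands, and ``co2_amplitude`` plants CO2 contamination.
    """
    rng = _rng(config, f"spectrum:{polymer}:{treated}")
    n = n_spots if n_spots is not None else config.replicates
    lo, hi = config.wn_range
    wn = np.arange(lo, hi + config.wn_step / 2, config.wn_step)
    base = (
        _gauss(wn, 2915.0, 25.0, 1.0)    # C-H stretch
        + _gauss(wn, 2848.0, 20.0, 0.8)
        + _gauss(wn, 1455.0, 15.0, 0.5)  # anchor bands, cancellation window
        + _gauss(wn, 1375.0, 12.0, 0.35)
        + _gauss(wn, 720.0, 10.0, 0.2)
    )
    degradation = np.zeros_like(wn)
    for center in config.degradation_bands:
        degradation += _gauss(wn, center, 12.0, config.degradation_amplitude)
    co2 = gen_co2_reference(config).absorbance
    spectra, truth = [], []
    for i in range(n):
        gain = float(np.exp(rng.normal(0.0, config.spot_gain_sd)))
        ab = gain * base
        if treated:
            ab = ab + degradation
        if config.co2_amplitude:
            ab = ab + config.co2_amplitude * co2
        if config.spectrum_noise_sd > 0:
            ab = ab + rng.normal(0.0, config.spectrum_noise_sd, ab.size)
        label = f"{polymer} {'Biofilm' if treated else 'Control'} spot{i}"
        spectra.append(Spectrum(wavenumber=wn.copy(), absorbance=ab, label=label))
        truth.append(
            {"spot": i, "gain": gain, "treated": treated,
             "co2_factor": config.co2_amplitude,
             "bands": list(config.degradation_bands) if treated else []}
        )
    return spectra, pd.DataFrame(truth)


def gen_otu_table(config: ScenarioConfig) -> Tuple[OtuTable, pd.DataFrame]:
    """Zero-inflated negative-binomial OTU counts with planted effects.

    Baseline relative abundances are lognormal and shared across
    samples; designated OTUs (drawn from the abundant tail so the
    planted signal is identifiable at realistic depths) are multiplied
    by their polymer-specific fold factor; per-sample depths vary
    uniformly over ``depth_range``; counts are NB(mean, size) draws with
    abundance-dependent structural zeros
    ``P(zero) = zero_inflation * exp(-mean / zero_inflation_tau)``.

    Returns the table and the truth frame (otu, polymer, fold, log2_fc).
    """
    if len(config.differential_otus) > config.n_otus:
        raise ValueError("more differential OTUs than OTUs in the table")
    rng = _rng(config, "otu_table")
    s = config.n_otus
    base = np.exp(rng.normal(0.0, config.lognormal_sigma, s))
    base /= base.sum()
    otu_ids = [f"OTU_{i:06d}" for i in range(1, s + 1)]

    # plant differential OTUs among the more abundant features
    order = np.argsort(base)[::-1]
    planted_idx = order[5 : 5 + len(config.differential_otus)]
    truth_rows = []
    fold_matrix = {p: np.ones(s) for p in config.polymers}
    for idx, (polymer, fold) in zip(planted_idx, config.differential_otus):
        fold_matrix[polymer][idx] *= fold
        truth_rows.append(
            {"otu": otu_ids[idx], "polymer": polymer, "fold": fold,
             "log2_fc": float(np.log2(fold))}
        )

    samples, meta_rows, rows = [], [], []
    for polymer in config.polymers:
        props = base * fold_matrix[polymer]
        props = props / props.sum()
        for rep in range(1, config.replicates + 1):
            sid = f"{polymer}_rep{rep}"
            depth = int(rng.integers(config.depth_range[0],
                                     config.depth_range[1] + 1))
            mu = props * depth
            lam = rng.gamma(shape=config.nb_size, scale=mu / config.nb_size)
            counts = rng.poisson(lam)
            p_zero = config.zero_inflation * np.exp(-mu / config.zero_inflation_tau)
            counts = np.where(rng.random(s) < p_zero, 0, counts)
            samples.append(sid)
            meta_rows.append(
                {"sample": sid, "polymer": polymer, "treatment": "Biofilm",
                 "replicate": rep}
            )
            rows.append(counts)

    counts_df = pd.DataFrame(np.array(rows), index=pd.Index(samples, name="sample"),
                             columns=otu_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    taxonomy = pd.Series(
        [TAXONOMY_POOL[i % len(TAXONOMY_POOL)] for i in range(s)],
        index=otu_ids, name="taxonomy",
    )
    # label planted OTUs with the matching plastisphere lineages
    for row, lineage in zip(truth_rows, TAXONOMY_POOL):
        taxonomy.loc[row["otu"]] = lineage
    table = OtuTable(counts=counts_df, metadata=metadata, taxonomy=taxonomy)
    return table, pd.DataFrame(truth_rows)
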