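"""Plain-text readers and writers for the pipeline's file dialects.

Curves, thermograms and spectra travel as two-column CSVs with the
header naming the units; height maps as TSV matrices with a one-line
``# pixel_size_nm`` header; OTU count, metadata and taxonomy tables as
TSV.  Manifest TSVs map data files to polymer / treatment / replicate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .calorimetry import Thermogram
from .community import OtuTable
from .mechanics import LoadStrainCurve
from .spectroscopy import Spectrum
from .topography import HeightMap

PathLike = Union[str, Path]

CURVE_HEADER = ["strain_mm_per_mm", "load_N"]
THERMOGRAM_HEADER = ["temperature_C", "heat_flow_W_per_g"]
SPECTRUM_HEADER = ["wavenumber_cm-1", "absorbance"]


def write_curve(curve: LoadStrainCurve, path: PathLike) -> None:
    pd.DataFrame(
        {CURVE_HEADER[0]: curve.strain, CURVE_HEADER[1]: curve.load}
    ).to_csv(path, index=False)


def read_curve(path: PathLike, bead_id: str = "", initial_diameter: float = 1.0
               ) -> LoadStrainCurve:
    df = pd.read_csv(path)
    return LoadStrainCurve(
        strain=df[CURVE_HEADER[0]].to_numpy(),
        load=df[CURVE_HEADER[1]].to_numpy(),
        bead_id=bead_id or Path(path).stem,
        initial_diameter=initial_diameter,
    )


def write_thermogram(tg: Thermogram, path: PathLike) -> None:
    pd.DataFrame(
        {THERMOGRAM_HEADER[0]: tg.temperature, THERMOGRAM_HEADER[1]: tg.heat_flow}
    ).to_csv(path, index=False)


def read_thermogram(
    path: PathLike, heating_rate: float = 10.0, segment: str = "second heating"
) -> Thermogram:
    df = pd.read_csv(path)
    return Thermogram(
        temperature=df[THERMOGRAM_HEADER[0]].to_numpy(),
        heat_flow=df[THERMOGRAM_HEADER[1]].to_numpy(),
        heating_rate=heating_rate,
        segment=segment,
    )


def write_spectrum(spectrum: Spectrum, path: PathLike) -> None:
    pd.DataFrame(
        {SPECTRUM_HEADER[0]: spectrum.wavenumber,
         SPECTRUM_HEADER[1]: spectrum.absorbance}
    ).to_csv(path, index=False)


def read_spectrum(path: PathLike, label: str = "") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        wavenumber=df[SPECTRUM_HEADER[0]].to_numpy(),
        absorbance=df[SPECTRUM_HEADER[1]].to_numpy(),
        label=label or Path(path).stem,
    )


def write_heightmap(hm: HeightMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_nm\t{hm.pixel_size}\n")
        np.savetxt(fh, hm.heights, delimiter="\t", fmt="%.6g")


def read_heightmap(path: PathLike) -> HeightMap:
    pixel_size = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            pixel_size = float(first.split("\t")[-1])
            heights = np.loadtxt(fh, delimiter="\t")
        else:
            fh.seek(0)
            heights = np.loadtxt(fh, delimiter="\t")
    return HeightMap(heights=heights, pixel_size=pixel_size)


def write_otu_table(table: OtuTable, directory: PathLike, prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.counts.to_csv(directory / f"{prefix}otu.tsv", sep="\t")
    table.metadata.to_csv(directory / f"{prefix}meta.tsv", sep="\t")
    if len(table.taxonomy):
        table.taxonomy.rename("taxonomy").to_csv(
            directory / f"{prefix}taxonomy.tsv", sep="\t"
        )


def read_otu_table(
    otu_path: PathLike, meta_path: PathLike, taxonomy_path: PathLike = None
) -> OtuTable:
    counts = pd.read_csv(otu_path, sep="\t", index_col=0)
    metadata = pd.read_csv(meta_path, sep="\t", index_col=0)
    taxonomy = pd.Series(dtype=object)
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)["taxonomy"]
    return OtuTable(counts=counts, metadata=metadata, taxonomy=taxonomy)


def read_manifest(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
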