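"""Plain-text file interchange: sample CSVs, wide spectra CSVs, ASCII grids.

Rasters use the ESRI ASCII grid format (one band per file, identical header
across co-registered variables), which round-trips through GDAL/rasterio.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_calibration import SpectrumSet
from .synthetic_data import RasterStack

NODATA = -9999.0


def write_ascii_grid(
    path, grid: np.ndarray, *, cellsize: float = 1000.0,
    xllcorner: float = 0.0, yllcorner: float = 0.0, nodata: float = NODATA,
) -> None:
    grid = np.asarray(grid, float)
    out = np.where(np.isfinite(grid), grid, nodata)
    header = (
        f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
        f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
        f"cellsize {cellsize}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path) -> np.ndarray:
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            key, _, val = fh.readline().partition(" ")
            if key.lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[key.lower()] = float(val)
            else:
                fh.seek(pos)
                break
        grid = np.loadtxt(fh)
    nodata = header.get("nodata_value", NODATA)
    return np.where(grid == nodata, np.nan, grid)


def write_rasters(stack: RasterStack, outdir, names=None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.grids.items():
        if names is None or name in names:
            write_ascii_grid(outdir / f"{name}.asc", grid,
                             cellsize=stack.cellsize_m)


def read_rasters(indir, names) -> RasterStack:
    indir = Path(indir)
    return RasterStack({n: read_ascii_grid(indir / f"{n}.asc") for n in names})


def write_spectra(spectra: SpectrumSet, path) -> None:
    spectra.to_frame().to_csv(path, index=False)


def read_spectra(path, state: dict | None = None) -> SpectrumSet:
    return SpectrumSet.from_frame(pd.read_csv(path), state)
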