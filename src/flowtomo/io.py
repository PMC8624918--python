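"""File formats: HDF5 sinogram series, TIFF volume stacks with JSON sidecars.

Sinogram series live in a single HDF5 file with datasets ``values``
(T x n_angles x rows x cols), ``times`` and ``angles`` plus a ``pixel_size``
attribute.  Volumes are multi-page TIFF stacks (one page per z-slice) with a
JSON sidecar recording n, dx and the grid origin.
"""

from __future__ import annotations

import json
import os

import h5py
import numpy as np
import tifffile

from .phantom import SinogramSeries
from .ray_geometry import CellField, DetectorGeometry

__all__ = ["save_sinogram_series", "load_sinogram_series",
           "save_volume", "load_volume"]


def save_sinogram_series(path, series: SinogramSeries) -> None:
    geo = series.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=series.values)
        f.create_dataset("times", data=series.times)
        f.create_dataset("angles", data=np.asarray(geo.angles))
        f.attrs["pixel_size"] = geo.pixel_size
        f.attrs["beam_model"] = geo.beam_model
        f.attrs["source_distance"] = geo.source_distance
        f.attrs["detector_distance"] = geo.detector_distance


def load_sinogram_series(path) -> SinogramSeries:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        times = f["times"][...]
        angles = tuple(f["angles"][...])
        geo = DetectorGeometry(
            n_rows=values.shape[2], n_cols=values.shape[3],
            pixel_size=float(f.attrs["pixel_size"]), angles=angles,
            beam_model=str(f.attrs.get("beam_model", "parallel")),
            source_distance=float(f.attrs.get("source_distance", 0.0)),
            detector_distance=float(f.attrs.get("detector_distance", 0.0)))
    return SinogramSeries(times=times, values=values, geometry=geo)


def _sidecar(path) -> str:
    return os.path.splitext(str(path))[0] + ".json"


def save_volume(path, field: CellField) -> None:
    """Multi-page TIFF, one page per z-slice, plus a JSON grid sidecar."""
    pages = np.moveaxis(field.values, 2, 0)   # page index = z
    tifffile.imwrite(str(path), pages.astype(np.float32))
    with open(_sidecar(path), "w") as f:
        json.dump({"n": field.n, "dx": field.dx,
                   "origin": list(field.origin)}, f)


def load_volume(path) -> CellField:
    pages = tifffile.imread(str(path))
    with open(_sidecar(path)) as f:
        meta = json.load(f)
    values = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
    return CellField(n=int(meta["n"]), dx=float(meta["dx"]),
                     origin=np.asarray(meta["origin"]), values=values)
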