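"""Reading and writing the package's file formats.

Native cube format is HDF5: dataset ``counts`` with axis order
(time, row, col) and root attributes ``bin_width_ps`` and ``rep_rate_hz``.
Multi-page TIFF (one page per time bin) is supported for interoperability,
with timing metadata either in the TIFF description tag or in a JSON sidecar
``<stem>.json`` next to the file.  Timing metadata is mandatory — a cube
without it is rejected rather than silently defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError
from .fitting import LifetimeImage
from .synth import AcquisitionConfig, TCSPCCube

__all__ = [
    "write_cube",
    "read_cube",
    "write_lifetime_image",
    "read_lifetime_image",
    "write_layout",
    "read_layout",
]


def write_cube(cube: TCSPCCube, path: str | Path) -> Path:
    """Write a TCSPC cube to HDF5 (.h5/.hdf5) or multi-page TIFF (.tif)."""
    path = Path(path)
    meta = {
        "bin_width_ps": cube.config.bin_width,
        "rep_rate_hz": cube.config.repetition_frequency,
    }
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("counts", data=cube.counts, compression=None)
            for k, v in meta.items():
                ds.attrs[k] = v
                f.attrs[k] = v
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path,
            cube.counts.astype(np.int32),
            photometric="minisblack",
            description=json.dumps(meta),
        )
        path.with_suffix(".json").write_text(json.dumps(meta))
    else:
        raise FormatError(f"unknown cube extension: {path.suffix!r}")
    return path


def _config_from_meta(meta: dict, shape: tuple[int, int, int]) -> AcquisitionConfig:
    try:
        bin_width = float(meta["bin_width_ps"])
        rep = float(meta["rep_rate_hz"])
    except KeyError as e:
        raise FormatError(f"cube is missing timing metadata attribute {e}") from e
    return AcquisitionConfig(
        n_bins=shape[0],
        bin_width=bin_width,
        repetition_frequency=rep,
        image_size=shape[1:],
    )


def read_cube(path: str | Path) -> TCSPCCube:
    """Read a TCSPC cube written by :func:`write_cube`.

    Raises
    ------
    FormatError
        Unknown extension, unreadable file, missing ``bin_width_ps`` /
        ``rep_rate_hz`` metadata, or non-integer counts.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        try:
            with h5py.File(path, "r") as f:
                if "counts" not in f:
                    raise FormatError(f"{path}: no 'counts' dataset")
                counts = f["counts"][...]
                meta = dict(f.attrs)
        except OSError as e:
            raise FormatError(f"{path}: not a readable HDF5 file ({e})") from e
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            with tifffile.TiffFile(path) as tf:
                counts = tf.asarray()
                desc = tf.pages[0].description
        except Exception as e:
            raise FormatError(f"{path}: not a readable TIFF file ({e})") from e
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
        sidecar = path.with_suffix(".json")
        if "bin_width_ps" not in meta and sidecar.exists():
            meta = json.loads(sidecar.read_text())
    else:
        raise FormatError(f"unknown cube extension: {path.suffix!r}")
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise FormatError(f"{path}: cube must be 3-D, got shape {counts.shape}")
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise FormatError(f"{path}: photon counts must be integers")
        counts = counts.astype(np.int64)
    config = _config_from_meta(meta, counts.shape)
    return TCSPCCube(counts=counts.astype(np.int64), config=config)


def write_lifetime_image(image: LifetimeImage, prefix: str | Path) -> dict[str, Path]:
    """Write tau_m and intensity maps as 32-bit float TIFF plus CSV.

    Returns the paths written, keyed by content.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    tau = np.where(image.mask, image.tau_m_map, np.nan).astype(np.float32)
    paths["tau_tif"] = Path(f"{prefix}_tau_m.tif")
    tifffile.imwrite(paths["tau_tif"], tau)
    paths["intensity_tif"] = Path(f"{prefix}_intensity.tif")
    tifffile.imwrite(paths["intensity_tif"], image.intensity_map.astype(np.float32))
    paths["tau_csv"] = Path(f"{prefix}_tau_m.csv")
    pd.DataFrame(tau).to_csv(paths["tau_csv"], index=False, header=False)
    return paths


def read_lifetime_image(tau_tif: str | Path) -> LifetimeImage:
    """Re-load a tau_m TIFF written by :func:`write_lifetime_image`."""
    tau = tifffile.imread(tau_tif).astype(float)
    mask = ~np.isnan(tau)
    return LifetimeImage(
        tau_m_map=tau, intensity_map=np.zeros_like(tau), mask=mask
    )


def write_layout(label_map: np.ndarray, path: str | Path) -> Path:
    """Write a region-label map as CSV (one cell per pixel)."""
    path = Path(path)
    pd.DataFrame(label_map).to_csv(path, index=False, header=False)
    return path


def read_layout(path: str | Path) -> np.ndarray:
    """Read a region-label map CSV back into an object array."""
    return pd.read_csv(path, header=None, dtype=str).to_numpy(dtype=object)
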