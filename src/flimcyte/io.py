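"""Reading and writing pipeline artifacts.

Decay stacks travel as HDF5 (one file per ROI: ``/decay`` [Z, Y, X, T]
uint16 plus optional ``/marker`` and ``/viability`` [Z, Y, X] float32,
acquisition metadata as root attributes) or as a multi-page TIFF with a
YAML sidecar carrying the same metadata.  Maps are written as float32
TIFF per Z plane, label images as 16-bit TIFF, tables as CSV with a
commented header stating units and conventions.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AcquisitionParams, DecayStack
from .segment import LabelImage

__all__ = [
    "write_decay_stack", "read_decay_stack",
    "write_map_tiff", "write_label_tiff",
    "write_table", "phasor_histogram_csv",
]

_H5_EXT = {".h5", ".hdf5"}
_TIFF_EXT = {".tif", ".tiff"}


class StackFormatError(ValueError):
    """Raised when a stack file is malformed or missing required metadata."""


def _acq_attrs(acq: AcquisitionParams) -> dict:
    return {
        "rep_frequency_hz": acq.rep_frequency,
        "n_time_bins": acq.n_time_bins,
        "pixel_size_um": acq.pixel_size,
        "z_step_um": acq.z_step,
        "n_z": acq.n_z,
        "frame_rows": acq.frame_shape[0],
        "frame_cols": acq.frame_shape[1],
    }


def _acq_from_attrs(attrs: dict, source: str) -> AcquisitionParams:
    required = ["rep_frequency_hz", "n_time_bins", "pixel_size_um", "z_step_um"]
    missing = [k for k in required if k not in attrs]
    if missing:
        raise StackFormatError(
            f"{source}: missing metadata attributes: {', '.join(missing)}")
    return AcquisitionParams(
        rep_frequency=float(attrs["rep_frequency_hz"]),
        n_time_bins=int(attrs["n_time_bins"]),
        pixel_size=float(attrs["pixel_size_um"]),
        z_step=float(attrs["z_step_um"]),
        frame_shape=(int(attrs.get("frame_rows", 0) or attrs["frame_rows"]),
                     int(attrs.get("frame_cols", 0) or attrs["frame_cols"])),
        n_z=int(attrs.get("n_z", 1)),
    )


def write_decay_stack(stack: DecayStack, path: str | os.PathLike) -> Path:
    """Write a decay stack as HDF5 (.h5/.hdf5) or TIFF + YAML sidecar."""
    path = Path(path)
    ext = path.suffix.lower()
    meta = _acq_attrs(stack.acq)
    meta.update(condition=stack.condition, timepoint_min=float(stack.timepoint))
    if ext in _H5_EXT:
        with h5py.File(path, "w") as f:
            f.create_dataset("decay", data=stack.decay.astype(np.uint16)
                             if np.issubdtype(stack.decay.dtype, np.integer)
                             else stack.decay, compression="gzip", compression_opts=4)
            if stack.marker is not None:
                f.create_dataset("marker", data=stack.marker.astype(np.float32))
            if stack.viability is not None:
                f.create_dataset("viability", data=stack.viability.astype(np.float32))
            for k, v in meta.items():
                f.attrs[k] = v
        return path
    if ext in _TIFF_EXT:
        # pages = Z*T frames of (Y, X); sidecar restores shape and channels
        z, y, x, t = stack.decay.shape
        arr = stack.decay
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.uint16)
        tifffile.imwrite(path, arr.transpose(0, 3, 1, 2).reshape(z * t, y, x),
                         photometric="minisblack")
        sidecar = {"metadata": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                                for k, v in meta.items()},
                   "axes": "ZTYX flattened to pages (Z outer, T inner)"}
        for name in ("marker", "viability"):
            ch = getattr(stack, name)
            if ch is not None:
                ch_path = path.with_suffix(f".{name}.tif")
                tifffile.imwrite(ch_path, np.asarray(ch, dtype=np.float32),
                                 photometric="minisblack")
                sidecar[f"{name}_file"] = ch_path.name
        with open(path.with_suffix(".yaml"), "w") as f:
            yaml.safe_dump(sidecar, f)
        return path
    raise StackFormatError(f"unsupported stack extension {ext!r}")


def read_decay_stack(path: str | os.PathLike) -> DecayStack:
    """Read a decay stack written by :func:`write_decay_stack`.

    The round trip is lossless for integer stacks; axis order is
    normalized to (Z, Y, X, T).  Malformed files raise
    :class:`StackFormatError` rather than propagating backend tracebacks.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _H5_EXT:
        try:
            with h5py.File(path, "r") as f:
                if "decay" not in f:
                    raise StackFormatError(f"{path}: missing /decay dataset")
                attrs = dict(f.attrs)
                acq = _acq_from_attrs(attrs, str(path))
                decay = f["decay"][...]
                marker = f["marker"][...] if "marker" in f else None
                viability = f["viability"][...] if "viability" in f else None
        except OSError as e:
            raise StackFormatError(f"{path}: not a readable HDF5 file ({e})") from e
        return DecayStack(decay=decay, acq=acq, marker=marker,
                          viability=viability,
                          condition=str(attrs.get("condition", "control")),
                          timepoint=float(attrs.get("timepoint_min", 0.0)))
    if ext in _TIFF_EXT:
        sidecar_path = path.with_suffix(".yaml")
        if not sidecar_path.exists():
            raise StackFormatError(f"{path}: missing metadata sidecar {sidecar_path.name}")
        try:
            with open(sidecar_path) as f:
                sidecar = yaml.safe_load(f)
            meta = sidecar["metadata"]
        except (yaml.YAMLError, KeyError, TypeError) as e:
            raise StackFormatError(f"{sidecar_path}: malformed sidecar ({e})") from e
        acq = _acq_from_attrs(meta, str(sidecar_path))
        try:
            pages = tifffile.imread(path)
        except (tifffile.TiffFileError, ValueError) as e:
            raise StackFormatError(f"{path}: unreadable TIFF ({e})") from e
        t = acq.n_time_bins
        if pages.ndim != 3 or pages.shape[0] % t:
            raise StackFormatError(f"{path}: page count not divisible by n_time_bins")
        z = pages.shape[0] // t
        decay = pages.reshape(z, t, *pages.shape[1:]).transpose(0, 2, 3, 1)
        channels = {}
        for name in ("marker", "viability"):
            key = f"{name}_file"
            if key in sidecar:
                channels[name] = tifffile.imread(path.parent / sidecar[key])
        return DecayStack(decay=decay, acq=acq,
                          marker=channels.get("marker"),
                          viability=channels.get("viability"),
                          condition=str(meta.get("condition", "control")),
                          timepoint=float(meta.get("timepoint_min", 0.0)))
    raise StackFormatError(f"unsupported stack extension {ext!r}")


def write_map_tiff(map3d: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a (Z, Y, X) float map as a multi-page float32 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(map3d, dtype=np.float32),
                     photometric="minisblack")
    return path


def write_label_tiff(labels: LabelImage, path: str | os.PathLike) -> Path:
    path = Path(path)
    tifffile.imwrite(path, labels.labels.astype(np.uint16))
    return path


def write_table(frame: pd.DataFrame, path: str | os.PathLike,
                header_comment: str | None = None) -> Path:
    """CSV with an optional '#'-prefixed header stating units/conventions."""
    path = Path(path)
    with open(path, "w") as f:
        if header_comment:
            for line in header_comment.splitlines():
                f.write(f"# {line}\n")
        frame.to_csv(f, index=False)
    return path


def phasor_histogram_csv(g: np.ndarray, s: np.ndarray, valid: np.ndarray,
                         path: str | os.PathLike, bins: int = 128) -> Path:
    """2-D phasor-plot histogram exported as (g, s, count) rows."""
    gv, sv = g[valid], s[valid]
    hist, ge, se = np.histogram2d(gv, sv, bins=bins,
                                  range=[[0.0, 1.0], [0.0, 0.6]])
    gi, si = np.nonzero(hist)
    frame = pd.DataFrame({
        "g": 0.5 * (ge[gi] + ge[gi + 1]),
        "s": 0.5 * (se[si] + se[si + 1]),
        "count": hist[gi, si].astype(int),
    })
    return write_table(frame, path,
                       "phasor-plot 2D histogram; g, s bin centers (unitless)")
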