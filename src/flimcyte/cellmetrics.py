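"""Per-cell aggregation of fraction-bound maps: per-Z means, volume means,
areas, and axial profiles.

A cell's statistic at one Z plane is the mean per-pixel fraction of bound
NAD(P)H over pixels that are inside the cell's mask AND above the photon
threshold.  The volume mean pools all valid in-mask voxels of the cell
across planes (equivalently: a valid-pixel-count-weighted mean of the
per-Z means), so planes where the cell has no signal simply contribute
nothing rather than zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AcquisitionParams
from .phasor import FractionBoundMap
from .segment import LabelImage

__all__ = ["CellRecord", "quantify_cells", "records_to_frame",
           "per_z_long_frame", "cell_area", "z_profile"]


@dataclass
class CellRecord:
    """Quantification of one cell in one ROI at one timepoint.

    ``per_z_mean_fbound`` holds NaN for planes where the cell has no valid
    pixel (explicit missingness, never zero); ``volume_mean_fbound`` is
    the mean over all valid in-mask voxels of the volume.
    """

    cell_id: int
    roi_id: str = "roi0"
    condition: str = "control"
    donor_or_replicate: str = "rep0"
    timepoint: float = 10.0
    per_z_mean_fbound: np.ndarray = field(default_factory=lambda: np.array([]))
    volume_mean_fbound: float = float("nan")
    area_um2: float = float("nan")
    area_px: int = 0
    valid_pixel_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def quantify_cells(fbound: FractionBoundMap, labels: LabelImage,
                   acq: AcquisitionParams, condition: str = "control",
                   timepoint: float = 10.0, roi_id: str = "roi0",
                   donor_or_replicate: str = "rep0") -> list[CellRecord]:
    """One CellRecord per labeled cell.

    Valid pixels are in-mask AND flagged valid in the fraction-bound map
    (above the photon threshold).  A plane with zero valid pixels for a
    cell is recorded as NaN and excluded from both the numerator and
    denominator of the volume mean.
    """
    fmap, vmask = fbound.f_bound, fbound.valid_mask
    if fmap.ndim != 3:
        raise ValueError("fraction-bound map must be (Z, Y, X)")
    if fmap.shape[1:] != labels.labels.shape:
        raise ValueError("label image does not match map frame shape")
    n_z = fmap.shape[0]
    records = []
    for cid in labels.cell_ids():
        cmask = labels.labels == cid
        per_z = np.full(n_z, np.nan)
        counts = np.zeros(n_z, dtype=int)
        vol_sum, vol_n = 0.0, 0
        for z in range(n_z):
            sel = cmask & vmask[z]
            n = int(sel.sum())
            counts[z] = n
            if n > 0:
                vals = fmap[z][sel]
                per_z[z] = float(vals.mean())
                vol_sum += float(vals.sum())
                vol_n += n
        records.append(CellRecord(
            cell_id=int(cid), roi_id=roi_id, condition=condition,
            donor_or_replicate=donor_or_replicate, timepoint=timepoint,
            per_z_mean_fbound=per_z,
            volume_mean_fbound=vol_sum / vol_n if vol_n else float("nan"),
            area_px=int(cmask.sum()),
            area_um2=float(cmask.sum()) * acq.pixel_size ** 2,
            valid_pixel_counts=counts))
    return records


def cell_area(labels: LabelImage, pixel_size: float) -> dict[int, float]:
    """Per-cell area in square micrometres: mask pixel count x pixel_size^2."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return {cid: n * pixel_size ** 2 for cid, n in labels.areas_px().items()}


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Tidy cell table: one row per cell x timepoint."""
    return pd.DataFrame([{
        "cell_id": r.cell_id, "roi_id": r.roi_id, "condition": r.condition,
        "donor_or_replicate": r.donor_or_replicate, "timepoint_min": r.timepoint,
        "volume_mean_fbound": r.volume_mean_fbound,
        "area_um2": r.area_um2, "area_px": r.area_px,
        "n_valid_pixels": int(r.valid_pixel_counts.sum()),
    } for r in records])


def per_z_long_frame(records: list[CellRecord], acq: AcquisitionParams
                     ) -> pd.DataFrame:
    """Long-format per-Z companion table (one row per cell x plane)."""
    z_um = acq.z_offsets_um()
    rows = []
    for r in records:
        for z, v in enumerate(r.per_z_mean_fbound):
            rows.append({
                "cell_id": r.cell_id, "roi_id": r.roi_id,
                "condition": r.condition,
                "donor_or_replicate": r.donor_or_replicate,
                "timepoint_min": r.timepoint, "z_index": z,
                "z_um": float(z_um[z]) if z < len(z_um) else np.nan,
                "mean_fbound": float(v),
                "n_valid_pixels": int(r.valid_pixel_counts[z]),
            })
    return pd.DataFrame(rows)


def z_profile(records: list[CellRecord], condition: str | None = None,
              timepoint: float | None = None,
              acq: AcquisitionParams | None = None) -> pd.DataFrame:
    """Across-cell mean and SD of the per-Z fraction bound.

    Returns a frame with one row per plane (z_index, z_um when acquisition
    metadata is given, mean, sd, n_cells).  NaN planes of individual cells
    are ignored plane-wise.  An empty selection yields an empty frame.
    """
    sel = [r for r in records
           if (condition is None or r.condition == condition)
           and (timepoint is None or r.timepoint == timepoint)]
    if not sel:
        return pd.DataFrame(columns=["z_index", "z_um", "mean", "sd", "n_cells"])
    n_z = max(len(r.per_z_mean_fbound) for r in sel)
    z_um = acq.z_offsets_um() if acq is not None else np.full(n_z, np.nan)
    rows = []
    for z in range(n_z):
        vals = np.array([r.per_z_mean_fbound[z] for r in sel
                         if len(r.per_z_mean_fbound) > z])
        vals = vals[~np.isnan(vals)]
        rows.append({
            "z_index": z, "z_um": float(z_um[z]) if z < len(z_um) else np.nan,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else
                  (0.0 if vals.size == 1 else np.nan),
            "n_cells": int(vals.size)})
    return pd.DataFrame(rows)
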