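"""Single-cell masks from marker or NAD(P)H intensity stacks.

The masking workflow mirrors a standard Fiji recipe: maximum-intensity
Z-projection, Gaussian blur, a global threshold (Otsu by default), hole
filling, connected components and small-object removal.  One 2-D label
image is produced per region of interest and reused at every Z plane;
out-of-focus planes are handled downstream by the per-pixel photon
threshold rather than per-plane masks.  When a membrane/actin marker
channel is available it is preferred for masking (the marker outlines the
cell even where NAD(P)H is dim); otherwise masks are built on the NAD(P)H
intensity itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import clear_border

__all__ = [
    "LabelImage",
    "max_project",
    "make_masks",
    "viability_filter",
    "link_timepoints",
]


@dataclass
class LabelImage:
    """2-D integer cell labels shared across all Z planes of one ROI.

    Label 0 is background; labels 1..n_cells are assigned in row-major
    centroid order, so segmentation of identical inputs is deterministic.
    """

    labels: np.ndarray
    source_channel: str = "marker"

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab.astype(np.int32)

    @property
    def n_cells(self) -> int:
        return int(len(self.cell_ids()))

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def centroids(self) -> dict[int, tuple[float, float]]:
        out = {}
        for p in regionprops(self.labels):
            out[int(p.label)] = (float(p.centroid[0]), float(p.centroid[1]))
        return out

    def areas_px(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the Z axis of a (Z, Y, X) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a non-empty (Z, Y, X) stack")
    return stack.max(axis=0)


def make_masks(image: np.ndarray, blur_sigma: float = 2.0,
               threshold_method: str = "otsu",
               threshold_value: float | None = None,
               min_area: int = 50, exclude_border: bool = False,
               source_channel: str = "marker") -> LabelImage:
    """Segment single cells in a 2-D projection image.

    Gaussian blur -> global threshold -> fill holes -> 4-connected
    components -> small-object removal -> optional border exclusion.
    Hole filling is needed because cortical-marker images are rings.  An
    all-background result yields an empty LabelImage (with a warning-free
    zero-cell outcome) rather than an error.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    blurred = gaussian(image, sigma=blur_sigma, preserve_range=True)
    if threshold_method == "otsu":
        if blurred.max() == blurred.min():
            return LabelImage(np.zeros(image.shape, dtype=np.int32),
                              source_channel=source_channel)
        thr = threshold_otsu(blurred)
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed thresholding requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = ndi.binary_fill_holes(blurred > thr)
    if exclude_border:
        binary = clear_border(binary)
    lab = cc_label(binary, connectivity=1)
    # drop small objects, then relabel deterministically by centroid order
    keep = []
    for p in regionprops(lab):
        if p.area >= min_area:
            keep.append((p.centroid, p.label))
    keep.sort(key=lambda c: (c[0][0], c[0][1]))
    out = np.zeros_like(lab, dtype=np.int32)
    for new_id, (_, old) in enumerate(keep, start=1):
        out[lab == old] = new_id
    return LabelImage(out, source_channel=source_channel)


def viability_filter(labels: LabelImage, viability_stack: np.ndarray,
                     cutoff: float) -> LabelImage:
    """Remove cells whose mean viability-dye signal exceeds ``cutoff``.

    The dye accumulates in dead cells; live cells stay near background.
    The mean is taken over the cell's mask pixels across all Z planes.
    """
    via = np.asarray(viability_stack, dtype=np.float64)
    if via.ndim != 3 or via.shape[1:] != labels.labels.shape:
        raise ValueError("viability stack must be (Z, Y, X) co-registered "
                         "with the label image")
    out = labels.labels.copy()
    for cid in labels.cell_ids():
        mask = labels.labels == cid
        if via[:, mask].mean() > cutoff:
            out[mask] = 0
    return LabelImage(out, source_channel=labels.source_channel)


def link_timepoints(labels_seq: list[LabelImage], max_displacement: float = 10.0
                    ) -> list[dict[int, int]]:
    """Greedy nearest-centroid tracking of cell identities across timepoints.

    Returns one mapping per timepoint from that timepoint's labels to
    persistent track identities.  Matching is one-to-one, closest pairs
    first, rejecting displacements beyond ``max_displacement`` pixels;
    unmatched cells open fresh tracks, and tracks with no match are
    retired (never reused).
    """
    mappings: list[dict[int, int]] = []
    next_track = 1
    prev_tracks: dict[int, tuple[float, float]] = {}
    for labels in labels_seq:
        cents = labels.centroids()
        pairs = []
        for cid, c in cents.items():
            for tid, pc in prev_tracks.items():
                d = float(np.hypot(c[0] - pc[0], c[1] - pc[1]))
                if d <= max_displacement:
                    pairs.append((d, cid, tid))
        pairs.sort()
        mapping: dict[int, int] = {}
        used_tracks: set[int] = set()
        for d, cid, tid in pairs:
            if cid in mapping or tid in used_tracks:
                continue
            mapping[cid] = tid
            used_tracks.add(tid)
        for cid in cents:
            if cid not in mapping:
                mapping[cid] = next_track
                next_track += 1
        mappings.append(mapping)
        prev_tracks = {mapping[cid]: cents[cid] for cid in cents}
    return mappings
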