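"""Synthetic TCSPC FLIM data: decay histograms, cell phantoms, ground truth.

The simulator stands in for the two-photon microscope.  It draws per-pixel
photon-count histograms from a bi-exponential free/bound NAD(P)H decay
model sampled at the TCSPC bin centers, with Poisson shot noise at the
photon budgets of a real acquisition (200-300 photons per in-cell pixel).
Cell phantoms emulate T cells spread on a coated coverslip: disk-shaped
cells with a dim nuclear core, a brighter mitochondria-rich cortex, and
mitochondrial puncta enriched at the bottom (coverslip / immune-synapse
side) and top planes of the volume.  An "activated" condition lowers the
bound fraction uniformly (the glycolytic shift); optional couplings add a
cell-area dependence and a synapse-side asymmetry.

Every stochastic operation takes an explicit seed; one master seed fans
out to independent child streams (placement, photon budgets, shot noise)
via numpy's SeedSequence spawning, so geometry is reproducible and is
shared between conditions rendered from the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import AcquisitionParams, DecayStack

__all__ = [
    "DecaySpec",
    "PhantomSpec",
    "GroundTruth",
    "make_decay_histogram",
    "decay_components",
    "simulate_reference",
    "render_phantom",
]


@dataclass(frozen=True)
class DecaySpec:
    """Bi-exponential free/bound NAD(P)H decay at one pixel.

    ``alpha_bound`` is the fractional *intensity* of the bound species: the
    expected share of collected photons emitted by bound NAD(P)H.  With
    this convention the pixel's phasor sits on the chord between the pure
    free and pure bound phasors at fractional distance alpha_bound from
    the free end.
    """

    tau_free_ns: float = 0.4
    tau_bound_ns: float = 3.2
    alpha_bound: float = 0.0
    photons: float = 250.0

    def __post_init__(self) -> None:
        if not (self.tau_bound_ns > self.tau_free_ns > 0):
            raise ValueError("require tau_bound > tau_free > 0")
        if not 0.0 <= self.alpha_bound <= 1.0:
            raise ValueError("alpha_bound must lie in [0, 1]")
        if self.photons < 0:
            raise ValueError("photons must be non-negative")


def decay_components(acq: AcquisitionParams, tau_free_ns: float,
                     tau_bound_ns: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sum free and bound decay shapes at the acquisition's bin centers.

    Each component is exp(-t_k / tau) over one laser period, normalized to
    sum to 1, so mixing them with weights (1-alpha, alpha) yields a
    histogram whose expected bound-photon share is exactly alpha.
    """
    t = acq.bin_centers()
    free = np.exp(-t / (tau_free_ns * 1e-9))
    bound = np.exp(-t / (tau_bound_ns * 1e-9))
    return free / free.sum(), bound / bound.sum()


def make_decay_histogram(spec: DecaySpec, acq: AcquisitionParams,
                         noiseless: bool = False,
                         rng: np.random.Generator | int | None = None) -> np.ndarray:
    """One pixel's photon-count histogram (length ``acq.n_time_bins``).

    The expectation in bin k is
    ``photons * ((1-alpha) * Fhat_k + alpha * Bhat_k)`` with Fhat/Bhat the
    unit-sum mono-exponential shapes; ``noiseless=True`` returns that
    expectation, otherwise independent Poisson counts are drawn per bin.
    """
    free, bound = decay_components(acq, spec.tau_free_ns, spec.tau_bound_ns)
    expected = spec.photons * ((1.0 - spec.alpha_bound) * free
                               + spec.alpha_bound * bound)
    if noiseless:
        return expected
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.poisson(expected)


def simulate_reference(tau_ns: float, photons: float, acq: AcquisitionParams,
                       instrument_shift: tuple[float, float] = (0.0, 1.0),
                       noiseless: bool = False,
                       rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Mono-exponential calibration-standard histogram with instrument response.

    ``instrument_shift = (phase_offset_rad, modulation_factor)`` describes
    the first-harmonic distortion of the instrument: the decay is delayed
    circularly by ``phase_offset / omega`` (rotating its phasor by the
    phase offset) and mixed with a uniform background pedestal sized so the
    phasor modulus shrinks by ``modulation_factor``.  A physical instrument
    response only reduces modulation, so the factor must lie in (0, 1].
    """
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    if photons < 0:
        raise ValueError("photons must be non-negative")
    phase_offset, mod_factor = instrument_shift
    if mod_factor <= 0:
        raise ValueError("modulation factor must be positive")
    if mod_factor > 1:
        raise ValueError("modulation factor above 1 is unphysical "
                         "(instrument response cannot sharpen a decay)")
    tau = tau_ns * 1e-9
    period = acq.period
    delay = phase_offset / acq.omega
    t = np.mod(acq.bin_centers() - delay, period)
    shape = np.exp(-t / tau)
    shape /= shape.sum()
    signal = mod_factor * photons
    background = (photons - signal) / acq.n_time_bins
    expected = signal * shape + background
    if noiseless:
        return expected
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return gen.poisson(expected)


@dataclass(frozen=True)
class PhantomSpec:
    """Scene description for a synthetic T-cell field of view.

    Geometry is in pixels.  ``compartment_alphas`` gives the bound
    fraction (nucleus, cytoplasm, mitochondria); ``condition_effect`` is
    added to every compartment in the "activated" condition (negative =
    more glycolytic).  ``area_coupling`` shifts a cell's alpha by
    ``area_coupling * (area - nominal area) / nominal area`` (nominal =
    pi * cell_radius^2) to emulate the association between spread area
    and metabolic state; its default magnitude matches the activation
    effect, because spreading is the activated phenotype.
    ``mito_z_weights`` modulates the mitochondrial puncta count per plane
    (default U-shaped: mitochondria at the bottom and top of the cell);
    ``synapse_bias`` > 0 additionally enriches bottom planes in the
    activated condition.
    """

    n_cells: int = 10
    cell_radius: float = 10.0
    radius_jitter: float = 0.15
    min_gap: float = 6.0
    nucleus_radius_fraction: float = 0.55
    mito_density: float = 12.0
    mito_radius: float = 1.5
    compartment_alphas: tuple[float, float, float] = (0.25, 0.40, 0.70)
    condition_effect: float = -0.1
    area_coupling: float = -0.1
    synapse_bias: float = 0.0
    activated_size_factor: float = 1.0
    mito_z_weights: tuple[float, ...] | None = None
    photons_range: tuple[float, float] = (200.0, 300.0)
    nucleus_brightness: float = 0.35
    mito_brightness: float = 1.5
    background_photons: float = 1.0
    dead_fraction: float = 0.0
    dead_alpha_shift: float = -0.15
    tau_free_ns: float = 0.4
    tau_bound_ns: float = 3.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.cell_radius <= 0 or self.mito_radius <= 0:
            raise ValueError("radii must be positive")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")
        for a in self.compartment_alphas:
            if not 0 <= a <= 1:
                raise ValueError("compartment alphas must lie in [0, 1]")
        if not 0 <= self.dead_fraction <= 1:
            raise ValueError("dead_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Simulator truth for recovery tests.

    ``label_image`` is 2-D (cells are columnar through Z, like the shared
    2-D masks of the analysis); ``alpha_map`` is the per-pixel bound
    fraction per plane; ``per_cell_alpha`` is the exact mask-average of
    ``alpha_map`` over each cell's pixels across all planes.
    """

    alpha_map: np.ndarray            # (Z, Y, X)
    label_image: np.ndarray          # (Y, X), 0 = background
    per_cell_alpha: dict[int, float]
    per_cell_area: dict[int, int]    # pixels
    condition: str
    dead_cells: frozenset[int] = field(default_factory=frozenset)

    def recompute_per_cell_alpha(self) -> dict[int, float]:
        """Brute-force mask-average of alpha_map, for consistency checks."""
        out = {}
        for cid in np.unique(self.label_image):
            if cid == 0:
                continue
            mask = self.label_image == cid
            out[int(cid)] = float(self.alpha_map[:, mask].mean())
        return out


def _place_cells(spec: PhantomSpec, shape: tuple[int, int], radii: np.ndarray,
                 rng: np.random.Generator, max_tries_per_cell: int = 20000
                 ) -> np.ndarray:
    """Sequential non-overlapping placement of disk centers; raises on jam.

    Cells are placed largest-first (the order that packs hardest), which
    markedly raises the success rate of sequential placement at dense
    coverages; returned centers are re-ordered to match the input radii.
    """
    rows, cols = shape
    order = np.argsort(-np.asarray(radii))
    centers_sorted: list[tuple[float, float]] = []
    gap = spec.min_gap
    radii_sorted = np.asarray(radii)[order]
    centers: list[tuple[float, float]] = centers_sorted
    radii = radii_sorted
    for i, r in enumerate(radii):
        margin = r + 2.0
        if 2 * margin >= min(rows, cols):
            raise RuntimeError("cell radius too large for the frame")
        for _ in range(max_tries_per_cell):
            cy = rng.uniform(margin, rows - margin)
            cx = rng.uniform(margin, cols - margin)
            ok = all((cy - py) ** 2 + (cx - px) ** 2 > (r + radii[j] + gap) ** 2
                     for j, (py, px) in enumerate(centers))
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(
                f"phantom placement failed: could not place cell {i + 1} of "
                f"{spec.n_cells} without overlap (frame too crowded)")
    out = np.empty((len(radii), 2))
    out[order] = np.asarray(centers)
    return out


def render_phantom(spec: PhantomSpec, acq: AcquisitionParams,
                   condition: str = "control", timepoint: float = 10.0,
                   noiseless: bool = False) -> tuple[DecayStack, GroundTruth]:
    """Render one field of view: decay stack, companion channels, truth.

    The returned :class:`DecayStack` carries the marker (LifeAct-like
    cortical ring) and viability channels; :class:`GroundTruth` carries the
    per-pixel bound fraction and per-cell labels.  Rendering the same seed
    under both conditions reuses identical geometry, so a pure
    ``condition_effect`` shifts every cell's truth alpha by exactly that
    amount.
    """
    if condition not in ("control", "activated"):
        raise ValueError("condition must be 'control' or 'activated'")
    activated = condition == "activated"
    rows, cols = acq.frame_shape
    n_z = acq.n_z
    ss = np.random.SeedSequence(spec.seed)
    rng_geom, rng_mito, rng_photon, rng_noise, rng_chan = (
        np.random.default_rng(s) for s in ss.spawn(5))

    radii = spec.cell_radius * (1.0 + spec.radius_jitter
                                * rng_geom.uniform(-1, 1, size=spec.n_cells))
    if activated:
        radii = radii * spec.activated_size_factor
    centers = _place_cells(spec, (rows, cols), radii, rng_geom)

    yy, xx = np.mgrid[0:rows, 0:cols]
    labels = np.zeros((rows, cols), dtype=np.int32)
    nucleus2d = np.zeros((rows, cols), dtype=bool)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        labels[d2 <= r * r] = i
        nucleus2d |= d2 <= (spec.nucleus_radius_fraction * r) ** 2

    areas = {i: int((labels == i).sum()) for i in range(1, spec.n_cells + 1)}
    # area shifts are centered on the nominal cell area, not the realized
    # field mean: a cell's metabolic state depends on its own spread area,
    # and field-mean centering would couple cells within a field
    nominal_area = np.pi * spec.cell_radius ** 2

    a_nuc, a_cyt, a_mit = spec.compartment_alphas
    dead: set[int] = set()
    if spec.dead_fraction > 0:
        n_dead = int(round(spec.dead_fraction * spec.n_cells))
        dead = set(int(i) for i in
                   rng_geom.choice(np.arange(1, spec.n_cells + 1),
                                   size=n_dead, replace=False))

    cell_shift = {}
    for i in range(1, spec.n_cells + 1):
        shift = spec.area_coupling * (areas[i] - nominal_area) / nominal_area
        if activated:
            shift += spec.condition_effect
        if i in dead:
            shift += spec.dead_alpha_shift
        cell_shift[i] = shift

    # per-plane mitochondrial enrichment (U-shaped by default)
    if spec.mito_z_weights is not None:
        zw = np.asarray(spec.mito_z_weights, dtype=float)
        if zw.size != n_z:
            raise ValueError("mito_z_weights length must equal n_z")
    else:
        u = np.linspace(-1, 1, n_z)
        zw = 0.2 + 0.8 * u ** 2
    if activated and spec.synapse_bias != 0:
        bottomness = np.linspace(1.0, 0.0, n_z)
        zw = zw * (1.0 + spec.synapse_bias * bottomness)

    alpha_map = np.zeros((n_z, rows, cols), dtype=np.float64)
    base2d = np.zeros((rows, cols), dtype=np.float64)
    for i in range(1, spec.n_cells + 1):
        m = labels == i
        base2d[m] = a_cyt + cell_shift[i]
        base2d[m & nucleus2d] = a_nuc + cell_shift[i]
    alpha_map[:] = base2d[None]

    # every cell is a scaled copy of one template (punctum radius and
    # placement scale with cell radius), so the compartment composition —
    # hence truth alpha — is independent of cell size by construction
    mito_mask = np.zeros((n_z, rows, cols), dtype=bool)
    for z in range(n_z):
        for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
            n_p = rng_mito.poisson(spec.mito_density * zw[z])
            if n_p == 0:
                continue
            scale = r / spec.cell_radius
            mr = spec.mito_radius * scale
            rho = rng_mito.uniform(spec.nucleus_radius_fraction * r,
                                   max(r - mr, spec.nucleus_radius_fraction * r),
                                   size=n_p)
            ang = rng_mito.uniform(0, 2 * np.pi, size=n_p)
            pad = int(np.ceil(mr)) + 1
            for p in range(n_p):
                py, px = cy + rho[p] * np.sin(ang[p]), cx + rho[p] * np.cos(ang[p])
                y0, y1 = int(max(0, py - pad)), int(min(rows, py + pad + 1))
                x0, x1 = int(max(0, px - pad)), int(min(cols, px + pad + 1))
                sub = ((yy[y0:y1, x0:x1] - py) ** 2
                       + (xx[y0:y1, x0:x1] - px) ** 2) <= mr ** 2
                patch = mito_mask[z, y0:y1, x0:x1]
                patch |= sub & (labels[y0:y1, x0:x1] == i)
                mito_mask[z, y0:y1, x0:x1] = patch
            m = (labels == i)
            alpha_map[z][mito_mask[z] & m] = a_mit + cell_shift[i]

    if alpha_map.min() < 0 or alpha_map.max() > 1:
        raise ValueError("compartment alphas plus shifts leave [0, 1]; "
                         "adjust condition_effect / couplings")

    # photon budget: uniform 200-300 in cells, dim nucleus, bright mitochondria
    in_cell = labels > 0
    photons = np.full((n_z, rows, cols), float(spec.background_photons))
    lo, hi = spec.photons_range
    per_px = rng_photon.uniform(lo, hi, size=(n_z, rows, cols))
    photons[:, in_cell] = per_px[:, in_cell]
    photons[:, in_cell & nucleus2d] *= spec.nucleus_brightness
    photons[mito_mask] *= spec.mito_brightness

    free, bound = decay_components(acq, spec.tau_free_ns, spec.tau_bound_ns)
    decay = np.empty((n_z, rows, cols, acq.n_time_bins),
                     dtype=np.float64 if noiseless else np.uint16)
    for z in range(n_z):
        expected = (photons[z, ..., None]
                    * ((1.0 - alpha_map[z, ..., None]) * free
                       + alpha_map[z, ..., None] * bound))
        decay[z] = expected if noiseless else rng_noise.poisson(expected)

    # marker channel: bright cortical ring, dim interior, mild noise
    marker2d = np.zeros((rows, cols), dtype=np.float64)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring = (d2 <= r * r) & (d2 >= (0.65 * r) ** 2)
        marker2d[(d2 < (0.65 * r) ** 2)] = 0.25
        marker2d[ring] = 1.0
    marker = np.repeat(marker2d[None], n_z, axis=0)
    marker = marker + rng_chan.normal(0, 0.02, size=marker.shape)

    viability = rng_chan.normal(0.02, 0.01, size=(n_z, rows, cols))
    for i in dead:
        viability[:, labels == i] += 1.0

    stack = DecayStack(decay=decay, acq=acq, marker=marker,
                       viability=viability, condition=condition,
                       timepoint=timepoint)
    per_cell_alpha = {i: float(alpha_map[:, labels == i].mean())
                      for i in range(1, spec.n_cells + 1)}
    truth = GroundTruth(alpha_map=alpha_map, label_image=labels,
                        per_cell_alpha=per_cell_alpha, per_cell_area=areas,
                        condition=condition, dead_cells=frozenset(dead))
    return stack, truth
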