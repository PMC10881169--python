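"""First-harmonic phasor analysis of TCSPC decays.

Every pixel's decay histogram I_k is mapped to a point in the phasor plane,

    g = sum_k I_k cos(omega t_k) / sum_k I_k
    s = sum_k I_k sin(omega t_k) / sum_k I_k

with t_k the bin-center timestamps and omega = 2*pi*f the laser angular
frequency.  Mono-exponential decays of lifetime tau fall on the universal
semicircle at

    g = 1 / (1 + (omega tau)^2),   s = omega tau / (1 + (omega tau)^2),

and mixtures fall inside it, on the chord joining the pure-species
locations, at a fractional position equal to the intensity fraction of each
species.  The fraction of bound NAD(P)H at a pixel is the Euclidean
distance between its calibrated phasor and the free-NAD(P)H reference
location; no bound-species location is assumed, because the bound lifetime
depends on which enzyme NAD(P)H is bound to.

Instrument response is handled by calibration against a mono-exponential
standard of known lifetime (fluorescein at pH 9, 4.04 ns): the measured
reference phasor is compared with its analytic location, and the resulting
phase offset and modulation factor are divided out of every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AcquisitionParams, DecayStack

__all__ = [
    "PhasorImage",
    "CalibrationTransform",
    "FreeNADHReference",
    "FractionBoundMap",
    "LifetimeMaps",
    "single_exp_phasor",
    "decay_to_phasor",
    "fit_calibration",
    "apply_calibration",
    "phasor_to_lifetimes",
    "fraction_bound",
]

#: Fluorescein at pH 9: the mono-exponential lifetime standard, in ns.
FLUORESCEIN_TAU_NS = 4.04

#: Free NAD(P)H in solution, in ns.
FREE_NADH_TAU_NS = 0.4


@dataclass
class PhasorImage:
    """Per-pixel first-harmonic phasor coordinates for one stack.

    ``g``/``s`` have shape (Z, Y, X); ``valid`` flags pixels with nonzero
    total counts (the phasor of an empty histogram is undefined; such
    pixels hold g = s = 0 but must be interpreted through the mask).
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    omega: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        if not (self.g.shape == self.s.shape == self.intensity.shape == self.valid.shape):
            raise ValueError("g, s, intensity and valid must share a shape")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class CalibrationTransform:
    """Instrument response in first-harmonic terms.

    ``phase_offset`` (rad) and ``modulation_factor`` (unitless > 0) are the
    rotation and radial scaling the instrument applies to every phasor.
    Calibration removes them: rotate by -phase_offset, scale by
    1/modulation_factor.
    """

    phase_offset: float
    modulation_factor: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.phase_offset) or not np.isfinite(self.modulation_factor):
            raise ValueError("calibration parameters must be finite")
        if self.modulation_factor <= 0:
            raise ValueError("modulation_factor must be positive")

    @classmethod
    def identity(cls) -> "CalibrationTransform":
        return cls(0.0, 1.0)


@dataclass(frozen=True)
class FreeNADHReference:
    """Phasor location of free NAD(P)H, the origin of the fraction-bound axis."""

    tau_free_ns: float
    g_free: float
    s_free: float

    @classmethod
    def from_lifetime(cls, tau_free_ns: float = FREE_NADH_TAU_NS,
                      omega: float = 2 * np.pi * 80e6) -> "FreeNADHReference":
        """Place the reference analytically on the universal semicircle."""
        g, s = single_exp_phasor(tau_free_ns * 1e-9, omega)
        return cls(tau_free_ns, g, s)

    def max_distance(self) -> float:
        """Largest distance from the reference to the closed unit semicircular
        region — the geometric ceiling of the fraction-bound statistic."""
        corners = np.linspace(0, np.pi, 2001)
        pts = np.stack([0.5 + 0.5 * np.cos(corners), 0.5 * np.sin(corners)], axis=1)
        d = np.hypot(pts[:, 0] - self.g_free, pts[:, 1] - self.s_free)
        return float(max(d.max(), np.hypot(self.g_free, self.s_free),
                         np.hypot(1 - self.g_free, self.s_free)))


@dataclass
class FractionBoundMap:
    """Per-pixel fraction of bound NAD(P)H with its validity mask."""

    f_bound: np.ndarray
    valid_mask: np.ndarray
    reference: FreeNADHReference
    photon_threshold: float

    def __post_init__(self) -> None:
        if self.f_bound.shape != self.valid_mask.shape:
            raise ValueError("f_bound and valid_mask must share a shape")


@dataclass
class LifetimeMaps:
    """Phase (TauP) and modulation (TauM) lifetimes in ns, per pixel."""

    tau_phase: np.ndarray
    tau_mod: np.ndarray
    valid: np.ndarray


def single_exp_phasor(tau: float, omega: float) -> tuple[float, float]:
    """Analytic phasor of a mono-exponential decay.

    Parameters
    ----------
    tau : float
        Lifetime in seconds (>= 0).
    omega : float
        Angular frequency in rad/s.

    Returns
    -------
    (g, s) on the universal semicircle: g = 1/(1+(wt)^2), s = wt/(1+(wt)^2).
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    wt = omega * tau
    denom = 1.0 + wt * wt
    return 1.0 / denom, wt / denom


def decay_to_phasor(stack: DecayStack) -> PhasorImage:
    """Transform a decay stack to per-pixel (g, s) phasor coordinates.

    The transform is the normalized first Fourier coefficient of each
    pixel's histogram, evaluated at the laser frequency with bin-center
    timestamps.  Pixels with zero total count are flagged invalid.  The
    intensity image is the per-pixel histogram sum.
    """
    acq = stack.acq
    if acq.n_time_bins < 2:
        raise ValueError("need at least 2 time bins for a phasor transform")
    t = acq.bin_centers()
    w = acq.omega
    cos_t = np.cos(w * t)
    sin_t = np.sin(w * t)

    decay = stack.decay.astype(np.float64, copy=False)
    total = decay.sum(axis=-1)
    valid = total > 0
    # flat matmul over the time axis: (Npix, T) @ (T, 2)
    proj = decay.reshape(-1, acq.n_time_bins) @ np.stack([cos_t, sin_t], axis=1)
    proj = proj.reshape(*decay.shape[:3], 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(valid, proj[..., 0] / np.where(valid, total, 1.0), 0.0)
        s = np.where(valid, proj[..., 1] / np.where(valid, total, 1.0), 0.0)
    return PhasorImage(g=g, s=s, intensity=total, valid=valid, omega=w,
                       calibrated=False)


def phasor_of_histogram(counts: np.ndarray, acq: AcquisitionParams) -> tuple[float, float]:
    """Phasor of a single histogram vector (convenience for references)."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size != acq.n_time_bins:
        raise ValueError("counts must be a vector of length n_time_bins")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    t = acq.bin_centers()
    w = acq.omega
    return (float(counts @ np.cos(w * t) / total),
            float(counts @ np.sin(w * t) / total))


def fit_calibration(reference_phasor: tuple[float, float], reference_tau: float,
                    omega: float) -> CalibrationTransform:
    """Fit the instrument transform from a measured mono-exponential standard.

    Parameters
    ----------
    reference_phasor : (g, s)
        Measured phasor of the standard (e.g. fluorescein at pH 9).
    reference_tau : float
        The standard's known lifetime in seconds.
    omega : float
        Angular frequency in rad/s.

    Returns
    -------
    CalibrationTransform with
    phase_offset = measured phase - analytic phase and
    modulation_factor = measured modulus / analytic modulus.
    """
    g_m, s_m = reference_phasor
    if not (np.isfinite(g_m) and np.isfinite(s_m)):
        raise ValueError("reference phasor must be finite")
    mod_m = float(np.hypot(g_m, s_m))
    if mod_m == 0:
        raise ValueError("degenerate calibration: reference phasor has zero modulus")
    g_a, s_a = single_exp_phasor(reference_tau, omega)
    phase_offset = float(np.arctan2(s_m, g_m) - np.arctan2(s_a, g_a))
    modulation_factor = mod_m / float(np.hypot(g_a, s_a))
    return CalibrationTransform(phase_offset, modulation_factor)


def apply_calibration(phasor: PhasorImage, cal: CalibrationTransform) -> PhasorImage:
    """Remove the instrument transform from every pixel's phasor.

    Each (g, s) is rotated by -phase_offset and scaled by
    1/modulation_factor in polar form.  Intensity and validity are
    untouched.  Calibrating twice is refused.
    """
    if phasor.calibrated:
        raise ValueError("phasor image is already calibrated")
    c = np.cos(-cal.phase_offset)
    si = np.sin(-cal.phase_offset)
    scale = 1.0 / cal.modulation_factor
    g = scale * (phasor.g * c - phasor.s * si)
    s = scale * (phasor.g * si + phasor.s * c)
    return PhasorImage(g=g, s=s, intensity=phasor.intensity.copy(),
                       valid=phasor.valid.copy(), omega=phasor.omega,
                       calibrated=True)


def phasor_to_lifetimes(phasor: PhasorImage) -> LifetimeMaps:
    """Phase and modulation lifetimes (ns) from a calibrated phasor image.

    TauP = (s/g)/omega and TauM = sqrt(1/(g^2+s^2) - 1)/omega.  Pixels with
    g <= 0 or modulus >= 1 (outside the physical range for decays) are
    flagged invalid rather than raising.
    """
    if not phasor.calibrated:
        raise ValueError("lifetimes require a calibrated phasor image")
    g, s = phasor.g, phasor.s
    mod2 = g * g + s * s
    valid = phasor.valid & (g > 0) & (mod2 < 1) & (mod2 > 0)
    w = phasor.omega
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_p = np.where(valid, s / np.where(g != 0, g, 1.0) / w, np.nan)
        tau_m = np.where(valid,
                         np.sqrt(np.where(valid, 1.0 / np.where(mod2 > 0, mod2, 1.0) - 1.0, 0.0)) / w,
                         np.nan)
    return LifetimeMaps(tau_phase=tau_p * 1e9, tau_mod=tau_m * 1e9, valid=valid)


def fraction_bound(phasor: PhasorImage, ref: FreeNADHReference,
                   photon_threshold: float = 5.0) -> FractionBoundMap:
    """Fraction of bound NAD(P)H: distance to the free-NAD(P)H phasor.

    f_bound(pixel) = sqrt((g - g_free)^2 + (s - s_free)^2), a raw Euclidean
    distance in phasor space.  Pixels are valid only where the total photon
    count is strictly above ``photon_threshold`` (default 5 photons, the
    background-exclusion rule) and the phasor itself is defined.
    """
    if not phasor.calibrated:
        raise ValueError("fraction_bound requires a calibrated phasor image")
    if photon_threshold < 0:
        raise ValueError("photon_threshold must be non-negative")
    f = np.hypot(phasor.g - ref.g_free, phasor.s - ref.s_free)
    valid = phasor.valid & (phasor.intensity > photon_threshold)
    return FractionBoundMap(f_bound=f, valid_mask=valid, reference=ref,
                            photon_threshold=photon_threshold)
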