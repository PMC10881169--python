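"""Core containers shared across the pipeline: acquisition metadata and decay stacks.

A FLIM acquisition records, for every pixel of every Z plane, a histogram of
photon arrival times relative to the laser pulse (time-correlated single
photon counting, TCSPC).  The decay stack is therefore a 4-D photon-count
array with axes (Z, Y, X, time-bin).  The laser repetition frequency sets
both the histogram span (one period) and the angular frequency at which the
first-harmonic phasor transform is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["AcquisitionParams", "DecayStack"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for a TCSPC FLIM stack.

    Parameters
    ----------
    rep_frequency : float
        Laser repetition frequency in Hz (default 80 MHz, typical of
        Ti:Sapphire two-photon sources).
    n_time_bins : int
        Number of TCSPC histogram bins spanning one laser period.
    pixel_size : float
        Lateral pixel size in micrometres.
    z_step : float
        Axial spacing between Z planes in micrometres.
    frame_shape : tuple of int
        (rows, cols) of each frame.
    n_z : int
        Number of Z planes acquired per volume.
    """

    rep_frequency: float = 80e6
    n_time_bins: int = 256
    pixel_size: float = 0.5
    z_step: float = 3.0
    frame_shape: tuple[int, int] = (256, 256)
    n_z: int = 6

    def __post_init__(self) -> None:
        if self.rep_frequency <= 0:
            raise ValueError("rep_frequency must be positive")
        if self.n_time_bins < 16:
            raise ValueError("n_time_bins must be at least 16")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 1:
            raise ValueError("frame_shape must be two positive integers")
        if self.n_z < 1:
            raise ValueError("n_z must be at least 1")
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size and z_step must be positive")

    @property
    def period(self) -> float:
        """Laser period in seconds (histogram span)."""
        return 1.0 / self.rep_frequency

    @property
    def omega(self) -> float:
        """First-harmonic angular frequency, omega = 2*pi*f, in rad/s."""
        return 2.0 * np.pi * self.rep_frequency

    def bin_centers(self) -> np.ndarray:
        """Time-bin center timestamps in seconds, shape (n_time_bins,).

        Bins tile one laser period uniformly; bin k is centered at
        (k + 1/2) * period / n_time_bins.
        """
        dt = self.period / self.n_time_bins
        return (np.arange(self.n_time_bins) + 0.5) * dt

    def z_offsets_um(self) -> np.ndarray:
        """Axial offset of each plane in micrometres.

        Plane index 0 is the coverslip-proximal plane; its offset is one
        z_step above the coverslip, so offsets are (index + 1) * z_step.
        """
        return (np.arange(self.n_z) + 1) * self.z_step


@dataclass
class DecayStack:
    """A 4-D photon-count histogram stack plus optional companion channels.

    Attributes
    ----------
    decay : ndarray, shape (Z, Y, X, T)
        Per-pixel photon counts per time bin.  Integer counts for measured
        or Poisson-sampled data; float for noiseless expectations.
    acq : AcquisitionParams
    marker : ndarray (Z, Y, X), optional
        Co-registered membrane/actin marker intensity (LifeAct-like).
    viability : ndarray (Z, Y, X), optional
        Co-registered viability-dye intensity (high in dead cells).
    condition : str
        Experimental condition label ("control" or "activated").
    timepoint : float
        Timepoint label in minutes.
    """

    decay: np.ndarray
    acq: AcquisitionParams
    marker: Optional[np.ndarray] = None
    viability: Optional[np.ndarray] = None
    condition: str = "control"
    timepoint: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.decay)
        if d.ndim != 4:
            raise ValueError("decay must be 4-D (Z, Y, X, T)")
        if d.shape[-1] != self.acq.n_time_bins:
            raise ValueError(
                f"decay has {d.shape[-1]} time bins but acquisition metadata "
                f"declares {self.acq.n_time_bins}"
            )
        for name in ("marker", "viability"):
            ch = getattr(self, name)
            if ch is not None and np.asarray(ch).shape != d.shape[:3]:
                raise ValueError(f"{name} channel shape must match decay (Z, Y, X)")
        self.decay = d

    @property
    def n_z(self) -> int:
        return self.decay.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.decay.shape[1], self.decay.shape[2]

    def intensity(self) -> np.ndarray:
        """NAD(P)H intensity image: per-pixel total photons, shape (Z, Y, X)."""
        return self.decay.sum(axis=-1)
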