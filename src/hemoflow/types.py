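"""Domain containers for the Doppler-to-anomaly pipeline.

Conventions: rasters are row-major numpy arrays, 0-based, origin top-left.
Velocities are expressed in the same units as the Nyquist velocity
``f_nyquist`` (the maximum unambiguous Doppler velocity); normalized flow
images divide by ``f_nyquist`` so pixels live in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: tolerance for the unit-circle bound on normalized autocorrelation components
_EPS = 1e-6


class DataIntegrityError(ValueError):
    """Raw data violates a physical invariant (non-finite, out of range)."""


class DegenerateInputError(ValueError):
    """Input admits no meaningful result (e.g. constant raster for Otsu)."""


class NoFlowError(ValueError):
    """A frame contains no flow pixels after masking; it should be skipped."""


class ContractError(ValueError):
    """Caller violated an interface precondition (shape, range, label)."""


class Label(str, Enum):
    """Class tag of a flow image."""

    NORMAL = "normal"
    HEMORRHAGE = "hemorrhage"
    UNKNOWN = "unknown"


@dataclass
class QuadratureFrame:
    """Raw per-pixel Doppler autocorrelation data for one color-flow frame.

    ``rxx``/``rxy`` are the real/imaginary quadrature components of the
    normalized lag-1 autocorrelation of the Doppler ensemble (dimensionless,
    magnitude <= 1); ``power_db`` is the signal power in decibels;
    ``f_nyquist`` is the Nyquist velocity that scales decoded velocities.
    """

    rxx: np.ndarray
    rxy: np.ndarray
    power_db: np.ndarray
    f_nyquist: float
    frame_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.rxx = np.asarray(self.rxx, dtype=float)
        self.rxy = np.asarray(self.rxy, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if not (self.rxx.shape == self.rxy.shape == self.power_db.shape):
            raise ContractError(
                f"rxx {self.rxx.shape}, rxy {self.rxy.shape}, power_db "
                f"{self.power_db.shape} must share one shape"
            )
        if self.rxx.ndim != 2:
            raise ContractError("rasters must be 2-D")
        if not self.f_nyquist > 0:
            raise ContractError(f"f_nyquist must be > 0, got {self.f_nyquist}")
        for name, arr in (("rxx", self.rxx), ("rxy", self.rxy), ("power_db", self.power_db)):
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise DataIntegrityError(
                    f"non-finite value in {name} at pixel (row={bad[0]}, col={bad[1]})"
                )
        mag2 = self.rxx**2 + self.rxy**2
        if np.any(mag2 > 1.0 + _EPS):
            bad = np.argwhere(mag2 > 1.0 + _EPS)[0]
            raise DataIntegrityError(
                f"|rxx + i rxy| > 1 at pixel (row={bad[0]}, col={bad[1]})"
            )

    @property
    def height(self) -> int:
        return self.rxx.shape[0]

    @property
    def width(self) -> int:
        return self.rxx.shape[1]


@dataclass
class VelocityMap:
    """Decoded velocity/power rasters with a flow-validity mask.

    ``cf_vel`` is the color-flow velocity estimate in [-f_nyquist, f_nyquist];
    ``cf_power`` the linear power R(0,0); ``mask`` is true on flow pixels.
    After masking, ``cf_vel`` is zero wherever ``mask`` is false.
    """

    cf_vel: np.ndarray
    cf_power: np.ndarray
    mask: np.ndarray
    f_nyquist: float
    frame_id: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.cf_vel = np.asarray(self.cf_vel, dtype=float)
        self.cf_power = np.asarray(self.cf_power, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.cf_vel.shape == self.cf_power.shape == self.mask.shape):
            raise ContractError("cf_vel, cf_power and mask must share one shape")
        if np.any(np.abs(self.cf_vel) > self.f_nyquist * (1 + _EPS)):
            raise DataIntegrityError("|cf_vel| exceeds f_nyquist")
        if np.any(self.cf_power < 0):
            raise DataIntegrityError("cf_power must be non-negative")


@dataclass
class FlowImage:
    """A standardized 64x64 normalized velocity image, the GAN's sample space."""

    pixels: np.ndarray
    label: Label = Label.UNKNOWN
    provenance: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ContractError(f"flow image must be square 2-D, got {self.pixels.shape}")
        if np.any(np.abs(self.pixels) > 1.0 + _EPS):
            raise DataIntegrityError("flow image pixels must lie in [-1, 1]")
        self.label = Label(self.label)


@dataclass
class AnomalyResult:
    """Output of mapping one query image into the generator's latent space."""

    reconstruction: np.ndarray
    residual: np.ndarray
    score: float
    loss_trajectory: np.ndarray
    final_z: np.ndarray
    residual_loss: float = 0.0
    discrimination_loss: float = 0.0
    raw_residual_sum: float = 0.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.residual = np.asarray(self.residual, dtype=float)
        self.loss_trajectory = np.asarray(self.loss_trajectory, dtype=float)
        if np.any(self.residual < 0):
            raise ContractError("residual map must be non-negative")
        if not (0.0 <= self.score <= 1.0):
            raise ContractError(f"anomaly score must lie in [0, 1], got {self.score}")
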