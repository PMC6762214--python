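"""Core containers for molecule-count trajectories, spectra, and rate TCFs.

Conventions used throughout the package:

* Spectra are *two-sided*: ``S(omega) = int_{-inf}^{inf} dt e^{-i omega t} C(t)``
  for a stationary autocovariance ``C``.  Because ``C`` is even, ``S`` is real
  and even; it is stored on ``omega >= 0`` only, without doubling.
* Frequencies are angular (rad / time unit).
* The ``omega = 0`` bin is excluded from estimated spectra: renewal-rate
  spectra carry a delta function there that mean subtraction removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

__all__ = [
    "SpectrumKind",
    "TrajectoryEnsemble",
    "FrequencySpectrum",
    "StationaryProduct",
    "RateTCF",
]


class SpectrumKind(str, Enum):
    """What quantity a spectral density describes.

    FSPN
        Frequency spectrum of product number: units count^2 * time.
    FSRR
        Frequency spectrum of reaction rate: units rate^2 * time.  May be
        negative (sub-Poisson timing), bounded below by ``-2<R>``.
    MEAN_SCALED
        A spectrum divided by the square of the mean of its process,
        ``S_q(omega)/<q>^2``: units time.
    """

    FSPN = "FSPN"
    FSRR = "FSRR"
    MEAN_SCALED = "MEAN_SCALED"


@dataclass
class TrajectoryEnsemble:
    """An ensemble of integer molecule-count time traces on a uniform grid.

    Parameters
    ----------
    counts : ndarray, shape (n_traj, n_points)
        Nonnegative integer molecule numbers, one row per trajectory.
    dt : float
        Recording step (time between grid points), > 0.
    t0 : float
        Time of the first grid point (after any burn-in).
    species_label : str
        Name of the recorded species (e.g. ``"product"``, ``"mRNA"``).
    provenance : dict
        Free-form metadata (model name, parameters, seed, burn_in, ...).
    """

    counts: np.ndarray
    dt: float
    t0: float = 0.0
    species_label: str = "product"
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D array (n_traj, n_points)")
        if c.shape[1] < 2:
            raise ValueError("trajectories need at least 2 time points")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        self.counts = c

    @property
    def n_traj(self) -> int:
        return self.counts.shape[0]

    @property
    def n_points(self) -> int:
        return self.counts.shape[1]

    @property
    def window_length(self) -> float:
        """Observation window ``T = (n_points - 1) * dt``."""
        return (self.n_points - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_points)

    def grand_mean(self) -> float:
        """Mean count over the whole ensemble (all trajectories, all times)."""
        return float(self.counts.mean())


@dataclass
class FrequencySpectrum:
    """A real spectral density sampled at nonnegative angular frequencies."""

    omegas: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    mean_level: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.omegas, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.shape != w.shape:
            raise ValueError("omegas and values must be 1-D arrays of equal length")
        if (w < 0).any():
            raise ValueError("omegas must be >= 0")
        if w.size > 1 and not (np.diff(w) > 0).all():
            raise ValueError("omegas must be strictly increasing")
        if not np.isfinite(v).all():
            raise ValueError("spectral values must be finite")
        self.kind = SpectrumKind(self.kind)
        if self.kind is SpectrumKind.MEAN_SCALED and self.mean_level is None:
            raise ValueError("MEAN_SCALED spectra require mean_level")
        self.omegas = w
        self.values = v

    def same_grid(self, other: "FrequencySpectrum", rtol: float = 1e-9) -> bool:
        return self.omegas.shape == other.omegas.shape and np.allclose(
            self.omegas, other.omegas, rtol=rtol, atol=0.0
        )

    def require_kind(self, kind: SpectrumKind) -> None:
        if self.kind is not SpectrumKind(kind):
            raise ValueError(
                f"expected spectrum of kind {SpectrumKind(kind).value}, "
                f"got {self.kind.value}"
            )


@dataclass
class StationaryProduct:
    """Stationary description of one birth-death stage.

    ``mean_rate = gamma * mean_count`` (flux balance of creation against
    first-order decay with inverse lifetime ``gamma``).  Construct from any
    two of the three quantities via the classmethods.
    """

    mean_count: float
    gamma: float
    mean_rate: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if not self.mean_rate > 0:
            raise ValueError("mean_rate must be > 0")
        if not np.isclose(self.mean_rate, self.gamma * self.mean_count, rtol=1e-9):
            raise ValueError("mean_rate must equal gamma * mean_count")

    @classmethod
    def from_mean_count(cls, mean_count: float, gamma: float) -> "StationaryProduct":
        return cls(mean_count=mean_count, gamma=gamma, mean_rate=gamma * mean_count)

    @classmethod
    def from_mean_rate(cls, mean_rate: float, gamma: float) -> "StationaryProduct":
        return cls(mean_count=mean_rate / gamma, gamma=gamma, mean_rate=mean_rate)


@dataclass
class RateTCF:
    """Stationary time correlation function of a rate (or count) fluctuation."""

    lags: np.ndarray
    values: np.ndarray
    mean_rate: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.lags, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if t[0] != 0 or (np.diff(t) <= 0).any():
            raise ValueError("lags must ascend from 0")
        if not np.isfinite(v).all():
            raise ValueError("TCF values must be finite")
        self.lags = t
        self.values = v
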