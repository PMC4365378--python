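"""Kinematic bookkeeping for uniaxial compression records.

A compression test commands a crosshead extension trajectory e(t) starting
from the reference extension e0 (the unloaded sample thickness).  Three
equivalent deformation measures are used throughout the package:

* stretch ratio          lambda  = e / e0
* strain (Eulerian-type) eps     = (e - e0) / e  = 1 - 1/lambda
* engineering strain     eps_eng = (e - e0) / e0 = lambda - 1

Compression means e < e0, hence lambda < 1 and both strains negative.
Test protocols are programmed in *magnitudes* of engineering strain (a 20%
compression is eps_eng = -0.20); the signed quantities live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinematicSignal",
    "stretch_from_strain",
    "strain_from_stretch",
    "stress_conversion",
]


def stretch_from_strain(eps):
    """Stretch ratio lambda = (1 - eps)^-1 from the strain eps = (e - e0)/e.

    Raises ValueError for eps >= 1, where the stretch is undefined.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps >= 1.0):
        raise ValueError("stretch undefined for eps >= 1")
    return 1.0 / (1.0 - eps)


def strain_from_stretch(lam):
    """Inverse of :func:`stretch_from_strain`: eps = 1 - 1/lambda, lambda > 0."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    return 1.0 - 1.0 / lam


def stress_conversion(sigma, e, e0):
    """Convert Eulerian (Cauchy) stress sigma to the stress measure T = sigma*e0/e.

    At lambda = 1 the two coincide.  ``e`` must be positive.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("extension must be positive")
    return np.asarray(sigma, dtype=float) * (e0 / e)


@dataclass(frozen=True)
class KinematicSignal:
    """Sampled extension trajectory of one compression test.

    Parameters
    ----------
    t : array
        Time grid in seconds, strictly increasing.
    e : array
        Extension in mm, strictly positive (the platen never closes fully).
    e0 : float
        Reference extension at t = 0, mm.

    The strain/stretch views are derived properties, so they are mutually
    consistent with (e, e0) by construction.
    """

    t: np.ndarray
    e: np.ndarray
    e0: float

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "e", e)
        if t.ndim != 1 or e.shape != t.shape:
            raise ValueError("t and e must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("empty signal")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not self.e0 > 0:
            raise ValueError("e0 must be positive")
        if np.any(e <= 0):
            raise ValueError("extension must stay positive")

    @property
    def lam(self) -> np.ndarray:
        """Stretch ratio lambda = e/e0 (> 0)."""
        return self.e / self.e0

    @property
    def eps(self) -> np.ndarray:
        """Strain eps = (e - e0)/e; satisfies lambda = (1 - eps)^-1."""
        return 1.0 - self.e0 / self.e

    @property
    def eps_eng(self) -> np.ndarray:
        """Engineering strain (e - e0)/e0 = lambda - 1."""
        return self.e / self.e0 - 1.0

    def __len__(self) -> int:
        return self.t.size

    @classmethod
    def from_strain(cls, t, eps, e0) -> "KinematicSignal":
        """Build from the signed strain eps = (e - e0)/e."""
        return cls(t=np.asarray(t, float), e=e0 * stretch_from_strain(eps), e0=e0)

    @classmethod
    def from_eng_strain(cls, t, eps_eng, e0) -> "KinematicSignal":
        """Build from the signed engineering strain (e - e0)/e0."""
        e = e0 * (1.0 + np.asarray(eps_eng, float))
        return cls(t=np.asarray(t, float), e=e, e0=e0)

    @classmethod
    def from_stretch(cls, t, lam, e0) -> "KinematicSignal":
        return cls(t=np.asarray(t, float), e=e0 * np.asarray(lam, float), e0=e0)
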