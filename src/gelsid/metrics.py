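"""Validation metrics and graphical diagnostics.

FIT is the normalized goodness-of-fit percentage

    FIT = 100 * (1 - ||y_model - y_meas|| / ||y_meas - mean(y_meas)||)

(Euclidean norm over the whole record): 100 for a perfect match, 0 for the
mean predictor, unbounded below.  FPE is Akaike's final prediction error
(loss/N) * (1 + d/N)/(1 - d/N) for d estimated parameters on N samples,
used to rank structures on the identification data.

The Mooney-Rivlin linearization plots z = sigma/(lambda^2 - 1/lambda)
against x = 1/lambda: data obeying the hyperelastic law fall on the line
z = C1 + C2*x, so the intercept and slope of the least-squares line read
off the constants, and zero slope is the Neo Hookean signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "fit_percent",
    "fpe",
    "mr_linearize",
    "MRLinearization",
    "hysteresis_area",
    "split_first_compression",
    "FitReport",
]


def fit_percent(y_model, y_meas) -> float:
    """Goodness-of-fit percentage; <= 100 always, 100 iff the signals match.

    Requires equal lengths >= 2 and a non-constant measured signal (the
    denominator vanishes otherwise).
    """
    y_model = np.asarray(y_model, dtype=float)
    y_meas = np.asarray(y_meas, dtype=float)
    if y_model.shape != y_meas.shape:
        raise ValueError("signals must have equal shapes")
    if y_meas.size < 2:
        raise ValueError("need at least two samples")
    denom = np.linalg.norm(y_meas - np.mean(y_meas))
    if denom == 0.0:
        raise ValueError("measured signal is constant: FIT undefined")
    return float(100.0 * (1.0 - np.linalg.norm(y_model - y_meas) / denom))


def fpe(loss: float, n_params: int, n_samples: int) -> float:
    """Akaike final prediction error (loss/N)*(1 + d/N)/(1 - d/N)."""
    if n_samples <= n_params:
        raise ValueError("need more samples than parameters")
    d, N = n_params, n_samples
    return (loss / N) * (1.0 + d / N) / (1.0 - d / N)


@dataclass(frozen=True)
class MRLinearization:
    """Transformed point cloud and fitted line of the Mooney-Rivlin diagnostic."""

    x: np.ndarray          # 1/lambda
    z: np.ndarray          # sigma / (lambda^2 - 1/lambda)
    intercept: float       # C1 for data obeying the hyperelastic law
    slope: float           # C2 likewise
    n_excluded: int        # points dropped in the guard band around lambda = 1


def mr_linearize(lam, sigma, guard: float = 0.01) -> MRLinearization:
    """Least-squares line through the Mooney-Rivlin-transformed stress data.

    Points with |lambda - 1| < guard are excluded (the transform is singular
    at lambda = 1); at least two admissible points are required.
    """
    lam = np.asarray(lam, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if lam.shape != sigma.shape:
        raise ValueError("lam and sigma must have equal shapes")
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    keep = np.abs(lam - 1.0) >= guard
    n_excluded = int(np.sum(~keep))
    lam_k = lam[keep]
    sig_k = sigma[keep]
    if lam_k.size < 2:
        raise ValueError(
            f"fewer than 2 admissible points after excluding {n_excluded} near lambda = 1"
        )
    x = 1.0 / lam_k
    z = sig_k / (lam_k**2 - 1.0 / lam_k)
    slope, intercept = np.polyfit(x, z, 1)
    return MRLinearization(
        x=x, z=z, intercept=float(intercept), slope=float(slope), n_excluded=n_excluded
    )


def hysteresis_area(eps_cycle, y_cycle, closure_rtol: float = 1e-3) -> float:
    """Dissipated work per cycle, the loop integral of y deps in time order.

    The trajectory must form a closed cycle (first and last points agree to
    closure_rtol relative to the signal ranges); the closing segment is
    included.  Non-negative for passive parameter sets at steady state; zero
    for a purely elastic response.
    """
    eps = np.asarray(eps_cycle, dtype=float)
    y = np.asarray(y_cycle, dtype=float)
    if eps.shape != y.shape or eps.size < 3:
        raise ValueError("need matching arrays of at least 3 points")
    eps_range = np.ptp(eps) or 1.0
    y_range = np.ptp(y) or 1.0
    gap_eps = abs(eps[-1] - eps[0]) / eps_range
    gap_y = abs(y[-1] - y[0]) / y_range
    if gap_eps > closure_rtol or gap_y > closure_rtol:
        raise ValueError(
            "trajectory is not closed: relative endpoint gaps "
            f"(eps: {gap_eps:.3g}, y: {gap_y:.3g}) exceed tolerance {closure_rtol:g}"
        )
    eps_c = np.append(eps, eps[0])
    y_c = np.append(y, y[0])
    return float(np.sum(0.5 * (y_c[1:] + y_c[:-1]) * np.diff(eps_c)))


def split_first_compression(eps_eng, lower_bound: float):
    """Split a cyclic record into first compression and the cycling rest.

    The split index is the first sample whose compression magnitude
    |eps_eng| reaches the lower cycle bound; returns (first, rest) index
    arrays.  The convention keys on the bound rather than on the first
    load peak, so it needs no peak detection.
    """
    mag = np.abs(np.asarray(eps_eng, dtype=float))
    hit = np.nonzero(mag >= lower_bound)[0]
    if hit.size == 0:
        raise ValueError("record never reaches the lower cycle bound")
    k = int(hit[0])
    n = mag.size
    return np.arange(0, k), np.arange(k, n)


@dataclass
class FitReport:
    """Comparison table of identified structures.

    fit maps structure -> {sample label -> FIT%}; fpe maps structure -> FPE
    on the identification cycling data; params maps structure -> estimated
    parameter record.  The ranking orders structures by ascending FPE.
    """

    fit: dict = field(default_factory=dict)
    fpe: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def fpe_ranking(self) -> list:
        return sorted(self.fpe, key=self.fpe.get)

    def best_by_validation_fit(self) -> str:
        """Structure with the highest median validation FIT."""
        med = {s: float(np.median(list(v.values()))) for s, v in self.fit.items() if v}
        return max(med, key=med.get)

    def to_frame(self):
        """Long-format table (structure, sample, FIT%, FPE) as a DataFrame."""
        import pandas as pd

        rows = []
        for s, by_sample in self.fit.items():
            for label, val in by_sample.items():
                rows.append(
                    {"structure": s, "sample": label, "fit_percent": val,
                     "fpe": self.fpe.get(s, np.nan)}
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["structure,sample,fit_percent,fpe"]
        for s, by_sample in self.fit.items():
            for label, val in by_sample.items():
                lines.append(f"{s},{label},{val:.4f},{self.fpe.get(s, float('nan')):.6e}")
        lines.append(f"# fpe_ranking = {' < '.join(self.fpe_ranking)}")
        return "\n".join(lines) + "\n"
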