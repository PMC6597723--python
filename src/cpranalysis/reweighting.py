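"""Canonical-ensemble estimates from boosted (aMD) snapshot ensembles.

Each snapshot's statistical weight is exp(ΔV/k_BT); weights are
computed with a max-shift so the largest exponent is zero before
normalization, making them exactly invariant under ΔV → ΔV + c and
immune to overflow.  Free-energy surfaces are −k_BT ln P over the
probability *density* of the binned observables, shifted so the lowest
occupied bin is exactly zero; empty bins are masked rather than given a
numeric value.  Every reweighted estimate should be reported together
with the effective sample size (Σw)²/Σw² as a reliability diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import kbt
from .exceptions import StatisticsError, ValidationError

__all__ = [
    "WeightedEnsemble",
    "FreeEnergySurface",
    "snapshot_weights",
    "effective_sample_size",
    "weighted_histogram",
    "free_energy_2d",
    "weighted_pearson",
    "select_window",
    "default_edges",
]


@dataclass(frozen=True)
class WeightedEnsemble:
    """Observable value(s) per snapshot with normalized weights."""

    values: np.ndarray  # (n,) or (n, k)
    weights: np.ndarray  # (n,), sum 1
    temperature: float = 310.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)
        if len(values) != len(weights):
            raise ValidationError("values and weights must have the same length")
        if np.any(weights < 0):
            raise ValidationError("weights must be >= 0")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValidationError("weights must sum to 1 within 1e-12")

    @property
    def ess(self) -> float:
        return effective_sample_size(self.weights)


def snapshot_weights(delta_v: Sequence[float], temperature: float = 310.0) -> np.ndarray:
    """Normalized snapshot weights wᵢ ∝ exp(ΔVᵢ/k_BT)."""
    dv = np.asarray(delta_v, dtype=float)
    if dv.size == 0:
        raise ValidationError("empty ΔV series")
    if np.any(dv < 0) or not np.all(np.isfinite(dv)):
        raise ValidationError("ΔV values must be finite and >= 0")
    expo = (dv - dv.max()) / kbt(temperature)
    w = np.exp(expo)
    return w / w.sum()


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (Σw)²/Σw²."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w * w).sum())


def weighted_histogram(
    values: np.ndarray,
    weights: Optional[np.ndarray],
    edges: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Probability mass per bin over the retained (in-range) values.

    Returns (bin masses summing to 1, number of dropped out-of-range
    values).  Raises when no weight falls inside the edges.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValidationError("histogram edges must be strictly increasing")
    if weights is None:
        weights = np.full(len(values), 1.0 / max(len(values), 1))
    weights = np.asarray(weights, dtype=float)
    inside = (values >= edges[0]) & (values <= edges[-1])
    n_dropped = int(np.count_nonzero(~inside))
    mass, _ = np.histogram(values[inside], bins=edges, weights=weights[inside])
    total = mass.sum()
    if total <= 0:
        raise StatisticsError("no weight retained inside the histogram range")
    return mass / total, n_dropped


@dataclass(frozen=True)
class FreeEnergySurface:
    """2D binned free energies (kcal/mol) with min over occupied bins = 0.

    ``free_energy`` is a masked array: empty bins are masked, occupied
    bins hold −k_BT ln(density) shifted so the minimum is exactly zero.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ma.MaskedArray
    temperature: float
    probability_mass: np.ndarray  # per-bin mass, sums to 1 over occupied bins

    @property
    def occupied(self) -> np.ndarray:
        return ~self.free_energy.mask

    def write_tsv(self, path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        with open(path, "w") as fh:
            fh.write(f"# free-energy surface, T={self.temperature} K; empty bins omitted\n")
            fh.write("# x_center\ty_center\tfree_energy_kcal_mol\tprobability_mass\n")
            for i in range(len(xc)):
                for j in range(len(yc)):
                    if not self.free_energy.mask[i, j]:
                        fh.write(f"{xc[i]:.6g}\t{yc[j]:.6g}\t"
                                 f"{self.free_energy[i, j]:.10g}\t"
                                 f"{self.probability_mass[i, j]:.10g}\n")


def free_energy_2d(
    x: np.ndarray,
    y: np.ndarray,
    weights: Optional[np.ndarray],
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    temperature: float = 310.0,
) -> FreeEnergySurface:
    """Reweighted 2D free-energy surface f = −k_BT ln P, min-shifted to 0.

    P is the probability density from the weighted joint histogram of
    (x, y); out-of-range points are dropped and the retained mass
    renormalized.  With fewer than 2 occupied bins a warning is issued
    but the surface is still returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if np.any(np.diff(x_edges) <= 0) or np.any(np.diff(y_edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing")
    if weights is None:
        weights = np.full(len(x), 1.0 / max(len(x), 1))
    weights = np.asarray(weights, dtype=float)
    inside = (
        (x >= x_edges[0]) & (x <= x_edges[-1]) & (y >= y_edges[0]) & (y <= y_edges[-1])
    )
    mass, _, _ = np.histogram2d(x[inside], y[inside], bins=(x_edges, y_edges),
                                weights=weights[inside])
    total = mass.sum()
    if total <= 0:
        raise StatisticsError("no weight retained inside the surface range")
    mass = mass / total
    area = np.outer(np.diff(x_edges), np.diff(y_edges))
    occupied = mass > 0
    if np.count_nonzero(occupied) < 2:
        import warnings

        warnings.warn("free-energy surface has fewer than 2 occupied bins")
    kt = kbt(temperature)
    f = np.ma.masked_all(mass.shape)
    with np.errstate(divide="ignore"):
        f[occupied] = -kt * np.log(mass[occupied] / area[occupied])
    f -= f.min()
    # exact zero at the minimum (guard against rounding in the subtraction)
    f[np.unravel_index(np.ma.argmin(f), f.shape)] = 0.0
    return FreeEnergySurface(x_edges, y_edges, f, temperature, mass)


def weighted_pearson(
    x: np.ndarray, y: np.ndarray, weights: Optional[np.ndarray] = None
) -> float:
    """Weighted Pearson correlation; uniform weights give the standard r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have the same length")
    if weights is None:
        weights = np.ones(len(x))
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be >= 0")
    pos = w > 0
    if len(np.unique(np.c_[x[pos], y[pos]], axis=0)) < 2:
        raise StatisticsError("need >= 2 distinct points with positive weight")
    w = w / w.sum()
    mx, my = w @ x, w @ y
    dx, dy = x - mx, y - my
    cov = w @ (dx * dy)
    vx, vy = w @ (dx * dx), w @ (dy * dy)
    if vx <= 0 or vy <= 0:
        raise StatisticsError("zero variance: correlation undefined")
    return float(np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0))


def select_window(times: np.ndarray, t_start: float, t_end: float) -> np.ndarray:
    """Indices of frames with t_start <= t < t_end (half-open window)."""
    times = np.asarray(times, dtype=float)
    if not t_start < t_end:
        raise ValidationError(f"empty window: t_start={t_start} >= t_end={t_end}")
    idx = np.flatnonzero((times >= t_start) & (times < t_end))
    if idx.size == 0:
        raise ValidationError(
            f"window [{t_start}, {t_end}) contains no frames "
            f"(data range {times.min()}..{times.max()})"
        )
    return idx


def default_edges(
    values: np.ndarray,
    weights: Optional[np.ndarray] = None,
    n_bins: int = 50,
    percentiles: tuple[float, float] = (0.5, 99.5),
) -> np.ndarray:
    """Default binning: n_bins spanning the weighted percentile range."""
    values = np.asarray(values, dtype=float)
    if weights is None:
        lo, hi = np.percentile(values, percentiles)
    else:
        w = np.asarray(weights, dtype=float)
        lo, hi = np.percentile(
            values, percentiles, weights=w / w.sum(), method="inverted_cdf"
        )
    if hi <= lo:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)
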