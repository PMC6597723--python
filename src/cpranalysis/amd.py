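"""Accelerated-MD boost and a toy Langevin simulator.

The boost lifts the potential below a threshold E_B:

    V*(r) = V(r) + ΔV(r),
    ΔV(r) = 0                                   for V(r) >= E_B,
            (E_B - V(r))² / (α + E_B - V(r))    for V(r) <  E_B,

with α > 0 controlling how strongly the surface is flattened.  The
boosted force is the unboosted force scaled by

    dV*/dV = α² / (α + E_B - V)²   (= 1 above the threshold),

a factor in (0, 1] that vanishes deep below the threshold.  Canonical
statistics are recovered downstream by weighting each snapshot with
exp(ΔV/k_BT) (see :mod:`cpranalysis.reweighting`).

The simulator integrates underdamped Langevin dynamics with the BAOAB
splitting (exact Ornstein–Uhlenbeck friction substep), which samples
the configurational Boltzmann distribution with O(dt²) bias — the toy
stand-in for the all-atom thermostat whose sampled distribution is what
matters here.  Units: kcal/mol, Å, ps, amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .constants import KCAL_PER_MOL_ACCEL, kbt
from .exceptions import IntegrationError, ValidationError
from .model_io import write_deltav_log

__all__ = [
    "BoostSpec",
    "boost_delta_v",
    "force_scale",
    "Harmonic",
    "DoubleWell",
    "CustomPotential",
    "SimSpec",
    "ToyTrajectory",
    "run_langevin",
]


# ---------------------------------------------------------------------------
# boost
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoostSpec:
    """Boost threshold E_B and depth parameter α, both kcal/mol, α > 0."""

    e_b: float
    alpha: float

    def __post_init__(self):
        if not np.isfinite(self.e_b):
            raise ValidationError("boost threshold e_b must be finite")
        if not (self.alpha > 0):
            raise ValidationError("boost parameter alpha must be > 0")

    def delta_v(self, v):
        v = np.asarray(v, dtype=float)
        below = v < self.e_b
        gap = np.where(below, self.e_b - v, 0.0)
        out = np.where(below, gap * gap / (self.alpha + gap), 0.0)
        return out if out.ndim else float(out)

    def force_scale(self, v):
        v = np.asarray(v, dtype=float)
        below = v < self.e_b
        gap = np.where(below, self.e_b - v, 0.0)
        out = np.where(below, (self.alpha / (self.alpha + gap)) ** 2, 1.0)
        return out if out.ndim else float(out)


BoostLike = Union[BoostSpec, Sequence[BoostSpec], None]


def _boost_list(boost: BoostLike) -> list[BoostSpec]:
    if boost is None:
        return []
    if isinstance(boost, BoostSpec):
        return [boost]
    return list(boost)


def boost_delta_v(v, boost: BoostLike):
    """Total boost energy ΔV(V) in kcal/mol; a list of boosts adds."""
    specs = _boost_list(boost)
    if not specs:
        return np.zeros_like(np.asarray(v, dtype=float)) if np.ndim(v) else 0.0
    total = specs[0].delta_v(v)
    for b in specs[1:]:
        total = total + b.delta_v(v)
    return total


def force_scale(v, boost: BoostLike):
    """d(V + ΣΔVᵢ)/dV: the factor multiplying the unboosted force.

    For a single boost this is α²/(α + E_B − V)² below threshold and 1
    above; additive boosts compose as 1 + Σ(sᵢ − 1).
    """
    specs = _boost_list(boost)
    if not specs:
        return np.ones_like(np.asarray(v, dtype=float)) if np.ndim(v) else 1.0
    total = specs[0].force_scale(v)
    for b in specs[1:]:
        total = total + b.force_scale(v) - 1.0
    return total


# ---------------------------------------------------------------------------
# toy potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Harmonic:
    """V(x) = ½ k |x − c|², k in kcal/mol/Å²."""

    k: float = 10.0
    dim: int = 1
    center: tuple[float, ...] = ()

    def _c(self):
        return np.asarray(self.center if self.center else np.zeros(self.dim))

    def value(self, x) -> float:
        d = np.asarray(x, dtype=float) - self._c()
        return 0.5 * self.k * float(d @ d)

    def gradient(self, x) -> np.ndarray:
        return self.k * (np.asarray(x, dtype=float) - self._c())

    def minimum(self) -> np.ndarray:
        return self._c()


@dataclass(frozen=True)
class DoubleWell:
    """Quartic double well V(x) = h (x² − a²)²/a⁴ + tilt·x/a (1D).

    Minima near ±a, barrier height h at x = 0 (for tilt = 0); a small
    tilt makes the wells inequivalent by ≈ 2·tilt.
    """

    barrier: float = 7.0  # kcal/mol
    half_separation: float = 1.0  # Å
    tilt: float = 0.0  # kcal/mol
    dim: int = 1

    def value(self, x) -> float:
        x0 = float(np.asarray(x, dtype=float).ravel()[0])
        a = self.half_separation
        return self.barrier * (x0 * x0 - a * a) ** 2 / a**4 + self.tilt * x0 / a

    def gradient(self, x) -> np.ndarray:
        x0 = float(np.asarray(x, dtype=float).ravel()[0])
        a = self.half_separation
        g = 4.0 * self.barrier * x0 * (x0 * x0 - a * a) / a**4 + self.tilt / a
        return np.array([g])

    def minimum(self) -> np.ndarray:
        return np.array([-self.half_separation])


@dataclass(frozen=True)
class CustomPotential:
    """Adapter for a user-supplied bounded-below potential with gradient."""

    value_fn: Callable[[np.ndarray], float]
    gradient_fn: Callable[[np.ndarray], np.ndarray]
    dim: int = 1

    def value(self, x) -> float:
        return float(self.value_fn(np.asarray(x, dtype=float)))

    def gradient(self, x) -> np.ndarray:
        return np.asarray(self.gradient_fn(np.asarray(x, dtype=float)), dtype=float)

    def minimum(self) -> np.ndarray:
        return np.zeros(self.dim)


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSpec:
    """Langevin run settings (T in K, friction ps⁻¹, timestep ps, mass amu)."""

    temperature: float = 310.0
    friction: float = 1.0
    timestep: float = 0.002
    n_steps: int = 100_000
    stride: int = 10
    seed: int = 0
    mass: float = 12.0
    x0: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValidationError("timestep must be > 0")
        if self.temperature < 0:
            raise ValidationError("temperature must be >= 0")
        if self.friction <= 0:
            raise ValidationError("friction must be > 0")
        if self.stride < 1 or self.n_steps < 1:
            raise ValidationError("n_steps and stride must be >= 1")


@dataclass
class ToyTrajectory:
    """Saved frames of a toy run: times (ps), positions (Å), V and ΔV."""

    times: np.ndarray
    positions: np.ndarray  # (n_saved, dim)
    potential_energy: np.ndarray  # kcal/mol, unboosted V
    delta_v: Optional[np.ndarray]  # kcal/mol, None for unbiased runs
    spec: SimSpec
    boost: Optional[tuple[BoostSpec, ...]]

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def write_tsv(self, path) -> None:
        dv = self.delta_v if self.delta_v is not None else np.zeros(self.n_frames)
        with open(path, "w") as fh:
            fh.write("# step\ttime_ps\t" +
                     "\t".join(f"x{i}" for i in range(self.positions.shape[1])) +
                     "\tV_kcal_mol\tdeltaV_kcal_mol\n")
            for i in range(self.n_frames):
                xs = "\t".join(f"{v:.8g}" for v in self.positions[i])
                fh.write(f"{i * self.spec.stride}\t{self.times[i]:.6g}\t{xs}\t"
                         f"{self.potential_energy[i]:.8g}\t{dv[i]:.8g}\n")

    def write_deltav_log(self, path) -> None:
        dv = self.delta_v if self.delta_v is not None else np.zeros(self.n_frames)
        write_deltav_log(path, dv)


def run_langevin(potential, spec: SimSpec, boost: BoostLike = None) -> ToyTrajectory:
    """Integrate (optionally boosted) Langevin dynamics; reproducible by seed.

    When a boost is given the dynamics run on V* = V + ΔV (force scaled
    by :func:`force_scale`) and ΔV is logged for every saved frame.
    Saved frames are every ``stride`` steps, including the initial state.
    """
    specs = tuple(_boost_list(boost)) or None
    dim = potential.dim
    x = np.array(spec.x0 if spec.x0 is not None else potential.minimum(), dtype=float)
    if x.shape != (dim,):
        raise ValidationError(f"x0 must have dimension {dim}")
    rng = np.random.default_rng(spec.seed)
    dt, m = spec.timestep, spec.mass
    c1 = np.exp(-spec.friction * dt)
    # velocity units Å/ps: kBT in kcal/mol -> amu·Å²/ps² via the
    # acceleration conversion factor
    kt_vel = kbt(spec.temperature) * KCAL_PER_MOL_ACCEL / m if spec.temperature > 0 else 0.0
    c2 = np.sqrt((1.0 - c1 * c1) * kt_vel)
    v = rng.normal(0.0, np.sqrt(kt_vel) if kt_vel > 0 else 0.0, size=dim)
    noise = rng.standard_normal((spec.n_steps, dim))

    def eff_force(pos):
        vpot = potential.value(pos)
        if not np.isfinite(vpot):
            return vpot, None
        f = -potential.gradient(pos)
        if specs is not None:
            f = f * force_scale(vpot, specs)
        return vpot, f * (KCAL_PER_MOL_ACCEL / m)  # acceleration Å/ps²

    n_saved = spec.n_steps // spec.stride + 1
    times = np.empty(n_saved)
    positions = np.empty((n_saved, dim))
    energies = np.empty(n_saved)

    vpot, acc = eff_force(x)
    if acc is None:
        raise IntegrationError("non-finite energy at step 0")
    times[0], positions[0], energies[0] = 0.0, x, vpot
    isave = 1
    for step in range(spec.n_steps):
        v = v + 0.5 * dt * acc
        x = x + 0.5 * dt * v
        v = c1 * v + c2 * noise[step]
        x = x + 0.5 * dt * v
        vpot, acc = eff_force(x)
        if acc is None or not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite energy at step {step + 1}")
        v = v + 0.5 * dt * acc
        if (step + 1) % spec.stride == 0:
            times[isave] = (step + 1) * dt
            positions[isave] = x
            energies[isave] = vpot
            isave += 1

    delta_v = boost_delta_v(energies, specs) if specs is not None else None
    return ToyTrajectory(times[:isave], positions[:isave], energies[:isave],
                         delta_v, spec, specs)
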