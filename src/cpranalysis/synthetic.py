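"""Synthetic fixtures with known ground truth.

Three generators stand in for data the analysis would normally get from
all-atom MD of cytochrome P450 reductase:

* a Boltzmann-density quadrature oracle on toy potentials, the
  independent reference for reweighting checks;
* bivariate (FAD–FMN, FMN–heme) distance ensembles per redox-state
  preset, with the reported anticorrelations (−0.21 oxidized, −0.41
  reduced) and an optional importance-tilted draw whose pseudo-ΔV makes
  exp(ΔV/k_BT) reweighting recover the preset exactly in expectation;
* a two-domain bead model written as multi-model PDB + ΔV log, so the
  whole file-based pipeline (selections, COM distances, superposition
  prediction, reweighting) can be exercised end to end.

Only the correlation coefficients are anchored to the CPR study; the
distance means/SDs are package choices of realistic magnitude (the
study reports no numeric distance values).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import kbt
from .exceptions import ValidationError
from .model_io import (
    ALLOXAZINE_RING_ATOMS,
    SelectionSpec,
    Structure,
    Topology,
    Trajectory,
    write_deltav_log,
    write_pdb,
)
from .geometry import ComplexReference

__all__ = [
    "StatePreset",
    "OXIDIZED",
    "REDUCED",
    "PRESETS",
    "boltzmann_density_oracle",
    "boltzmann_bin_masses",
    "DistanceEnsemble",
    "generate_two_state_ensemble",
    "BeadModelSpec",
    "build_bead_trajectory",
    "build_complex_reference",
    "generate_bead_trajectory",
    "bead_selections",
]

#: max weight ratio allowed for pseudo-ΔV draws (keeps the effective
#: sample size of the tilted construction usable)
MAX_WEIGHT_RATIO = 1.0e3


@dataclass(frozen=True)
class StatePreset:
    """Redox-state preset for the bivariate distance ensemble (Å).

    ``rho`` is the Pearson correlation between the FAD–FMN and the
    FMN–heme distances; the reduced state opens by ``open_shift`` Å
    relative to the oxidized state.
    """

    name: str
    d_fad_fmn_mean: float
    d_fad_fmn_sd: float
    d_fmn_heme_mean: float
    d_fmn_heme_sd: float
    rho: float
    open_shift: float = 0.0

    def __post_init__(self):
        if self.d_fad_fmn_sd <= 0 or self.d_fmn_heme_sd <= 0:
            raise ValidationError("preset SDs must be > 0")
        if not abs(self.rho) < 1:
            raise ValidationError("preset correlation must satisfy |rho| < 1")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.d_fad_fmn_mean, self.d_fmn_heme_mean])

    @property
    def covariance(self) -> np.ndarray:
        s1, s2 = self.d_fad_fmn_sd, self.d_fmn_heme_sd
        c = self.rho * s1 * s2
        return np.array([[s1 * s1, c], [c, s2 * s2]])


OXIDIZED = StatePreset("oxidized", 12.0, 2.0, 25.0, 3.0, -0.21, open_shift=0.0)
REDUCED = StatePreset("reduced", 14.0, 2.5, 22.0, 3.0, -0.41, open_shift=2.0)
PRESETS = {"oxidized": OXIDIZED, "reduced": REDUCED}

if not REDUCED.d_fad_fmn_mean > OXIDIZED.d_fad_fmn_mean:
    raise AssertionError("reduced preset must be more open than oxidized")


# ---------------------------------------------------------------------------
# Boltzmann oracle
# ---------------------------------------------------------------------------

def _values_on_grid(potential, grid: np.ndarray) -> np.ndarray:
    return np.array([potential.value(np.atleast_1d(g)) for g in np.asarray(grid)])


def boltzmann_density_oracle(
    potential, temperature: float, grid: Union[np.ndarray, tuple]
) -> np.ndarray:
    """Normalized Boltzmann density exp(−V/k_BT)/Z on a 1D or 2D grid.

    Normalization is by trapezoidal quadrature on the grid; the grid
    must cover essentially all the probability mass.
    """
    kt = kbt(temperature)
    if isinstance(grid, tuple):
        gx, gy = (np.asarray(g, dtype=float) for g in grid)
        v = np.array(
            [[potential.value(np.array([x, y])) for y in gy] for x in gx]
        )
        p = np.exp(-(v - v.min()) / kt)
        z = np.trapezoid(np.trapezoid(p, gy, axis=1), gx)
        return p / z
    grid = np.asarray(grid, dtype=float)
    v = _values_on_grid(potential, grid)
    p = np.exp(-(v - v.min()) / kt)
    return p / np.trapezoid(p, grid)


def boltzmann_bin_masses(
    potential, temperature: float, edges: np.ndarray, points_per_bin: int = 129
) -> np.ndarray:
    """Exact-per-bin Boltzmann probability masses (1D) by fine quadrature.

    Simpson's rule per bin (odd point count), normalized over the
    binned range; refinement-stable well below 1e-6 per bin mass.
    """
    from scipy.integrate import simpson

    edges = np.asarray(edges, dtype=float)
    kt = kbt(temperature)
    masses = np.empty(len(edges) - 1)
    n_pts = points_per_bin + 1 - points_per_bin % 2  # force odd
    for i in range(len(masses)):
        g = np.linspace(edges[i], edges[i + 1], n_pts)
        v = _values_on_grid(potential, g)
        masses[i] = simpson(np.exp(-v / kt), x=g)
    # normalized over the binned range
    return masses / masses.sum()


# ---------------------------------------------------------------------------
# bivariate distance ensembles
# ---------------------------------------------------------------------------

@dataclass
class DistanceEnsemble:
    """Sampled (d_FAD–FMN, d_FMN–heme) pairs with a pseudo-ΔV series."""

    d_fad_fmn: np.ndarray
    d_fmn_heme: np.ndarray
    delta_v: np.ndarray
    preset: StatePreset
    temperature: float
    tilted: bool

    @property
    def n(self) -> int:
        return len(self.d_fad_fmn)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# frame\td_fad_fmn\td_fmn_heme\n")
            for i in range(self.n):
                fh.write(f"{i}\t{self.d_fad_fmn[i]:.8g}\t{self.d_fmn_heme[i]:.8g}\n")

    def write_deltav_log(self, path) -> None:
        write_deltav_log(path, self.delta_v)


def generate_two_state_ensemble(
    preset: StatePreset,
    n: int,
    seed: int,
    temperature: float = 310.0,
    tilted: bool = False,
    tilt_fraction: float = 0.5,
) -> DistanceEnsemble:
    """Draw n (d_FAD–FMN, d_FMN–heme) pairs from a redox-state preset.

    Untilted: exact bivariate normal per the preset, ΔV ≡ 0 (uniform
    weights recover the preset directly).  Tilted: the draw comes from
    the preset density shifted by ``tilt_fraction``·SD along the
    FAD–FMN axis, and the pseudo-ΔV is k_BT times the log density ratio
    (preset over tilted), shifted to be non-negative and capped so the
    max weight ratio is ≤ 10³ — so exp(ΔV/k_BT)-weighted estimates
    recover the preset while unweighted ones recover the tilted draw.
    """
    if n < 2:
        raise ValidationError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    cov = preset.covariance
    mean = preset.mean
    if not tilted:
        samples = rng.multivariate_normal(mean, cov, size=n)
        dv = np.zeros(n)
    else:
        shift = np.array([tilt_fraction * preset.d_fad_fmn_sd, 0.0])
        qmean = mean + shift
        samples = rng.multivariate_normal(qmean, cov, size=n)
        prec = np.linalg.inv(cov)
        dq = samples - qmean
        dp = samples - mean
        log_ratio = 0.5 * (
            np.einsum("ij,jk,ik->i", dq, prec, dq)
            - np.einsum("ij,jk,ik->i", dp, prec, dp)
        )
        kt = kbt(temperature)
        dv = kt * log_ratio
        dv -= dv.min()
        dv = np.clip(dv, 0.0, kt * np.log(MAX_WEIGHT_RATIO))
    return DistanceEnsemble(
        samples[:, 0].copy(), samples[:, 1].copy(), dv, preset, temperature, tilted
    )


# ---------------------------------------------------------------------------
# bead model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadModelSpec:
    """Two-domain bead model settings.

    Each domain is a rigid scatter of ``beads_per_domain`` Cα pseudo-
    atoms with a flavin-ring pseudo-residue at its mass center.  The
    heme of the companion complex-reference file sits ``heme_distance``
    Å from the FAD-domain center.  ``closed_separation``/``open_
    separation`` are the fixed interdomain distances used when no
    preset is supplied.
    """

    beads_per_domain: int = 8
    closed_separation: float = 12.0
    open_separation: float = 16.0
    jitter_sd: float = 0.15
    n_frames: int = 1000
    seed: int = 0
    heme_distance: float = 26.0
    frame_dt_ns: float = 0.01
    random_pose: bool = True

    def __post_init__(self):
        if self.beads_per_domain < 3:
            raise ValidationError("need >= 3 beads per rigid unit (superposable)")
        if self.jitter_sd < 0:
            raise ValidationError("jitter SD must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


_RING_ELEMENTS = {name: name[0] for name in ALLOXAZINE_RING_ATOMS}
_HEME_ATOMS = ("FE", "NA", "NB", "NC", "ND")


def _domain_scatter(n: int, template_seed: int, extent: float = 6.0) -> np.ndarray:
    """Deterministic rigid scatter of n beads, centroid exactly at 0."""
    rng = np.random.default_rng(template_seed)
    pts = rng.uniform(-extent, extent, size=(n, 3))
    return pts - pts.mean(axis=0)


def _ring_template(radius: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Planar 15-atom flavin-ring stand-in, mass-weighted centroid at 0."""
    from .model_io import _element_masses

    names = np.array(ALLOXAZINE_RING_ATOMS)
    angles = 2 * np.pi * np.arange(len(names)) / len(names)
    pts = np.c_[radius * np.cos(angles), radius * np.sin(angles), np.zeros(len(names))]
    masses = _element_masses(np.array([_RING_ELEMENTS[n] for n in names]), names)
    pts -= (masses[:, None] * pts).sum(axis=0) / masses.sum()
    return names, pts


def _heme_template(radius: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    from .model_io import _element_masses

    names = np.array(_HEME_ATOMS)
    pts = np.array(
        [[0.0, 0, 0], [radius, 0, 0], [0, radius, 0], [-radius, 0, 0], [0, -radius, 0]]
    )
    masses = _element_masses(np.array(["FE", "N", "N", "N", "N"]), names)
    pts -= (masses[:, None] * pts).sum(axis=0) / masses.sum()
    return names, pts


def _bead_topology(spec: BeadModelSpec, with_heme: bool) -> tuple[Topology, dict]:
    """Topology plus the index layout of the bead model."""
    nb = spec.beads_per_domain
    ring_names, ring_pts = _ring_template()
    heme_names, heme_pts = _heme_template()
    atom_name, res_name, res_id, chain_id, element = [], [], [], [], []

    def add(an, rn, ri, ch, el):
        atom_name.append(an)
        res_name.append(rn)
        res_id.append(ri)
        chain_id.append(ch)
        element.append(el)

    for i in range(nb):  # FAD-domain beads
        add("CA", "ALA", 1 + i, "A", "C")
    for an in ring_names:  # FAD cofactor ring
        add(an, "FAD", 900, "A", _RING_ELEMENTS[an])
    for i in range(nb):  # FMN-domain beads
        add("CA", "ALA", 101 + i, "A", "C")
    for an in ring_names:  # FMN cofactor ring
        add(an, "FMN", 901, "A", _RING_ELEMENTS[an])
    if with_heme:
        for an, el in zip(heme_names, ("FE", "N", "N", "N", "N")):
            add(an, "HEM", 1, "B", el)

    from .model_io import _element_masses

    top = Topology(
        atom_name=np.array(atom_name),
        res_name=np.array(res_name),
        res_id=np.array(res_id, dtype=int),
        chain_id=np.array(chain_id),
        element=np.array(element),
        mass=_element_masses(np.array(element), np.array(atom_name)),
    )
    layout = {
        "fad_beads": np.arange(nb),
        "fad_ring": np.arange(nb, nb + len(ring_names)),
        "fmn_beads": np.arange(nb + len(ring_names), 2 * nb + len(ring_names)),
        "fmn_ring": np.arange(2 * nb + len(ring_names), 2 * (nb + len(ring_names))),
        "heme": (
            np.arange(2 * (nb + len(ring_names)), 2 * (nb + len(ring_names)) + len(heme_names))
            if with_heme
            else None
        ),
        "ring_pts": ring_pts,
        "heme_pts": heme_pts,
    }
    return top, layout


def _base_coords(spec: BeadModelSpec, layout, fmn_position, with_heme: bool) -> np.ndarray:
    nb = spec.beads_per_domain
    fad_scatter = _domain_scatter(nb, template_seed=1_234_501)
    fmn_scatter = _domain_scatter(nb, template_seed=1_234_502)
    n_atoms = 2 * (nb + len(layout["ring_pts"])) + (len(layout["heme_pts"]) if with_heme else 0)
    coords = np.empty((n_atoms, 3))
    coords[layout["fad_beads"]] = fad_scatter
    coords[layout["fad_ring"]] = layout["ring_pts"]
    coords[layout["fmn_beads"]] = fmn_scatter + fmn_position
    coords[layout["fmn_ring"]] = layout["ring_pts"] + fmn_position
    if with_heme:
        coords[layout["heme"]] = layout["heme_pts"] + np.array([spec.heme_distance, 0.0, 0.0])
    return coords


def _fmn_position(d1: float, d2: float, heme_distance: float) -> np.ndarray:
    """Place the FMN-unit center at distance d1 from the FAD center
    (origin) and d2 from the heme center (L, 0, 0); infeasible (d1, d2)
    pairs are clamped to the triangle-inequality boundary."""
    eps = 0.05
    d1 = max(d1, eps)
    lo, hi = abs(heme_distance - d1) + eps, heme_distance + d1 - eps
    d2 = float(np.clip(d2, lo, hi))
    x = (d1 * d1 - d2 * d2 + heme_distance * heme_distance) / (2 * heme_distance)
    y = float(np.sqrt(max(d1 * d1 - x * x, 0.0)))
    return np.array([x, y, 0.0])


def bead_selections(spec: BeadModelSpec) -> dict[str, SelectionSpec]:
    """Named selections matching the bead-model topology."""
    nb = spec.beads_per_domain
    return {
        "fad_domain": SelectionSpec(
            "fad_domain", residue_ranges=((1, nb),), atom_names=frozenset({"CA"}), chain_id="A"
        ),
        "fmn_domain": SelectionSpec(
            "fmn_domain", residue_ranges=((101, 100 + nb),), atom_names=frozenset({"CA"}),
            chain_id="A",
        ),
        "fad_ring": SelectionSpec(
            "fad_ring", residue_names=frozenset({"FAD"}),
            atom_names=frozenset(ALLOXAZINE_RING_ATOMS),
        ),
        "fmn_ring": SelectionSpec(
            "fmn_ring", residue_names=frozenset({"FMN"}),
            atom_names=frozenset(ALLOXAZINE_RING_ATOMS),
        ),
        "heme": SelectionSpec("heme", residue_names=frozenset({"HEM"}), chain_id="B"),
    }


def build_complex_reference(
    spec: BeadModelSpec, d_fad_fmn: float = 15.0, d_fmn_heme: float = 12.0
) -> ComplexReference:
    """In-memory open-form complex reference (CPR beads + partner heme)."""
    top, layout = _bead_topology(spec, with_heme=True)
    pos = _fmn_position(d_fad_fmn, d_fmn_heme, spec.heme_distance)
    structure = Structure(top, _base_coords(spec, layout, pos, with_heme=True))
    sels = bead_selections(spec)
    return ComplexReference(structure, sels["fad_domain"], sels["fmn_ring"], sels["heme"])


def build_bead_trajectory(
    spec: BeadModelSpec,
    preset: Optional[StatePreset] = None,
    tilted: bool = False,
    temperature: float = 310.0,
) -> tuple[Trajectory, DistanceEnsemble]:
    """In-memory bead-model trajectory with its generating ensemble.

    With a preset, interdomain (d_FAD–FMN) and heme (d_FMN–heme)
    separations are sampled per frame from the preset's bivariate
    normal; without one, every frame uses ``closed_separation`` with
    the FMN unit on the FAD→heme axis.  Per-atom Gaussian jitter and an
    optional random rigid pose per frame are then applied.
    """
    top, layout = _bead_topology(spec, with_heme=False)
    rng = np.random.default_rng(spec.seed)
    if preset is not None:
        ens = generate_two_state_ensemble(
            preset, max(spec.n_frames, 2), seed=spec.seed, temperature=temperature,
            tilted=tilted,
        )
        d1 = ens.d_fad_fmn[: spec.n_frames]
        d2 = ens.d_fmn_heme[: spec.n_frames]
        dv = ens.delta_v[: spec.n_frames]
        # the generator's own rng consumed nothing yet: re-seed the pose
        # stream independently of the ensemble stream
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]).generate_state(1)[0])
    else:
        d1 = np.full(spec.n_frames, spec.closed_separation)
        d2 = spec.heme_distance - d1  # collinear placement
        dv = np.zeros(spec.n_frames)
        ens = DistanceEnsemble(
            d1.copy(), d2.copy(), dv.copy(),
            StatePreset("fixed", spec.closed_separation, 1.0, 1.0, 1.0, 0.0),
            temperature, False,
        )
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    heme_center = np.array([spec.heme_distance, 0.0, 0.0])
    d1_enc = np.empty(spec.n_frames)
    d2_enc = np.empty(spec.n_frames)
    for t in range(spec.n_frames):
        pos = _fmn_position(float(d1[t]), float(d2[t]), spec.heme_distance)
        # ground truth actually encoded in the geometry (identical to the
        # sampled values except for rare triangle-inequality clamps)
        d1_enc[t] = float(np.linalg.norm(pos))
        d2_enc[t] = float(np.linalg.norm(pos - heme_center))
        c = _base_coords(spec, layout, pos, with_heme=False)
        if spec.jitter_sd > 0:
            c = c + rng.normal(0.0, spec.jitter_sd, size=c.shape)
        if spec.random_pose:
            rot = Rotation.random(rng=rng).as_matrix()
            c = c @ rot.T + rng.uniform(-10.0, 10.0, size=3)
        coords[t] = c
    times = np.arange(spec.n_frames, dtype=float) * spec.frame_dt_ns
    traj = Trajectory(top, coords, times, delta_v=dv)
    ens_out = DistanceEnsemble(
        d1_enc, d2_enc, np.asarray(dv, dtype=float), ens.preset, temperature, tilted,
    )
    return traj, ens_out


def generate_bead_trajectory(
    spec: BeadModelSpec,
    preset: Optional[StatePreset] = None,
    out_dir=".",
    tilted: bool = False,
    temperature: float = 310.0,
) -> dict[str, Path]:
    """Write the bead-model fixture set to disk.

    Emits a multi-model PDB trajectory, a ΔV log, a companion complex-
    reference PDB (with a HEM pseudo-residue on the partner chain), and
    a JSON manifest recording all parameters.  All files round-trip
    through :mod:`cpranalysis.model_io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traj, ens = build_bead_trajectory(spec, preset, tilted=tilted, temperature=temperature)
    paths = {
        "trajectory": out / "trajectory.pdb",
        "deltav": out / "deltav.log",
        "complex_reference": out / "complex_reference.pdb",
        "manifest": out / "manifest.json",
    }
    write_pdb(paths["trajectory"], traj)
    write_deltav_log(paths["deltav"], ens.delta_v)
    write_pdb(paths["complex_reference"], build_complex_reference(spec).structure)
    manifest = {
        "generator": "cpranalysis.synthetic.generate_bead_trajectory",
        "spec": asdict(spec),
        "preset": asdict(preset) if preset is not None else None,
        "tilted": tilted,
        "temperature_K": temperature,
        "com_convention": "mass-weighted over heavy atoms",
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
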