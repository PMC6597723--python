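"""Structural observables: COM distances, Kabsch superposition, and the
complex-reference FMN–heme distance prediction.

The FMN–heme distance of a snapshot is *predicted*: the snapshot's FAD
domain is superposed onto the FAD domain of a CPR–monooxygenase complex
structure, the superposition is applied to the whole snapshot, and the
distance is measured from the transformed snapshot's FMN alloxazine-ring
center of mass to the complex's heme center of mass.  Because the
superposition removes any global rigid motion, the prediction is
invariant under rigid transforms of the input frame.

Atom pairing for the superposition is by (residue_id, atom_name)
intersection, Cα-only by default (robust to hetero-group differences);
the fit is unweighted by default.  Both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .exceptions import DegenerateGeometryError, PairingError, ValidationError
from .model_io import (
    SelectionSpec,
    Structure,
    center_of_mass,
    resolve_selection,
)

__all__ = [
    "RigidTransform",
    "ComplexReference",
    "kabsch_superpose",
    "interdomain_distance",
    "intercofactor_distance",
    "predict_fmn_heme_distance",
]

SelectionLike = Union[np.ndarray, SelectionSpec]


def _as_indices(structure: Structure, sel: SelectionLike) -> np.ndarray:
    if isinstance(sel, SelectionSpec):
        return resolve_selection(structure, sel)
    return np.asarray(sel)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (R orthogonal, det +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-10):
            raise ValidationError("rotation matrix is not orthogonal (1e-10)")
        if abs(np.linalg.det(r) - 1.0) > 1e-10:
            raise ValidationError("rotation matrix must have det +1 (1e-10)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def kabsch_superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of paired point sets (Kabsch, via SVD).

    Returns the proper-rotation transform minimizing the weighted RMSD
    of ``mobile`` onto ``reference`` (reflections corrected), and that
    minimized RMSD in Å.  Requires >= 3 non-collinear points.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValidationError("paired (n, 3) coordinate sets required")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for superposition, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError("superposition weights must be >= 0, not all zero")
        w = w / w.sum()
    mob_centroid = w @ mob
    ref_centroid = w @ ref
    mob_c = mob - mob_centroid
    ref_c = ref - ref_centroid
    sv = np.linalg.svd(mob_c * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are (near-)collinear; rotation ill-defined")
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, ref_centroid - rot @ mob_centroid)
    resid = transform.apply(mob) - ref
    rmsd = float(np.sqrt(w @ np.einsum("ij,ij->i", resid, resid)))
    return transform, rmsd


def interdomain_distance(
    frame: Structure, domain_a: SelectionLike, domain_b: SelectionLike
) -> float:
    """Distance (Å) between the mass-weighted centers of two domains."""
    com_a = center_of_mass(frame, _as_indices(frame, domain_a))
    com_b = center_of_mass(frame, _as_indices(frame, domain_b))
    return float(np.linalg.norm(com_a - com_b))


def intercofactor_distance(
    frame: Structure, fad_ring: SelectionLike, fmn_ring: SelectionLike
) -> float:
    """Distance (Å) between the alloxazine-ring COMs of FAD and FMN."""
    return interdomain_distance(frame, fad_ring, fmn_ring)


@dataclass(frozen=True)
class ComplexReference:
    """CPR–monooxygenase complex anchoring the FMN–heme prediction."""

    structure: Structure
    fad_domain: SelectionSpec
    fmn_ring: SelectionSpec
    heme: SelectionSpec

    def __post_init__(self):
        fad_idx = resolve_selection(self.structure, self.fad_domain)
        heme_idx = resolve_selection(self.structure, self.heme)
        resolve_selection(self.structure, self.fmn_ring)
        heme_chains = set(self.structure.topology.chain_id[heme_idx])
        cpr_chains = set(self.structure.topology.chain_id[fad_idx])
        if heme_chains & cpr_chains:
            raise ValidationError(
                "heme selection must belong to the partner protein chain, "
                f"but shares chain(s) {sorted(heme_chains & cpr_chains)} with the FAD domain"
            )

    def heme_com(self) -> np.ndarray:
        return center_of_mass(self.structure, resolve_selection(self.structure, self.heme))


def _pair_by_residue_atom(
    frame: Structure,
    frame_idx: np.ndarray,
    ref: Structure,
    ref_idx: np.ndarray,
    ca_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    def keymap(s: Structure, idx: np.ndarray) -> dict:
        top = s.topology
        out = {}
        for i in idx:
            if ca_only and top.atom_name[i] != "CA":
                continue
            out[(int(top.res_id[i]), str(top.atom_name[i]))] = i
        return out

    fmap = keymap(frame, frame_idx)
    rmap = keymap(ref, ref_idx)
    common = sorted(set(fmap) & set(rmap))
    if len(common) < 3:
        missing = sorted(set(rmap) - set(fmap))[:10]
        raise PairingError(
            f"only {len(common)} paired atoms between frame and reference FAD "
            f"domains; unmatched reference atoms include {missing}"
        )
    return (
        np.array([fmap[k] for k in common]),
        np.array([rmap[k] for k in common]),
    )


def predict_fmn_heme_distance(
    frame: Structure,
    fad_domain: SelectionLike,
    fmn_ring: SelectionLike,
    complex_ref: ComplexReference,
    ca_only: bool = True,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Predicted FMN-ring-to-heme COM distance (Å) for one snapshot.

    Superposes the snapshot's FAD domain onto the reference complex's
    FAD domain, applies the transform to the snapshot, and measures the
    COM distance from the transformed FMN alloxazine ring to the
    reference heme.
    """
    frame_fad = _as_indices(frame, fad_domain)
    ref_fad = resolve_selection(complex_ref.structure, complex_ref.fad_domain)
    fi, ri = _pair_by_residue_atom(frame, frame_fad, complex_ref.structure, ref_fad, ca_only)
    transform, _ = kabsch_superpose(
        frame.coord[fi], complex_ref.structure.coord[ri], weights
    )
    moved = frame.transformed(transform.rotation, transform.translation)
    fmn_com = center_of_mass(moved, _as_indices(moved, fmn_ring))
    return float(np.linalg.norm(fmn_com - complex_ref.heme_com()))
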