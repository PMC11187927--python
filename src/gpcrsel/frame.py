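"""Common membrane coordinate frame via rigid-body superposition.

All angle measurements assume the receptor sits in a frame whose +Z axis is
the membrane normal pointing extracellular.  A reference receptor supplies
that frame; every other structure is Kabsch-superposed onto it over the
Calpha atoms of GRN-matched residues.  The default atom set spans TM1-TM4
and TM7 — the helices whose alignment is conserved between Gs- and
Gi/o-coupled complexes — so the frame is not biased by the TM5/TM6 geometry
being measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GrnLookupError, InsufficientDataError
from .structures import AnnotatedStructure

#: Superposition atom set: Calpha of all GRN-matched residues in these helices.
DEFAULT_SELECTION = {"helices": [1, 2, 3, 4, 7], "atom": "CA"}

_COLLINEAR_TOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rotation plus translation: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3, translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1 (no reflections)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_json(self) -> str:
        return json.dumps(
            {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        d = json.loads(text)
        return cls(np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class FrameResult:
    """Outcome of one superposition: transform, its RMSD, atoms used."""

    transform: RigidTransform
    rmsd: float
    n_atoms_used: int
    grns_used: list[str] = field(default_factory=list)


def _selection_grns(s: AnnotatedStructure, selection: Optional[dict]) -> dict[str, np.ndarray]:
    """GRN -> atom coordinate for the selection, receptor chain only."""
    selection = selection or DEFAULT_SELECTION
    atom_name = selection.get("atom", "CA")
    helices = selection.get("helices")
    grns = selection.get("grns")
    out: dict[str, np.ndarray] = {}
    for res in s.receptor_residues:
        if res.grn is None:
            continue
        if grns is not None and res.grn not in grns:
            continue
        if grns is None and helices is not None and res.grn_helix not in helices:
            continue
        atom = res.atom(atom_name)
        if atom is not None:
            out[res.grn] = atom.coord
    return out


def _matched_coords(
    mobile: AnnotatedStructure,
    reference: AnnotatedStructure,
    selection: Optional[dict],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    mob = _selection_grns(mobile, selection)
    ref = _selection_grns(reference, selection)
    common = sorted(set(mob) & set(ref))
    if len(common) < 3:
        raise InsufficientDataError(
            f"only {len(common)} GRN-matched atoms between "
            f"{mobile.structure_id} and {reference.structure_id}; need >= 3"
        )
    return (
        np.array([mob[g] for g in common]),
        np.array([ref[g] for g in common]),
        common,
    )


def kabsch_superpose(
    mobile: AnnotatedStructure,
    reference: AnnotatedStructure,
    selection: Optional[dict] = None,
) -> FrameResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the optimal proper rotation and translation (Kabsch solution)
    over the GRN-matched atom set, together with the RMSD over that set.
    ``mobile`` is not mutated.  Collinear correspondence sets are refused:
    the in-plane orientation would be arbitrary.
    """
    mob, ref, grns = _matched_coords(mobile, reference, selection)
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # collinearity check: second singular value of either centered set ~ 0
    for name, arr in (("mobile", mob_c), ("reference", ref_c)):
        sv = np.linalg.svd(arr, compute_uv=False)
        if sv[1] <= _COLLINEAR_TOL * max(sv[0], 1.0):
            raise InsufficientDataError(
                f"{name} correspondence set is collinear; superposition is underdetermined"
            )
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return FrameResult(
        transform=RigidTransform(R, t), rmsd=rmsd, n_atoms_used=len(grns), grns_used=grns
    )


def to_membrane_frame(
    s: AnnotatedStructure,
    reference: AnnotatedStructure,
    selection: Optional[dict] = None,
) -> AnnotatedStructure:
    """Return a copy of ``s`` superposed into the reference's membrane frame."""
    result = kabsch_superpose(s, reference, selection)
    return s.transformed(result.transform.rotation, result.transform.translation)


def ca_displacement(
    a: AnnotatedStructure,
    b: AnnotatedStructure,
    grn: str,
    frame_reference: Optional[AnnotatedStructure] = None,
    selection: Optional[dict] = None,
    chain: Optional[str] = None,
) -> float:
    """Distance (angstrom) between the Calpha atoms of one GRN in two structures.

    Both structures are first placed in the common frame defined by
    ``frame_reference`` (defaults to ``a`` itself).
    """
    ref = frame_reference if frame_reference is not None else a
    fa = to_membrane_frame(a, ref, selection)
    fb = to_membrane_frame(b, ref, selection)
    pa = fa.find_grn(grn, chain).ca()
    pb = fb.find_grn(grn, chain).ca()
    if pa is None or pb is None:
        raise GrnLookupError(f"GRN {grn} lacks a CA atom in one of the structures")
    return float(np.linalg.norm(pa.coord - pb.coord))
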