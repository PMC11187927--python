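"""Buried-surface and contact analysis between receptor TMs and Galpha.

Contact area is measured as half the solvent-accessible surface area lost on
complex formation, ``(SASA(A) + SASA(B) - SASA(AB)) / 2``, with a 1.4-A
probe and Bondi-type element radii — the standard interface-area convention
that matches the magnitudes reported for receptor-Galpha interfaces
(~1100-1600 A^2).  SASA itself is Shrake-Rupley sphere sampling on a
deterministic Fibonacci (golden-spiral) lattice, so no seed is involved.

The "extended TM" residues — TM5 at or past 5.69 toward the cytosol in
Gs-coupled receptors, TM6 at or past 6.29 in Gi/o-coupled ones — form the
non-canonical receptor-Galpha interface; their count is regressed against
the additional contact area they bury.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

import biotite.structure as bst

from . import constants as C
from .structures import AnnotatedStructure, HelixSegment, ResidueRecord

#: Bondi-type van der Waals radii (angstrom)
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
FALLBACK_RADIUS = 1.8

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
CONTACT_CUTOFF = 4.0


@dataclass
class SASAResult:
    per_atom_area: np.ndarray
    total: float
    probe_radius: float
    n_sphere_points: int


@dataclass
class InterfaceResult:
    buried_area_total: float
    per_residue_buried: dict[tuple[str, int, str], float]
    interface_residues_a: set[tuple[str, int, str]]
    interface_residues_b: set[tuple[str, int, str]]
    extended_residue_count: int = 0
    metadata: dict = field(default_factory=dict)


@dataclass
class ExtendedTmRegression:
    """OLS of additional contact area on extended-residue count."""

    points: np.ndarray  # (n, 2): extended_residue_count, additional_contact_area
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float


ResidueSelection = Sequence[ResidueRecord]


def _flatten(residues: ResidueSelection) -> tuple[np.ndarray, np.ndarray, list]:
    coords, radii, owners = [], [], []
    for res in residues:
        for atom in res.atoms.values():
            coords.append(atom.coord)
            el = atom.element.upper()
            r = VDW_RADII.get(el)
            if r is None:
                warnings.warn(f"no vdW radius for element {el!r}; using {FALLBACK_RADIUS} A")
                r = FALLBACK_RADIUS
            radii.append(r)
            owners.append(res.residue_id)
    if not coords:
        raise ValueError("selection contains no atoms")
    return np.array(coords, float), np.array(radii, float), owners


def shrake_rupley(
    residues: ResidueSelection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SASAResult:
    """Per-atom solvent-accessible surface area of a residue selection."""
    coords, radii, _ = _flatten(residues)
    arr = bst.AtomArray(len(coords))
    arr.coord = coords
    areas = bst.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=radii,
        ignore_ions=False,
    )
    areas = np.nan_to_num(np.asarray(areas, dtype=float))
    return SASAResult(
        per_atom_area=areas,
        total=float(areas.sum()),
        probe_radius=probe,
        n_sphere_points=n_points,
    )


def residues_of(s: AnnotatedStructure, chain_id: str) -> list[ResidueRecord]:
    return s.chains[chain_id]


def buried_area(
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> float:
    """Half the SASA buried between two disjoint selections (angstrom^2)."""
    ids_a = {r.residue_id for r in selection_a}
    ids_b = {r.residue_id for r in selection_b}
    if ids_a & ids_b:
        raise ValueError(f"selections overlap on residues {sorted(ids_a & ids_b)[:3]}...")
    sasa_a = shrake_rupley(selection_a, probe, n_points).total
    sasa_b = shrake_rupley(selection_b, probe, n_points).total
    sasa_ab = shrake_rupley(list(selection_a) + list(selection_b), probe, n_points).total
    return 0.5 * (sasa_a + sasa_b - sasa_ab)


def interface_residues(
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    cutoff: float = CONTACT_CUTOFF,
) -> tuple[set, set]:
    """Residues of each selection with any atom within ``cutoff`` of the other."""
    from scipy.spatial import cKDTree

    coords_a, _, owners_a = _flatten(selection_a)
    coords_b, _, owners_b = _flatten(selection_b)
    pairs = cKDTree(coords_a).query_ball_tree(cKDTree(coords_b), r=cutoff)
    res_a, res_b = set(), set()
    for i, hits in enumerate(pairs):
        if hits:
            res_a.add(owners_a[i])
            for j in hits:
                res_b.add(owners_b[j])
    return res_a, res_b


def analyze_interface(
    s: AnnotatedStructure,
    receptor_residues: ResidueSelection | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    cutoff: float = CONTACT_CUTOFF,
) -> InterfaceResult:
    """Full receptor-vs-Galpha interface report for one complex."""
    if s.galpha_chain is None:
        raise ValueError(f"{s.structure_id} has no Galpha chain")
    rec = list(receptor_residues) if receptor_residues is not None else s.receptor_residues
    gal = s.chains[s.galpha_chain]
    total = buried_area(rec, gal, probe, n_points)
    res_a, res_b = interface_residues(rec, gal, cutoff)

    # per-receptor-residue burial: isolated-SASA minus in-complex SASA, halved
    alone = shrake_rupley(rec, probe, n_points)
    joint = shrake_rupley(rec + gal, probe, n_points)
    _, _, owners = _flatten(rec)
    per_res: dict = {}
    for idx, owner in enumerate(owners):
        delta = 0.5 * (alone.per_atom_area[idx] - joint.per_atom_area[idx])
        per_res[owner] = per_res.get(owner, 0.0) + float(delta)
    return InterfaceResult(
        buried_area_total=total,
        per_residue_buried=per_res,
        interface_residues_a=res_a,
        interface_residues_b=res_b,
        metadata={
            "convention": "half buried SASA",
            "probe_radius": probe,
            "n_sphere_points": n_points,
            "radii_set": "Bondi",
            "contact_cutoff": cutoff,
        },
    )


# ---------------------------------------------------------------------------
# extended TMs

def extended_tm(seg: HelixSegment, coupling: str) -> list[ResidueRecord]:
    """The extended-TM residue subset of a helix segment.

    Gs receptors extend TM5 past position 5.69 (inclusive) toward the
    cytosol; Gi/o receptors extend TM6 past 6.29 (inclusive).  An empty list
    means the helix is not extended.
    """
    if coupling == C.GS:
        if seg.helix != 5:
            raise ValueError("Gs extended-TM analysis applies to TM5")
        return [
            r for r in seg.residues
            if r.grn_position is not None and r.grn_position >= C.EXTENDED_TM5_ANCHOR_POSITION
        ]
    if coupling == C.GIO:
        if seg.helix != 6:
            raise ValueError("Gi/o extended-TM analysis applies to TM6")
        return [
            r for r in seg.residues
            if r.grn_position is not None and r.grn_position <= C.EXTENDED_TM6_ANCHOR_POSITION
        ]
    raise ValueError(f"unknown coupling label {coupling!r}")


def fit_area_regression(points: Iterable[tuple[float, float]]) -> ExtendedTmRegression:
    """OLS of additional contact area (A^2) on extended-residue count."""
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (count, area) points")
    if np.ptp(pts[:, 0]) == 0:
        raise ValueError("extended-residue counts are constant; slope undefined")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    return ExtendedTmRegression(
        points=pts,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
    )
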