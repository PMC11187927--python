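"""Synthetic inputs: ideal-helix receptor stubs, feature tables, toy complexes.

Everything the pipeline consumes can be generated here without touching
deposited structures.  Helices are built atom-by-atom from internal
coordinates (ideal bond lengths/angles with alpha-helical phi/psi), which
yields physically realistic backbone carbonyl orientations — the quantity
the axis-estimation code actually averages.  Feature tables are drawn from
the per-group Gaussian summaries of the three descriptors (independent
features by default, with an optional TM5 length/tilt correlation hook).

The generator is the package's model of the study conditions: group means,
spreads, and the 24 Gs : 74 Gi/o training composition are fixed at the
reported values and all randomness flows from one explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .axis import helix_axis
from .errors import ConsistencyError
from .structures import (
    AnnotatedStructure,
    AtomRecord,
    ResidueRecord,
    helix_ascending_is_cytosolic,
    parse_grn,
)

# ideal backbone internal coordinates (angstrom / degrees); the N-CA-C angle
# and the default psi below are solved so the generated helix realizes exactly
# 1.5 A rise and 100 deg twist per residue (3.6 residues/turn)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 109.77074
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_OMEGA = 180.0


@dataclass
class HelixSpec:
    """Recipe for one ideal TM helix.

    ``tilt_deg``/``azimuth_deg`` orient the cytosolic-pointing helix axis
    relative to -Z (the membrane normal points +Z, extracellular).  GRNs are
    assigned sequentially from ``grn_start``; the sequence direction through
    the membrane follows helix parity (odd helices run extracellular to
    cytosolic) unless ``seq_toward_cytosol`` overrides it.
    """

    n_residues: int
    grn_start: str
    tilt_deg: float = 0.0
    azimuth_deg: float = 0.0
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    phi: float = -57.0
    psi: float = -47.6125
    chain_id: str = "R"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seq_toward_cytosol: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError("n_residues must be >= 4")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be positive")
        parse_grn(self.grn_start)

    @property
    def helix(self) -> int:
        return parse_grn(self.grn_start)[0]

    @property
    def positions(self) -> list[int]:
        start = parse_grn(self.grn_start)[1]
        end = start + self.n_residues - 1
        if end > 99:
            raise ValueError(f"GRN positions exceed 99 ({self.grn_start} + {self.n_residues})")
        return list(range(start, end + 1))

    def cytosolic_direction(self) -> np.ndarray:
        t = math.radians(self.tilt_deg)
        a = math.radians(self.azimuth_deg)
        return np.array([math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), -math.cos(t)])


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension placement of atom D from A-B-C internal coordinates."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_u)
    n_u = n / np.linalg.norm(n)
    m = np.cross(n_u, bc_u)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.cos(chi) * math.sin(theta), bond * math.sin(chi) * math.sin(theta)]
    )
    return c + np.column_stack([bc_u, m, n_u]) @ d_local


def _build_backbone(n_residues: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Chain-extend an ideal helix backbone; returns per-residue atom dicts."""
    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    Ccoord = CA + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    residues = [{"N": N, "CA": CA, "C": Ccoord}]
    for _ in range(1, n_residues):
        prev = residues[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_next = _place_atom(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl O anti to the next amide N about the CA-C axis
    for res in residues:
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
    return residues


def _min_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smallest rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2 * K @ K
    w = np.cross(u, v)
    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + K + K @ K / (1 + c)


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def _tip_roll(ca: np.ndarray, axis: np.ndarray, tip_index: int) -> np.ndarray:
    """Rotation about ``axis`` phasing the tip residue to the bottom of its turn."""
    down = np.array([0.0, 0.0, -1.0])
    d = down - np.dot(down, axis) * axis
    if np.linalg.norm(d) < 1e-9:  # vertical helix: every phase is equivalent
        return np.eye(3)
    d /= np.linalg.norm(d)
    i = len(ca) - 2 if tip_index in (-1, len(ca) - 1) else 1
    r_in = ca[i - 1] + ca[i + 1] - 2 * ca[i]
    r_prev = ca[i - 2] + ca[i] - 2 * ca[i - 1] if i >= 2 else ca[i] + ca[i + 2] - 2 * ca[i + 1]
    cos_twist = float(
        np.clip(np.dot(r_in, r_prev) / (np.linalg.norm(r_in) * np.linalg.norm(r_prev)), -1, 1)
    )
    radius = np.linalg.norm(r_in) / (2 * (1 - cos_twist))
    center = ca[i] + r_in / np.linalg.norm(r_in) * radius
    v = ca[tip_index] - center
    radial = v - np.dot(v, axis) * axis
    radial /= np.linalg.norm(radial)
    angle = math.atan2(float(np.dot(np.cross(radial, d), axis)), float(np.dot(radial, d)))
    return _rodrigues(axis, angle)


def make_ideal_helix(spec: HelixSpec) -> AnnotatedStructure:
    """Build a full-backbone (N, CA, C, O) ideal helix as an annotated structure.

    The helix screw axis is aligned to the requested (tilt, azimuth)
    direction and the residue nearest position x.50 is translated to
    ``spec.origin``; GRNs run sequentially from ``grn_start``.
    """
    backbone = _build_backbone(spec.n_residues, spec.phi, spec.psi)
    ca = np.array([r["CA"] for r in backbone])
    # exact screw axis (bisector-cross estimate), oriented first -> last residue
    axis = helix_axis(ca)

    toward_cyt = spec.seq_toward_cytosol
    if toward_cyt is None:
        toward_cyt = helix_ascending_is_cytosolic(spec.helix)
    cyt_dir = spec.cytosolic_direction()
    target = cyt_dir if toward_cyt else -cyt_dir
    R = _min_rotation(axis, target)
    ca_rot = ca @ R.T

    # Roll about the helix axis (a free gauge) so the cytosolic terminal
    # residue sits at the lowest phase of its turn: the measured tip is then
    # always the terminal residue, at any tilt.
    R = _tip_roll(ca_rot, target, tip_index=-1 if toward_cyt else 0) @ R
    ca_rot = ca @ R.T

    positions = spec.positions
    anchor_idx = int(np.argmin([abs(p - 50) for p in positions]))
    shift = np.asarray(spec.origin, dtype=float) - ca_rot[anchor_idx]

    residues: list[ResidueRecord] = []
    for pos, atoms in zip(positions, backbone):
        rec = ResidueRecord(
            chain_id=spec.chain_id,
            author_seq_id=spec.helix * 100 + pos,
            residue_name="ALA",
            grn=f"{spec.helix}.{pos}",
        )
        for name, coord in atoms.items():
            rec.atoms[name] = AtomRecord(
                atom_name=name, element=name[0], coord=R @ coord + shift
            )
        residues.append(rec)
    return AnnotatedStructure(
        structure_id=f"helix_{spec.grn_start}",
        chains={spec.chain_id: residues},
        receptor_chain=spec.chain_id,
    )


# scaffold helices sit on a wide ring so tilted TM5/TM6 (up to ~35 deg)
# cannot collide with them
_SCAFFOLD_OFFSETS = {1: (0.0, 20.0), 2: (17.0, 19.0), 3: (-17.0, 19.0), 4: (-20.0, 0.0), 7: (0.0, -20.0)}
_TM6_LATERAL_OFFSET = 16.0


def make_receptor_stub(
    tm5: HelixSpec,
    tm6: HelixSpec,
    structure_id: str = "stub",
    coupling_label: Optional[str] = None,
    with_scaffold: bool = True,
    min_separation: float = 2.0,
) -> AnnotatedStructure:
    """Assemble a framed receptor stub: TM5 + TM6 (+ TM1-4/7 scaffolds).

    All helices share one chain; TM6 is offset laterally from TM5 and short
    vertical scaffold helices provide the TM1-4/7 superposition atom set.
    The stub is born in the membrane frame (+Z extracellular, x.50 anchors
    near z = 0).
    """
    if tm5.helix != 5 or tm6.helix != 6:
        raise ValueError("tm5/tm6 specs must carry helix 5 and 6 GRNs")
    from dataclasses import replace as dc_replace

    tm5 = dc_replace(tm5, origin=(0.0, 0.0, 0.0))
    tm6 = dc_replace(tm6, origin=(_TM6_LATERAL_OFFSET, 0.0, 0.0))
    helices = [make_ideal_helix(tm5), make_ideal_helix(tm6)]
    if with_scaffold:
        for h, (x, y) in _SCAFFOLD_OFFSETS.items():
            spec = HelixSpec(
                n_residues=11,
                grn_start=f"{h}.45",
                chain_id=tm5.chain_id,
                origin=(x, y, 0.0),
            )
            helices.append(make_ideal_helix(spec))

    coords = [np.array([a.coord for _, a in h.iter_atoms()]) for h in helices] if min_separation > 0 else []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            if d.min() < min_separation:
                raise ConsistencyError(
                    f"helix placement overlap ({d.min():.2f} A < {min_separation} A)"
                )

    residues: list[ResidueRecord] = []
    for h in helices:
        residues.extend(h.receptor_residues)
    residues.sort(key=lambda r: r.author_seq_id)
    return AnnotatedStructure(
        structure_id=structure_id,
        chains={tm5.chain_id: residues},
        receptor_chain=tm5.chain_id,
        coupling_label=coupling_label,
    )


def stub_from_features(
    tm5_len: int,
    tm5_tilt: float,
    tm6_outward: float,
    tm6_len: float = 21,
    structure_id: str = "stub",
    coupling_label: Optional[str] = None,
    tm5_azimuth: float = 90.0,
    tm6_azimuth: float = 270.0,
    with_scaffold: bool = True,
    min_separation: float = 2.0,
) -> AnnotatedStructure:
    """Receptor stub whose descriptors are (approximately) the given values.

    TM5 spans 5.36 to 5.(50+tm5_len); TM6 spans 6.(50-tm6_len) to 6.60.
    Tilts are realized exactly in the construction; extraction recovers them
    to within the carbonyl-averaging error (well under a degree).
    """
    tm5_tip = 50 + int(round(tm5_len))
    tm6_tip = 50 - int(round(tm6_len))
    if not (51 <= tm5_tip <= 99 and 1 <= tm6_tip <= 49):
        raise ValueError("requested lengths put helix tips outside GRN range")
    tm5_spec = HelixSpec(
        n_residues=tm5_tip - 36 + 1, grn_start="5.36", tilt_deg=tm5_tilt, azimuth_deg=tm5_azimuth
    )
    tm6_spec = HelixSpec(
        n_residues=60 - tm6_tip + 1,
        grn_start=f"6.{tm6_tip}",
        tilt_deg=tm6_outward,
        azimuth_deg=tm6_azimuth,
    )
    return make_receptor_stub(
        tm5_spec, tm6_spec, structure_id=structure_id, coupling_label=coupling_label,
        with_scaffold=with_scaffold, min_separation=min_separation,
    )


def make_reference_stub(structure_id: str = "reference") -> AnnotatedStructure:
    """The synthetic reference receptor: untilted TM5/TM6, TM5 >= 22 residues.

    Stands in for the pre-oriented reference receptor that defines the
    membrane frame and the TM5 reference orientation.
    """
    return stub_from_features(
        25, 0.0, 0.0, tm6_len=22, structure_id=structure_id, with_scaffold=True
    )


# ---------------------------------------------------------------------------
# feature tables

@dataclass
class GroupModel:
    """Gaussian summary of one coupling group's descriptors."""

    label: str
    mean: np.ndarray  # (tm5_len, tm5_tilt, tm6_outward, tm6_len)
    sd: np.ndarray
    len_tilt_corr: float = 0.0  # optional TM5 length/tilt correlation

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ValueError("group SDs must be positive")
        if not -1 < self.len_tilt_corr < 1:
            raise ValueError("correlation must lie in (-1, 1)")


def default_group_models(len_tilt_corr: dict[str, float] | None = None) -> list[GroupModel]:
    """The two reported group models (Gs, Gi/o) at the published parameters."""
    corr = len_tilt_corr or {}
    return [
        GroupModel(lab, C.GROUP_MEAN[lab], C.GROUP_SD[lab], corr.get(lab, 0.0))
        for lab in (C.GS, C.GIO)
    ]


def sample_feature_table(
    models: Sequence[GroupModel],
    n_per_group: dict[str, int] | int,
    seed: int,
) -> pd.DataFrame:
    """Draw labeled feature rows from the group Gaussians.

    Lengths are rounded to integers (floor 4); angles are floored at 0.
    Columns match the feature-CSV interchange format.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for model in models:
        n = n_per_group[model.label] if isinstance(n_per_group, dict) else int(n_per_group)
        if n < 1:
            raise ValueError("n_per_group must be >= 1")
        draws = rng.standard_normal((n, 4))
        if model.len_tilt_corr:
            r = model.len_tilt_corr
            draws[:, 1] = r * draws[:, 0] + math.sqrt(1 - r * r) * draws[:, 1]
        values = model.mean + draws * model.sd
        tm5_len = np.maximum(np.rint(values[:, 0]), 4).astype(int)
        tm6_len = np.maximum(np.rint(values[:, 3]), 4).astype(int)
        tm5_tilt = np.maximum(values[:, 1], 0.0)
        tm6_outward = np.maximum(values[:, 2], 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "structure_id": [f"{model.label.lower()}_{i:04d}" for i in range(n)],
                    "coupling_label": model.label,
                    "tm5_len": tm5_len,
                    "tm6_len": tm6_len,
                    "tm5_tilt": np.round(tm5_tilt, 3),
                    "tm6_outward": np.round(tm6_outward, 3),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# toy receptor-Galpha complex

def make_toy_complex(
    helix: Optional[HelixSpec] = None,
    slab_gap: float = 0.0,
    slab_margin: float = 4.0,
    slab_spacing: float = 2.0,
) -> AnnotatedStructure:
    """A helix lying on a planar slab of pseudo-Galpha carbon atoms.

    The helix is laid horizontally (its whole length faces the slab, as a
    TM tip faces the flattened Galpha surface) with the slab's top plane
    ``2.5 + slab_gap`` angstroms below the helix's lowest atom: ``slab_gap =
    0`` is van-der-Waals contact along the helix, large gaps bury nothing.
    Exercises interface-area code without a real Galpha fold.
    """
    if slab_gap < 0:
        raise ValueError("slab_gap must be >= 0")
    helix = helix or HelixSpec(n_residues=11, grn_start="5.45", chain_id="R", tilt_deg=90.0)
    hs = make_ideal_helix(helix)
    coords = np.array([a.coord for _, a in hs.iter_atoms()])
    z_slab = coords[:, 2].min() - 2.5 - slab_gap

    xs = np.arange(coords[:, 0].min() - slab_margin, coords[:, 0].max() + slab_margin, slab_spacing)
    ys = np.arange(coords[:, 1].min() - slab_margin, coords[:, 1].max() + slab_margin, slab_spacing)
    slab_residues = []
    for idx, (gx, gy) in enumerate(((x, y) for x in xs for y in ys), start=1):
        rec = ResidueRecord(chain_id="G", author_seq_id=idx, residue_name="UNK")
        rec.atoms["CA"] = AtomRecord(
            atom_name="CA", element="C", coord=np.array([gx, gy, z_slab])
        )
        slab_residues.append(rec)

    return AnnotatedStructure(
        structure_id="toy_complex",
        chains={"R": hs.receptor_residues, "G": slab_residues},
        receptor_chain="R",
        galpha_chain="G",
    )
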