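"""The four TM5/TM6 geometric descriptors of coupling selectivity.

Given a receptor in the membrane frame (+Z extracellular), this module
measures, per structure:

* ``tm5_len`` / ``tm6_len`` — helix length in residues, counted by GRN
  position from the conserved x.50 anchor to the cytosolic tip (the modeled
  residue whose Calpha lies deepest on the -Z side).  Counting by GRN
  position makes the length robust to unmodeled gaps.
* ``tm5_tilt`` — angle between the cytosolic TM5 orientation and the
  reference receptor's TM5 orientation (22-residue window on the reference).
* ``tm6_outward`` — angle between the cytosolic TM6 orientation and the
  receptor central axis -Z; the amplitude of the activation-associated
  outward swing.

Helix orientations are estimated from the backbone carbonyls: the unit C->O
bond vectors of an 11-residue window at the cytosolic tip (about three
helical turns, so the perpendicular components cancel) are averaged and the
residual perpendicular component is removed by projecting onto a
bisector-cross helix-axis estimate of the window's Calpha trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .axis import helix_axis
from .errors import (
    DegenerateSegmentError,
    GrnLookupError,
    InsufficientDataError,
)
from .structures import (
    AnnotatedStructure,
    HelixSegment,
    ResidueRecord,
    helix_ascending_is_cytosolic,
    select_helix,
    select_segment,
)

#: cytosolic direction of the membrane frame
CYTOSOLIC = np.array([0.0, 0.0, -1.0])

DEFAULT_WINDOW = 11
REFERENCE_WINDOW = 22
MIN_USABLE_RESIDUES = 4


@dataclass
class HelixOrientation:
    """A unit helix-axis estimate pointing extracellular -> cytosolic."""

    axis: np.ndarray
    n_residues_used: int
    window: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("orientation axis must be unit length")


@dataclass
class ReferenceOrientations:
    """Reference directions the TM5/TM6 angles are measured against."""

    tm5_reference_axis: np.ndarray
    tm6_reference_axis: np.ndarray = field(default_factory=lambda: CYTOSOLIC.copy())

    def __post_init__(self) -> None:
        for v in (self.tm5_reference_axis, self.tm6_reference_axis):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("reference axes must be unit vectors")


@dataclass
class GeometryFeatures:
    """One receptor's descriptor row."""

    structure_id: str
    tm5_len: int
    tm6_len: int
    tm5_tilt: float
    tm6_outward: float
    coupling_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tm5_len < 0 or self.tm6_len < 0:
            raise ValueError("helix lengths must be >= 0")
        for a in (self.tm5_tilt, self.tm6_outward):
            if not 0 <= a < 180:
                raise ValueError("angles must lie in [0, 180)")


@dataclass
class SegmentConfig:
    """Optional per-structure GRN bounds for the TM5/TM6 segments.

    When a bound pair is None the full annotated helix is used (the tips of
    built models are taken as modeled, which is how segment ends are defined
    here).
    """

    tm5_bounds: Optional[tuple[str, str]] = None
    tm6_bounds: Optional[tuple[str, str]] = None
    window: int = DEFAULT_WINDOW


def _segment(s: AnnotatedStructure, helix: int, bounds: Optional[tuple[str, str]]) -> HelixSegment:
    if bounds is not None:
        return select_segment(s, f"TM{helix}", bounds[0], bounds[1])
    return select_helix(s, helix)


# ---------------------------------------------------------------------------
# elementary operations

def cytosolic_tip(seg: HelixSegment) -> ResidueRecord:
    """The modeled residue with the lowest Calpha Z (deepest cytosolic).

    The segment's parent structure must already sit in the membrane frame.
    Raises if the anchor x.50 is absent or if the putative tip sits on the
    extracellular side of the anchor (an inverted or mis-framed segment).
    """
    with_ca = [r for r in seg.residues if r.ca() is not None]
    if not with_ca:
        raise InsufficientDataError(f"{seg.label}: no CA atoms in segment")
    anchor = next((r for r in seg.residues if r.grn == seg.anchor_grn), None)
    if anchor is None or anchor.ca() is None:
        raise GrnLookupError(f"{seg.label}: anchor {seg.anchor_grn} not present in segment")
    tip = min(with_ca, key=lambda r: r.ca().coord[2])
    if tip is not anchor:
        # the deepest residue must also be intracellular of x.50 in GRN terms,
        # else the segment is inverted or mis-framed
        ascending = helix_ascending_is_cytosolic(seg.helix)
        ic_side = (tip.grn_position or 50) > 50 if ascending else (tip.grn_position or 50) < 50
        if not ic_side or tip.ca().coord[2] >= anchor.ca().coord[2]:
            raise DegenerateSegmentError(
                f"{seg.label}: cytosolic tip lies extracellular of anchor {seg.anchor_grn}"
            )
    return tip


def helix_length(seg: HelixSegment) -> int:
    """Residue count from the x.50 anchor (exclusive) to the cytosolic tip.

    Counted by GRN position — ``|position(tip) - 50|`` — so modeling gaps do
    not shorten the helix.
    """
    tip = cytosolic_tip(seg)
    if tip.grn is None:
        raise GrnLookupError(f"{seg.label}: tip residue lacks a GRN")
    return abs(tip.grn_position - 50)


def helix_orientation(seg: HelixSegment, n_window: int = DEFAULT_WINDOW) -> HelixOrientation:
    """Cytosolic helix orientation from carbonyl averaging over a tip window.

    Walks from the cytosolic tip toward the extracellular side collecting
    residues with complete C/O/CA backbone until ``n_window`` usable residues
    (or the segment is exhausted; minimum 4).  The mean unit C->O vector is
    projected onto the window's helix-axis estimate and oriented toward the
    tip.
    """
    # segment order is extracellular -> cytosolic; walk from the tip end
    usable: list[ResidueRecord] = []
    for res in reversed(seg.residues):
        if all(res.atom(a) is not None for a in ("C", "O", "CA")):
            usable.append(res)
        if len(usable) == n_window:
            break
    usable.reverse()  # back to extracellular -> cytosolic
    if len(usable) < MIN_USABLE_RESIDUES:
        raise InsufficientDataError(
            f"{seg.label}: only {len(usable)} residues with C/O/CA; need >= {MIN_USABLE_RESIDUES}"
        )
    ca = np.array([r.ca().coord for r in usable])
    co = np.array([r.atom("O").coord - r.atom("C").coord for r in usable])
    co /= np.linalg.norm(co, axis=1, keepdims=True)
    mean_co = co.mean(axis=0)

    provisional = helix_axis(ca)  # points extracellular -> cytosolic (tip last)
    projected = provisional * float(np.dot(mean_co, provisional))
    norm = np.linalg.norm(projected)
    if norm < 1e-12:
        raise InsufficientDataError(f"{seg.label}: carbonyl mean orthogonal to helix axis")
    axis = projected / norm
    # orient toward the cytosolic tip
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return HelixOrientation(
        axis=axis, n_residues_used=len(usable), window=[r.residue_id for r in usable]
    )


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle in degrees between two non-zero vectors, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle undefined for zero vector")
    return math.degrees(math.acos(float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))))


# ---------------------------------------------------------------------------
# descriptor extraction

def build_reference(
    ref_structure: AnnotatedStructure,
    tm5_bounds: Optional[tuple[str, str]] = None,
) -> ReferenceOrientations:
    """Reference orientations: 22-residue TM5 window of the reference receptor.

    The TM6 reference is the receptor central axis -Z by definition.
    """
    seg = _segment(ref_structure, 5, tm5_bounds)
    orientation = helix_orientation(seg, n_window=REFERENCE_WINDOW)
    if orientation.n_residues_used < REFERENCE_WINDOW:
        raise InsufficientDataError(
            f"reference TM5 has {orientation.n_residues_used} usable residues; "
            f"need {REFERENCE_WINDOW}"
        )
    return ReferenceOrientations(tm5_reference_axis=orientation.axis)


def tm5_tilt(
    s: AnnotatedStructure,
    refs: ReferenceOrientations,
    config: Optional[SegmentConfig] = None,
) -> float:
    config = config or SegmentConfig()
    seg = _segment(s, 5, config.tm5_bounds)
    return angle_between(helix_orientation(seg, config.window).axis, refs.tm5_reference_axis)


def tm6_outward(
    s: AnnotatedStructure,
    config: Optional[SegmentConfig] = None,
) -> float:
    config = config or SegmentConfig()
    seg = _segment(s, 6, config.tm6_bounds)
    return angle_between(helix_orientation(seg, config.window).axis, CYTOSOLIC)


def extract_features(
    s: AnnotatedStructure,
    refs: ReferenceOrientations,
    config: Optional[SegmentConfig] = None,
) -> GeometryFeatures:
    """All four descriptors of one membrane-framed receptor."""
    config = config or SegmentConfig()
    values: dict[str, float | int] = {}
    for label, helix, bounds in (("TM5", 5, config.tm5_bounds), ("TM6", 6, config.tm6_bounds)):
        try:
            seg = _segment(s, helix, bounds)
            values[f"{label.lower()}_len"] = helix_length(seg)
            orientation = helix_orientation(seg, config.window)
            if helix == 5:
                values["tm5_tilt"] = angle_between(orientation.axis, refs.tm5_reference_axis)
            else:
                values["tm6_outward"] = angle_between(orientation.axis, CYTOSOLIC)
        except Exception as exc:
            raise type(exc)(f"{s.structure_id} {label}: {exc}") from exc
    return GeometryFeatures(
        structure_id=s.structure_id,
        tm5_len=int(values["tm5_len"]),
        tm6_len=int(values["tm6_len"]),
        tm5_tilt=float(values["tm5_tilt"]),
        tm6_outward=float(values["tm6_outward"]),
        coupling_label=s.coupling_label,
    )


# ---------------------------------------------------------------------------
# feature-table interchange format

FEATURE_COLUMNS = ["structure_id", "coupling_label", "tm5_len", "tm6_len", "tm5_tilt", "tm6_outward"]


def features_to_frame(features: Sequence[GeometryFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "structure_id": f.structure_id,
                "coupling_label": f.coupling_label,
                "tm5_len": f.tm5_len,
                "tm6_len": f.tm6_len,
                "tm5_tilt": round(f.tm5_tilt, 3),
                "tm6_outward": round(f.tm6_outward, 3),
            }
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    )


def write_feature_table(features: Sequence[GeometryFeatures] | pd.DataFrame, path: str | Path) -> Path:
    df = features if isinstance(features, pd.DataFrame) else features_to_frame(features)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.3f")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} lacks columns {sorted(missing)}")
    return df
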