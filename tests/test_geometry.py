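"""Helix descriptors: tips, lengths, orientations, angles, extraction."""

import math

import numpy as np
import pytest

from gpcrsel.errors import (
    DegenerateSegmentError,
    GrnLookupError,
    InsufficientDataError,
)
from gpcrsel.geometry import (
    angle_between,
    build_reference,
    cytosolic_tip,
    extract_features,
    helix_length,
    helix_orientation,
    tm5_tilt,
    tm6_outward,
)
from gpcrsel.structures import select_helix, select_segment
from gpcrsel.synth import HelixSpec, make_ideal_helix, stub_from_features


def tm5_segment(tm5_len, tilt=0.0, azimuth=90.0):
    s = stub_from_features(tm5_len, tilt, 20.0, tm5_azimuth=azimuth)
    return select_helix(s, 5)


class TestCytosolicTip:
    def test_tip_is_deepest_annotated_residue(self):
        seg = tm5_segment(25)
        assert cytosolic_tip(seg).grn == "5.75"

    def test_single_residue_segment_is_its_own_tip(self):
        s = stub_from_features(25, 0.0, 20.0)
        seg = select_segment(s, "TM5", "5.50", "5.50")
        tip = cytosolic_tip(seg)
        assert tip.grn == "5.50"
        assert helix_length(seg) == 0

    def test_inverted_segment_rejected(self):
        # flip the sequence direction so the helix runs extracellular-ward
        h = make_ideal_helix(HelixSpec(n_residues=25, grn_start="5.36", seq_toward_cytosol=False))
        seg = select_helix(h, 5)
        with pytest.raises(DegenerateSegmentError):
            cytosolic_tip(seg)

    def test_missing_anchor_rejected(self):
        h = make_ideal_helix(HelixSpec(n_residues=11, grn_start="5.55"))  # no 5.50
        seg = select_helix(h, 5)
        with pytest.raises(GrnLookupError):
            cytosolic_tip(seg)


class TestHelixLength:
    @pytest.mark.parametrize("tm5_len", [19, 23, 25])
    def test_length_is_tip_position_minus_fifty(self, tm5_len):
        assert helix_length(tm5_segment(tm5_len)) == tm5_len

    def test_difference_between_tips(self):
        # tips at 5.66 vs 5.75 differ by nine residues
        assert helix_length(tm5_segment(25)) - helix_length(tm5_segment(16)) == 9

    def test_gap_does_not_shorten_helix(self):
        seg = tm5_segment(25)
        seg.residues = [r for r in seg.residues if r.grn not in ("5.70", "5.71")]
        assert helix_length(seg) == 25  # counted by GRN position, not modeled count


class TestHelixOrientation:
    def test_vertical_helix_points_cytosolic(self):
        h = make_ideal_helix(HelixSpec(n_residues=11, grn_start="5.45"))
        orientation = helix_orientation(select_helix(h, 5), 11)
        assert orientation.axis @ np.array([0.0, 0.0, -1.0]) >= 0.999
        assert orientation.n_residues_used == 11

    def test_tilted_axis_recovered_within_a_degree(self):
        t, a = math.radians(18.0), math.radians(130.0)
        expected = np.array([math.sin(t) * math.cos(a), math.sin(t) * math.sin(a), -math.cos(t)])
        h = make_ideal_helix(HelixSpec(n_residues=20, grn_start="5.40", tilt_deg=18.0, azimuth_deg=130.0))
        orientation = helix_orientation(select_helix(h, 5), 11)
        assert angle_between(orientation.axis, expected) <= 1.0

    def test_window_extends_past_residues_missing_carbonyls(self):
        h = make_ideal_helix(HelixSpec(n_residues=20, grn_start="5.40"))
        seg = select_helix(h, 5)
        for r in seg.residues[-3:]:  # strip O from the three tip residues
            del r.atoms["O"]
        orientation = helix_orientation(seg, 11)
        assert orientation.n_residues_used == 11
        assert orientation.axis @ np.array([0.0, 0.0, -1.0]) >= 0.999

    def test_fragment_too_short(self):
        h = make_ideal_helix(HelixSpec(n_residues=11, grn_start="5.45"))
        seg = select_helix(h, 5)
        seg.residues = seg.residues[:3]
        with pytest.raises(InsufficientDataError):
            helix_orientation(seg)

    def test_tm6_orientation_points_cytosolic_despite_sequence_reversal(self):
        h = make_ideal_helix(HelixSpec(n_residues=25, grn_start="6.30"))
        orientation = helix_orientation(select_helix(h, 6), 11)
        assert orientation.axis @ np.array([0.0, 0.0, -1.0]) >= 0.999


class TestAngleBetween:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
            ((0, 0, 1), (0, math.sin(math.radians(12)), math.cos(math.radians(12))), 12.0),
            ((0, 0, 1), (0, 0, -1), 180.0),
        ],
    )
    def test_analytic_angles(self, u, v, expected):
        assert angle_between(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            angle_between(np.zeros(3), np.array([1.0, 0, 0]))


class TestDescriptors:
    def test_reference_tm5_tilt_is_zero(self, reference_stub, reference_orientations):
        assert tm5_tilt(reference_stub, reference_orientations) == pytest.approx(0.0, abs=0.5)

    def test_tilt_against_reference(self, reference_orientations):
        s = stub_from_features(23, 18.0, 20.0)
        assert tm5_tilt(s, reference_orientations) == pytest.approx(18.0, abs=1.0)

    @pytest.mark.parametrize("outward", [0.0, 23.8, 90.0])
    def test_tm6_outward(self, outward):
        s = stub_from_features(23, 0.0, outward, with_scaffold=False)
        assert tm6_outward(s) == pytest.approx(outward, abs=1.0)

    def test_build_reference_requires_22_usable_residues(self):
        short = stub_from_features(15, 0.0, 0.0)  # TM5 5.36..5.65: 30 residues OK
        # strip carbonyls so fewer than 22 usable remain
        for r in short.receptor_residues:
            if r.grn_helix == 5 and r.grn_position > 52:
                del r.atoms["O"]
        with pytest.raises(InsufficientDataError):
            build_reference(short)

    def test_tm6_reference_is_minus_z(self, reference_orientations):
        assert np.allclose(reference_orientations.tm6_reference_axis, [0, 0, -1])


class TestExtraction:
    def test_gs_like_stub_round_trip(self, gs_stub, reference_orientations):
        f = extract_features(gs_stub, reference_orientations)
        assert f.tm5_len == 23
        assert f.tm5_tilt == pytest.approx(12.0, abs=1.0)
        assert f.tm6_outward == pytest.approx(23.8, abs=1.0)
        assert f.coupling_label == "GS"

    def test_extraction_deterministic(self, gs_stub, reference_orientations):
        f1 = extract_features(gs_stub, reference_orientations)
        f2 = extract_features(gs_stub, reference_orientations)
        assert (f1.tm5_len, f1.tm5_tilt, f1.tm6_outward) == (f2.tm5_len, f2.tm5_tilt, f2.tm6_outward)

    def test_missing_tm6_error_names_the_helix(self, reference_orientations):
        h = make_ideal_helix(HelixSpec(n_residues=25, grn_start="5.36"))
        with pytest.raises(GrnLookupError, match="TM6"):
            extract_features(h, reference_orientations)


class TestInvariances:
    def test_rotation_about_z_preserves_tm6_outward(self, gs_stub):
        from gpcrsel.synth import _rodrigues

        before = tm6_outward(gs_stub)
        Rz = _rodrigues(np.array([0.0, 0.0, 1.0]), math.radians(73.0))
        rotated = gs_stub.transformed(Rz, np.zeros(3))
        assert tm6_outward(rotated) == pytest.approx(before, abs=1e-6)

    def test_translation_preserves_all_descriptors(self, gs_stub, reference_orientations):
        f0 = extract_features(gs_stub, reference_orientations)
        moved = gs_stub.transformed(np.eye(3), np.array([11.0, -7.0, 3.0]))
        f1 = extract_features(moved, reference_orientations)
        assert f0.tm5_len == f1.tm5_len
        assert f0.tm5_tilt == pytest.approx(f1.tm5_tilt, abs=1e-9)
        assert f0.tm6_outward == pytest.approx(f1.tm6_outward, abs=1e-9)

    def test_window_11_vs_22_agree_on_ideal_helices(self):
        h = make_ideal_helix(HelixSpec(n_residues=30, grn_start="5.36", tilt_deg=14.0, azimuth_deg=45.0))
        seg = select_helix(h, 5)
        a11 = helix_orientation(seg, 11).axis
        a22 = helix_orientation(seg, 22).axis
        assert angle_between(a11, a22) <= 0.5
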