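"""Alignment, section levels, and contour extraction (stack + mesh paths)."""

import numpy as np
import pytest
import trimesh

from asymbone._geometry import signed_area
from asymbone.errors import ConfigurationError
from asymbone.sectioning import (align_bone, default_section_levels,
                                 extract_section, section_levels, SectionLevels)
from asymbone.synthetic import (DiaphysisProfile, base_diaphysis, stack_to_mesh)


class TestSectionLevels:
    def test_reference_scheme_has_28_levels(self):
        levels = default_section_levels()
        assert len(levels) == 28
        lv = np.asarray(list(levels))
        assert np.sum((lv >= 12.5) & (lv <= 25.0)) == 6
        assert np.sum((lv >= 37.5) & (lv <= 90.0)) == 22

    def test_single_interval_arithmetic_sequence(self):
        levels = section_levels(2.5, [(12.5, 25.0)])
        assert list(levels) == [12.5, 15.0, 17.5, 20.0, 22.5, 25.0]

    def test_no_level_inside_excluded_band(self):
        lv = np.asarray(list(default_section_levels()))
        assert not np.any((lv > 25.0) & (lv < 37.5))

    def test_overlapping_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            section_levels(2.5, [(20.0, 40.0)])
        with pytest.raises(ConfigurationError):
            SectionLevels((10.0, 30.0), excluded_band=(25.0, 37.5))


class TestAlignMesh:
    def test_cylinder_length_recovered(self):
        mesh = trimesh.creation.cylinder(radius=2.0, height=30.0, sections=64)
        # arbitrary pose
        T = trimesh.transformations.rotation_matrix(0.7, [1, 0.3, 0.2])
        T[:3, 3] = [5.0, -2.0, 1.0]
        mesh.apply_transform(T)
        aligned, L = align_bone(mesh)
        assert L == pytest.approx(30.0, abs=1e-6)
        v = np.asarray(aligned.vertices)
        assert v[:, 2].min() == pytest.approx(0.0, abs=1e-9)

    def test_prealigned_cylinder_is_unchanged_up_to_tolerance(self):
        mesh = trimesh.creation.cylinder(radius=2.0, height=30.0, sections=64)
        mesh.apply_translation([0, 0, 15.0])
        aligned, L = align_bone(mesh)
        assert L == pytest.approx(30.0, abs=1e-9)
        assert np.allclose(np.sort(np.asarray(aligned.vertices)[:, 2]),
                           np.sort(np.asarray(mesh.vertices)[:, 2]), atol=1e-9)

    def test_random_rotations_preserve_length(self, rng):
        stack = base_diaphysis(n_levels=21, n_vertices=64)
        mesh = stack_to_mesh(stack)
        _, L0 = align_bone(mesh)
        for _ in range(3):
            m = mesh.copy()
            axis = rng.normal(size=3)
            m.apply_transform(trimesh.transformations.rotation_matrix(
                rng.uniform(0, np.pi), axis / np.linalg.norm(axis)))
            _, L = align_bone(m)
            assert L == pytest.approx(L0, abs=1e-6)

    def test_proximal_end_points_up(self):
        # the flared (proximal) end must land at high z regardless of pose
        stack = base_diaphysis(n_levels=21, n_vertices=64)
        mesh = stack_to_mesh(stack)
        flipped = mesh.copy()
        flipped.apply_transform(trimesh.transformations.rotation_matrix(
            np.pi, [1, 0, 0]))
        for m in (mesh, flipped):
            aligned, L = align_bone(m)
            v = np.asarray(aligned.vertices)
            lo = v[v[:, 2] < 0.1 * L]
            hi = v[v[:, 2] > 0.9 * L]
            assert np.hypot(hi[:, 0], hi[:, 1]).mean() > \
                np.hypot(lo[:, 0], lo[:, 1]).mean()


class TestExtractSection:
    def test_annular_tube_area_ratio(self):
        mesh = trimesh.creation.annulus(r_min=1.0, r_max=2.0, height=30.0,
                                        sections=512)
        mesh.apply_translation([0, 0, 15.0])
        sec = extract_section(mesh, 50.0, excluded_band=None)
        a_out = signed_area(sec.periosteal)
        a_in = signed_area(sec.endosteal)
        assert a_out / a_in == pytest.approx(4.0, rel=0.005)
        assert a_out == pytest.approx(4 * np.pi, rel=0.005)

    def test_detached_second_element_is_discarded(self):
        # tibia-like annulus plus a small detached fibula tube: only the
        # largest curve and its interior partner are kept
        tibia = trimesh.creation.annulus(r_min=1.0, r_max=2.0, height=30.0,
                                         sections=256)
        fibula = trimesh.creation.annulus(r_min=0.2, r_max=0.4, height=30.0,
                                          sections=64)
        fibula.apply_translation([3.5, 0.0, 0.0])
        both = trimesh.util.concatenate([tibia, fibula])
        both.apply_translation([0, 0, 15.0])
        sec = extract_section(both, 50.0, excluded_band=None)
        assert signed_area(sec.periosteal) == pytest.approx(4 * np.pi, rel=0.01)
        assert signed_area(sec.endosteal) == pytest.approx(np.pi, rel=0.01)

    def test_contours_counter_clockwise_and_nested(self):
        stack = base_diaphysis(n_levels=21, n_vertices=128)
        for level in (12.5, 50.0, 90.0):
            sec = extract_section(stack, level).validate()
            assert signed_area(sec.periosteal) > 0
            assert signed_area(sec.endosteal) > 0

    def test_level_in_excluded_band_rejected(self):
        stack = base_diaphysis(n_levels=21, n_vertices=64)
        with pytest.raises(ConfigurationError):
            extract_section(stack, 30.0)

    def test_area_converges_with_resolution(self):
        # relative polygon-area error < 0.5% at >= 500 boundary vertices
        mesh = trimesh.creation.annulus(r_min=1.0, r_max=2.0, height=10.0,
                                        sections=500)
        mesh.apply_translation([0, 0, 5.0])
        sec = extract_section(mesh, 50.0, excluded_band=None, n_resample=1000)
        assert abs(signed_area(sec.periosteal) - 4 * np.pi) / (4 * np.pi) < 0.005


def test_rigid_motion_before_alignment_does_not_change_sections(rng):
    stack = base_diaphysis(n_levels=21, n_vertices=96,
                           profile_params=DiaphysisProfile(curvature_mm=0.0))
    mesh = stack_to_mesh(stack)
    ref_aligned, _ = align_bone(mesh)
    ref = extract_section(ref_aligned, 50.0, excluded_band=None)
    moved = mesh.copy()
    axis = rng.normal(size=3)
    T = trimesh.transformations.rotation_matrix(1.1, axis / np.linalg.norm(axis))
    T[:3, 3] = [4.0, 2.0, -7.0]
    moved.apply_transform(T)
    aligned, _ = align_bone(moved)
    sec = extract_section(aligned, 50.0, excluded_band=None)
    from asymbone.csg import csg_parameters
    r0, r1 = csg_parameters(ref), csg_parameters(sec)
    for name in ("TotA", "MedA", "TotP", "Imin", "Imax", "J"):
        assert getattr(r1, name) == pytest.approx(getattr(r0, name), rel=1e-4)
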