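"""Ring projection, polygon clipping and per-step stacking overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Polygon

from basestack import dna_geometry as dg
from basestack import stacking
from basestack import synthetic_data as syn
from basestack.stacking import RingPolygon, points_in_polygon
from basestack.structure_io import Atom, Residue

from conftest import random_rotation


def _square(offset=(0.0, 0.0), side=1.0) -> RingPolygon:
    ox, oy = offset
    verts = np.array([[ox, oy], [ox + side, oy],
                      [ox + side, oy + side], [ox, oy + side]])
    res = Residue("A", 1, "", "DUM", "none", False, [])
    return RingPolygon(res, verts, "pyrimidine")


def _steps(structure):
    return dg.build_steps(dg.detect_base_pairs(structure, "A", "B"))


class TestProjection:
    def test_in_plane_ring_projects_congruently(self):
        res = _planar_residue("C")
        poly = stacking.project_ring(res, np.array([0, 0, 1.0]), np.zeros(3))
        ring3d = np.array([res.atom(n).pos[:2]
                           for n in stacking.templates.RING_ATOMS["C"]])
        assert Polygon(poly.vertices).area == pytest.approx(
            Polygon(ring3d).area, abs=1e-9)

    def test_tilted_ring_area_scales_with_cosine(self):
        theta = np.deg2rad(35.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(theta), -np.sin(theta)],
                        [0, np.sin(theta), np.cos(theta)]])
        flat = stacking.project_ring(_planar_residue("G"),
                                     np.array([0, 0, 1.0]), np.zeros(3))
        tilted = stacking.project_ring(_planar_residue("G", rot),
                                       np.array([0, 0, 1.0]), np.zeros(3))
        assert Polygon(tilted.vertices).area == pytest.approx(
            Polygon(flat.vertices).area * np.cos(theta), rel=1e-9)

    def test_methyl_group_cannot_change_the_polygon(self):
        plain = _planar_residue("C")
        methylated = _planar_residue("C")
        methylated.base_code = "mC"
        methylated.is_methylated = True
        methylated.atoms.append(Atom("C5M", "C", np.array([2.4, 5.2, 0.0])))
        axis, origin = np.array([0, 0, 1.0]), np.zeros(3)
        pa = stacking.project_ring(plain, axis, origin)
        pb = stacking.project_ring(methylated, axis, origin)
        assert np.abs(pa.vertices - pb.vertices).max() == 0.0

    def test_missing_ring_atom_errors(self):
        res = _planar_residue("A")
        res.atoms = [a for a in res.atoms if a.name != "N7"]
        with pytest.raises(ValueError, match="N7"):
            stacking.project_ring(res, np.array([0, 0, 1.0]), np.zeros(3))


def _planar_residue(base, rot=None):
    rot = np.eye(3) if rot is None else rot
    atoms = [Atom(n, n[0], rot @ p)
             for n, p in stacking.templates.base_template(base).items()]
    return Residue("A", 1, "", f"D{base}", base, False, atoms)


class TestIntersectionArea:
    def test_identity_and_offset_squares(self):
        a = _square()
        assert stacking.polygon_intersection_area(a, a) == pytest.approx(1.0)
        b = _square(offset=(0.5, 0.0))
        assert stacking.polygon_intersection_area(a, b) == pytest.approx(0.5)
        far = _square(offset=(5.0, 5.0))
        assert stacking.polygon_intersection_area(a, far) == 0.0

    def test_degenerate_polygon_returns_zero(self):
        res = Residue("A", 1, "", "DUM", "none", False, [])
        line = RingPolygon(res, np.array([[0, 0], [1, 0], [2, 0], [3, 0]]),
                           "pyrimidine")
        assert stacking.polygon_intersection_area(line, _square()) == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_monte_carlo_on_random_convex_hexagons(self, seed):
        rng = np.random.default_rng(seed)
        polys = []
        for _ in range(2):
            # convex hexagon: circle points under a random affine map
            ang = np.sort(rng.uniform(0, 2 * np.pi, 6))
            unit = np.c_[np.cos(ang), np.sin(ang)]
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            scale = np.diag(rng.uniform(1.0, 3.0, 2))
            centre = rng.uniform(-1, 1, 2)
            verts = centre + unit @ (rot @ scale).T
            res = Residue("A", 1, "", "DUM", "none", False, [])
            polys.append(RingPolygon(res, verts, "pyrimidine"))
        exact = stacking.polygon_intersection_area(*polys)
        lo = np.maximum(polys[0].vertices.min(0), polys[1].vertices.min(0))
        hi = np.minimum(polys[0].vertices.max(0), polys[1].vertices.max(0))
        if np.any(hi <= lo):
            assert exact == pytest.approx(0.0, abs=1e-9)
            return
        pts = rng.uniform(lo, hi, size=(1_000_000, 2))
        inside = (points_in_polygon(polys[0].vertices, pts)
                  & points_in_polygon(polys[1].vertices, pts))
        mc = float(np.prod(hi - lo)) * inside.mean()
        assert exact == pytest.approx(mc, rel=0.01, abs=0.01)


class TestStepOverlap:
    def test_polya_steps_identical_by_helical_symmetry(self):
        s = syn.build_bdna("AAAAAAAAAA")
        results = [stacking.step_overlap(st_) for st_ in _steps(s)]
        values = [r.s_oa for r in results]
        assert np.ptp(values) < 1e-6
        assert values[0] > 0.5  # purine-purine stacking overlaps substantially

    def test_step_soa_matches_monte_carlo(self):
        s = syn.build_bdna("AAAAAAAAAA")
        step = _steps(s)[4]
        clip = stacking.step_overlap(step).s_oa
        mc = stacking.monte_carlo_step_overlap(step, 1_000_000, seed=3)
        assert clip == pytest.approx(mc, rel=0.01)

    def test_additivity_of_pair_areas(self, smgre):
        for r in (stacking.step_overlap(st_) for st_ in _steps(smgre)):
            assert r.s_oa == pytest.approx(sum(r.pair_areas.values()), abs=1e-12)

    def test_distant_pairs_do_not_overlap(self):
        s = syn.build_bdna("AT", fiber=syn.FiberParams(rise=3.4, shift=20.0))
        r = stacking.step_overlap(_steps(s)[0])
        assert r.s_oa == 0.0

    def test_profile_shape_and_determinism(self, gre):
        p1 = stacking.structure_soa_profile(gre, "A", "B")
        p2 = stacking.structure_soa_profile(gre, "A", "B")
        assert len(p1) == 1 and len(p1[0]) == 14
        assert [r.s_oa for r in p1[0]] == [r.s_oa for r in p2[0]]

    def test_rigid_motion_invariance(self):
        s = syn.build_bdna("AGAACATC")
        ref = [r.s_oa for r in stacking.structure_soa_profile(s, "A", "B")[0]]
        rng = np.random.default_rng(99)
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.normal(0, 50, 3)
            moved = s.model(0)
            moved.set_coords(moved.coords() @ rot.T + t)
            got = [r.s_oa for r in
                   stacking.structure_soa_profile(moved, "A", "B")[0]]
            assert np.abs(np.array(got) - ref).max() < 1e-6

    def test_strand_swap_reverses_profile(self, smgre):
        ab = [r.s_oa for r in stacking.structure_soa_profile(smgre, "A", "B")[0]]
        ba = [r.s_oa for r in stacking.structure_soa_profile(smgre, "B", "A")[0]]
        assert np.abs(np.array(ab) - np.array(ba)[::-1]).max() < 1e-6

    def test_multi_model_profiles_one_per_model(self, gre):
        ens = syn.perturb_structure(gre, 0.05, 3, seed=2)
        profiles = stacking.structure_soa_profile(ens, "A", "B")
        assert len(profiles) == 3
        assert all(len(p) == 14 for p in profiles)
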