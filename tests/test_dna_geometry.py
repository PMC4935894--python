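"""Base frames, pair detection, step construction and classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from basestack import dna_geometry as dg
from basestack import synthetic_data as syn
from basestack import templates
from basestack.structure_io import Atom, Residue, Structure

from conftest import random_rotation


def _residue_from_template(base: str, rot=None, origin=None, noise=None,
                           rng=None) -> Residue:
    rot = np.eye(3) if rot is None else rot
    origin = np.zeros(3) if origin is None else origin
    atoms = []
    for name, pos in templates.base_template(base).items():
        p = rot @ pos + origin
        if noise:
            p = p + rng.normal(0, noise, 3)
        atoms.append(Atom(name, name[0], p))
    return Residue("A", 1, "", f"D{base}", base, False, atoms)


class TestFitBaseFrame:
    def test_exact_recovery_of_identity_placement(self):
        frame = dg.fit_base_frame(_residue_from_template("G"))
        assert np.abs(frame.origin).max() < 1e-6
        assert np.abs(frame.axes - np.eye(3)).max() < 1e-6
        assert frame.fit_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_equivariance_under_rotation(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            rot = random_rotation(rng)
            t = rng.normal(0, 10, 3)
            frame = dg.fit_base_frame(_residue_from_template("C", rot, t))
            assert np.abs(frame.axes - rot).max() < 1e-6
            assert np.abs(frame.origin - t).max() < 1e-6

    def test_fit_rmsd_tracks_known_noise(self):
        rng = np.random.default_rng(42)
        rmsds = [dg.fit_base_frame(
            _residue_from_template("A", noise=0.05, rng=rng)).fit_rmsd
            for _ in range(100)]
        # per-axis sigma 0.05 A on 9 ring atoms leaves an expected residual
        # rmsd of sigma * sqrt((3n-6)/n) ~ 0.076 A after the rigid fit
        assert 0.02 <= np.mean(rmsds) <= 0.10
        assert all(0.02 <= r <= 0.13 for r in rmsds)

    def test_missing_ring_atom_errors(self):
        res = _residue_from_template("T")
        res.atoms = [a for a in res.atoms if a.name != "C4"]
        with pytest.raises(ValueError, match="C4"):
            dg.fit_base_frame(res)

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(6), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            dg.kabsch(pts, pts)


class TestPairDetection:
    def test_ideal_duplex_fully_paired(self, gre):
        pairs = dg.detect_base_pairs(gre, "A", "B")
        assert len(pairs) == 15
        assert all(p.is_wc for p in pairs)
        assert [p.res_w.seq_num for p in pairs] == list(range(1, 16))
        assert all(8.0 < p.c1c1_dist < 12.0 for p in pairs)

    def test_offset_register_leaves_overhangs(self):
        s = syn.build_bdna("AGAACATCATGTTCTA")  # 16 bp
        del s.chains["A"][15]
        del s.chains["B"][15]
        pairs = dg.detect_base_pairs(s, "A", "B")
        # brute force: A_i pairs B_{17-i}; dropping A16 and B16 strands 14 pairs
        assert len(pairs) == 14

    def test_symmetry_under_strand_swap(self, gre):
        ab = dg.detect_base_pairs(gre, "A", "B")
        ba = dg.detect_base_pairs(gre, "B", "A")
        set_ab = {(p.res_w.seq_num, p.res_c.seq_num) for p in ab}
        set_ba = {(p.res_c.seq_num, p.res_w.seq_num) for p in ba}
        assert set_ab == set_ba

    def test_missing_or_nonnucleic_strand_errors(self, gre):
        with pytest.raises(KeyError):
            dg.detect_base_pairs(gre, "A", "Z")
        protein = Structure("p", {
            "A": gre.model(0).chains["A"],
            "P": [Residue("P", 1, "", "GLY", "none", False,
                          [Atom("CA", "C", np.zeros(3))])]})
        with pytest.raises(ValueError):
            dg.detect_base_pairs(protein, "A", "P")

    def test_pair_frames_are_proper_orthonormal(self, smgre):
        for p in dg.detect_base_pairs(smgre, "A", "B"):
            assert np.abs(p.axes @ p.axes.T - np.eye(3)).max() < 1e-6
            assert np.linalg.det(p.axes) == pytest.approx(1.0, abs=1e-6)


class TestSteps:
    def test_n_minus_one_steps_and_unit_axis(self, gre):
        pairs = dg.detect_base_pairs(gre, "A", "B")
        steps = dg.build_steps(pairs)
        assert len(steps) == 14
        for s in steps:
            assert np.linalg.norm(s.helix_axis) == pytest.approx(1.0, abs=1e-9)

    def test_straight_duplex_axes_parallel_to_build_axis(self, gre):
        steps = dg.build_steps(dg.detect_base_pairs(gre, "A", "B"))
        for s in steps:
            assert abs(abs(s.helix_axis @ np.array([0, 0, 1.0])) - 1) < 1e-6

    def test_fewer_than_two_pairs_yields_no_steps(self, gre):
        pairs = dg.detect_base_pairs(gre, "A", "B")
        assert dg.build_steps(pairs[:1]) == []

    def test_mmgre_methylated_step_labels(self):
        s = syn.build_bdna(syn.MMGRE)
        steps = dg.build_steps(dg.detect_base_pairs(s, "A", "B"))
        assert steps[6].step_label == "TmC"  # step between positions 7 and 8
        assert steps[7].step_label == "mCA"  # step between positions 8 and 9


class TestClassification:
    def test_reverse_complement_pairs_share_a_class(self):
        assert dg.classify_step("AC") == dg.classify_step("GT")
        assert dg.classify_step("CA") == dg.classify_step("TG")

    def test_self_complementary_step_is_own_class(self):
        assert dg.classify_step("AT") == "AT"

    def test_sixteen_dinucleotides_give_ten_classes(self):
        labels = {dg.classify_step(a + b)
                  for a, b in itertools.product("ACGT", repeat=2)}
        assert len(labels) == 10

    def test_methylation_distinguishes_classes(self):
        assert dg.classify_step("AmC") != dg.classify_step("AC")
        assert dg.classify_step("mCA") != dg.classify_step("CA")

    def test_unknown_symbol_errors(self):
        with pytest.raises(ValueError):
            dg.classify_step("AX")
        with pytest.raises(ValueError):
            dg.classify_step("A")

    @settings(derandomize=True, max_examples=64)
    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_classify_invariant_and_idempotent(self, a, b):
        rc = templates.COMPLEMENT[b] + templates.COMPLEMENT[a]
        label = dg.classify_step(a + b)
        assert label == dg.classify_step(rc)
        assert dg.classify_step(label) == label  # canonical form is a fixpoint
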