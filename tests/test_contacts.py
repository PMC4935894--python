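"""Hydrogen bonds, water bridges, distances, superposition, distributions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from basestack import contacts as ct
from basestack import synthetic_data as syn
from basestack.structure_io import Atom, Residue, Structure

from conftest import random_rotation


def _mini(*residues) -> Structure:
    chains: dict[str, list[Residue]] = {}
    for r in residues:
        chains.setdefault(r.chain_id, []).append(r)
    return Structure("mini", chains)


def _lys(chain, num, nz_pos):
    return Residue(chain, num, "", "LYS", "none", False,
                   [Atom("NZ", "N", np.asarray(nz_pos, float))])


def _gua(chain, num, o6_pos):
    return Residue(chain, num, "", "DG", "G", False,
                   [Atom("O6", "O", np.asarray(o6_pos, float))])


def _thy(chain, num, o4_pos):
    return Residue(chain, num, "", "DT", "T", False,
                   [Atom("O4", "O", np.asarray(o4_pos, float))])


def _wat(chain, num, pos):
    return Residue(chain, num, "", "HOH", "none", False,
                   [Atom("O", "O", np.asarray(pos, float))])


class TestHBonds:
    def test_threshold_is_sharp(self):
        near = _mini(_lys("A", 1, [0, 0, 0]), _gua("D", 5, [3.4, 0, 0]))
        far = _mini(_lys("A", 1, [0, 0, 0]), _gua("D", 5, [3.6, 0, 0]))
        assert len(ct.find_hbonds(near, "A/1/*", "D/5/*")) == 1
        assert ct.find_hbonds(far, "A/1/*", "D/5/*") == []

    def test_lysine_guanine_geometry(self):
        s = _mini(_lys("A", 461, [0, 0, 0]), _gua("D", 8, [0, 2.9, 0]))
        bonds = ct.find_hbonds(s, "A/461/NZ", "D/*/*")
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-3)
        assert bonds[0].donor_atom.name == "NZ"  # lysine donates
        assert bonds[0].acceptor_atom.name == "O6"

    def test_symmetric_in_selection_order_and_monotone_in_cutoff(self):
        s = _mini(_lys("A", 1, [0, 0, 0]), _gua("D", 5, [3.0, 0, 0]),
                  _thy("D", 6, [0, 3.3, 0]))
        ab = ct.find_hbonds(s, "A/*/*", "D/*/*")
        ba = ct.find_hbonds(s, "D/*/*", "A/*/*")
        assert {(b.donor_atom.name, b.acceptor_atom.name) for b in ab} == \
               {(b.donor_atom.name, b.acceptor_atom.name) for b in ba}
        small = ct.find_hbonds(s, "A/*/*", "D/*/*", d_max=3.1)
        large = ct.find_hbonds(s, "A/*/*", "D/*/*", d_max=3.5)
        assert {b.distance for b in small} <= {b.distance for b in large}

    def test_empty_selection_errors(self):
        s = _mini(_lys("A", 1, [0, 0, 0]), _gua("D", 5, [3.0, 0, 0]))
        with pytest.raises(ValueError):
            ct.find_hbonds(s, "Z/*/*", "D/*/*")


class TestWaterBridges:
    def test_equidistant_bridge_detected(self):
        s = _mini(_lys("A", 461, [0, 0, 0]), _thy("D", 7, [5.6, 0, 0]),
                  _wat("W", 1, [2.8, 0, 0]))
        bridges = ct.find_water_bridges(s, "A/*/*", "D/*/*")
        assert len(bridges) == 1
        b = bridges[0]
        assert b.bridged_by is not None
        assert b.leg_a == pytest.approx(2.8, abs=1e-6)
        assert b.leg_b == pytest.approx(2.8, abs=1e-6)

    def test_no_waters_gives_empty_list(self):
        s = _mini(_lys("A", 1, [0, 0, 0]), _thy("D", 7, [5.6, 0, 0]))
        assert ct.find_water_bridges(s, "A/*/*", "D/*/*") == []

    def test_only_true_bridges_among_several_waters(self):
        s = _mini(_lys("A", 1, [0, 0, 0]), _thy("D", 7, [5.6, 0, 0]),
                  _wat("W", 1, [2.8, 0, 0]),       # bridges both sides
                  _wat("W", 2, [2.8, 8, 0]),       # near neither
                  _wat("W", 3, [-2.0, 0, 0]))      # near lysine only
        # brute force: exactly one water is <= 3.5 A from both selections
        bridges = ct.find_water_bridges(s, "A/*/*", "D/*/*")
        assert len(bridges) == 1
        assert bridges[0].bridged_by.pos[0] == pytest.approx(2.8)


class TestDistances:
    def test_pythagorean_distance_and_zero(self):
        s = _mini(_lys("A", 1, [0, 0, 0]), _gua("D", 5, [3, 4, 0]))
        assert ct.measure_distance(s, "A/1/NZ", "D/5/O6") == [pytest.approx(5.0)]
        assert ct.measure_distance(s, "A/1/NZ", "A/1/NZ") == [pytest.approx(0.0)]

    def test_ambiguous_selection_errors(self, gre):
        with pytest.raises(ValueError, match="exactly one"):
            ct.measure_distance(gre, "A/*/C1'", "B/1/C1'")

    def test_distribution_of_constant_distance_occupies_one_bin(self):
        ens = syn.make_distance_ensemble(4.0, 0.0, 100, seed=1)
        d = ct.distance_distribution(ens, "X/1/X1", "Y/1/X2", bin_width=0.1)
        assert int(d.counts.sum()) == 100
        assert np.count_nonzero(d.counts) == 1

    def test_distribution_recovers_sampling_mean(self):
        ens = syn.make_distance_ensemble(7.0, 0.5, 2000, seed=8)
        d = ct.distance_distribution(ens, "X/1/X1", "Y/1/X2", bin_width=0.1)
        assert d.mean == pytest.approx(7.0, abs=0.05)
        assert int(d.counts.sum()) == 2000

    def test_lower_bound_of_separation_holds(self):
        # emulates an exclusion-zone ensemble where the methyl-bearing carbon
        # stays away from the arginine amino group
        ens = syn.make_distance_ensemble(3.5, 0.4, 500, seed=3)
        d = ct.distance_distribution(ens, "X/1/X1", "Y/1/X2")
        assert d.values.min() > 2.0


class TestSuperposition:
    def test_self_superposition_is_identity(self, gre):
        amap = ct.dna_atom_map(gre, gre, ["A", "B"])
        res = ct.superpose(gre, gre, amap)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.abs(res.rotation - np.eye(3)).max() < 1e-9

    def test_rigid_motion_recovered(self, gre):
        rng = np.random.default_rng(5)
        rot = random_rotation(rng)
        t = rng.normal(0, 20, 3)
        moved = gre.model(0)
        moved.set_coords(moved.coords() @ rot.T + t)
        res = ct.superpose(gre, moved, ct.dna_atom_map(gre, moved, ["A", "B"]))
        assert res.rmsd < 1e-6

    def test_noisy_rmsd_agrees_with_independent_fit(self, gre):
        """Own Kabsch vs scipy's align_vectors on the same noisy coordinates."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            noisy = gre.model(0)
            noisy.set_coords(noisy.coords() + rng.normal(0, 0.3,
                                                         (gre.n_atoms, 3)))
            amap = ct.dna_atom_map(gre, noisy, ["A", "B"])
            res = ct.superpose(gre, noisy, amap)
            ref = gre.coords()
            mov = noisy.coords()
            rot, rssd = Rotation.align_vectors(ref - ref.mean(0),
                                               mov - mov.mean(0))
            rmsd_scipy = rssd / np.sqrt(len(ref))
            assert res.rmsd == pytest.approx(rmsd_scipy, rel=1e-6)

    def test_methyl_carbon_dropped_from_cross_methylation_map(self, gre, smgre):
        amap = ct.dna_atom_map(gre, smgre, ["A", "B"])
        names = {sel_ref.atom for sel_ref, _ in amap}
        assert "C5M" not in names
        res = ct.superpose(gre, smgre, amap)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)  # same ideal geometry

    def test_degenerate_map_errors(self, gre):
        amap = ct.dna_atom_map(gre, gre, ["A"])[:2]
        with pytest.raises(ValueError):
            ct.superpose(gre, gre, amap)
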