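import numpy as np
import pytest

from hydramem import detect_hbonds, hb_balance
from hydramem.constants import DEFAULT_CONSTANTS, Constants
from hydramem.frame import AtomRecord, Frame, FrameError
from hydramem.hbonds import HBBalance, HBRecord, bridging_hbonds, delta_hb_curve
from hydramem.synth import LamellarSpec, gen_bulk_water_frame, gen_lamellar_frame

from oracles import brute_force_hbonds


def donor_acceptor_frame(r_da, angle_deg, box=10.0):
    """Minimal two-molecule frame with one candidate D-H...A triple."""
    d = np.array([2.0, 2.0, 2.0])
    a = d + np.array([r_da, 0.0, 0.0])
    ang = np.deg2rad(angle_deg)
    h = d + 0.1 * np.array([np.cos(ang), np.sin(ang), 0.0])
    atoms = [
        AtomRecord(1, "OW", "SOL", "water", hb_role={"donor"}),
        AtomRecord(1, "HW1", "SOL", "water", hb_role={"hydrogen"}, bonded_heavy=0),
        AtomRecord(2, "OW", "SOL", "water", hb_role={"acceptor"}),
    ]
    return Frame(np.array([d, h, a]), np.full(3, box), atoms)


class TestCriterionBoundary:
    def test_inside_both_cutoffs(self):
        assert len(detect_hbonds(donor_acceptor_frame(0.30, 10.0))) == 1

    def test_distance_just_inside_and_outside(self):
        assert len(detect_hbonds(donor_acceptor_frame(0.3499, 0.0))) == 1
        assert len(detect_hbonds(donor_acceptor_frame(0.3501, 0.0))) == 0

    def test_distance_exactly_at_cutoff_is_not_a_bond(self):
        d = np.array([0.0, 0.0, 0.0])
        a = np.array([np.float64(0.35), 0.0, 0.0])
        h = np.array([0.1, 0.0, 0.0])
        atoms = [
            AtomRecord(1, "OW", "SOL", "water", hb_role={"donor"}),
            AtomRecord(1, "HW1", "SOL", "water", hb_role={"hydrogen"}, bonded_heavy=0),
            AtomRecord(2, "OW", "SOL", "water", hb_role={"acceptor"}),
        ]
        frame = Frame(np.array([d, h, a]), np.full(3, 10.0), atoms)
        assert detect_hbonds(frame) == []

    def test_angle_just_inside_and_outside(self):
        assert len(detect_hbonds(donor_acceptor_frame(0.30, 29.99))) == 1
        assert len(detect_hbonds(donor_acceptor_frame(0.30, 30.01))) == 0

    def test_bond_across_periodic_boundary(self):
        d = np.array([0.05, 5.0, 5.0])
        a = np.array([9.80, 5.0, 5.0])  # 0.25 nm through the wrap
        h = d - np.array([0.1, 0.0, 0.0])
        atoms = [
            AtomRecord(1, "OW", "SOL", "water", hb_role={"donor"}),
            AtomRecord(1, "HW1", "SOL", "water", hb_role={"hydrogen"}, bonded_heavy=0),
            AtomRecord(2, "OW", "SOL", "water", hb_role={"acceptor"}),
        ]
        frame = Frame(np.array([d, h, a]), np.full(3, 10.0), atoms)
        records = detect_hbonds(frame)
        assert len(records) == 1
        assert records[0].r_da == pytest.approx(0.25, abs=1e-12)

    def test_same_molecule_excluded(self):
        frame = donor_acceptor_frame(0.30, 10.0)
        frame.atoms[2].molecule_id = 1
        assert detect_hbonds(frame) == []

    def test_custom_constants(self):
        frame = donor_acceptor_frame(0.40, 10.0)
        assert detect_hbonds(frame) == []
        wide = Constants(r_hb=0.45, theta_hb=30.0)
        assert len(detect_hbonds(frame, wide)) == 1

    def test_unannotated_frame_raises(self):
        frame = Frame(np.zeros((1, 3)), np.ones(3), [AtomRecord(1, "X")])
        with pytest.raises(FrameError, match="annotation"):
            detect_hbonds(frame)


class TestClasses:
    def test_classes_and_subtags(self):
        spec = LamellarSpec(
            n_lipids_per_leaflet=9,
            n_w=6.0,
            planted_hb=[("ll", 2), ("lw", 4), ("ww", 3)],
            seed=21,
        )
        frame, truth = gen_lamellar_frame(spec)
        records = detect_hbonds(frame)
        by_class = {}
        for r in records:
            by_class.setdefault(r.hb_class, []).append(r)
        assert {k: len(v) for k, v in by_class.items()} == truth.counts()
        subtags = sorted(r.subtag for r in by_class["lw"])
        want = sorted(b.subtag for b in truth.bonds if b.hb_class == "lw")
        assert subtags == want

    def test_one_donor_two_acceptors(self):
        d = np.array([5.0, 5.0, 5.0])
        h = d + np.array([0.1, 0.0, 0.0])
        a1 = d + np.array([0.30, 0.0, 0.0])
        a2 = d + np.array([0.30 * np.cos(0.3), 0.30 * np.sin(0.3), 0.0])
        atoms = [
            AtomRecord(1, "OW", "SOL", "water", hb_role={"donor"}),
            AtomRecord(1, "HW1", "SOL", "water", hb_role={"hydrogen"}, bonded_heavy=0),
            AtomRecord(2, "OW", "SOL", "water", hb_role={"acceptor"}),
            AtomRecord(3, "OW", "SOL", "water", hb_role={"acceptor"}),
        ]
        frame = Frame(np.array([d, h, a1, a2]), np.full(3, 10.0), atoms)
        records = detect_hbonds(frame)
        assert {r.acceptor_atom for r in records} == {2, 3}
        assert all(r.hydrogen == 1 for r in records)


class TestOracleEquivalence:
    def test_matches_brute_force_on_lamellar_frames(self):
        for seed in range(8):
            spec = LamellarSpec(
                n_lipids_per_leaflet=4,
                n_w=4.0,
                n_oh=2,
                planted_hb=[("ll", 1), ("lw", 1), ("ww", 1)],
                seed=seed,
            )
            frame, _ = gen_lamellar_frame(spec)
            got = {(r.donor_atom, r.hydrogen, r.acceptor_atom) for r in detect_hbonds(frame)}
            assert got == brute_force_hbonds(frame)

    def test_matches_brute_force_on_dense_water(self):
        for seed in range(4):
            frame = gen_bulk_water_frame(33.4, 1.5, seed=seed)
            got = {(r.donor_atom, r.hydrogen, r.acceptor_atom) for r in detect_hbonds(frame)}
            want = brute_force_hbonds(frame)
            assert got == want
            assert len(want) > 0  # dense packing must produce some bonds


class TestBalance:
    def test_identity_and_bulk_subtraction(self):
        records = [
            HBRecord(0, 1, 2, 0.3, 10.0, "ll"),
            HBRecord(3, 4, 5, 0.3, 10.0, "lw", "lipid_donor"),
            HBRecord(6, 7, 8, 0.3, 10.0, "ww"),
            HBRecord(9, 10, 11, 0.3, 10.0, "ww"),
        ]
        bal = hb_balance(records, n_lipids=2, n_w=3.0, d_w=1.0)
        assert bal.n_ll == 0.5
        assert bal.n_lw == 0.5
        assert bal.n_ww_raw == 1.0
        assert bal.n_ww_excess == pytest.approx(1.0 - 3.0 * DEFAULT_CONSTANTS.hb_bulk)
        assert bal.n_tot == pytest.approx(bal.n_ll + bal.n_lw + bal.n_ww_excess)

    def test_validation(self):
        with pytest.raises(ValueError):
            hb_balance([], n_lipids=0, n_w=1.0)
        with pytest.raises(ValueError):
            hb_balance([], n_lipids=2, n_w=-1.0)
        with pytest.raises(ValueError, match="identity"):
            HBBalance(1.0, 1.0, 1.0, 0.0, 5.0, 1.0, 1.0)


class TestBridging:
    def make_frame(self):
        atoms = [
            AtomRecord(1, "O1", "HGL", "lipid", leaflet="upper", hb_role={"donor", "acceptor"}),
            AtomRecord(2, "O1", "HGL", "lipid", leaflet="upper", hb_role={"donor", "acceptor"}),
            AtomRecord(3, "O1", "HGL", "lipid", leaflet="lower", hb_role={"donor", "acceptor"}),
        ]
        for m in (4, 5):
            atoms.append(AtomRecord(m, "OW", "SOL", "water", hb_role={"donor", "acceptor"}))
            atoms.append(
                AtomRecord(m, "HW1", "SOL", "water", hb_role={"hydrogen"}, bonded_heavy=len(atoms) - 1)
            )
        return Frame(np.zeros((7, 3)), np.full(3, 10.0), atoms)

    def test_same_leaflet_bridge_counted(self):
        frame = self.make_frame()
        # water 4 (atoms 3,4) donates to lipids 1 and 2 (same leaflet)
        records = [
            HBRecord(3, 4, 0, 0.3, 5.0, "lw", "water_donor"),
            HBRecord(3, 4, 1, 0.3, 5.0, "lw", "water_donor"),
        ]
        bridges = bridging_hbonds(records, frame)
        assert bridges == {1: 1, 2: 1, 3: 0}

    def test_cross_leaflet_not_a_bridge(self):
        frame = self.make_frame()
        # water 5 (atoms 5,6) links lipid 1 (upper) and lipid 3 (lower)
        records = [
            HBRecord(5, 6, 0, 0.3, 5.0, "lw", "water_donor"),
            HBRecord(5, 6, 2, 0.3, 5.0, "lw", "water_donor"),
        ]
        assert bridging_hbonds(records, frame) == {1: 0, 2: 0, 3: 0}

    def test_water_counted_once_per_headgroup(self):
        frame = self.make_frame()
        # water bonded twice to lipid 1 (donating and accepting) and once to 2
        records = [
            HBRecord(3, 4, 0, 0.3, 5.0, "lw", "water_donor"),
            HBRecord(0, 4, 3, 0.3, 5.0, "lw", "lipid_donor"),
            HBRecord(3, 4, 1, 0.3, 5.0, "lw", "water_donor"),
        ]
        assert bridging_hbonds(records, frame) == {1: 1, 2: 1, 3: 0}


class TestDeltaCurve:
    def balances(self, n_tots, d_ws):
        out = []
        for n_tot, d_w in zip(n_tots, d_ws):
            out.append(HBBalance(n_tot, 0.0, 0.0, 0.0, n_tot, 1.0, d_w))
        return out

    def test_reference_largest_dw(self):
        curve = delta_hb_curve(self.balances([3.0, 1.0, 2.0], [0.5, 1.5, 1.0]))
        assert np.array_equal(curve.x, [0.5, 1.0, 1.5])
        assert np.allclose(curve.y, [2.0, 1.0, 0.0])

    def test_explicit_reference(self):
        curve = delta_hb_curve(self.balances([3.0, 1.0], [0.5, 1.5]), reference=0.5)
        assert np.allclose(curve.y, [2.5, 0.5])

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            delta_hb_curve(self.balances([1.0, 2.0], [0.5, 0.5]))
        with pytest.raises(ValueError, match="two"):
            delta_hb_curve(self.balances([1.0], [0.5]))
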