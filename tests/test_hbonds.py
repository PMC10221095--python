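"""H-bond detection, occupancy statistics and force-response typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rampclamp import hbonds
from rampclamp.errors import EmptyInputError, ModeError, RampClampError
from rampclamp.structures import Atom, Structure, Trajectory
from rampclamp.synthetic import (
    InterfaceSpec,
    WT_INTERFACE_PAIRS,
    build_complex,
    jitter_trajectory,
)


def brute_force_detect(X, donors, acceptors, d_cut=3.5, ang_cut=30.0):
    """Exhaustive O(N²) enumeration with independent criterion math."""
    found = set()
    for (d, h) in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            if np.sqrt(np.sum((X[d] - X[a]) ** 2)) > d_cut:
                continue
            u = X[d] - X[h]
            v = X[a] - X[h]
            cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if 180.0 - ang <= ang_cut:
                found.add((d, a))
    return found


def _random_frame(seed, n_donors=5, n_acceptors=8):
    """A random frame with explicit hydrogens near each donor."""
    rng = np.random.default_rng(seed)
    atoms = []
    donors = []
    serial = 1
    for i in range(n_donors):
        xn = rng.uniform(0, 12, 3)
        xh = xn + rng.normal(scale=0.4, size=3)
        xh = xn + (xh - xn) / np.linalg.norm(xh - xn)  # N–H at 1.0 Å
        atoms.append(Atom(serial, f"N{i}", "N", "XXX", i + 1, "A", xn))
        nd = len(atoms) - 1
        serial += 1
        atoms.append(Atom(serial, f"H{i}", "H", "XXX", i + 1, "A", xh))
        donors.append((nd, len(atoms) - 1))
        serial += 1
    acceptors = []
    for i in range(n_acceptors):
        atoms.append(Atom(serial, f"O{i}", "O", "YYY", 100 + i, "B",
                          rng.uniform(0, 12, 3)))
        acceptors.append(len(atoms) - 1)
        serial += 1
    return Structure(atoms), donors, acceptors


class TestDetection:
    def _bond_geometry(self, d_a, deviation_deg):
        xd = np.array([0.0, 0.0, 0.0])
        xa = np.array([0.0, 0.0, d_a])
        phi = np.radians(deviation_deg)
        # place H so the D–H···A deviation is approximately as requested
        xh = xd + np.array([np.sin(phi) * 0.6, 0.0, np.cos(phi)])
        atoms = [
            Atom(1, "N", "N", "ASN", 1, "A", xd),
            Atom(2, "H", "H", "ASN", 1, "A", xh),
            Atom(3, "O", "O", "GLU", 2, "B", xa),
        ]
        return Structure(atoms)

    def test_inside_both_cutoffs(self):
        s = self._bond_geometry(3.4, 10.0)
        out = hbonds.detect_frame(s, [(0, 1)], [2])
        assert len(out) == 1
        (t,) = out
        assert (t.donor, t.acceptor) == (0, 2)

    def test_distance_fail(self):
        s = self._bond_geometry(3.6, 0.0)
        assert hbonds.detect_frame(s, [(0, 1)], [2]) == set()

    def test_angle_fail(self):
        s = self._bond_geometry(3.0, 55.0)
        assert hbonds.detect_frame(s, [(0, 1)], [2]) == set()

    def test_distance_only_fallback(self):
        s = self._bond_geometry(3.0, 55.0)
        out = hbonds.detect_frame(s, [(0, None)], [2], distance_only=True)
        assert len(out) == 1

    def test_angle_mode_without_hydrogens_errors(self):
        s = self._bond_geometry(3.0, 0.0)
        with pytest.raises(ModeError):
            hbonds.detect_frame(s, [(0, None)], [2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_enumeration(self, seed):
        s, donors, acceptors = _random_frame(seed)
        ours = {(t.donor, t.acceptor)
                for t in hbonds.detect_frame(s, donors, acceptors)}
        assert ours == brute_force_detect(s.coords, donors, acceptors)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_trajectory_detection_equals_per_frame(self, seed):
        s, donors, acceptors = _random_frame(seed)
        rng = np.random.default_rng(seed + 50)
        coords = s.coords[None] + rng.normal(scale=0.8, size=(6,) + s.coords.shape)
        traj = Trajectory(s, coords)
        fast = hbonds.detect_trajectory(traj, donors, acceptors)
        for f in range(6):
            slow = hbonds.detect_frame(coords[f], donors, acceptors,
                                       atom_table=s)
            assert {(t.donor, t.acceptor) for t in fast[f]} == \
                   {(t.donor, t.acceptor) for t in slow}


class TestInterfacialFilter:
    def test_intra_chain_dropped(self, wt_complex, wt_spec):
        cplx, _ = wt_complex
        bonds = hbonds.detect_frame(cplx, hbonds.find_donors(cplx),
                                    hbonds.find_acceptors(cplx))
        inter = hbonds.interfacial_filter(bonds, {"A"}, {"B"})
        assert len(bonds) == wt_spec.n_bonds + 1     # one intra-chain decoy
        assert len(inter) == wt_spec.n_bonds
        for t in inter:
            assert {t.donor_res[0], t.acceptor_res[0]} == {"A", "B"}

    def test_both_directions_kept(self):
        atoms = [
            Atom(1, "N", "N", "ASN", 1, "A", [0, 0, 0]),
            Atom(2, "H", "H", "ASN", 1, "A", [0, 0, 1]),
            Atom(3, "O", "O", "GLU", 2, "B", [0, 0, 2.9]),
            Atom(4, "N", "N", "ASN", 3, "B", [20, 0, 0]),
            Atom(5, "H", "H", "ASN", 3, "B", [20, 0, 1]),
            Atom(6, "O", "O", "GLU", 4, "A", [20, 0, 2.9]),
        ]
        s = Structure(atoms)
        bonds = hbonds.detect_frame(s, [(0, 1), (3, 4)], [2, 5])
        inter = hbonds.interfacial_filter(bonds, {"A"}, {"B"})
        assert len(inter) == 2


class TestNhbAndOccupancy:
    def test_persistent_bonds_constant(self, wt_complex):
        cplx, gt = wt_complex
        spec = InterfaceSpec(pairs=[(p[0], p[1], 1.0)
                                    for p in WT_INTERFACE_PAIRS[:5]])
        c5, gt5 = build_complex(spec, seed=0)
        traj, _ = jitter_trajectory(c5, gt5, spec, n_frames=20, seed=1)
        fb = hbonds.detect_trajectory(traj, hbonds.find_donors(c5),
                                      hbonds.find_acceptors(c5))
        inter = hbonds.interfacial_filter(fb, {"A"}, {"B"})
        assert np.all(hbonds.nhb_series(inter) == 5)

    def test_empty_interface_zero(self):
        assert np.array_equal(hbonds.nhb_series([set(), set()]), [0, 0])

    def test_mean_recovers_generator_expectation(self, wt_spec, wt_complex):
        cplx, gt = wt_complex
        traj, truth = jitter_trajectory(cplx, gt, wt_spec, n_frames=2000,
                                        seed=5)
        fb = hbonds.detect_trajectory(traj, hbonds.find_donors(cplx),
                                      hbonds.find_acceptors(cplx))
        inter = hbonds.interfacial_filter(fb, {"A"}, {"B"})
        nhb = hbonds.nhb_series(inter)
        expected = wt_spec.occupancies.sum()
        # per-frame count variance = Σ p(1−p) for independent bonds
        se = np.sqrt(np.sum(wt_spec.occupancies
                            * (1 - wt_spec.occupancies)) / 2000)
        assert abs(nhb.mean() - expected) <= 3 * se

    def test_occupancy_fraction(self):
        frames = []
        t = hbonds.HBondTriplet(0, 1, 2, ("A", "GLU", 1), ("B", "LYS", 2))
        for i in range(50):
            frames.append({t} if i < 26 else set())
        key = hbonds.pair_key_of(t, {"A"})
        assert hbonds.occupancy(frames, key, {"A"}) == pytest.approx(0.52)

    def test_occupancy_extremes(self):
        t = hbonds.HBondTriplet(0, 1, 2, ("A", "GLU", 1), ("B", "LYS", 2))
        key = hbonds.pair_key_of(t, {"A"})
        assert hbonds.occupancy([set()] * 10, key, {"A"}) == 0.0
        assert hbonds.occupancy([{t}] * 10, key, {"A"}) == 1.0

    def test_residue_pair_union_of_triplets(self):
        # two distinct atom triplets of one residue pair: per-frame union
        t1 = hbonds.HBondTriplet(0, 1, 2, ("A", "GLU", 1), ("B", "LYS", 2))
        t2 = hbonds.HBondTriplet(3, 4, 5, ("A", "GLU", 1), ("B", "LYS", 2))
        frames = [{t1}, {t2}, {t1, t2}, set()]
        key = hbonds.pair_key_of(t1, {"A"})
        assert hbonds.occupancy(frames, key, {"A"}) == pytest.approx(0.75)

    def test_markov_occupancy_within_effective_se(self):
        spec = InterfaceSpec(temporal_model="markov", p_stay=0.9)
        cplx, gt = build_complex(spec, seed=0)
        traj, truth = jitter_trajectory(cplx, gt, spec, n_frames=2000, seed=42)
        fb = hbonds.detect_trajectory(traj, hbonds.find_donors(cplx),
                                      hbonds.find_acceptors(cplx))
        inter = hbonds.interfacial_filter(fb, {"A"}, {"B"})
        occ = hbonds.occupancies(inter, {"A"})
        by_label = {f"{k[0][1]}{k[0][2]}-{k[1][1]}{k[1][2]}": v
                    for k, v in occ.items()}
        # the estimator reproduces the realised presence exactly ...
        for b, ((ra, sa), (rb, sb), target) in enumerate(spec.pairs):
            est = by_label.get(f"{ra}{sa}-{rb}{sb}", 0.0)
            assert est == pytest.approx(truth.realized_occupancy[b], abs=1e-12)
        # ... and the strong GLU35–ARG69 bond (0.82) is recovered within
        # 3 SEs of the Markov-effective sample size
        n_eff = 2000 * (1 - 0.9) / (1 + 0.9)
        se = np.sqrt(0.82 * 0.18 / n_eff)
        assert abs(by_label["GLU35-ARG69"] - 0.82) <= 3 * se

    def test_empty_frames_error(self):
        with pytest.raises(EmptyInputError):
            hbonds.occupancies([], {"A"})


class TestDissociation:
    def test_independence_single_bond(self):
        est = hbonds.dissociation_probability([0.7])
        assert est.probability == pytest.approx(0.3)

    def test_independence_two_bonds(self):
        est = hbonds.dissociation_probability([0.5, 0.5])
        assert est.probability == pytest.approx(0.25)

    def test_independence_bounds_and_monotonicity(self):
        occ = [0.2, 0.5, 0.8]
        p = hbonds.dissociation_probability(occ).probability
        assert p <= min(1 - o for o in occ)
        p2 = hbonds.dissociation_probability([0.3, 0.5, 0.8]).probability
        assert p2 < p

    def test_empirical_matches_independence_on_iid_generator(self):
        rng = np.random.default_rng(9)
        occ = np.array([0.3, 0.4, 0.5])
        n = 4000
        pres = rng.random((n, 3)) < occ
        nhb = pres.sum(axis=1)
        emp = hbonds.dissociation_probability(
            nhb_per_frame=nhb, method="empirical_all_broken")
        exact = np.prod(1 - occ)
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(emp.probability - exact) <= 3 * se

    def test_rule_of_three_upper_bound(self):
        est = hbonds.dissociation_probability(
            nhb_per_frame=np.ones(600), method="empirical_all_broken")
        assert est.probability == 0.0
        assert est.upper_bound_95 == pytest.approx(3 / 600)

    def test_empty_inputs_error(self):
        with pytest.raises(EmptyInputError):
            hbonds.dissociation_probability([])
        with pytest.raises(EmptyInputError):
            hbonds.dissociation_probability(nhb_per_frame=[],
                                            method="empirical_all_broken")


class TestForceTyping:
    def _runs(self, pairs_vals):
        key = lambda i: (("A", "GLU", i), ("B", "LYS", i))
        return {key(i): vals for i, vals in enumerate(pairs_vals)}

    def test_delta_rule(self):
        static = self._runs([[0.50, 0.50], [0.80, 0.80], [0.66, 0.66]])
        force = self._runs([[0.80, 0.80], [0.50, 0.50], [0.65, 0.65]])
        calls = hbonds.classify_force_response(static, force, test=None)
        assert [c.bond_type for c in calls] == ["II", "III", "I"]

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(3)
        static = self._runs([list(rng.uniform(0, 1, 3)) for _ in range(8)])
        force = self._runs([list(rng.uniform(0, 1, 3)) for _ in range(8)])
        fwd = hbonds.classify_force_response(static, force, test=None)
        rev = hbonds.classify_force_response(force, static, test=None)
        swap = {"II": "III", "III": "II", "I": "I"}
        assert [swap[c.bond_type] for c in fwd] == [c.bond_type for c in rev]

    def test_welch_gate_demotes_noisy_changes(self):
        static = self._runs([[0.4, 0.9, 0.2]])   # huge replicate scatter
        force = self._runs([[0.6, 0.3, 0.95]])
        calls = hbonds.classify_force_response(static, force, test="welch")
        assert calls[0].bond_type == "I"
        assert calls[0].p_value > 0.05

    def test_mismatched_keys_error(self):
        static = self._runs([[0.5, 0.5]])
        force = {(("A", "GLU", 99), ("B", "LYS", 99)): [0.5, 0.5]}
        with pytest.raises(KeyError):
            hbonds.classify_force_response(static, force)
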