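"""Native-contact extraction and soft-cutoff fractions vs independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressmap.contacts import (ContactParams, ContactSet,
                                build_reference_contacts, contact_series,
                                count_total_contacts, residue_fraction,
                                soft_cut_fraction)
from stressmap.errors import DegenerateInputError, ShapeError
from stressmap.structure_io import DomainMap, Structure, Trajectory


def _structure_from_coords(coords, resseq, names=None):
    n = len(coords)
    return Structure(
        serials=np.arange(1, n + 1),
        names=np.array(names or ["CA"] * n, object),
        elements=np.array(["C"] * n, object),
        resseq=np.asarray(resseq),
        resnames=np.array(["ALA"] * n, object),
        chains=np.array(["A"] * n, object),
        coords=np.asarray(coords, float))


TWO_DOMAIN_MAP = DomainMap({"D1": (1, 5), "D2": (6, 10)},
                           {"D1-D2": ("D1", "D2")})


class TestBuildReferenceContacts:
    def test_interface_pair_below_cutoff(self):
        s = _structure_from_coords([[0, 0, 0], [4.4, 0, 0]], [1, 6])
        cs = build_reference_contacts(s, "D1-D2", TWO_DOMAIN_MAP)
        assert cs.n_pairs == 1
        assert cs.r0[0] == pytest.approx(4.4)

    def test_pair_above_cutoff_excluded(self):
        s = _structure_from_coords([[0, 0, 0], [4.6, 0, 0]], [1, 6])
        cs = build_reference_contacts(s, "D1-D2", TWO_DOMAIN_MAP)
        assert cs.n_pairs == 0

    def test_matches_brute_force_enumeration(self, rng):
        coords = rng.uniform(0, 8, (10, 3))
        resseq = np.arange(1, 11)
        s = _structure_from_coords(coords, resseq)
        dm = DomainMap({"D": (1, 10)})
        params = ContactParams()
        cs = build_reference_contacts(s, "D", dm, params)
        brute = set()
        for i in range(10):
            for j in range(i + 1, 10):
                d = np.linalg.norm(coords[i] - coords[j])
                if d <= params.ref_radius and abs(resseq[i] - resseq[j]) >= 3:
                    brute.add((i, j))
        assert set(zip(cs.i, cs.j)) == brute

    def test_sequence_separation_only_intra(self):
        # residues 1 and 2 close in space: excluded intra, kept cross-domain
        s = _structure_from_coords([[0, 0, 0], [3.0, 0, 0]], [1, 2])
        dm_intra = DomainMap({"D": (1, 5)})
        cs = build_reference_contacts(s, "D", dm_intra)
        assert cs.n_pairs == 0
        s2 = _structure_from_coords([[0, 0, 0], [3.0, 0, 0]], [5, 6])
        cs2 = build_reference_contacts(s2, "D1-D2", TWO_DOMAIN_MAP)
        assert cs2.n_pairs == 1


class TestSoftCutFraction:
    def test_reference_frame_is_nearly_one(self, toy_fab, domain_map):
        cs = build_reference_contacts(toy_fab, "CL", domain_map)
        assert soft_cut_fraction(toy_fab.coords, cs) > 0.999

    def test_logistic_midpoint_is_half(self):
        cs = ContactSet("toy", np.array([0]), np.array([1]),
                        np.array([2.0]), np.array([1]), np.array([5]))
        params = ContactParams()
        frame = np.array([[0.0, 0, 0], [params.lam * 2.0, 0, 0]])
        assert soft_cut_fraction(frame, cs, params) == pytest.approx(0.5)

    def test_single_pair_direct_formula_value(self):
        # r0 = 4 A stretched to 8 A: Q = 1/(1+exp(5*(8-7.2))) ~ 0.0180
        cs = ContactSet("toy", np.array([0]), np.array([1]),
                        np.array([4.0]), np.array([1]), np.array([5]))
        frame = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        q = soft_cut_fraction(frame, cs)
        assert q == pytest.approx(1.0 / (1.0 + np.exp(5.0 * 0.8)), rel=1e-9)
        assert q == pytest.approx(0.0180, abs=2e-4)

    def test_matches_mdanalysis_soft_cut_q(self, rng):
        """Independent oracle: MDAnalysis' soft-cut contact score."""
        from MDAnalysis.analysis.contacts import soft_cut_q
        r0 = rng.uniform(2.5, 4.5, 40)
        r = r0 * rng.uniform(0.8, 3.0, 40)
        cs = ContactSet("toy", np.arange(40), np.arange(40, 80), r0,
                        np.arange(40), np.arange(40, 80))
        frame = np.zeros((80, 3))
        frame[40:, 0] = r          # pair distances equal r
        params = ContactParams()
        mine = soft_cut_fraction(frame, cs, params)
        theirs = float(soft_cut_q(r, r0, beta=params.beta,
                                  lambda_constant=params.lam))
        assert mine == pytest.approx(theirs, rel=1e-9)

    def test_empty_contact_set_rejected(self):
        cs = ContactSet("toy", np.empty(0, int), np.empty(0, int),
                        np.empty(0), np.empty(0, int), np.empty(0, int))
        with pytest.raises(DegenerateInputError):
            soft_cut_fraction(np.zeros((2, 3)), cs)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(1.0, 3.0))
    def test_monotone_under_uniform_stretching(self, seed, scale):
        r = np.random.default_rng(seed)
        n = 15
        r0 = r.uniform(2.5, 4.5, n)
        frame = np.zeros((2 * n, 3))
        frame[n:, 0] = r0 * r.uniform(0.9, 1.5, n)
        cs = ContactSet("toy", np.arange(n), np.arange(n, 2 * n), r0,
                        np.arange(n), np.arange(n, 2 * n))
        stretched = frame.copy()
        stretched[n:, 0] *= scale
        assert soft_cut_fraction(stretched, cs) <= \
            soft_cut_fraction(frame, cs) + 1e-12


class TestContactSeries:
    def test_static_reference_trajectory_is_one(self, toy_fab, domain_map):
        cs = build_reference_contacts(toy_fab, "VL-VH", domain_map)
        frames = np.repeat(toy_fab.coords[None], 3, axis=0)
        traj = Trajectory(toy_fab, frames, frame_interval_ns=1.0)
        series = contact_series(traj, cs)
        assert np.all(series.q > 0.99)

    def test_half_pairs_stretched_matches_closed_form(self):
        """Move half the pairs to 3x their native distance: the final Q is
        the closed-form mixture of intact and stretched logistic scores."""
        n = 10
        r0 = np.full(n, 4.0)
        cs = ContactSet("toy", np.arange(n), np.arange(n, 2 * n), r0,
                        np.arange(n), np.arange(n, 2 * n))
        params = ContactParams()
        frame = np.zeros((2 * n, 3))
        frame[n:, 0] = r0
        frame[n + n // 2:, 0] = 3.0 * r0[n // 2:]
        intact = 1.0 / (1.0 + np.exp(params.beta * (4.0 - params.lam * 4.0)))
        stretched = 1.0 / (1.0 + np.exp(params.beta * (12.0 - params.lam * 4.0)))
        expected = 0.5 * (intact + stretched)
        assert soft_cut_fraction(frame, cs, params) == pytest.approx(expected)

    def test_topology_mismatch_raises(self, toy_fab):
        cs = ContactSet("toy", np.array([10 ** 6]), np.array([10 ** 6 + 1]),
                        np.array([3.0]), np.array([1]), np.array([2]))
        with pytest.raises(ShapeError):
            soft_cut_fraction(toy_fab.coords, cs)


class TestResidueFraction:
    def test_reference_frame_all_near_one(self, toy_fab, domain_map):
        cs = build_reference_contacts(toy_fab, "CL", domain_map)
        rf = residue_fraction(toy_fab.coords, cs)
        assert rf and all(v > 0.999 for v in rf.values())

    def test_only_stretched_residue_drops(self):
        # residues 1, 5, 9 in a line; stretch residue 9's pair only
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        cs = ContactSet("toy", np.array([0, 1]), np.array([1, 2]),
                        np.array([4.0, 4.0]), np.array([1, 5]),
                        np.array([5, 9]))
        frame = coords.copy()
        frame[2, 0] = 4.0 + 12.0       # pair (5,9) now at 3*r0
        rf = residue_fraction(frame, cs)
        assert rf[1] > 0.999
        assert rf[9] < 0.02
        assert 0.4 < rf[5] < 0.6       # mean of one intact, one broken pair

    def test_difference_map_bounded(self, toy_fab, domain_map, low_ph_runs,
                                    reference_runs):
        cs = build_reference_contacts(toy_fab, "CL", domain_map)
        stress = residue_fraction(low_ph_runs[0][0].frames[-1], cs)
        ref = residue_fraction(reference_runs[0][0].frames[-1], cs)
        deltas = [stress[r] - ref[r] for r in stress]
        assert all(-1.0 <= d <= 1.0 for d in deltas)


class TestTotalContacts:
    def test_distant_sets_have_zero(self):
        frame = np.vstack([np.zeros((3, 3)), np.zeros((3, 3)) + 10.0])
        assert count_total_contacts(frame, (np.arange(3), np.arange(3, 6))) == 0

    def test_constructed_count_matches_brute_force(self, rng):
        frame = rng.uniform(0, 10, (12, 3))
        a, b = np.arange(6), np.arange(6, 12)
        brute = sum(1 for i in a for j in b
                    if np.linalg.norm(frame[i] - frame[j]) <= 6.0)
        assert count_total_contacts(frame, (a, b)) == brute
        assert brute > 0

    def test_symmetric_in_the_two_sets(self, rng):
        frame = rng.uniform(0, 8, (10, 3))
        a, b = np.arange(5), np.arange(5, 10)
        assert count_total_contacts(frame, (a, b)) == \
            count_total_contacts(frame, (b, a))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ShapeError):
            count_total_contacts(np.zeros((4, 3)),
                                 (np.array([0, 1]), np.array([1, 2])))
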