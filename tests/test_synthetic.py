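"""Generator contracts: geometry, determinism, designed ground truth."""

import dataclasses

import numpy as np
import pytest

from stressmap.contacts import build_reference_contacts, contact_series
from stressmap.errors import ConfigError, DegenerateInputError
from stressmap.saltbridges import bridge_occurrence, detect_salt_bridges
from stressmap.secondary import assign_beta
from stressmap.superposition import domain_rmsd_series
from stressmap.synthetic import (StressProfile, ToyFabSpec, build_backbone,
                                 build_toy_fab, default_profiles,
                                 recover_exposure_fraction,
                                 simulate_stress_trajectory, toy_apr_set,
                                 toy_domain_map, toy_strand_map)


class TestBuildBackbone:
    def test_ca_ca_distance_is_virtual_bond(self):
        s = build_backbone(12)
        ca = s.coords[np.asarray(s.names) == "CA"]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        np.testing.assert_allclose(d, 3.80, atol=0.05)

    def test_two_residues_is_valid(self):
        s = build_backbone(2)
        assert s.n_atoms == 8
        names = np.asarray(s.names)
        c0 = s.coords[names == "C"][0]
        n1 = s.coords[names == "N"][1]
        assert np.linalg.norm(c0 - n1) == pytest.approx(1.329, abs=1e-6)

    def test_paired_ideal_strands_assign_beta(self):
        """Cross-module oracle: the builder's geometry must satisfy the
        bridge rules of the independent assignment code."""
        from stressmap.synthetic import (_apply_pair_transform,
                                         _canonical_strand,
                                         _solve_pair_transform)
        from stressmap.structure_io import Structure
        n = 10
        strand = _canonical_strand(n)
        partner = _apply_pair_transform(strand.coords, _solve_pair_transform(n))
        s = Structure(np.arange(1, 2 * strand.n_atoms + 1),
                      np.concatenate([strand.names] * 2),
                      np.concatenate([strand.elements] * 2),
                      np.concatenate([strand.resseq, strand.resseq + n]),
                      np.concatenate([strand.resnames] * 2),
                      np.concatenate([strand.chains] * 2),
                      np.vstack([strand.coords, partner]))
        codes = assign_beta(s)
        interior = [r for r in range(3, n - 1)]
        assert all(codes[r] == "E" for r in interior)

    def test_non_finite_dihedral_rejected(self):
        with pytest.raises(ConfigError):
            build_backbone(3, [(np.nan, 135.0, 180.0)] * 3)


class TestBuildToyFab:
    def test_designed_bridges_exactly_detected(self, toy_fab, toy_spec):
        found = detect_salt_bridges(toy_fab.coords, toy_fab)
        designed = {(b.acid_res, b.base_res) for b in toy_spec.bridges}
        assert found == designed

    def test_no_bridges_spec_gives_empty_set(self):
        spec = ToyFabSpec(bridges=())
        s = build_toy_fab(spec)
        assert detect_salt_bridges(s.coords, s) == set()

    def test_domain_layout_consistent_with_maps(self, toy_fab, domain_map,
                                                strand_map):
        assert toy_fab.residue_ids.size == 96
        for label in strand_map.strands:
            assert strand_map.domain_of_strand(label) is not None

    def test_interfaces_have_native_contacts(self, toy_fab, domain_map):
        for iface in domain_map.interfaces:
            cs = build_reference_contacts(toy_fab, iface, domain_map)
            assert cs.n_pairs > 10


class TestSimulate:
    def test_zero_sigma_reference_is_static(self, toy_fab, toy_spec,
                                            domain_map):
        profile = StressProfile("reference", jitter_sigma=0.0,
                                bridge_occupancy={})
        trajs, _ = simulate_stress_trajectory(toy_fab, profile, n_frames=5,
                                              n_replicates=1, spec=toy_spec)
        np.testing.assert_allclose(trajs[0].frames,
                                   np.repeat(toy_fab.coords[None], 5, 0))
        ser = domain_rmsd_series(trajs[0], toy_fab, "CL", domain_map)
        np.testing.assert_allclose(ser.values, 0.0, atol=1e-12)

    def test_fixed_seed_is_bitwise_reproducible(self, toy_fab, toy_spec):
        profile = default_profiles(seed=123)["high_temp_like"]
        a, _ = simulate_stress_trajectory(toy_fab, profile, n_frames=4,
                                          n_replicates=2, spec=toy_spec)
        b, _ = simulate_stress_trajectory(toy_fab, profile, n_frames=4,
                                          n_replicates=2, spec=toy_spec)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.frames, tb.frames)

    def test_replicates_differ_but_derive_from_master_seed(self, toy_fab,
                                                           toy_spec):
        profile = default_profiles(seed=5)["reference"]
        trajs, _ = simulate_stress_trajectory(toy_fab, profile, n_frames=3,
                                              n_replicates=2, spec=toy_spec)
        assert not np.array_equal(trajs[0].frames, trajs[1].frames)

    def test_scheduled_occupancy_is_exact(self, toy_fab, toy_spec):
        profile = StressProfile("low_ph_like",
                                bridge_occupancy={"E30-K33": 0.4,
                                                  "E25-K6": 1.0,
                                                  "D28-R35": 1.0,
                                                  "D74-K81": 1.0})
        trajs, gt = simulate_stress_trajectory(toy_fab, profile, n_frames=20,
                                               n_replicates=1, spec=toy_spec)
        occ = bridge_occurrence(trajs[0])
        assert occ[(30, 33)] == pytest.approx(40.0)
        assert gt["bridges"]["E30-K33"]["occupancy_pct"] == pytest.approx(40.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            StressProfile("boiling")

    def test_too_few_frames_rejected(self, toy_fab, toy_spec):
        with pytest.raises(DegenerateInputError):
            simulate_stress_trajectory(toy_fab, default_profiles()["reference"],
                                       n_frames=1, n_replicates=1,
                                       spec=toy_spec)


class TestParameterRecovery:
    """The full-pipeline recovery properties over many seeds live in the
    acceptance suite; here two seeds guard the mechanics cheaply."""

    def test_low_ph_targets_cl_first(self, toy_fab, toy_spec, domain_map):
        for seed in (1, 2):
            profs = default_profiles(seed)
            ref, _ = simulate_stress_trajectory(toy_fab, profs["reference"],
                                                n_frames=11, n_replicates=1,
                                                spec=toy_spec)
            low, _ = simulate_stress_trajectory(toy_fab, profs["low_ph_like"],
                                                n_frames=11, n_replicates=1,
                                                spec=toy_spec)
            deltas = {}
            for dom in domain_map.domains:
                ms = domain_rmsd_series(low[0], toy_fab, dom, domain_map).values[-1]
                mr = domain_rmsd_series(ref[0], toy_fab, dom, domain_map).values[-1]
                deltas[dom] = ms - mr
            assert max(deltas, key=deltas.get) == "CL"

    def test_high_temp_interface_loss_dominates(self, toy_fab, toy_spec,
                                                domain_map):
        profs = default_profiles(3)
        ref, _ = simulate_stress_trajectory(toy_fab, profs["reference"],
                                            n_frames=11, n_replicates=1,
                                            spec=toy_spec)
        hot, gt = simulate_stress_trajectory(toy_fab, profs["high_temp_like"],
                                             n_frames=11, n_replicates=1,
                                             spec=toy_spec)
        dq = {}
        for region in list(domain_map.domains) + list(domain_map.interfaces):
            cs = build_reference_contacts(toy_fab, region, domain_map)
            dq[region] = (contact_series(hot[0], cs).q[-1]
                          - contact_series(ref[0], cs).q[-1])
        worst_domain = min(dq[d] for d in domain_map.domains)
        for iface in domain_map.interfaces:
            assert dq[iface] < worst_domain
        # the noiseless final-frame Q prediction brackets the jittered one
        for iface, q_pred in gt["separation"]["predicted_final_q"].items():
            assert q_pred < 0.05

    def test_apr_schedule_recovered_within_5_points(self, toy_fab, toy_spec):
        from stressmap.surface import apr_sasa_change
        profs = default_profiles(9)
        ref, _ = simulate_stress_trajectory(toy_fab, profs["reference"],
                                            n_frames=11, n_replicates=1,
                                            spec=toy_spec)
        low, gt = simulate_stress_trajectory(toy_fab, profs["low_ph_like"],
                                             n_frames=11, n_replicates=1,
                                             spec=toy_spec)
        df = apr_sasa_change(low, ref, toy_apr_set(toy_spec)).set_index("apr")
        info = gt["apr_exposure"]["CL_core"]
        implied = recover_exposure_fraction(
            float(df.loc["CL_core", "change_pct"]),
            info["sasa_buried"], info["sasa_exposed"])
        assert implied * 100 == pytest.approx(
            info["exposed_fraction"] * 100, abs=5.0)
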