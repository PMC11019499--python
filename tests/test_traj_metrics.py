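"""Trajectory observables: oracle checks, conservation laws, bounds, and
planted-parameter recovery."""

import cmath

import numpy as np
import pytest

from lamella.core_io import CGFrame, StructureFactorSettings, ValidationError
from lamella.synthetic import (
    LamellarSpec,
    generate_lamellar_config,
    generate_lamellar_trajectory,
    planted_flip_mol_ids,
)
from lamella.traj_metrics import (
    assign_leaflets,
    bilayer_metrics,
    chain_angle_distribution,
    d_pp,
    density_profile,
    detect_flipflops,
    ethanol_penetration,
    harmonic_q_grid,
    molecular_area,
    segmental_order,
    structure_factor,
)


def _solvent_frame(z, box, bead="WAT"):
    """Minimal frame of solvent beads at given z positions."""
    n = len(z)
    pos = np.column_stack([np.full(n, 0.5), np.full(n, 0.5), np.asarray(z, float)])
    return CGFrame(
        positions=pos,
        bead_names=np.array([bead] * n, dtype=object),
        mol_ids=np.arange(1, n + 1),
        resnames=np.array([bead if bead in ("WAT", "ETNL") else "WAT"] * n, dtype=object),
        box=np.asarray(box, float),
    )


class TestStructureFactor:
    def test_single_bead_intensity_is_flat(self):
        frame = _solvent_frame([1.234], box=[1, 1, 2 * np.pi])
        res = structure_factor([frame])
        np.testing.assert_allclose(res.intensity_normalized, 1.0, rtol=1e-12)

    def test_two_beads_destructive_interference(self):
        # dz = pi kills q = 1 exactly
        frame = _solvent_frame([0.0, np.pi], box=[1, 1, 2 * np.pi])
        res = structure_factor([frame])
        q1_idx = np.argmin(np.abs(res.q - 1.0))
        assert res.intensity[q1_idx] == pytest.approx(0.0, abs=1e-20)

    def test_zero_q_equals_total_scattering(self, sys1_frame):
        res = structure_factor([sys1_frame])
        assert res.intensity[0] == pytest.approx(sys1_frame.n_beads**2, rel=1e-12)

    def test_off_grid_q_rejected(self, sys1_frame):
        with pytest.raises(ValidationError, match="2\\*pi/Lz"):
            structure_factor([sys1_frame], q=np.array([1.0]))

    def test_brute_force_oracle_equivalence(self):
        spec = LamellarSpec(n_bilayers=1, lipids_per_leaflet=8, seed=13)
        frame = generate_lamellar_config(spec)
        assert frame.n_beads <= 1000
        res = structure_factor([frame])
        # independent oracle: plain python complex sum
        for qi, expected in zip(res.q, res.intensity):
            F = sum(cmath.exp(1j * qi * z) for z in frame.positions[:, 2])
            assert abs(abs(F) ** 2 - expected) <= 1e-10 * max(expected, 1.0)

    def test_scattering_factors_and_polarization_applied(self):
        frame = _solvent_frame([0.3, 0.7], box=[1, 1, 2 * np.pi])
        settings = StructureFactorSettings(
            polarization=0.5, scattering_factors={"WAT": 2.0}
        )
        res = structure_factor([frame], settings=settings)
        assert res.intensity[0] == pytest.approx(0.5 * (2.0 + 2.0) ** 2)

    def test_dominant_peak_is_first_bragg_order(self, sys1_frame):
        """d = 6.1 stack in an Lz = 18.3 box: the strongest non-zero-q
        harmonic is the lamellar fundamental at q = 2*pi/6.1 = 1.030."""
        res = structure_factor([sys1_frame])
        m_dom = int(np.argmax(res.intensity[1:]) + 1)
        assert res.q[m_dom] == pytest.approx(2 * np.pi / 6.1, rel=1e-6)
        # and every off-harmonic value is well below it
        off = [res.intensity[m] for m in range(1, len(res.q)) if m % 3]
        assert res.intensity[m_dom] > 5 * max(off)


class TestDensityProfile:
    def test_uniform_solvent_is_flat_within_poisson_bands(self):
        rng = np.random.default_rng(8)
        frame = _solvent_frame(rng.uniform(0, 12.0, 6000), box=[3, 3, 12.0])
        prof = density_profile([frame], ["WAT"], n_bins=20)
        counts = prof.densities["WAT"] * prof.bin_width * prof.box_area
        expected = 6000 / 20
        # 4 sigma: 20 bins are being compared simultaneously
        assert np.all(np.abs(counts - expected) <= 4 * np.sqrt(expected))

    def test_integral_reproduces_bead_counts(self, sys1_frame):
        prof = density_profile([sys1_frame], ["PH", "WAT", "POPC"], n_bins=60)
        for key, want in (
            ("PH", sys1_frame.n_lipids),
            ("WAT", int(np.sum(sys1_frame.bead_names == "WAT"))),
            ("POPC", int(np.sum(sys1_frame.resnames == "POPC"))),
        ):
            assert prof.counts(key) == pytest.approx(want, abs=0.5)

    def test_no_ethanol_gives_zero_etnl_density(self, sys1_frame):
        prof = density_profile([sys1_frame], ["ETNL"], n_bins=30)
        assert np.all(prof.densities["ETNL"] == 0)

    def test_partitioned_ethanol_reaches_membrane_center(self):
        spec = LamellarSpec(
            n_bilayers=3, lipids_per_leaflet=50, area_per_lipid=0.926,
            d_pp=3.34, d_spacing=4.4, ethanol_vol_pct=57.0,
            membrane_partition=0.35, seed=17,
        )
        frame = generate_lamellar_config(spec)
        prof = density_profile([frame], ["ETNL"], n_bins=66)
        rec = assign_leaflets(frame)
        near_mid = np.min(
            np.abs(prof.z[:, None] - rec.midplanes[None, :]), axis=1
        ) < 0.3
        assert np.all(prof.densities["ETNL"][near_mid] > 0)

    def test_empty_selection_rejected(self, sys1_frame):
        with pytest.raises(ValidationError, match="empty"):
            density_profile([sys1_frame], [])


class TestMolecularArea:
    def test_arithmetic(self):
        frame = generate_lamellar_config(
            LamellarSpec(n_bilayers=1, lipids_per_leaflet=50,
                         area_per_lipid=0.72, seed=1)
        )
        assert molecular_area(frame) == pytest.approx(0.72)
        assert frame.box[0] == pytest.approx(6.0)

    def test_planted_area_recovered_exactly(self):
        frame = generate_lamellar_config(
            LamellarSpec(n_bilayers=3, lipids_per_leaflet=40,
                         area_per_lipid=0.851, d_pp=3.42, d_spacing=4.7, seed=2)
        )
        assert molecular_area(frame) == pytest.approx(0.851, rel=1e-12)

    def test_invariant_under_joint_doubling(self, sys1_frame):
        a = molecular_area(sys1_frame)
        doubled = generate_lamellar_config(
            LamellarSpec(n_bilayers=3, lipids_per_leaflet=100, seed=11)
        )
        assert molecular_area(doubled) == pytest.approx(a, rel=1e-12)


class TestLeafletsAndDpp:
    def test_ideal_stack_six_planes_even_split(self, sys1_frame):
        rec = assign_leaflets(sys1_frame)
        for b in range(3):
            for leaf in ("upper", "lower"):
                assert np.sum((rec.bilayer == b) & (rec.leaflet == leaf)) == 50

    def test_planted_flip_assigned_to_opposite_leaflet(self):
        spec = LamellarSpec(n_bilayers=3, lipids_per_leaflet=50, n_flipflops=3, seed=3)
        frame = generate_lamellar_config(spec)
        rec = assign_leaflets(frame)
        for mol in planted_flip_mol_ids(spec):
            b, leaf = rec.label(mol)
            assert leaf == "upper"  # home cohort is the lower leaflet

    def test_assignment_stable_under_jitter(self):
        base = dict(n_bilayers=3, lipids_per_leaflet=50, seed=31)
        clean = assign_leaflets(generate_lamellar_config(LamellarSpec(jitter=0.0, **base)))
        noisy = assign_leaflets(generate_lamellar_config(LamellarSpec(jitter=0.05, **base)))
        np.testing.assert_array_equal(clean.bilayer, noisy.bilayer)
        np.testing.assert_array_equal(clean.leaflet, noisy.leaflet)

    def test_planted_dpp_recovered(self, sys1_frame):
        rec = assign_leaflets(sys1_frame)
        mean, sd, degenerate = d_pp([sys1_frame], [rec])
        assert not degenerate.any()
        # plane jitter 0.05 / sqrt(50) per leaflet
        np.testing.assert_allclose(mean, 3.85, atol=3 * 0.05 / np.sqrt(25))

    def test_wrong_bilayer_count_errors_with_diagnostics(self, sys1_frame):
        with pytest.raises(ValidationError, match="gap"):
            assign_leaflets(sys1_frame, n_bilayers=5)

    def test_bilayer_metrics_bundle(self, sys1_frame):
        metrics = bilayer_metrics([sys1_frame], n_bilayers=3)
        assert metrics.area == pytest.approx(0.647, rel=1e-12)
        assert metrics.d_pp.shape == (3,)


class TestSegmentalOrder:
    def test_bounds_hold_on_generated_frames(self, system_trajectories):
        for traj in system_trajectories:
            prof = segmental_order(traj[:1])
            for chain in ("palmitoyl", "oleoyl"):
                assert np.all(prof.order[chain] >= -0.5 - 1e-12)
                assert np.all(prof.order[chain] <= 1.0 + 1e-12)

    def test_perfect_alignment_gives_unity(self):
        frame = generate_lamellar_config(
            LamellarSpec(n_bilayers=1, lipids_per_leaflet=9,
                         order_target=1.0, jitter=0.0, seed=5)
        )
        prof = segmental_order([frame])
        for chain in ("palmitoyl", "oleoyl"):
            np.testing.assert_allclose(prof.order[chain], 1.0, atol=1e-12)

    def test_perpendicular_bonds_give_minus_half(self):
        frame = generate_lamellar_config(
            LamellarSpec(n_bilayers=1, lipids_per_leaflet=9,
                         order_target=-0.5, jitter=0.0, seed=5)
        )
        prof = segmental_order([frame])
        for chain in ("palmitoyl", "oleoyl"):
            np.testing.assert_allclose(prof.order[chain], -0.5, atol=1e-12)

    def test_isotropic_limit_vanishes(self):
        spec = LamellarSpec(
            n_bilayers=3, lipids_per_leaflet=100, order_target=0.0,
            chain_inward_bias=False, seed=29,
        )
        traj = generate_lamellar_trajectory(spec, n_frames=17)
        prof = segmental_order(traj)
        assert prof.n_samples >= 10_000
        for chain in ("palmitoyl", "oleoyl"):
            assert np.all(np.abs(prof.order[chain]) < 0.03)

    def test_bond_numbering_runs_from_ester(self):
        prof = segmental_order(
            [generate_lamellar_config(LamellarSpec(n_bilayers=1, lipids_per_leaflet=4, seed=1))]
        )
        assert prof.bond_index["palmitoyl"].tolist() == [1, 2, 3, 4]
        assert prof.bond_index["oleoyl"].tolist() == [1, 2, 3, 4, 5]


class TestChainAngles:
    def test_ordered_stack_peaks_at_plus_minus_one(self):
        frame = generate_lamellar_config(
            LamellarSpec(n_bilayers=1, lipids_per_leaflet=25,
                         order_target=1.0, jitter=0.0, seed=7)
        )
        dist = chain_angle_distribution([frame], n_bins=20)
        assert dist.probability[0] + dist.probability[-1] == pytest.approx(1.0)
        assert dist.probability.sum() == pytest.approx(1.0)

    def test_isotropic_chains_flat_histogram(self):
        spec = LamellarSpec(
            n_bilayers=3, lipids_per_leaflet=100, order_target=0.0,
            chain_inward_bias=False, seed=37,
        )
        traj = generate_lamellar_trajectory(spec, n_frames=4)
        dist = chain_angle_distribution(traj, n_bins=20)
        n_samples = 2 * 600 * 4
        expected = 1.0 / 20
        se = np.sqrt(expected * (1 - expected) / n_samples)
        assert np.all(np.abs(dist.probability - expected) < 5 * se)

    def test_disorder_widens_distribution(self, system_trajectories):
        spreads = [
            chain_angle_distribution(traj).alignment_spread
            for traj in system_trajectories
        ]
        assert spreads[0] < spreads[1] < spreads[2]


class TestFlipFlops:
    def test_static_trajectory_has_no_events(self):
        spec = LamellarSpec(n_bilayers=3, lipids_per_leaflet=50, seed=41)
        traj = generate_lamellar_trajectory(spec, n_frames=3)
        recs = [assign_leaflets(f) for f in traj]
        events, counts = detect_flipflops(recs)
        assert events == [] and counts == {}

    def test_single_crossing_is_one_event(self):
        spec = LamellarSpec(n_bilayers=3, lipids_per_leaflet=50, n_flipflops=1, seed=43)
        traj = generate_lamellar_trajectory(spec, n_frames=2, flip_frame=1)
        recs = [assign_leaflets(f) for f in traj]
        events, _ = detect_flipflops(recs)
        assert len(events) == 1
        assert events[0].mol_id == planted_flip_mol_ids(spec)[0]
        assert events[0].frame == 1

    def test_five_planted_flips_recovered_without_false_positives(self):
        spec = LamellarSpec(
            n_bilayers=3, lipids_per_leaflet=50, n_flipflops=5, jitter=0.05, seed=47
        )
        traj = generate_lamellar_trajectory(spec, n_frames=4, flip_frame=2)
        recs = [assign_leaflets(f) for f in traj]
        events, counts = detect_flipflops(recs)
        assert sorted(e.mol_id for e in events) == sorted(planted_flip_mol_ids(spec))
        assert sum(counts.values()) == 5
        assert set(counts) == {0, 1, 2}  # spread round-robin over bilayers


class TestEthanolPenetration:
    def test_no_ethanol_returns_zero(self, sys1_frame):
        prof = density_profile([sys1_frame], ["ETNL"], n_bins=30)
        rec = assign_leaflets(sys1_frame)
        assert ethanol_penetration(prof, rec.midplanes, 3.85, sys1_frame.box[2]) == 0.0

    def test_uniform_ethanol_ratio_is_one(self):
        prof = density_profile(
            [_solvent_frame(np.linspace(0.01, 18.29, 4000), [3, 3, 18.3], bead="ETNL")],
            ["ETNL"],
            n_bins=61,
        )
        mids = np.array([3.05, 9.15, 15.25])
        ratio = ethanol_penetration(prof, mids, 3.85, 18.3)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_solvent_only_partition_gives_near_zero_ratio(self):
        spec = LamellarSpec(
            n_bilayers=3, lipids_per_leaflet=50, area_per_lipid=0.851,
            d_pp=3.42, d_spacing=4.7, ethanol_vol_pct=48.0,
            membrane_partition=0.0, seed=53,
        )
        frame = generate_lamellar_config(spec)
        prof = density_profile([frame], ["ETNL"], n_bins=70)
        rec = assign_leaflets(frame)
        ratio = ethanol_penetration(prof, rec.midplanes, 3.42, frame.box[2])
        assert ratio < 0.05


class TestEthanolTrends:
    def test_systems_reproduce_monotone_structural_trends(self, system_trajectories):
        """Across water -> 48 vol% -> 57 vol% fixtures: area grows, the
        membrane thins, chains disorder, and the chain-angle distribution
        widens."""
        areas, dpps, orders, spreads = [], [], [], []
        for traj in system_trajectories:
            recs = [assign_leaflets(f) for f in traj]
            areas.append(np.mean([molecular_area(f) for f in traj]))
            mean, _, _ = d_pp(traj, recs)
            dpps.append(mean.mean())
            prof = segmental_order(traj)
            orders.append(np.mean(np.concatenate(list(prof.order.values()))))
            spreads.append(chain_angle_distribution(traj).alignment_spread)
        assert areas[0] < areas[1] < areas[2]
        assert dpps[0] > dpps[1] > dpps[2]
        assert orders[0] > orders[1] > orders[2]
        assert spreads[0] < spreads[1] < spreads[2]

    def test_planted_recovery_within_two_percent(self, system_specs, system_trajectories):
        for spec, traj in zip(system_specs, system_trajectories):
            recs = [assign_leaflets(f) for f in traj]
            area = np.mean([molecular_area(f) for f in traj])
            mean, _, _ = d_pp(traj, recs)
            assert area == pytest.approx(spec.area_per_lipid, rel=0.02)
            assert mean.mean() == pytest.approx(spec.d_pp, rel=0.02)
            prof = segmental_order(traj)
            measured_s = np.mean(np.concatenate(list(prof.order.values())))
            assert measured_s == pytest.approx(spec.order_target, abs=0.02)
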