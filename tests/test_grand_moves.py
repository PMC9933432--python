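"""Adams parameters, GC region logic and instantaneous GCMC moves."""

import math

import numpy as np
import pytest

from gcncmc import (AdamsParameters, GCRegion, MoleculeTemplate,
                    ParticleSystem, adams_equilibrium,
                    attempt_instantaneous_move, gcmc_deletion_acceptance,
                    gcmc_insertion_acceptance, make_ideal_gas, make_lj_fluid,
                    region_members, sample_insertion_pose, total_energy)
from gcncmc.constants import KB
from gcncmc.errors import DomainError
from gcncmc.fixtures import IDEAL_GAS, LJ_SOLVENT
from gcncmc.io import default_water_template
from gcncmc.model import Site, molecule_interaction_energy

from test_model import reference_total_energy


def birth_death_stationary(B, n_max=50):
    """Oracle: exact stationary distribution of the insert/delete chain on an
    ideal gas, states capped at ``n_max`` (transition-matrix eigenvector)."""
    P = np.zeros((n_max + 1, n_max + 1))
    for N in range(n_max + 1):
        up = 0.5 * min(1.0, math.exp(B) / (N + 1)) if N < n_max else 0.0
        down = 0.5 * min(1.0, N * math.exp(-B)) if N > 0 else 0.0
        if N < n_max:
            P[N, N + 1] = up
        if N > 0:
            P[N, N - 1] = down
        P[N, N] = 1.0 - up - down
    vals, vecs = np.linalg.eig(P.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = np.abs(pi)
    return pi / pi.sum()


def truncated_poisson(mean, n_max=50):
    n = np.arange(n_max + 1)
    logp = n * math.log(mean) - mean - np.array([math.lgamma(k + 1) for k in n])
    p = np.exp(logp)
    return p / p.sum()


class TestAdamsParameters:
    def test_bulk_water_equilibrium_value(self):
        B = adams_equilibrium(-6.09, 64020.0, 30.345, 298.0)
        assert B == pytest.approx(-2.630, abs=5e-4)

    def test_zero_when_both_terms_vanish(self):
        assert adams_equilibrium(0.0, 30.345, 30.345, 298.0) == 0.0

    def test_six_angstrom_sphere(self):
        V = (4.0 / 3.0) * math.pi * 6.0**3
        # independent high-precision scalar evaluation
        expected = -6.09 / (KB * 298.0) + math.log(V / 30.345)
        B = adams_equilibrium(-6.09, V, 30.345, 298.0)
        assert B == pytest.approx(expected, rel=1e-12)
        assert B == pytest.approx(-6.889, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            adams_equilibrium(-6.09, -1.0)
        with pytest.raises(DomainError):
            adams_equilibrium(-6.09, 100.0, temperature=0.0)

    def test_equilibrium_constructor(self):
        a = AdamsParameters.equilibrium(-6.09, 64020.0)
        assert a.B == pytest.approx(-2.630, abs=5e-4)
        assert a.beta == pytest.approx(1.0 / (KB * 298.0))


def _sphere_system(radius=5.0, box=24.0):
    """Empty box with a frozen two-site anchor defining a sphere center."""
    anchor = MoleculeTemplate.rigid(
        "anchor",
        [Site("A1", 50.0, 0, 0, 0), Site("A2", 50.0, 0, 0, 0)],
        [[10.0, 12.0, 12.0], [14.0, 12.0, 12.0]])
    sys = ParticleSystem(np.full(3, box), cutoff=8.0)
    sys.add_molecule(anchor, frozen=True)
    sys.add_molecule(IDEAL_GAS, real=False)
    region = GCRegion(mode="sphere", species="gas", radius=radius,
                      center_sites=(0, 1))
    return sys, region


class TestRegion:
    def test_center_is_anchor_midpoint(self):
        sys, region = _sphere_system()
        np.testing.assert_allclose(region.center(sys), [12.0, 12.0, 12.0])

    def test_membership_boundary_is_strict(self):
        sys, region = _sphere_system(radius=5.0)
        assert region_members(sys, region) == []
        at_center = sys.add_molecule(IDEAL_GAS, positions=[[12.0, 12.0, 12.0]])
        outside = sys.add_molecule(IDEAL_GAS, positions=[[12.0 + 5.01, 12.0, 12.0]])
        exactly_on = sys.add_molecule(IDEAL_GAS, positions=[[12.0, 12.0 + 5.0, 12.0]])
        members = region_members(sys, region)
        assert at_center in members
        assert outside not in members
        assert exactly_on not in members

    def test_membership_uses_minimum_image(self):
        sys, region = _sphere_system(radius=5.0, box=24.0)
        # 12 + 23 wraps to 12 - 1: inside
        wrapped = sys.add_molecule(IDEAL_GAS, positions=[[12.0 + 23.0, 12.0, 12.0]])
        assert wrapped in region_members(sys, region)

    def test_whole_box_returns_all_movable(self):
        sys = make_ideal_gas(5, seed=0)
        region = GCRegion(mode="whole-box", species="gas")
        assert len(region_members(sys, region)) == 5

    def test_sphere_volume(self):
        sys, region = _sphere_system(radius=6.0)
        assert region.volume(sys) == pytest.approx((4 / 3) * math.pi * 216.0)


class TestInsertionPose:
    def test_radial_cdf_of_uniform_sphere(self):
        sys, region = _sphere_system(radius=5.0)
        rng = np.random.default_rng(6)
        n = 20000
        r3 = np.empty(n)
        for k in range(n):
            pose = sample_insertion_pose(sys, region, IDEAL_GAS, rng)
            d = pose[0] - region.center(sys)
            r3[k] = np.linalg.norm(d) ** 3
        R3 = 5.0**3
        se = R3 / math.sqrt(12 * n)  # var(r³) = R⁶/12 for uniform-in-sphere
        assert abs(r3.mean() - R3 / 2) < 3 * se

    def test_single_site_orientation_noop(self):
        sys, region = _sphere_system()
        rng = np.random.default_rng(1)
        pose = sample_insertion_pose(sys, region, IDEAL_GAS, rng)
        assert pose.shape == (1, 3)

    def test_rigid_geometry_preserved_and_axis_uniform(self):
        water = default_water_template()
        sys, region = _sphere_system(radius=5.0)
        rng = np.random.default_rng(7)
        n = 20000
        axes = np.empty((n, 3))
        for k in range(n):
            pose = sample_insertion_pose(sys, region, water, rng)
            if k < 50:  # geometry spot-check on a subset
                for i, j, d in water.constraints:
                    assert np.linalg.norm(pose[i] - pose[j]) == pytest.approx(d, rel=1e-9)
            axis = pose[1] - pose[0]
            axes[k] = axis / np.linalg.norm(axis)
        # Rayleigh test: the resultant of n uniform unit vectors is O(sqrt(n))
        resultant = np.linalg.norm(axes.sum(axis=0))
        assert resultant < 4.0 * math.sqrt(n)


class TestAcceptanceProbabilities:
    def test_insertion_examples(self):
        assert gcmc_insertion_acceptance(0.0, 0.0, 0) == 1.0
        assert gcmc_insertion_acceptance(0.0, -2.630, 0) == pytest.approx(
            math.exp(-2.630), rel=1e-12)
        assert gcmc_insertion_acceptance(0.0, -2.630, 0) == pytest.approx(0.0721, abs=2e-4)
        assert gcmc_insertion_acceptance(1e6, 0.0, 0) == pytest.approx(0.0, abs=1e-300)

    def test_deletion_examples(self):
        assert gcmc_deletion_acceptance(0.0, 0.0, 1) == 1.0
        got = gcmc_deletion_acceptance(4.0, -2.630, 3, 298.0)
        expected = min(1.0, 3 * math.exp(2.630) * math.exp(-4.0 / (KB * 298.0)))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.0485, abs=2e-4)

    def test_probabilities_capped_at_one(self):
        assert gcmc_deletion_acceptance(-50.0, 0.0, 10) == 1.0
        assert gcmc_insertion_acceptance(-50.0, 5.0, 0) == 1.0

    def test_preconditions(self):
        with pytest.raises(DomainError):
            gcmc_insertion_acceptance(0.0, 0.0, -1)
        with pytest.raises(DomainError):
            gcmc_deletion_acceptance(0.0, 0.0, 0)


class TestInstantaneousMoves:
    def test_empty_region_deletion_auto_rejected(self):
        sys, region = _sphere_system()
        adams = AdamsParameters(B=0.0)
        rng = np.random.default_rng(3)
        seen_auto = False
        for _ in range(20):
            rec = attempt_instantaneous_move(sys, region, adams, rng)
            if rec.kind == "delete" and rec.n_before == 0:
                assert rec.auto_rejected and not rec.accepted
                seen_auto = True
                break
            if rec.accepted:  # remove again to keep the region empty
                sys.make_ghost(rec.molecule_id)
        assert seen_auto

    def test_rejection_restores_system_exactly(self):
        sys = make_lj_fluid(12, box=18.0, seed=10)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=-30.0)  # essentially everything rejected
        rng = np.random.default_rng(5)
        pos0, vel0 = sys.positions.copy(), sys.velocities.copy()
        n0 = len(sys.real_molecule_ids())
        for _ in range(50):
            rec = attempt_instantaneous_move(sys, region, adams, rng)
            if rec.accepted:
                break
        else:
            real_pos = sys.positions[:pos0.shape[0]]
            assert len(sys.real_molecule_ids()) == n0
            np.testing.assert_array_equal(real_pos, pos0)
            np.testing.assert_array_equal(sys.velocities[:vel0.shape[0]], vel0)

    def test_energy_bookkeeping_incremental_vs_recomputed(self):
        sys = make_lj_fluid(10, box=18.0, seed=20)
        sys.tracked_energy = total_energy(sys)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=-1.0)
        rng = np.random.default_rng(8)
        for _ in range(150):
            attempt_instantaneous_move(sys, region, adams, rng)
            assert sys.tracked_energy == pytest.approx(total_energy(sys), abs=1e-8)

    def test_ghost_hygiene_after_many_moves(self):
        sys = make_lj_fluid(8, box=18.0, seed=30)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=0.0)
        rng = np.random.default_rng(9)
        for _ in range(300):
            attempt_instantaneous_move(sys, region, adams, rng)
        for mol_id, m in enumerate(sys.molecules):
            if not m.real:
                assert molecule_interaction_energy(sys, mol_id) == 0.0
                assert sys.mol_lam_vdw[mol_id] == 0.0
        # total energy counts real molecules only (double-loop oracle)
        assert total_energy(sys) == pytest.approx(reference_total_energy(sys), abs=1e-9)

    def test_ideal_gas_chain_matches_birth_death_oracle(self):
        """Occupancy of the non-interacting chain at B = 0: mean within 3 SE
        of the capped birth-death stationary mean (≈ e^0 = 1)."""
        pi = birth_death_stationary(0.0)
        np.testing.assert_allclose(pi, truncated_poisson(1.0), atol=1e-9)
        sys = make_ideal_gas(1, seed=2)
        region = GCRegion(mode="whole-box", species="gas")
        adams = AdamsParameters(B=0.0)
        rng = np.random.default_rng(12)
        n_moves, burn = 60000, 5000
        occ = np.empty(n_moves - burn)
        count = len(sys.real_molecule_ids("gas"))
        for k in range(n_moves):
            rec = attempt_instantaneous_move(sys, region, adams, rng)
            if rec.accepted:
                count += 1 if rec.kind == "insert" else -1
            if k >= burn:
                occ[k - burn] = count
        n_eff = len(occ) / 50.0  # generous autocorrelation allowance
        se = occ.std() / math.sqrt(n_eff)
        assert abs(occ.mean() - 1.0) < 3 * se

    def test_detailed_balance_state_ratios(self):
        """Empirical visit ratios of adjacent occupancy states match the
        analytic stationary ratio e^B/(N+1)."""
        B = 0.5
        sys = make_ideal_gas(1, seed=4)
        region = GCRegion(mode="whole-box", species="gas")
        adams = AdamsParameters(B=B)
        rng = np.random.default_rng(14)
        visits = np.zeros(40)
        count = 1
        for k in range(80000):
            rec = attempt_instantaneous_move(sys, region, adams, rng)
            if rec.accepted:
                count += 1 if rec.kind == "insert" else -1
            if k >= 5000:
                visits[count] += 1
        for N in range(3):
            ratio = visits[N + 1] / visits[N]
            expected = math.exp(B) / (N + 1)
            assert ratio == pytest.approx(expected, rel=0.15)
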