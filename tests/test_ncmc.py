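"""NCMC protocols, switching moves, work bookkeeping and acceptance."""

import math

import numpy as np
import pytest

from gcncmc import (AdamsParameters, GCRegion, IntegratorSettings,
                    NCMCProtocol, attempt_instantaneous_move,
                    attempt_ncmc_move, gcmc_deletion_acceptance,
                    gcmc_insertion_acceptance, gcncmc_deletion_acceptance,
                    gcncmc_insertion_acceptance, make_ideal_gas,
                    make_lj_fluid, protocol_from_time, run_switch)
from gcncmc.errors import ConfigurationError, DomainError
from gcncmc.fixtures import IDEAL_GAS, LJ_SOLVENT
from gcncmc.grand_moves import _prepare_insertion, region_members
from gcncmc.ncmc import take_snapshot


class TestProtocol:
    @pytest.mark.parametrize("tau,n_prop,dt,n_pert", [
        (10.0, 10, 0.002, 499),
        (15.0, 50, 0.002, 149),
        (0.02, 10, 0.002, 0),  # τ = n_prop·δt: single propagation, no perturbation
    ])
    def test_switching_time_relation(self, tau, n_prop, dt, n_pert):
        p = protocol_from_time(tau, n_prop, dt)
        assert p.n_pert == n_pert
        assert p.switching_time == pytest.approx(tau)

    def test_non_divisible_time_reports_nearest(self):
        with pytest.raises(ConfigurationError, match="nearest valid"):
            protocol_from_time(0.05, 7, 0.002)

    def test_lambda_schedule_equally_spaced(self):
        p = NCMCProtocol(n_pert=4, n_prop=2)
        np.testing.assert_allclose(p.lambdas, [0, 0.25, 0.5, 0.75, 1.0])
        assert p.total_md_steps == 10

    def test_invalid_arguments(self):
        with pytest.raises(ConfigurationError):
            protocol_from_time(-1.0, 10)
        with pytest.raises(ConfigurationError):
            protocol_from_time(1.0, 0)

    def test_degenerate_protocol_cannot_switch(self):
        sys = make_ideal_gas(1, seed=0)
        region = GCRegion(mode="whole-box", species="gas")
        with pytest.raises(ConfigurationError, match="perturbation"):
            run_switch(sys, 0, "decouple", NCMCProtocol(n_pert=0, n_prop=5),
                       region, IntegratorSettings(), np.random.default_rng(1))


class TestAcceptanceForms:
    def test_trivial_values(self):
        assert gcncmc_insertion_acceptance(0.0, 0.0, 1) == 1.0
        assert gcncmc_deletion_acceptance(0.0, 0.0, 1) == 1.0
        assert gcncmc_insertion_acceptance(1e6, 0.0, 1) == pytest.approx(0.0, abs=1e-300)

    def test_preconditions(self):
        with pytest.raises(DomainError):
            gcncmc_insertion_acceptance(0.0, 0.0, 0)
        with pytest.raises(DomainError):
            gcncmc_deletion_acceptance(0.0, 0.0, 0)

    def test_matches_instantaneous_forms_on_random_inputs(self):
        """In the instantaneous limit N_T = N+1 and N_0 = N, so the GCNCMC
        acceptance must coincide with the GCMC acceptance for any (W, B, N)."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            W = rng.normal(0, 5)
            B = rng.normal(0, 3)
            N = int(rng.integers(0, 10))
            assert gcncmc_insertion_acceptance(W, B, N + 1) == pytest.approx(
                gcmc_insertion_acceptance(W, B, N), rel=1e-12)
            if N >= 1:
                assert gcncmc_deletion_acceptance(W, B, N) == pytest.approx(
                    gcmc_deletion_acceptance(W, B, N), rel=1e-12)


class TestRunSwitch:
    def test_ideal_gas_work_is_zero(self):
        sys = make_ideal_gas(3, seed=1)
        region = GCRegion(mode="whole-box", species="gas")
        rng = np.random.default_rng(2)
        mol, _ = _prepare_insertion(sys, region, rng)
        W, n0, nT, du, _ = run_switch(sys, mol, "couple",
                                      NCMCProtocol(n_pert=5, n_prop=2),
                                      region, IntegratorSettings(),
                                      np.random.default_rng(3))
        assert W == 0.0
        assert np.all(du == 0.0)
        assert nT == n0 + 1

    def test_instantaneous_limit_work_equals_delta_u(self):
        from gcncmc.model import molecule_interaction_energy
        sys = make_lj_fluid(12, box=18.0, seed=3)
        region = GCRegion(mode="whole-box", species="lj")
        rng = np.random.default_rng(4)
        mol, _ = _prepare_insertion(sys, region, rng)
        dU = molecule_interaction_energy(sys, mol, state=1.0)
        W, _, _, du, _ = run_switch(sys, mol, "couple",
                                    NCMCProtocol(n_pert=1, n_prop=0),
                                    region, IntegratorSettings(),
                                    np.random.default_rng(5))
        assert W == pytest.approx(dU, abs=1e-12)
        assert len(du) == 1

    def test_frozen_environment_path_symmetry(self):
        """With propagation disabled, coupling and decoupling the same pose
        traverse the same energies: W(couple) = −W(decouple)."""
        sys = make_lj_fluid(10, box=18.0, seed=6)
        region = GCRegion(mode="whole-box", species="lj")
        rng = np.random.default_rng(7)
        mol, _ = _prepare_insertion(sys, region, rng)
        proto = NCMCProtocol(n_pert=7, n_prop=0)
        settings = IntegratorSettings()
        W_c, _, _, du_c, _ = run_switch(sys, mol, "couple", proto, region,
                                        settings, np.random.default_rng(8))
        W_d, _, _, du_d, _ = run_switch(sys, mol, "decouple", proto, region,
                                        settings, np.random.default_rng(8))
        assert W_c == pytest.approx(-W_d, abs=1e-10)
        np.testing.assert_allclose(du_c, -du_d[::-1], atol=1e-12)

    def test_work_equals_resummed_perturbation_trace(self):
        sys = make_lj_fluid(15, box=18.0, seed=9)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=-2.0)
        proto = NCMCProtocol(n_pert=4, n_prop=2)
        rng = np.random.default_rng(10)
        md = np.random.default_rng(11)
        for _ in range(20):
            rec = attempt_ncmc_move(sys, region, adams, proto,
                                    IntegratorSettings(), rng, md_rng=md)
            if rec.perturbation_du is not None:
                assert rec.work == pytest.approx(float(np.sum(rec.perturbation_du)),
                                                 abs=1e-10)


class TestNCMCMoves:
    def test_rejection_restores_snapshot_bitwise(self):
        sys = make_lj_fluid(12, box=18.0, seed=12)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=-60.0)  # force rejection
        proto = NCMCProtocol(n_pert=2, n_prop=2)
        rng = np.random.default_rng(13)
        md = np.random.default_rng(14)
        checked = 0
        for _ in range(30):
            before = take_snapshot(sys, md)
            rec = attempt_ncmc_move(sys, region, adams, proto,
                                    IntegratorSettings(), rng, md_rng=md)
            if rec.accepted:  # deletions accept at very negative B; skip those
                continue
            checked += 1
            after = take_snapshot(sys, md)
            for key in ("positions", "velocities", "mol_lam_vdw", "mol_lam_elec"):
                np.testing.assert_array_equal(before[key], after[key],
                                              err_msg=key)
            assert before["md_rng_state"] == after["md_rng_state"]
            assert [m.real for m in before["molecules"]] == \
                   [m.real for m in after["molecules"]]
        assert checked >= 5

    def test_ideal_gas_acceptance_probabilities_exact(self):
        """With W ≡ 0 and B = 0 every move has probability min(1, 1/N_T) for
        insertions and min(1, N_0) for deletions, exactly."""
        sys = make_ideal_gas(2, seed=15)
        region = GCRegion(mode="whole-box", species="gas")
        adams = AdamsParameters(B=0.0)
        proto = NCMCProtocol(n_pert=3, n_prop=1)
        rng = np.random.default_rng(16)
        md = np.random.default_rng(17)
        checked = 0
        for _ in range(200):
            rec = attempt_ncmc_move(sys, region, adams, proto,
                                    IntegratorSettings(), rng, md_rng=md)
            if rec.auto_rejected:
                continue
            if rec.kind == "insert":
                assert rec.probability == min(1.0, 1.0 / rec.nT)
            else:
                assert rec.probability == min(1.0, float(rec.n0))
            checked += 1
        assert checked > 100

    def test_insertion_leaving_sphere_is_auto_rejected(self):
        """Free flight carries an inserted ideal-gas particle out of a small
        sphere during propagation: the move must auto-reject regardless of W."""
        from test_grand_moves import _sphere_system
        sys, region = _sphere_system(radius=1.0)
        adams = AdamsParameters(B=5.0)  # would otherwise accept everything
        proto = NCMCProtocol(n_pert=3, n_prop=30)
        rng = np.random.default_rng(18)
        md = np.random.default_rng(19)
        seen = False
        for _ in range(40):
            before = take_snapshot(sys, md)
            rec = attempt_ncmc_move(sys, region, adams, proto,
                                    IntegratorSettings(), rng, md_rng=md)
            if rec.kind == "insert" and rec.auto_rejected:
                assert "non-reversible" in rec.auto_reject_reason
                after = take_snapshot(sys, md)
                np.testing.assert_array_equal(before["positions"], after["positions"])
                seen = True
                break
        assert seen

    def test_instantaneous_limit_equivalence_shared_stream(self):
        """n_pert=1, n_prop=0 GCNCMC reproduces instantaneous GCMC decisions
        move for move when both consume the same proposal stream."""
        sys_a = make_lj_fluid(20, box=18.0, seed=21)
        sys_b = make_lj_fluid(20, box=18.0, seed=21)
        region = GCRegion(mode="whole-box", species="lj")
        adams = AdamsParameters(B=-1.0)
        proto = NCMCProtocol(n_pert=1, n_prop=0)
        rng_a = np.random.default_rng(22)
        rng_b = np.random.default_rng(22)
        md = np.random.default_rng(23)
        for k in range(1000):
            rec_a = attempt_instantaneous_move(sys_a, region, adams, rng_a)
            rec_b = attempt_ncmc_move(sys_b, region, adams, proto,
                                      IntegratorSettings(), rng_b, md_rng=md)
            assert rec_a.kind == rec_b.kind, k
            assert rec_a.accepted == rec_b.accepted, k
            assert rec_a.work == pytest.approx(rec_b.work, abs=1e-10)
        assert np.array_equal(sys_a.positions[:sys_b.n_sites - 1],
                              sys_b.positions[:sys_b.n_sites - 1]) or \
            sys_a.n_sites == sys_b.n_sites

    def test_ideal_gas_ncmc_chain_is_poisson(self):
        """Stationary occupancy of the non-interacting GCNCMC chain at B = −1
        equals e^{-1} within 3 SE (work is identically zero)."""
        sys = make_ideal_gas(1, seed=24)
        region = GCRegion(mode="whole-box", species="gas")
        adams = AdamsParameters(B=-1.0)
        proto = NCMCProtocol(n_pert=1, n_prop=1)
        rng = np.random.default_rng(25)
        md = np.random.default_rng(26)
        settings = IntegratorSettings()
        n_moves, burn = 15000, 2000
        occ = []
        for k in range(n_moves):
            attempt_ncmc_move(sys, region, adams, proto, settings, rng, md_rng=md)
            if k >= burn:
                occ.append(len(sys.real_molecule_ids("gas")))
        occ = np.array(occ, dtype=float)
        n_eff = len(occ) / 50.0
        se = max(occ.std() / math.sqrt(n_eff), 1e-3)
        assert abs(occ.mean() - math.exp(-1.0)) < 3 * se
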