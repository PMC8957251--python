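"""Circulation assembly, mass balance, dosing, and solver fidelity."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from pbpksim import (
    DoseEvent,
    DoseRegimen,
    EcsParams,
    HlsParams,
    SoluteSpec,
    assemble_system,
    compute_clearance,
    compute_partitions,
    simulate,
    total_amount,
)


def ecs_solute(f_p=0.8, renal=0.0, fclr=None):
    return SoluteSpec(
        name="test-ecs",
        mode="ecs",
        ecs=EcsParams(f_p=f_p, fclr_muscle=fclr),
        renal_clearance_fraction=renal,
    )


def hls_solute(p_lw=2e5, f_l_blood=0.0075, hepatic=0.0):
    return SoluteSpec(
        name="test-hls",
        mode="hls",
        hls=HlsParams(p_lw=p_lw, f_l_blood=f_l_blood),
        hepatic_clearance_fraction=hepatic,
    )


class TestSoluteSpec:
    def test_requires_matching_parameter_block(self):
        with pytest.raises(ValueError, match="parameter block"):
            SoluteSpec(name="x", mode="hls", ecs=EcsParams(f_p=0.8))
        with pytest.raises(ValueError, match="parameter block"):
            SoluteSpec(name="x", mode="hls")

    def test_clearance_fraction_range(self):
        with pytest.raises(ValueError):
            SoluteSpec(name="x", mode="hls", hls=HlsParams(p_lw=100.0), renal_clearance_fraction=1.5)


class TestDoseRegimen:
    def test_bolus_requires_amount(self):
        with pytest.raises(ValueError):
            DoseEvent("bolus", start=0.0)

    def test_infusion_requires_window(self):
        with pytest.raises(ValueError):
            DoseEvent("infusion", start=10.0, stop=5.0, rate=1.0)

    def test_events_must_be_ordered(self):
        with pytest.raises(ValueError):
            DoseRegimen(
                (
                    DoseEvent("bolus", start=10.0, amount=1.0),
                    DoseEvent("bolus", start=0.0, amount=1.0),
                )
            )

    def test_piecewise_rates(self):
        reg = DoseRegimen.infusion(rate=2.0, start=5.0, stop=15.0)
        assert reg.infusion_rate(10.0) == 2.0
        assert reg.infusion_rate(20.0) == 0.0


class TestComputePartitions:
    def test_cannabinol_organ_table(self, body):
        k = compute_partitions(body, hls_solute())
        assert k["adipose"] == pytest.approx(106.6, rel=1e-3)
        assert k["adipose 2"] == pytest.approx(106.6, rel=1e-3)
        expected_muscle = (0.0136 * 2e5 + 0.9864) / (0.0075 * 2e5 + 0.9925)
        assert k["muscle"] == pytest.approx(expected_muscle, rel=1e-12)
        assert k["muscle"] == pytest.approx(1.81, rel=1e-2)

    def test_amoxicillin_organ_table(self, body):
        k = compute_partitions(body, ecs_solute(f_p=0.8))
        assert k["muscle"] == pytest.approx(0.9)
        assert k["skin"] == pytest.approx(0.8 + 0.2 * 0.25)

    def test_free_solute_partitions_to_unity(self, body):
        k = compute_partitions(body, ecs_solute(f_p=1.0))
        assert all(v == pytest.approx(1.0) for v in k.values())


class TestComputeClearance:
    def test_renal_from_plasma_flow(self, body):
        clear = compute_clearance(body, ecs_solute(renal=0.353))
        assert clear.renal == pytest.approx(0.353 * 0.31 * 4.0 * 0.55, rel=1e-12)
        assert clear.renal == pytest.approx(0.241, abs=5e-4)  # printed precision

    def test_hepatic_from_liver_blood_flow(self, body):
        clear = compute_clearance(body, hls_solute(hepatic=0.651))
        assert clear.hepatic == pytest.approx(0.651 * (1.8 * 0.25 + 1.5 * 0.75), rel=1e-12)
        assert clear.hepatic == pytest.approx(1.025, rel=1e-3)

    def test_zero_fraction(self, body):
        clear = compute_clearance(body, ecs_solute(renal=0.0))
        assert clear.renal == 0.0 and clear.hepatic == 0.0


class TestAssembly:
    def test_zero_state_has_zero_derivative(self, body):
        system = assemble_system(body, ecs_solute(renal=0.353))
        assert np.allclose(system.A @ np.zeros(system.n_states), 0.0)

    @pytest.mark.parametrize("solute", [ecs_solute(), hls_solute()], ids=["ecs", "hls"])
    def test_closed_system_conserves_mass_exactly(self, body, solute):
        # with no clearance, d(total amount)/dt = capacities . (A x) = 0 for
        # every state, i.e. the capacity vector is a left null vector of A
        system = assemble_system(body, solute)
        residual = system.capacities @ system.A
        assert np.max(np.abs(residual)) < 1e-12 * np.max(np.abs(system.A))

    def test_inconsistent_mode_fails_at_assembly(self, body):
        with pytest.raises(ValueError, match="ECS"):
            assemble_system(body, hls_solute(), permeability_limited=True)

    def test_brain_is_passthrough_for_ecs(self, body):
        system = assemble_system(body, ecs_solute())
        assert "brain" not in system.state_names
        assert system.passthrough_organs == ("brain",)
        assert "brain" in assemble_system(body, hls_solute()).state_names


class TestSimulate:
    def test_bolus_conservation_without_clearance(self, body, grid_600):
        res = simulate(body, ecs_solute(), DoseRegimen.bolus(2.5), grid_600)
        totals = total_amount(res)
        assert np.max(np.abs(totals - 2.5)) < 1e-6 * 2.5
        assert res.cleared[-1] == 0.0

    def test_cleared_plus_stored_accounts_for_dose(self, body, grid_600):
        res = simulate(body, ecs_solute(renal=0.353), DoseRegimen.bolus(1.0), grid_600)
        totals = total_amount(res)
        assert np.max(np.abs(totals - 1.0)) < 1e-6
        assert res.cleared[-1] > 0.9  # mostly eliminated by 600 min
        stored = totals - res.cleared
        assert np.all(np.diff(stored) <= 1e-9)  # tissue total is non-increasing

    def test_dose_linearity(self, body, grid_600):
        r1 = simulate(body, ecs_solute(renal=0.353), DoseRegimen.bolus(1.0), grid_600)
        r2 = simulate(body, ecs_solute(renal=0.353), DoseRegimen.bolus(2.0), grid_600)
        scale = np.max(r1.venous)
        assert np.max(np.abs(r2.venous - 2 * r1.venous)) < 1e-6 * scale

    def test_equilibration_without_clearance(self, body):
        # a closed system relaxes to equal free concentration everywhere:
        # every state approaches dose / V_ss
        solute = ecs_solute()
        grid = np.linspace(0.0, 20000.0, 101)
        res = simulate(body, solute, DoseRegimen.bolus(1.0), grid)
        v_ss = res.system.capacities.sum()
        final = res.data[res.state_names].to_numpy()[-1]
        assert final == pytest.approx(np.full_like(final, 1.0 / v_ss), rel=1e-4)

    def test_steady_state_infusion_identity(self, body):
        solute = ecs_solute(renal=0.353)
        clear = compute_clearance(body, solute)
        reg = DoseRegimen.infusion(rate=0.01, start=0.0, stop=4000.0)
        res = simulate(body, solute, reg, np.linspace(0.0, 4000.0, 81))
        assert res.arterial[-1] == pytest.approx(0.01 / clear.renal, rel=1e-3)

    def test_matrix_exponential_oracle(self, body):
        # independent propagation of the same state matrix by repeated
        # matrix exponential steps
        solute = ecs_solute(renal=0.353)
        system = assemble_system(body, solute)
        ts = np.linspace(0.0, 600.0, 61)
        x = np.zeros(system.n_states)
        x[system.dose_index] = 1.0 / system.capacities[system.dose_index]
        step = expm(system.A * (ts[1] - ts[0]))
        oracle = [x]
        for _ in ts[1:]:
            x = step @ x
            oracle.append(x)
        oracle = np.array(oracle)
        res = simulate(body, solute, DoseRegimen.bolus(1.0), ts)
        sim = res.data[res.state_names].to_numpy()
        assert np.max(np.abs(sim - oracle)) < 1e-5 * np.max(np.abs(oracle))

    def test_flow_limited_limit_of_permeability_path(self, body, grid_600):
        solute = ecs_solute(renal=0.353, fclr=1.0)
        r_perm = simulate(body, solute, DoseRegimen.bolus(1.0), grid_600, permeability_limited=True)
        r_flow = simulate(body, solute, DoseRegimen.bolus(1.0), grid_600, permeability_limited=False)
        for name in r_flow.state_names:
            scale = np.max(np.abs(r_flow.organ(name))) or 1.0
            assert np.max(np.abs(r_perm.organ(name) - r_flow.organ(name))) < 1e-6 * scale

    def test_permeability_limitation_slows_tissue_uptake(self, body, grid_600):
        fast = simulate(body, ecs_solute(fclr=1.0), DoseRegimen.bolus(1.0), grid_600)
        slow = simulate(body, ecs_solute(fclr=0.2), DoseRegimen.bolus(1.0), grid_600)
        t_early = grid_600 < 15
        assert np.all(slow.organ("muscle")[t_early][1:] < fast.organ("muscle")[t_early][1:])

    def test_terminal_slope_is_clearance_over_vss(self, body):
        # a single small clearance: the slowest eigenmode decays at Cl/V_ss
        solute = ecs_solute(renal=0.02)
        system = assemble_system(body, solute)
        clear = compute_clearance(body, solute)
        v_ss = system.capacities.sum()
        assert system.slowest_time_constant() == pytest.approx(v_ss / clear.renal, rel=0.05)

    def test_inhalation_requires_volatile_mode(self, body, grid_600):
        reg = DoseRegimen.inhalation(0.01, 0.0, 30.0)
        with pytest.raises(ValueError, match="volatile"):
            simulate(body, ecs_solute(), reg, grid_600)

    def test_grid_must_increase(self, body):
        with pytest.raises(ValueError, match="increasing"):
            simulate(body, ecs_solute(), DoseRegimen.bolus(1.0), [0.0, 10.0, 5.0])


def test_csv_serialization_order(body, grid_600, tmp_path):
    res = simulate(body, ecs_solute(renal=0.353), DoseRegimen.bolus(1.0), grid_600)
    path = tmp_path / "run.csv"
    res.to_csv(path)
    frame = pd.read_csv(path)
    assert frame.columns[0] == "time_min"
    # state columns appear in parameter-table row order
    assert list(frame.columns[1 : 1 + len(res.state_names)]) == res.state_names
    assert res.state_names[0] == "vein" and res.state_names[1] == "artery"
    np.testing.assert_allclose(frame["vein"].to_numpy(), res.venous)
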