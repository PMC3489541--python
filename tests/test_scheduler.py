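"""Slot grids, the scheduling ILP, oracle equivalence, and metrics."""

import numpy as np
import pytest

import srmdesign as sd
from srmdesign import fixtures as fx
from srmdesign.digest import ValidationError

from conftest import assert_solution_valid, sweep_instances


def make_transition(tid, pep="PEPA", d=0.5, rt=10.0, prot="P1"):
    return sd.Transition(
        id=tid, peptide_sequence=pep, protein_accessions=frozenset({prot}),
        precursor_mz=500.0, precursor_charge=2, product_mz=600.0,
        ion_annotation=("y", 3, 1), detectability=d, rt_center=rt,
    )


class TestConfigAndSlots:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            sd.ScheduleConfig(delta=0.0)
        with pytest.raises(ValidationError):
            sd.ScheduleConfig(capacity=0)
        with pytest.raises(ValidationError):
            sd.ScheduleConfig(tau=0)
        assert sd.ScheduleConfig(delta=2.5).slot_width == 2.5

    def test_slot_count(self):
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=60.0)
        grid = sd.build_slots([], cfg)
        assert grid.n_slots == 24

    def test_window_slot_intersection(self):
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=60.0)
        grid = sd.build_slots([make_transition("t", rt=10.0)], cfg)
        # window [7.5, 12.5) intersects slots [7.5,10) and [10,12.5)
        assert grid.transition_slots["t"] == [3, 4]

    def test_out_of_gradient_transition_excluded(self):
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=60.0)
        with pytest.warns(UserWarning, match="outside the gradient"):
            grid = sd.build_slots([make_transition("t", rt=70.0)], cfg)
        assert grid.excluded == ["t"] and "t" not in grid.transition_slots

    def test_window_clipped_at_boundaries(self):
        cfg = sd.ScheduleConfig(delta=5.0, gradient_length=20.0, slot_width=5.0)
        grid = sd.build_slots([make_transition("t", rt=1.0)], cfg)
        assert grid.transition_slots["t"] == [0, 1]  # clipped at 0


class TestBuildILP:
    def test_variable_count(self):
        transitions = [make_transition(f"t{i}") for i in range(3)]
        targets = sd.TargetMap(proteins={"P1": ("PEPA", "PEPB")})
        cfg = sd.ScheduleConfig(rho=2)
        grid = sd.build_slots(transitions, cfg)
        ilp = sd.build_ilp(transitions, grid, targets, cfg)
        assert ilp.n_variables == 3 + 2 + 2 * 1

    def test_peptide_coverage_constraint_instantiated(self):
        transitions = [make_transition(f"t{i}") for i in range(3)]
        targets = sd.TargetMap(proteins={"P1": ("PEPA",)})
        cfg = sd.ScheduleConfig(tau=2, rho=1)
        grid = sd.build_slots(transitions, cfg)
        ilp = sd.build_ilp(transitions, grid, targets, cfg)
        A = ilp.constraints[0].A.toarray()
        lb = np.asarray(ilp.constraints[0].lb)
        # row: 2*y_p + x1 + x2 + x3 >= 2
        row = [r for r in range(A.shape[0])
               if lb[r] == 2 and A[r, 3] == 2 and all(A[r, :3] == 1)]
        assert len(row) == 1

    def test_z_penalty_weights(self):
        targets = sd.TargetMap(proteins={"S": ("PEPA",)})
        cfg = sd.ScheduleConfig(rho=2, omega_s=10.0)
        grid = sd.build_slots([], cfg)
        ilp = sd.build_ilp([], grid, targets, cfg)
        # variables: y, z_s0, z_s1 with objective weights -1, -40, -10
        assert ilp.c_maximize.tolist() == [-1.0, -40.0, -10.0]

    def test_bad_detectability_rejected(self):
        t = make_transition("t", d=1.5)
        cfg = sd.ScheduleConfig()
        grid = sd.build_slots([t], cfg)
        with pytest.raises(ValidationError):
            sd.build_ilp([t], grid, sd.TargetMap(proteins={}), cfg)


class TestSolve:
    def test_empty_instance_penalties(self):
        # no transitions, one protein with one peptide, rho=2:
        # objective = -omega_p - omega_s*(4 + 1) = -51
        cfg = sd.ScheduleConfig(tau=3, rho=2, omega_p=1.0, omega_s=10.0)
        targets = sd.TargetMap(proteins={"S1": ("PEP1",)})
        grid = sd.build_slots([], cfg)
        sol = sd.solve_ilp(sd.build_ilp([], grid, targets, cfg))
        assert sol.objective_value == pytest.approx(-51.0)
        assert sol.peptide_uncovered["PEP1"] == 1
        assert sol.protein_uncovered[("S1", 0)] == 1
        assert sol.protein_uncovered[("S1", 1)] == 1
        assert sol.solver_status == "optimal"

    def test_capacity_one_blocks_coverage(self):
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=20.0, capacity=1,
                                tau=2, rho=1, omega_p=1.0, omega_s=10.0)
        a = make_transition("a", d=0.9, rt=10.0)
        b = make_transition("b", pep="PEPA", d=0.8, rt=10.0)
        targets = sd.TargetMap(proteins={"P1": ("PEPA",)})
        grid = sd.build_slots([a, b], cfg)
        sol = sd.solve_ilp(sd.build_ilp([a, b], grid, targets, cfg))
        oracle = sd.brute_force([a, b], grid, targets, cfg)
        assert sol.objective_value == pytest.approx(oracle.objective_value)
        assert sol.selected == {"a"}  # picks the stronger one
        assert sol.peptide_uncovered["PEPA"] == 1

    def test_capacity_two_enables_coverage(self):
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=20.0, capacity=2,
                                tau=2, rho=1, omega_p=1.0, omega_s=10.0)
        a = make_transition("a", d=0.9, rt=10.0)
        b = make_transition("b", pep="PEPA", d=0.8, rt=10.0)
        targets = sd.TargetMap(proteins={"P1": ("PEPA",)})
        grid = sd.build_slots([a, b], cfg)
        sol = sd.solve_ilp(sd.build_ilp([a, b], grid, targets, cfg))
        assert sol.selected == {"a", "b"}
        assert sol.peptide_uncovered["PEPA"] == 0
        assert sol.objective_value == pytest.approx(0.9 + 0.8)

    def test_brute_force_guard(self):
        cfg = sd.ScheduleConfig()
        transitions = [make_transition(f"t{i:02d}") for i in range(21)]
        grid = sd.build_slots(transitions, cfg)
        with pytest.raises(ValidationError, match="guard"):
            sd.brute_force(transitions, grid,
                           sd.TargetMap(proteins={}), cfg)


class TestOracleEquivalence:
    def test_ilp_matches_brute_force_and_dominates_greedy(self):
        for seed, transitions, targets, cfg in sweep_instances(60):
            grid = sd.build_slots(transitions, cfg)
            ilp_sol = sd.solve_ilp(sd.build_ilp(transitions, grid, targets, cfg))
            oracle = sd.brute_force(transitions, grid, targets, cfg)
            greedy = sd.greedy_schedule(transitions, grid, targets, cfg)
            assert ilp_sol.objective_value == pytest.approx(
                oracle.objective_value, abs=1e-9
            ), f"seed {seed}"
            assert greedy.objective_value <= ilp_sol.objective_value + 1e-9
            for sol in (ilp_sol, oracle, greedy):
                assert_solution_valid(sol, grid, targets, cfg)

    def test_greedy_trap(self):
        transitions, targets, cfg = fx.greedy_trap_instance()
        grid = sd.build_slots(transitions, cfg)
        ilp_sol = sd.solve_ilp(sd.build_ilp(transitions, grid, targets, cfg))
        oracle = sd.brute_force(transitions, grid, targets, cfg)
        greedy = sd.greedy_schedule(transitions, grid, targets, cfg)
        assert ilp_sol.objective_value == pytest.approx(oracle.objective_value)
        assert greedy.objective_value < ilp_sol.objective_value - 0.5
        assert ilp_sol.selected == {"a1", "a2"}


class TestStructuralProperties:
    def test_objective_monotone_in_capacity(self):
        transitions, targets = fx.synthetic_schedule_instance(
            12, 4, 2, seed=42, gradient_length=20.0
        )
        previous = -np.inf
        for capacity in range(1, 6):
            cfg = sd.ScheduleConfig(delta=2.5, gradient_length=20.0,
                                    capacity=capacity, tau=2, rho=2)
            grid = sd.build_slots(transitions, cfg)
            sol = sd.solve_ilp(sd.build_ilp(transitions, grid, targets, cfg))
            assert sol.objective_value >= previous - 1e-9
            previous = sol.objective_value

    def test_zero_penalties_disjoint_windows_select_all_positive(self):
        cfg = sd.ScheduleConfig(delta=1.0, gradient_length=60.0, capacity=1,
                                tau=2, rho=1, omega_p=0.0, omega_s=0.0,
                                slot_width=2.0)
        transitions = [
            make_transition(f"t{i}", pep=f"PEP{i}", d=0.1 + 0.05 * i,
                            rt=3.0 + 6.0 * i, prot=f"P{i}")
            for i in range(8)
        ]
        targets = sd.TargetMap.from_transitions(transitions)
        grid = sd.build_slots(transitions, cfg)
        sol = sd.solve_ilp(sd.build_ilp(transitions, grid, targets, cfg))
        assert sol.selected == {t.id for t in transitions}

    def test_full_supply_reaches_occupancy_one(self):
        cfg = sd.ScheduleConfig(delta=1.0, gradient_length=20.0, capacity=3,
                                tau=1, rho=1, omega_p=0.0, omega_s=0.0,
                                slot_width=2.0)
        transitions, targets = fx.dense_schedule_instance(cfg, seed=3)
        grid = sd.build_slots(transitions, cfg)
        sol = sd.solve_ilp(sd.build_ilp(transitions, grid, targets, cfg))
        assert sol.occupancy == pytest.approx(1.0)


class TestMetrics:
    def test_occupancy_arithmetic(self):
        grid = sd.SlotGrid(
            n_slots=4, slot_width=2.5,
            membership={0: {"a", "b"}, 1: {"c"}, 2: {"d", "e"}, 3: {"f"}},
            per_peptide={}, transition_slots={},
        )
        cfg = sd.ScheduleConfig(delta=2.5, gradient_length=10.0, capacity=2)
        sol = sd.ScheduleSolution(
            selected={"a", "b", "c", "d", "e", "f"},
            peptide_uncovered={}, protein_uncovered={},
            objective_value=0.0, occupancy=0.0, solver_status="optimal",
        )
        assert sd.schedule_occupancy(sol, grid, cfg) == pytest.approx(0.75)
        sol.selected = set()
        assert sd.schedule_occupancy(sol, grid, cfg) == 0.0

    def test_assay_yield(self):
        assert round(sd.estimate_assay_yield([0.83, 0.86, 0.80]), 2) == 0.57
        assert sd.estimate_assay_yield([1.0, 1.0, 1.0]) == 1.0
        assert sd.estimate_assay_yield([]) == 1.0
        with pytest.raises(ValidationError):
            sd.estimate_assay_yield([1.2])
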