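"""Optimal SRM transition scheduling as an integer linear program.

The scheduling problem: given candidate transitions T, each with a joint
detectability d_t and a retention-time window of length 2δ around its
peptide's predicted elution time, select a subset that maximises

    Σ_t x_t d_t  −  ω^p Σ_p y_p  −  ω^s Σ_s Σ_{j=0}^{ρ−1} z_sj (ρ−j)²

subject to
  * coverage:    τ·y_p + Σ_{t ∈ T_p} x_t ≥ τ          for every peptide p,
  * protein:     (j+1)·z_sj + Σ_{p ∈ P_s} (1 − y_p) ≥ j+1
                 for every protein s and level j ∈ {0, …, ρ−1},
  * concurrency: Σ_{t ∈ T_Si} x_t ≤ C                 for every time slot i,

with all variables binary. y_p = 1 marks a peptide not covered by at
least τ transitions; z_sj = 1 marks a protein not represented by at least
j+1 covered peptides, penalised quadratically in the shortfall. The
protein constraint uses (1 − y_p) as the peptide-coverage indicator: the
coverage constraint forces y_p = 1 whenever fewer than τ of p's
transitions are selected, and the ω^p penalty drives y_p to 0 whenever
coverage is met, so at any optimum (1 − y_p) equals the nonlinear
"covered" indicator and the linearisation is exact.

The gradient [0, G) is divided into N = ceil(G / slot_width) half-open
slots; T_Si is the set of transitions whose RT window intersects slot i.
C is the instrument's concurrency limit (a few dozen transitions at best
on current triple quadrupoles).

Solved to proven optimality with branch-and-bound (HiGHS via
scipy.optimize.milp). A brute-force enumerator serves as a testing oracle
on tiny instances and a greedy heuristic as a baseline.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .digest import ValidationError
from .transitions import Transition

logger = logging.getLogger(__name__)

BRUTE_FORCE_MAX_TRANSITIONS = 20


@dataclass
class ScheduleConfig:
    """Instrument/penalty parameters of the scheduling problem."""

    delta: float = 2.5  # RT tolerance δ, minutes; windows are rt ± δ
    gradient_length: float = 60.0  # minutes
    capacity: int = 30  # C, max concurrent transitions per slot
    tau: int = 3  # τ, min transitions per covered peptide
    rho: int = 2  # ρ, min peptides per covered protein
    omega_p: float = 1.0  # ω^p, per-peptide shortfall penalty
    omega_s: float = 10.0  # ω^s, per-protein shortfall penalty weight
    slot_width: float | None = None  # defaults to delta

    def __post_init__(self) -> None:
        if self.slot_width is None:
            self.slot_width = self.delta
        if self.delta <= 0:
            raise ValidationError("delta must be > 0")
        if self.slot_width <= 0:
            raise ValidationError("slot_width must be > 0")
        if self.gradient_length <= 0:
            raise ValidationError("gradient_length must be > 0")
        if self.capacity < 1:
            raise ValidationError("capacity must be >= 1")
        if self.tau < 1:
            raise ValidationError("tau must be >= 1")
        if self.rho < 1:
            raise ValidationError("rho must be >= 1")


@dataclass
class TargetMap:
    """Protein → candidate-peptide structure the coverage penalties act on.

    Includes peptides that ended up with zero transitions (their y_p is
    forced to 1) and proteins with fewer than ρ candidate peptides (their
    top coverage levels are genuinely unreachable and stay penalised).
    """

    proteins: dict[str, tuple[str, ...]]

    @property
    def peptides(self) -> list[str]:
        seen: dict[str, None] = {}
        for peps in self.proteins.values():
            for p in peps:
                seen.setdefault(p)
        return list(seen)

    @classmethod
    def from_transitions(
        cls,
        transitions: list[Transition],
        extra: dict[str, tuple[str, ...]] | None = None,
    ) -> "TargetMap":
        proteins: dict[str, list[str]] = {}
        if extra:
            for acc in sorted(extra):
                proteins[acc] = list(dict.fromkeys(extra[acc]))
        for t in sorted(transitions, key=lambda t: t.id):
            acc = min(t.protein_accessions) if t.protein_accessions else "__unmapped__"
            peps = proteins.setdefault(acc, [])
            if t.peptide_sequence not in peps:
                peps.append(t.peptide_sequence)
        return cls(proteins={a: tuple(p) for a, p in proteins.items()})


@dataclass
class SlotGrid:
    """Discretised gradient: slot i covers [i·w, (i+1)·w)."""

    n_slots: int
    slot_width: float
    membership: dict[int, set[str]]  # slot index → transition ids
    per_peptide: dict[str, list[str]]  # peptide sequence → transition ids
    transition_slots: dict[str, list[int]]  # transition id → slot indices
    excluded: list[str] = field(default_factory=list)  # rt outside gradient


def build_slots(transitions: list[Transition], config: ScheduleConfig) -> SlotGrid:
    """Assign each transition's RT window to the slots it intersects.

    Windows are clipped at the gradient boundaries. Transitions whose
    rt_center falls outside [0, G) are excluded with a warning and listed
    in the grid for the design report.
    """
    w = config.slot_width
    n_slots = math.ceil(config.gradient_length / w)
    membership: dict[int, set[str]] = {}
    per_peptide: dict[str, list[str]] = {}
    transition_slots: dict[str, list[int]] = {}
    excluded: list[str] = []
    for t in sorted(transitions, key=lambda t: t.id):
        if not 0.0 <= t.rt_center < config.gradient_length:
            excluded.append(t.id)
            continue
        lo = max(0.0, t.rt_center - config.delta)
        hi = min(config.gradient_length, t.rt_center + config.delta)
        first = int(math.floor(lo / w))
        slots = [i for i in range(first, n_slots) if i * w < hi and (i + 1) * w > lo]
        transition_slots[t.id] = slots
        for i in slots:
            membership.setdefault(i, set()).add(t.id)
        per_peptide.setdefault(t.peptide_sequence, []).append(t.id)
    if excluded:
        warnings.warn(
            f"{len(excluded)} transitions outside the gradient were excluded "
            "from scheduling",
            stacklevel=2,
        )
    return SlotGrid(
        n_slots=n_slots,
        slot_width=w,
        membership=membership,
        per_peptide=per_peptide,
        transition_slots=transition_slots,
        excluded=excluded,
    )


@dataclass
class ScheduleSolution:
    """A selection x_t with its coverage indicators and quality metrics."""

    selected: set[str]
    peptide_uncovered: dict[str, int]  # y_p
    protein_uncovered: dict[tuple[str, int], int]  # z_sj
    objective_value: float
    occupancy: float
    solver_status: str  # optimal | feasible | infeasible-input


@dataclass
class ILPInstance:
    """The assembled integer linear program plus its index bookkeeping."""

    transition_ids: list[str]
    detectabilities: np.ndarray
    peptide_ids: list[str]
    protein_ids: list[str]
    c_maximize: np.ndarray
    constraints: list[LinearConstraint]
    grid: SlotGrid
    targets: TargetMap
    config: ScheduleConfig

    @property
    def n_variables(self) -> int:
        return len(self.c_maximize)


def build_ilp(
    transitions: list[Transition],
    grid: SlotGrid,
    targets: TargetMap,
    config: ScheduleConfig,
) -> ILPInstance:
    """Assemble variables, objective, and constraints.

    Variable layout: x_t for each schedulable transition (sorted by id),
    then y_p per peptide, then z_sj per protein × level j ∈ {0,…,ρ−1}.
    Any input yields a feasible program: x = 0, all indicators = 1.
    """
    by_id = {t.id: t for t in transitions}
    tids = sorted(tid for tid in grid.transition_slots)
    for tid in tids:
        d = by_id[tid].detectability
        if not 0.0 <= d <= 1.0:
            raise ValidationError(f"transition {tid}: detectability {d} outside [0, 1]")
    peptides = targets.peptides
    proteins = sorted(targets.proteins)
    rho, tau = config.rho, config.tau

    n_x, n_y, n_z = len(tids), len(peptides), rho * len(proteins)
    n = n_x + n_y + n_z
    x_ix = {tid: i for i, tid in enumerate(tids)}
    y_ix = {p: n_x + i for i, p in enumerate(peptides)}

    def z_ix(s_i: int, j: int) -> int:
        return n_x + n_y + s_i * rho + j

    d = np.array([by_id[tid].detectability for tid in tids])
    c = np.zeros(n)
    c[:n_x] = d
    c[n_x : n_x + n_y] = -config.omega_p
    for s_i in range(len(proteins)):
        for j in range(rho):
            c[z_ix(s_i, j)] = -config.omega_s * (rho - j) ** 2

    rows, cols, vals, lbs, ubs = [], [], [], [], []
    r = 0
    # (coverage) tau*y_p + sum_{t in T_p} x_t >= tau
    for p in peptides:
        rows.append(r); cols.append(y_ix[p]); vals.append(float(tau))
        for tid in grid.per_peptide.get(p, []):
            if tid in x_ix:
                rows.append(r); cols.append(x_ix[tid]); vals.append(1.0)
        lbs.append(float(tau)); ubs.append(np.inf)
        r += 1
    # (protein) (j+1) z_sj + sum_{p in P_s} (1 - y_p) >= j+1
    #        <=> (j+1) z_sj - sum y_p >= j+1 - |P_s|
    for s_i, s in enumerate(proteins):
        peps = targets.proteins[s]
        for j in range(rho):
            rows.append(r); cols.append(z_ix(s_i, j)); vals.append(float(j + 1))
            for p in peps:
                rows.append(r); cols.append(y_ix[p]); vals.append(-1.0)
            lbs.append(float(j + 1 - len(peps))); ubs.append(np.inf)
            r += 1
    # (concurrency) sum_{t in T_Si} x_t <= C
    for i in sorted(grid.membership):
        members = [tid for tid in sorted(grid.membership[i]) if tid in x_ix]
        if not members:
            continue
        for tid in members:
            rows.append(r); cols.append(x_ix[tid]); vals.append(1.0)
        lbs.append(-np.inf); ubs.append(float(config.capacity))
        r += 1

    constraints = []
    if r > 0 and n > 0:
        A = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n))
        constraints = [LinearConstraint(A, lbs, ubs)]

    return ILPInstance(
        transition_ids=tids,
        detectabilities=d,
        peptide_ids=peptides,
        protein_ids=proteins,
        c_maximize=c,
        constraints=constraints,
        grid=grid,
        targets=targets,
        config=config,
    )


def _canonical_solution(
    selected: set[str],
    detect: dict[str, float],
    grid: SlotGrid,
    targets: TargetMap,
    config: ScheduleConfig,
    status: str,
) -> ScheduleSolution:
    """Indicators and objective implied by a selection.

    y_p = 0 iff peptide p has >= tau selected transitions; z_sj = 0 iff at
    least j+1 of protein s's peptides are covered. Recomputing them from
    `selected` keeps reported indicators consistent even when penalty
    weights are zero and the solver leaves them slack.
    """
    y: dict[str, int] = {}
    for p in targets.peptides:
        cov = sum(1 for tid in grid.per_peptide.get(p, []) if tid in selected)
        y[p] = 0 if cov >= config.tau else 1
    z: dict[tuple[str, int], int] = {}
    obj = sum(detect[tid] for tid in selected)
    obj -= config.omega_p * sum(y.values())
    for s in sorted(targets.proteins):
        covered = sum(1 for p in targets.proteins[s] if y[p] == 0)
        for j in range(config.rho):
            z[(s, j)] = 0 if covered >= j + 1 else 1
            obj -= config.omega_s * z[(s, j)] * (config.rho - j) ** 2
    sol = ScheduleSolution(
        selected=selected,
        peptide_uncovered=y,
        protein_uncovered=z,
        objective_value=obj,
        occupancy=0.0,
        solver_status=status,
    )
    sol.occupancy = schedule_occupancy(sol, grid, config)
    return sol


def solve_ilp(ilp: ILPInstance, time_limit: float = 300.0) -> ScheduleSolution:
    """Solve to proven optimality by branch-and-bound.

    On hitting the time limit the incumbent feasible solution is returned
    with status "feasible" and a warning. The solve is deterministic under
    the fixed variable ordering of :func:`build_ilp`.
    """
    detect = dict(zip(ilp.transition_ids, ilp.detectabilities))
    if ilp.n_variables == 0:
        return _canonical_solution(
            set(), detect, ilp.grid, ilp.targets, ilp.config, "optimal"
        )
    res = milp(
        c=-ilp.c_maximize,  # milp minimises
        constraints=ilp.constraints,
        integrality=np.ones(ilp.n_variables),
        bounds=Bounds(0, 1),
        options={"time_limit": time_limit},
    )
    if res.x is None:
        # all-zero x with all indicators at 1 is always feasible, so this
        # can only mean the solver gave up before finding any incumbent
        warnings.warn("solver returned no incumbent; input treated as degenerate",
                      stacklevel=2)
        return _canonical_solution(
            set(), detect, ilp.grid, ilp.targets, ilp.config, "infeasible-input"
        )
    if res.status == 0:
        status = "optimal"
    else:
        status = "feasible"
        warnings.warn(
            f"solver stopped before proving optimality: {res.message}",
            stacklevel=2,
        )
    n_x = len(ilp.transition_ids)
    selected = {
        tid for tid, v in zip(ilp.transition_ids, res.x[:n_x]) if v > 0.5
    }
    return _canonical_solution(
        selected, detect, ilp.grid, ilp.targets, ilp.config, status
    )


def schedule(
    transitions: list[Transition],
    config: ScheduleConfig,
    targets: TargetMap | None = None,
    time_limit: float = 300.0,
) -> tuple[ScheduleSolution, SlotGrid]:
    """Convenience wrapper: build slots, assemble the ILP, and solve."""
    grid = build_slots(transitions, config)
    if targets is None:
        targets = TargetMap.from_transitions(transitions)
    ilp = build_ilp(transitions, grid, targets, config)
    return solve_ilp(ilp, time_limit=time_limit), grid


def brute_force(
    transitions: list[Transition],
    grid: SlotGrid,
    targets: TargetMap,
    config: ScheduleConfig,
) -> ScheduleSolution:
    """Exhaustive testing oracle for tiny instances (|T| <= 20).

    Enumerates capacity-feasible selections depth-first (capacity
    violations are monotone in supersets, so infeasible branches prune),
    computes exact indicators and objective for each, and returns the
    maximum; ties go to the lexicographically smallest selected-id set.
    """
    tids = sorted(grid.transition_slots)
    if len(tids) > BRUTE_FORCE_MAX_TRANSITIONS:
        raise ValidationError(
            f"brute_force guard: {len(tids)} transitions exceed the "
            f"{BRUTE_FORCE_MAX_TRANSITIONS}-transition limit"
        )
    detect = {t.id: t.detectability for t in transitions}
    slot_counts: dict[int, int] = {}
    best: list = [None, None]  # objective, sorted id tuple

    def evaluate(selected: set[str]) -> None:
        sol = _canonical_solution(
            selected, detect, grid, targets, config, "optimal"
        )
        key = tuple(sorted(selected))
        if (
            best[0] is None
            or sol.objective_value > best[0] + 1e-12
            or (abs(sol.objective_value - best[0]) <= 1e-12 and key < best[1])
        ):
            best[0], best[1] = sol.objective_value, key

    def dfs(k: int, selected: set[str]) -> None:
        if k == len(tids):
            evaluate(selected)
            return
        tid = tids[k]
        dfs(k + 1, selected)  # exclude
        if all(
            slot_counts.get(i, 0) < config.capacity
            for i in grid.transition_slots[tid]
        ):
            for i in grid.transition_slots[tid]:
                slot_counts[i] = slot_counts.get(i, 0) + 1
            selected.add(tid)
            dfs(k + 1, selected)
            selected.discard(tid)
            for i in grid.transition_slots[tid]:
                slot_counts[i] -= 1

    dfs(0, set())
    return _canonical_solution(
        set(best[1]), detect, grid, targets, config, "optimal"
    )


def greedy_schedule(
    transitions: list[Transition],
    grid: SlotGrid,
    targets: TargetMap,
    config: ScheduleConfig,
) -> ScheduleSolution:
    """Baseline heuristic: fill capacity by descending detectability.

    Visits transitions by (-d_t, id) and selects each one whose slots all
    have residual capacity; coverage indicators are computed afterwards.
    Never better than the ILP optimum, often worse when a high-d_t
    transition crowds out the transitions needed for peptide coverage.
    """
    detect = {t.id: t.detectability for t in transitions}
    order = sorted(grid.transition_slots, key=lambda tid: (-detect[tid], tid))
    residual = {i: config.capacity for i in range(grid.n_slots)}
    selected: set[str] = set()
    for tid in order:
        slots = grid.transition_slots[tid]
        if all(residual[i] > 0 for i in slots):
            for i in slots:
                residual[i] -= 1
            selected.add(tid)
    return _canonical_solution(selected, detect, grid, targets, config, "optimal")


def schedule_occupancy(
    solution: ScheduleSolution, grid: SlotGrid, config: ScheduleConfig
) -> float:
    """Fraction of total slot-capacity units (N × C) filled.

    Each selected transition contributes one unit per slot its RT window
    overlaps; a fully packed gradient scores 1.0.
    """
    filled = sum(
        len(solution.selected & members) for members in grid.membership.values()
    )
    total = grid.n_slots * config.capacity
    if total == 0:
        return 0.0
    return min(1.0, filled / total)


def estimate_assay_yield(accuracies: list[float]) -> float:
    """Probability that a designed transition is actually measurable.

    Combines the cross-validated accuracies of the independent prediction
    steps (proteotypicity, retention time, fragment intensity) as a plain
    product — the empty product is 1.0.
    """
    out = 1.0
    for a in accuracies:
        if not 0.0 <= a <= 1.0:
            raise ValidationError(f"accuracy {a} outside [0, 1]")
        out *= a
    return out
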