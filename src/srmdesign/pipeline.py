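"""End-to-end assay design: digest → predict → enumerate → schedule.

Ties the modules together in the order a user runs them: digest the
targets, mark proteotypic uniqueness against the background proteome (or
the targets themselves when none is given), annotate peptides with the
predictor bundle, enumerate and filter candidate transitions, optionally
merge a repository transition list, and solve the scheduling ILP. The
result carries everything the writers and the design report need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .digest import Peptide, ProteinRecord, digest, mark_uniqueness
from .predictors import PredictorSet
from .scheduler import (
    ScheduleConfig,
    ScheduleSolution,
    SlotGrid,
    TargetMap,
    build_ilp,
    build_slots,
    solve_ilp,
)
from .transitions import (
    DesignConfig,
    FilterReport,
    Transition,
    enumerate_transitions,
    interference_filter,
    merge_external,
)

logger = logging.getLogger(__name__)


@dataclass
class DesignResult:
    solution: ScheduleSolution
    grid: SlotGrid
    transitions: list[Transition]  # candidate set the ILP ran on
    targets: TargetMap
    report: dict = field(default_factory=dict)


def candidate_peptides(
    targets: list[ProteinRecord],
    background: list[ProteinRecord] | None = None,
    max_missed_cleavages: int = 0,
) -> list[Peptide]:
    """Digest targets and flag uniqueness against the reference proteome.

    The reference is the background proteome when supplied, otherwise the
    target set itself.
    """
    peptides: list[Peptide] = []
    for prot in targets:
        peptides.extend(digest(prot, max_missed_cleavages))
    reference = background if background else targets
    return mark_uniqueness(
        peptides, reference, max_missed_cleavages=max_missed_cleavages
    )


def design_assay(
    targets: list[ProteinRecord],
    predictors: PredictorSet,
    design_cfg: DesignConfig | None = None,
    sched_cfg: ScheduleConfig | None = None,
    background: list[ProteinRecord] | None = None,
    imported: list[Transition] | None = None,
    time_limit: float = 300.0,
) -> DesignResult:
    """Run the whole design pipeline and solve the scheduling problem."""
    design_cfg = design_cfg or DesignConfig()
    sched_cfg = sched_cfg or ScheduleConfig(
        gradient_length=design_cfg.gradient_length
    )
    report = FilterReport()

    peptides = candidate_peptides(targets, background)
    transitions = enumerate_transitions(peptides, predictors, design_cfg, report)
    transitions = interference_filter(
        transitions,
        q1_tol=design_cfg.q1_interference_tol,
        q3_tol=design_cfg.q3_interference_tol,
        delta=sched_cfg.delta,
        report=report,
    )
    if imported:
        rt_fill = predictors.rt if (predictors.rt_model or predictors.overrides.rt) \
            else None
        transitions = merge_external(
            transitions, imported, design_cfg, targets=targets, rt_fill=rt_fill
        )

    # coverage penalties act on every target protein, including those whose
    # peptides all failed the filters (reported, not silently dropped)
    protein_peptides: dict[str, tuple[str, ...]] = {
        prot.accession: tuple(
            dict.fromkeys(
                t.peptide_sequence
                for t in transitions
                if prot.accession in t.protein_accessions
            )
        )
        for prot in targets
    }
    report.proteins_without_candidates = sorted(
        acc for acc, peps in protein_peptides.items() if not peps
    )
    target_map = TargetMap(proteins=protein_peptides)

    grid = build_slots(transitions, sched_cfg)
    ilp = build_ilp(transitions, grid, target_map, sched_cfg)
    solution = solve_ilp(ilp, time_limit=time_limit)

    covered_proteins = sorted(
        acc
        for acc in protein_peptides
        if any(
            solution.peptide_uncovered.get(p, 1) == 0
            for p in protein_peptides[acc]
        )
    )
    result_report = {
        "parameters": {
            "delta_min": sched_cfg.delta,
            "gradient_length_min": sched_cfg.gradient_length,
            "capacity": sched_cfg.capacity,
            "tau": sched_cfg.tau,
            "rho": sched_cfg.rho,
            "omega_p": sched_cfg.omega_p,
            "omega_s": sched_cfg.omega_s,
            "q1_range_th": list(design_cfg.q1_range),
            "q3_range_th": list(design_cfg.q3_range),
            "charges": list(design_cfg.charges),
            "top_k_fragments": design_cfg.top_k_fragments,
            "pt_min": design_cfg.pt_min,
        },
        "n_target_proteins": len(targets),
        "n_candidate_transitions": len(transitions),
        "n_selected_transitions": len(solution.selected),
        "n_covered_peptides": sum(
            1 for v in solution.peptide_uncovered.values() if v == 0
        ),
        "n_covered_proteins": len(covered_proteins),
        "filters": report.as_dict(),
        "transitions_outside_gradient": len(grid.excluded),
        "objective_value": solution.objective_value,
        "occupancy": solution.occupancy,
        "solver_status": solution.solver_status,
    }
    return DesignResult(
        solution=solution,
        grid=grid,
        transitions=transitions,
        targets=target_map,
        report=result_report,
    )
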