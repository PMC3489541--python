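"""Candidate-transition enumeration, filtering, and hybrid-list merging.

A transition is the schedulable unit of an SRM assay: a (precursor m/z,
product m/z) pair monitored for one peptide inside a retention-time
window. This module turns annotated peptides into candidate transitions
(instrument mass-range filters, proteotypicity threshold, top-k fragments
per precursor), scores each with a joint detectability d_t, removes likely
cross-peptide interferences, and merges in pre-existing experimentally
validated transition lists for the hybrid design approach.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

from .digest import Peptide, ProteinRecord, ValidationError, digest, precursor_mz
from .predictors import FragmentIon, PredictorSet

logger = logging.getLogger(__name__)


@dataclass
class DesignConfig:
    """Instrument and candidacy parameters for transition enumeration."""

    q1_range: tuple[float, float] = (400.0, 1000.0)  # precursor filter, Th
    q3_range: tuple[float, float] = (400.0, 1200.0)  # product filter, Th
    charges: tuple[int, ...] = (2, 3)
    top_k_fragments: int = 5
    pt_min: float = 0.2
    min_peptide_length: int = 6
    max_peptide_length: int = 30
    gradient_length: float = 60.0  # minutes
    detectability_combiner: str = "product"  # product | min | geometric_mean
    q1_interference_tol: float = 0.7  # Th
    q3_interference_tol: float = 0.7  # Th
    imported_detectability: float = 1.0
    allow_unmapped_imports: bool = False

    def __post_init__(self) -> None:
        if self.q1_range[0] >= self.q1_range[1]:
            raise ValidationError(f"invalid Q1 range {self.q1_range}")
        if self.q3_range[0] >= self.q3_range[1]:
            raise ValidationError(f"invalid Q3 range {self.q3_range}")
        if self.gradient_length <= 0:
            raise ValidationError("gradient_length must be > 0")
        if self.detectability_combiner not in ("product", "min", "geometric_mean"):
            raise ValidationError(
                f"unknown detectability combiner {self.detectability_combiner!r}"
            )


@dataclass
class Transition:
    """One precursor→product ion pair with its annotations."""

    id: str
    peptide_sequence: str
    protein_accessions: frozenset[str]
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    ion_annotation: tuple[str, int, int]  # (series, position, charge)
    detectability: float
    rt_center: float  # minutes
    source: str = "predicted"  # predicted | imported

    def rt_window(self, delta: float) -> tuple[float, float]:
        return (self.rt_center - delta, self.rt_center + delta)


def joint_detectability(
    proteotypicity: float,
    fragment_relative_intensity: float,
    combiner: str = "product",
) -> float:
    """Combine peptide-level and fragment-level detectability into d_t.

    The default combiner is the product, which stays in [0, 1] and
    annihilates when either factor is hopeless; ``min`` and
    ``geometric_mean`` are available alternatives.
    """
    for name, v in (
        ("proteotypicity", proteotypicity),
        ("fragment_relative_intensity", fragment_relative_intensity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} {v} outside [0, 1]")
    if combiner == "product":
        return proteotypicity * fragment_relative_intensity
    if combiner == "min":
        return min(proteotypicity, fragment_relative_intensity)
    if combiner == "geometric_mean":
        return math.sqrt(proteotypicity * fragment_relative_intensity)
    raise ValidationError(f"unknown combiner {combiner!r}")


@dataclass
class FilterReport:
    """Why candidate peptides/fragments were dropped, for the design report."""

    non_unique_peptides: int = 0
    length_filtered_peptides: int = 0
    low_pt_peptides: int = 0
    rt_out_of_gradient_peptides: int = 0
    q1_filtered_precursors: int = 0
    q3_filtered_fragments: int = 0
    interference_removed: int = 0
    proteins_without_candidates: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "non_unique_peptides": self.non_unique_peptides,
            "length_filtered_peptides": self.length_filtered_peptides,
            "low_pt_peptides": self.low_pt_peptides,
            "rt_out_of_gradient_peptides": self.rt_out_of_gradient_peptides,
            "q1_filtered_precursors": self.q1_filtered_precursors,
            "q3_filtered_fragments": self.q3_filtered_fragments,
            "interference_removed": self.interference_removed,
            "proteins_without_candidates": list(self.proteins_without_candidates),
        }


def enumerate_transitions(
    peptides: list[Peptide],
    predictors: PredictorSet,
    config: DesignConfig,
    report: FilterReport | None = None,
) -> list[Transition]:
    """Candidate transitions for every detectable proteotypic peptide.

    For each unique peptide within the length bounds, with PT >= pt_min and
    predicted RT inside the gradient, every allowed precursor charge whose
    m/z falls in the Q1 range contributes its top-k fragments (by relative
    intensity) whose product m/z falls in the Q3 range. Transition ids are
    deterministic: ``accession_peptide_charge_ion``.
    """
    if report is None:
        report = FilterReport()
    out: list[Transition] = []
    for pep in peptides:
        if not pep.is_unique:
            report.non_unique_peptides += 1
            continue
        if not config.min_peptide_length <= len(pep) <= config.max_peptide_length:
            report.length_filtered_peptides += 1
            continue
        pt = predictors.pt(pep.sequence)
        if pt < config.pt_min:
            report.low_pt_peptides += 1
            continue
        rt = predictors.rt(pep.sequence)
        if not 0.0 <= rt < config.gradient_length:
            report.rt_out_of_gradient_peptides += 1
            continue
        acc = min(pep.parent_accessions)
        for charge in sorted(config.charges):
            pmz = precursor_mz(pep.monoisotopic_mass, charge)
            if not config.q1_range[0] <= pmz <= config.q1_range[1]:
                report.q1_filtered_precursors += 1
                continue
            kept = 0
            for ion in predictors.fragments(pep.sequence, charge):
                if kept >= config.top_k_fragments:
                    break
                if not config.q3_range[0] <= ion.mz <= config.q3_range[1]:
                    report.q3_filtered_fragments += 1
                    continue
                out.append(
                    Transition(
                        id=f"{acc}_{pep.sequence}_{charge}_"
                        f"{ion.series}{ion.position}",
                        peptide_sequence=pep.sequence,
                        protein_accessions=frozenset(pep.parent_accessions),
                        precursor_mz=pmz,
                        precursor_charge=charge,
                        product_mz=ion.mz,
                        ion_annotation=(ion.series, ion.position, ion.charge),
                        detectability=joint_detectability(
                            pt, ion.relative_intensity,
                            config.detectability_combiner,
                        ),
                        rt_center=rt,
                    )
                )
                kept += 1
    return out


def interference_filter(
    transitions: list[Transition],
    q1_tol: float = 0.7,
    q3_tol: float = 0.7,
    delta: float = 2.5,
    report: FilterReport | None = None,
) -> list[Transition]:
    """Drop the weaker of any two likely-interfering transitions.

    Two transitions of *different* peptides interfere when their precursor
    m/z differ by at most ``q1_tol``, their product m/z by at most
    ``q3_tol``, and their RT windows (rt_center ± delta) overlap. The
    higher-d_t transition survives; ties keep the lexicographically
    smaller id. The operation is idempotent.
    """
    ordered = sorted(transitions, key=lambda t: (-t.detectability, t.id))
    kept: list[Transition] = []
    for t in ordered:
        clash = False
        for k in kept:
            if k.peptide_sequence == t.peptide_sequence:
                continue
            if (
                abs(k.precursor_mz - t.precursor_mz) <= q1_tol
                and abs(k.product_mz - t.product_mz) <= q3_tol
                and _windows_overlap(k.rt_window(delta), t.rt_window(delta))
            ):
                clash = True
                break
        if clash:
            if report is not None:
                report.interference_removed += 1
        else:
            kept.append(t)
    id_order = {t.id: i for i, t in enumerate(transitions)}
    kept.sort(key=lambda t: id_order[t.id])
    return kept


def _windows_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def merge_external(
    predicted: list[Transition],
    imported: list[Transition],
    config: DesignConfig,
    targets: list[ProteinRecord] | None = None,
    rt_fill=None,
) -> list[Transition]:
    """Union of predicted and repository transitions (hybrid approach).

    Imported transitions are validated against the Q1/Q3 ranges; missing
    retention times are filled from ``rt_fill`` (a sequence → minutes
    callable, typically an RT model); missing detectability is set to the
    experimentally-validated ceiling (default 1.0). Duplicates — same
    peptide, charge and ion annotation with product m/z within 0.01 Th —
    collapse keeping the imported transition.
    """
    target_peptides: dict[str, set[str]] | None = None
    if targets is not None:
        target_peptides = {}
        for prot in targets:
            for frag in digest(prot, 0):
                target_peptides.setdefault(frag.sequence, set()).add(prot.accession)

    cleaned: list[Transition] = []
    for t in imported:
        if not config.q1_range[0] <= t.precursor_mz <= config.q1_range[1]:
            raise ValidationError(
                f"imported transition {t.id}: precursor m/z {t.precursor_mz:.4f} "
                f"outside Q1 range {config.q1_range}"
            )
        if not config.q3_range[0] <= t.product_mz <= config.q3_range[1]:
            raise ValidationError(
                f"imported transition {t.id}: product m/z {t.product_mz:.4f} "
                f"outside Q3 range {config.q3_range}"
            )
        if math.isnan(t.rt_center):
            if rt_fill is None:
                raise ValidationError(
                    f"imported transition {t.id} has no retention time and no "
                    "RT model is available to fill it"
                )
            t = replace(t, rt_center=float(rt_fill(t.peptide_sequence)))
        if math.isnan(t.detectability):
            t = replace(t, detectability=config.imported_detectability)
        if target_peptides is not None:
            accs = target_peptides.get(t.peptide_sequence)
            if accs is None:
                warnings.warn(
                    f"imported transition {t.id}: peptide "
                    f"{t.peptide_sequence} is not a tryptic peptide of any "
                    "target protein",
                    stacklevel=2,
                )
                if not config.allow_unmapped_imports:
                    continue
                t = replace(t, protein_accessions=frozenset())
            else:
                t = replace(t, protein_accessions=frozenset(accs))
        t = replace(t, source="imported")
        cleaned.append(t)

    def dup_key(t: Transition):
        series, position, charge = t.ion_annotation
        return (t.peptide_sequence, t.precursor_charge, series, position, charge)

    merged: dict = {}
    for t in predicted:
        merged[dup_key(t)] = t
    for t in cleaned:
        key = dup_key(t)
        prev = merged.get(key)
        if prev is not None and abs(prev.product_mz - t.product_mz) > 0.01:
            # same annotation but incompatible mass: keep both, distinct ids
            merged[key + ("imported",)] = t
        else:
            merged[key] = t
    return list(merged.values())
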