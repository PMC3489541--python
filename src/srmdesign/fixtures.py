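"""Deterministic synthetic data for exercising the whole pipeline.

Real assay development starts from a shotgun training run on the target
instrument and a protein mixture of interest; these generators emulate
that setting at desk scale: random proteomes with tryptic-peptide-friendly
K/R content, identification tables whose retention times follow a known
linear composition model (so parameter recovery is checkable), and small
random scheduling instances for the solver oracle suite. Every generator
is a pure function of its spec/seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .digest import ProteinRecord, digest
from .predictors import IdentifiedPeptideRecord
from .scheduler import ScheduleConfig, TargetMap
from .transitions import Transition

logger = logging.getLogger(__name__)

_RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")


def _default_rt_coefficients() -> dict[str, float]:
    # loosely hydrophobicity-ordered contributions, minutes per residue,
    # scaled so typical tryptic peptides spread across a 60-min gradient
    return {
        "A": 1.2, "C": 0.6, "D": -1.5, "E": -1.2, "F": 4.8,
        "G": 0.0, "H": -2.4, "I": 5.4, "K": -3.0, "L": 5.7,
        "M": 3.0, "N": -1.2, "P": 0.9, "Q": -0.9, "R": -2.7,
        "S": -0.3, "T": 0.3, "V": 4.2, "W": 5.1, "Y": 2.4,
    }


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 7
    n_proteins: int = 48  # mirrors a 48-protein standard mixture
    protein_length: tuple[int, int] = (120, 360)
    rt_intercept: float = 20.0  # minutes
    rt_coefficient_table: dict[str, float] = field(
        default_factory=_default_rt_coefficients
    )
    rt_noise_sd: float = 0.5  # minutes
    gradient_length: float = 60.0  # minutes
    # q-values uniform on [0, q_value_max]: with the 0.01 identification
    # cutoff this leaves ~9% of records above the cutoff
    q_value_max: float = 0.011
    duplicate_fraction: float = 0.10
    detectability_beta: tuple[float, float] = (2.0, 2.0)
    # P(peptide identified) = sigmoid(a + b·mean_hydropathy): shotgun runs
    # miss peptides, preferentially the poorly-ionising hydrophilic ones,
    # which leaves undetected peptides to serve as proteotypicity negatives
    detection_logit: tuple[float, float] = (0.8, 0.9)

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if self.protein_length[0] < 10 or self.protein_length[0] > self.protein_length[1]:
            raise ValueError(f"invalid protein_length {self.protein_length}")


# residue sampling weights: K and R boosted to ~5% each so fully-cleaved
# tryptic peptides are typically 6-25 residues long
def _residue_probs() -> np.ndarray:
    p = np.full(len(_RESIDUES), 0.9 / 18)
    for aa in "KR":
        p[_RESIDUES.index(aa)] = 0.05
    return p / p.sum()


def synthetic_proteome(spec: FixtureSpec) -> list[ProteinRecord]:
    """Random proteins with tryptic-friendly composition.

    Each protein is resampled until its digest yields at least one peptide
    of length >= 6, so downstream candidacy is never vacuously empty.
    """
    rng = np.random.default_rng(spec.seed)
    probs = _residue_probs()
    proteins: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        while True:
            length = int(rng.integers(spec.protein_length[0],
                                      spec.protein_length[1] + 1))
            seq = "".join(rng.choice(_RESIDUES, size=length, p=probs))
            rec = ProteinRecord(accession=f"SYN{i + 1:04d}", sequence=seq)
            if any(len(p) >= 6 for p in digest(rec, 0)):
                proteins.append(rec)
                break
    return proteins


def true_rt(sequence: str, spec: FixtureSpec) -> float:
    """Ground-truth retention time of the generating linear model."""
    rt = spec.rt_intercept
    for aa, coef in spec.rt_coefficient_table.items():
        rt += coef * sequence.count(aa)
    return rt


def synthetic_rt_table(
    proteome: list[ProteinRecord], spec: FixtureSpec
) -> list[IdentifiedPeptideRecord]:
    """Identification table with known RT structure.

    RT = intercept + Σ coef·count + N(0, rt_noise_sd), clipped to the
    gradient; q-values uniform on [0, q_value_max]; TIC log-uniform over
    [1e4, 1e7]. A duplicate_fraction of records is re-emitted with a
    different TIC to exercise TIC-based deduplication.
    """
    from .predictors import KYTE_DOOLITTLE

    rng = np.random.default_rng(spec.seed + 1)
    a, b = spec.detection_logit
    records: list[IdentifiedPeptideRecord] = []
    for prot in proteome:
        for pep in digest(prot, 0):
            if not 6 <= len(pep) <= 30:
                continue
            kd = sum(KYTE_DOOLITTLE[aa] for aa in pep.sequence) / len(pep)
            p_detect = 1.0 / (1.0 + np.exp(-(a + b * kd)))
            if rng.uniform() > p_detect:
                continue
            rt = true_rt(pep.sequence, spec) + rng.normal(0.0, spec.rt_noise_sd) \
                if spec.rt_noise_sd > 0 else true_rt(pep.sequence, spec)
            rt = float(np.clip(rt, 0.0, spec.gradient_length))
            records.append(
                IdentifiedPeptideRecord(
                    sequence=pep.sequence,
                    charge=2,
                    retention_time=rt,
                    q_value=float(rng.uniform(0.0, spec.q_value_max)),
                    tic=float(10 ** rng.uniform(4.0, 7.0)),
                )
            )
    n_dup = int(len(records) * spec.duplicate_fraction)
    if n_dup:
        picks = rng.choice(len(records), size=n_dup, replace=False)
        for i in picks:
            base = records[int(i)]
            records.append(
                IdentifiedPeptideRecord(
                    sequence=base.sequence,
                    charge=base.charge,
                    retention_time=base.retention_time,
                    q_value=base.q_value,
                    tic=float(10 ** rng.uniform(4.0, 7.0)),
                )
            )
    return records


def write_rt_table(records: list[IdentifiedPeptideRecord], path) -> None:
    """Emit the tab-separated training-table format the pipeline consumes."""
    with open(path, "w") as fh:
        fh.write("sequence\tcharge\trt\tq_value\ttic\n")
        for r in records:
            fh.write(
                f"{r.sequence}\t{r.charge}\t{r.retention_time:.4f}"
                f"\t{r.q_value:.6f}\t{r.tic:.1f}\n"
            )


def read_rt_table(path) -> list[IdentifiedPeptideRecord]:
    import pandas as pd

    from .digest import ValidationError

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sequence", "charge", "rt", "q_value", "tic"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: training table lacks columns {sorted(missing)}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                IdentifiedPeptideRecord(
                    sequence=row["sequence"],
                    charge=int(row["charge"]),
                    retention_time=float(row["rt"]),
                    q_value=float(row["q_value"]),
                    tic=float(row["tic"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(
                f"{path}: malformed training row at line {idx + 2}: {exc}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# Scheduler instances
# ---------------------------------------------------------------------------

def synthetic_schedule_instance(
    n_transitions: int,
    n_peptides: int,
    n_proteins: int,
    seed: int,
    gradient_length: float = 60.0,
    detectability_beta: tuple[float, float] = (2.0, 2.0),
) -> tuple[list[Transition], TargetMap]:
    """Random scheduling instance for oracle-equivalence and stress tests.

    Peptides are assigned to proteins and transitions to peptides
    uniformly at random (every peptide/protein gets at least one child
    when counts allow); rt_centers are uniform on the gradient and
    detectabilities Beta-distributed.
    """
    rng = np.random.default_rng(seed)
    pep_names = [f"PEP{i:03d}" for i in range(n_peptides)]
    prot_names = [f"PROT{i:02d}" for i in range(n_proteins)]
    pep_to_prot = {
        pep_names[i]: prot_names[i % n_proteins] if i < n_proteins * 1
        else prot_names[int(rng.integers(n_proteins))]
        for i in range(n_peptides)
    }
    # ensure each protein owns >= 1 peptide where possible
    for i, prot in enumerate(prot_names):
        if i < n_peptides:
            pep_to_prot[pep_names[i]] = prot

    a, b = detectability_beta
    transitions = []
    for i in range(n_transitions):
        pep = pep_names[i % n_peptides] if i < n_peptides \
            else pep_names[int(rng.integers(n_peptides))]
        transitions.append(
            Transition(
                id=f"t{i:03d}",
                peptide_sequence=pep,
                protein_accessions=frozenset({pep_to_prot[pep]}),
                precursor_mz=500.0 + i,
                precursor_charge=2,
                product_mz=700.0 + i,
                ion_annotation=("y", 3, 1),
                detectability=float(rng.beta(a, b)),
                rt_center=float(rng.uniform(0.0, gradient_length)),
            )
        )
    proteins: dict[str, list[str]] = {p: [] for p in prot_names}
    for pep in pep_names:
        proteins[pep_to_prot[pep]].append(pep)
    targets = TargetMap(proteins={p: tuple(v) for p, v in proteins.items()})
    return transitions, targets


def dense_schedule_instance(
    config: ScheduleConfig, per_slot: int | None = None, seed: int = 0
) -> tuple[list[Transition], TargetMap]:
    """Instance where every slot is overlapped by >= C disjoint-peptide
    transitions, so a fully packed (occupancy 1.0) schedule exists."""
    per_slot = per_slot if per_slot is not None else config.capacity
    n_slots = int(np.ceil(config.gradient_length / config.slot_width))
    rng = np.random.default_rng(seed)
    transitions = []
    proteins: dict[str, list[str]] = {}
    k = 0
    for i in range(n_slots):
        # centre of slot i; window length 2δ >= slot width, so it covers
        # the slot regardless of clipping at the gradient edges
        centre = min((i + 0.5) * config.slot_width,
                     config.gradient_length - 1e-9)
        for _ in range(per_slot):
            pep = f"DPEP{k:04d}"
            prot = f"DPROT{k:04d}"
            proteins[prot] = [pep]
            transitions.append(
                Transition(
                    id=f"d{k:04d}",
                    peptide_sequence=pep,
                    protein_accessions=frozenset({prot}),
                    precursor_mz=500.0,
                    precursor_charge=2,
                    product_mz=700.0,
                    ion_annotation=("y", 3, 1),
                    detectability=float(rng.uniform(0.5, 1.0)),
                    rt_center=centre,
                )
            )
            k += 1
    targets = TargetMap(proteins={p: tuple(v) for p, v in proteins.items()})
    return transitions, targets


def greedy_trap_instance() -> tuple[list[Transition], TargetMap, ScheduleConfig]:
    """Instance where the greedy heuristic provably underperforms the ILP.

    One decoy transition (d=0.9) of a peptide that can never reach τ=2
    coverage shares a slot with one of the two d=0.6 transitions needed to
    cover peptide A. Greedy grabs the decoy first and blocks A's coverage;
    the optimum forgoes the decoy.
    """
    config = ScheduleConfig(
        delta=1.0, gradient_length=10.0, capacity=1, tau=2, rho=1,
        omega_p=1.0, omega_s=1.0, slot_width=2.0,
    )
    mk = lambda tid, pep, prot, d, rt: Transition(
        id=tid, peptide_sequence=pep, protein_accessions=frozenset({prot}),
        precursor_mz=500.0, precursor_charge=2, product_mz=700.0,
        ion_annotation=("y", 3, 1), detectability=d, rt_center=rt,
    )
    transitions = [
        mk("a1", "PEPA", "PROTA", 0.6, 1.0),  # slot 0
        mk("a2", "PEPA", "PROTA", 0.6, 3.0),  # slot 1
        mk("x1", "PEPX", "PROTX", 0.9, 1.0),  # slot 0, blocks a1
    ]
    targets = TargetMap(proteins={"PROTA": ("PEPA",), "PROTX": ("PEPX",)})
    return transitions, targets, config
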