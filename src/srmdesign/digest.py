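"""In-silico tryptic digestion and peptide mass arithmetic.

Proteins are cleaved C-terminal to K or R except when the next residue is
proline. Peptide masses are monoisotopic, with carbamidomethylation of
cysteine as the (default-on) fixed modification, matching standard
triple-quadrupole transition-list conventions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)

WATER_MONO = 18.010565
PROTON_MASS = 1.007276
CARBAMIDOMETHYL_DELTA = 57.021464


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def validate_sequence(sequence: str, *, what: str = "sequence") -> str:
    """Check that ``sequence`` is a non-empty string of canonical residues.

    Returns the sequence unchanged; raises :class:`ValidationError` naming
    the offending position otherwise.
    """
    if not sequence:
        raise ValidationError(f"{what} is empty")
    for i, aa in enumerate(sequence):
        if aa not in CANONICAL_RESIDUES:
            raise ValidationError(
                f"{what} contains non-canonical residue {aa!r} at position {i + 1}"
            )
    return sequence


@dataclass(frozen=True)
class ProteinRecord:
    """A target or background protein sequence with its accession."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession is empty")
        validate_sequence(self.sequence, what=f"protein {self.accession}")


@dataclass
class Peptide:
    """A tryptic peptide with parent links and optional annotations."""

    sequence: str
    parent_accessions: set[str] = field(default_factory=set)
    missed_cleavages: int = 0
    monoisotopic_mass: float = 0.0
    is_unique: bool = False
    #: position of the first residue within the (first) parent protein, 0-based
    start: int = 0

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, what="peptide")
        if self.monoisotopic_mass == 0.0:
            self.monoisotopic_mass = monoisotopic_mass(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def monoisotopic_mass(sequence: str, *, carbamidomethyl: bool = True) -> float:
    """Monoisotopic peptide mass in Da.

    Sum of residue masses plus one water; carbamidomethylation adds
    57.021464 Da per cysteine when enabled (the default, matching the
    fixed-modification convention used for training data).
    """
    validate_sequence(sequence)
    m = WATER_MONO + sum(RESIDUE_MASSES[aa] for aa in sequence)
    if carbamidomethyl:
        m += CARBAMIDOMETHYL_DELTA * sequence.count("C")
    return m


def precursor_mz(mass: float, charge: int) -> float:
    """m/z of a peptide ion: (M + z·m_proton) / z."""
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cleaves (K/R not before P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed_cleavages: int = 0,
    *,
    carbamidomethyl: bool = True,
) -> list[Peptide]:
    """Tryptic digest of ``protein``.

    With 0 missed cleavages the returned peptides, concatenated in order,
    reproduce the protein sequence. With n allowed missed cleavages, every
    contiguous join of at most n+1 consecutive fully-cleaved fragments is
    additionally returned, annotated with its missed-cleavage count.
    """
    if max_missed_cleavages < 0:
        raise ValidationError("max_missed_cleavages must be >= 0")
    seq = protein.sequence
    sites = cleavage_sites(seq)
    bounds = [0] + [s + 1 for s in sites] + [len(seq)]
    fragments = [
        (bounds[i], seq[bounds[i] : bounds[i + 1]]) for i in range(len(bounds) - 1)
    ]

    peptides: list[Peptide] = []
    for n_joined in range(1, max_missed_cleavages + 2):
        for i in range(len(fragments) - n_joined + 1):
            start = fragments[i][0]
            joined = "".join(f[1] for f in fragments[i : i + n_joined])
            peptides.append(
                Peptide(
                    sequence=joined,
                    parent_accessions={protein.accession},
                    missed_cleavages=n_joined - 1,
                    monoisotopic_mass=monoisotopic_mass(
                        joined, carbamidomethyl=carbamidomethyl
                    ),
                    start=start,
                )
            )
    return peptides


def mark_uniqueness(
    peptides: list[Peptide],
    reference: list[ProteinRecord],
    *,
    max_missed_cleavages: int = 0,
    il_equivalent: bool = False,
) -> list[Peptide]:
    """Flag each peptide as proteotypic-unique against a reference proteome.

    A peptide is unique iff its sequence occurs as a tryptic peptide of
    exactly one reference protein. When no background proteome is available
    the target set itself serves as the reference. ``il_equivalent`` treats
    isoleucine and leucine as indistinguishable.
    """
    if not reference:
        warnings.warn(
            "empty reference proteome: all peptides flagged non-unique",
            stacklevel=2,
        )
        for pep in peptides:
            pep.is_unique = False
        return peptides

    def canon(s: str) -> str:
        return s.replace("I", "L") if il_equivalent else s

    origin: dict[str, set[str]] = {}
    for prot in reference:
        for frag in digest(prot, max_missed_cleavages):
            origin.setdefault(canon(frag.sequence), set()).add(prot.accession)

    for pep in peptides:
        parents = origin.get(canon(pep.sequence), set())
        pep.is_unique = len(parents) == 1
        if parents:
            pep.parent_accessions |= parents
    return peptides
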