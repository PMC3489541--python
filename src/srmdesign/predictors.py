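"""Trainable peptide-property predictors and training-data preparation.

Three peptide properties drive transition design: retention time RT(p),
proteotypicity PT(p) (the probability that a peptide is observable at all),
and fragment-ion intensities FI(p). Full-strength predictors for these are
substantial machine-learning systems in their own right; this module ships
deliberately simple, documented models behind a pluggable interface —

* RT: ridge regression on residue counts plus length,
* PT: L2-regularised logistic regression on physicochemical features,
* FI: a deterministic rule table encoding qualitative mobile-proton
  behaviour (y over b, proline enhancement, acidic enhancement when the
  proton is sequestered),

and every prediction can be overridden from a file of externally computed
values, so better predictors slot in without code changes.

Training-data preparation follows the shotgun-identification protocol:
TIC-based deduplication per (sequence, charge), positives as the best
1,000 identifications by q-value at a 0.01 cutoff, and negatives as
never-identified tryptic peptides from proteins with at least 15%
sequence coverage whose theoretical doubly-charged m/z is in range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import (
    CARBAMIDOMETHYL_DELTA,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MONO,
    Peptide,
    ProteinRecord,
    ValidationError,
    digest,
    monoisotopic_mass,
    precursor_mz,
    validate_sequence,
)

logger = logging.getLogger(__name__)

RESIDUES = sorted(RESIDUE_MASSES)

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

MIN_RT_TRAINING_EXAMPLES = 40
RECOMMENDED_PT_EXAMPLES = 1000


@dataclass(frozen=True)
class IdentifiedPeptideRecord:
    """One peptide-spectrum identification from a shotgun search."""

    sequence: str
    charge: int
    retention_time: float  # minutes
    q_value: float
    tic: float = 0.0

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if not 0.0 <= self.q_value <= 1.0:
            raise ValidationError(f"q_value {self.q_value} outside [0, 1]")
        if self.retention_time < 0:
            raise ValidationError(f"retention_time {self.retention_time} < 0")
        if self.tic < 0:
            raise ValidationError(f"tic {self.tic} < 0")


# ---------------------------------------------------------------------------
# Training-data preparation
# ---------------------------------------------------------------------------

def dedupe_by_tic(
    records: list[IdentifiedPeptideRecord],
) -> list[IdentifiedPeptideRecord]:
    """Keep, per (sequence, charge), the record with the highest TIC.

    Ties are broken by first occurrence; output order follows the first
    occurrence of each key, so the result is independent of duplicate
    placement.
    """
    best: dict[tuple[str, int], IdentifiedPeptideRecord] = {}
    for rec in records:
        key = (rec.sequence, rec.charge)
        if key not in best or rec.tic > best[key].tic:
            best[key] = rec
    return list(best.values())


def select_training_positives(
    records: list[IdentifiedPeptideRecord],
    q_cutoff: float = 0.01,
    n: int = 1000,
) -> list[IdentifiedPeptideRecord]:
    """Best ``n`` identifications with q-value <= ``q_cutoff``.

    Sorted ascending by q-value with a stable sort, so ties keep input
    order. Emptiness is legal here; RT training enforces its own minimum.
    """
    kept = [r for r in records if r.q_value <= q_cutoff]
    kept.sort(key=lambda r: r.q_value)  # Timsort: stable
    return kept[:n]


def select_training_negatives(
    identified: list[IdentifiedPeptideRecord],
    proteome: list[ProteinRecord],
    coverage_min: float = 0.15,
    mz_range: tuple[float, float] = (400.0, 1000.0),
    n: int = 1000,
) -> list[Peptide]:
    """Undetected tryptic peptides from well-covered proteins.

    A protein qualifies when the fraction of its residues covered by
    identified peptide sequences is at least ``coverage_min``. From
    qualifying proteins, tryptic peptides that were never identified
    anywhere in the dataset and whose theoretical doubly-charged m/z lies
    in ``mz_range`` are returned in deterministic (accession, position)
    order, truncated to ``n``.
    """
    identified_seqs = {r.sequence for r in identified}
    max_cov = 0.0
    negatives: list[Peptide] = []
    for prot in sorted(proteome, key=lambda p: p.accession):
        fragments = digest(prot, 0)
        covered = sum(len(f) for f in fragments if f.sequence in identified_seqs)
        cov = covered / len(prot.sequence)
        max_cov = max(max_cov, cov)
        if cov < coverage_min:
            continue
        for frag in fragments:
            if frag.sequence in identified_seqs:
                continue
            mz = precursor_mz(frag.monoisotopic_mass, 2)
            if mz_range[0] <= mz <= mz_range[1]:
                negatives.append(frag)
    if max_cov < coverage_min:
        raise ValidationError(
            f"no protein reaches sequence coverage {coverage_min:.2f}; "
            f"maximum observed coverage is {max_cov:.3f}"
        )
    return negatives[:n]


# ---------------------------------------------------------------------------
# Retention-time model
# ---------------------------------------------------------------------------

def _rt_design_matrix(sequences: list[str]) -> np.ndarray:
    X = np.zeros((len(sequences), len(RESIDUES) + 1))
    for i, seq in enumerate(sequences):
        for j, aa in enumerate(RESIDUES):
            X[i, j] = seq.count(aa)
        X[i, -1] = len(seq)
    return X


@dataclass
class RTModel:
    """Linear retention-time model: RT = b0 + Σ coef[aa]·count + c_len·length."""

    intercept: float
    residue_coefficients: dict[str, float]
    length_coefficient: float
    training_rmse: float
    ridge_lambda: float = 1.0

    def predict(self, sequence: str) -> float:
        validate_sequence(sequence)
        rt = self.intercept + self.length_coefficient * len(sequence)
        for aa, coef in self.residue_coefficients.items():
            rt += coef * sequence.count(aa)
        return float(rt)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "residue_coefficients": self.residue_coefficients,
            "length_coefficient": self.length_coefficient,
            "training_rmse": self.training_rmse,
            "ridge_lambda": self.ridge_lambda,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RTModel":
        return cls(
            intercept=d["intercept"],
            residue_coefficients=dict(d["residue_coefficients"]),
            length_coefficient=d["length_coefficient"],
            training_rmse=d["training_rmse"],
            ridge_lambda=d.get("ridge_lambda", 1.0),
        )


def train_rt(
    examples: list[tuple[str, float]],
    ridge_lambda: float = 1.0,
) -> RTModel:
    """Fit the linear RT model by ridge-regularised least squares.

    Requires at least 40 annotated peptides (a calibration run of that size
    suffices to characterise a chromatographic setup). The intercept is
    unpenalised; ``ridge_lambda=0`` gives the ordinary least-squares /
    minimum-norm fit, which interpolates noiseless realizable data.
    """
    if len(examples) < MIN_RT_TRAINING_EXAMPLES:
        raise ValidationError(
            f"RT training needs at least {MIN_RT_TRAINING_EXAMPLES} examples, "
            f"got {len(examples)}"
        )
    sequences = [s for s, _ in examples]
    for s in sequences:
        validate_sequence(s)
    y = np.array([rt for _, rt in examples], dtype=float)
    X = _rt_design_matrix(sequences)
    # centre so the intercept is unpenalised
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc, yc = X - x_mean, y - y_mean
    if ridge_lambda > 0:
        A = Xc.T @ Xc + ridge_lambda * np.eye(X.shape[1])
        beta = np.linalg.solve(A, Xc.T @ yc)
    else:
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    intercept = y_mean - x_mean @ beta
    resid = y - (X @ beta + intercept)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return RTModel(
        intercept=float(intercept),
        residue_coefficients={aa: float(beta[j]) for j, aa in enumerate(RESIDUES)},
        length_coefficient=float(beta[-1]),
        training_rmse=rmse,
        ridge_lambda=ridge_lambda,
    )


def predict_rt(model: RTModel, sequence: str) -> float:
    """Predicted retention time in minutes (deterministic, finite)."""
    return model.predict(sequence)


# ---------------------------------------------------------------------------
# Proteotypicity model
# ---------------------------------------------------------------------------

PT_FEATURE_NAMES = (
    ["length", "monoisotopic_mass", "mean_hydropathy", "frac_acidic",
     "frac_basic", "frac_aromatic"]
    + [f"comp_{aa}" for aa in RESIDUES]
)


def _pt_features(sequences: list[str]) -> np.ndarray:
    X = np.zeros((len(sequences), len(PT_FEATURE_NAMES)))
    for i, seq in enumerate(sequences):
        L = len(seq)
        X[i, 0] = L
        X[i, 1] = monoisotopic_mass(seq)
        X[i, 2] = sum(KYTE_DOOLITTLE[aa] for aa in seq) / L
        X[i, 3] = sum(seq.count(aa) for aa in "DE") / L
        X[i, 4] = sum(seq.count(aa) for aa in "KRH") / L
        X[i, 5] = sum(seq.count(aa) for aa in "FWY") / L
        for j, aa in enumerate(RESIDUES):
            X[i, 6 + j] = seq.count(aa) / L
    return X


@dataclass
class PTModel:
    """Logistic proteotypicity model over physicochemical features."""

    feature_weights: dict[str, float]
    bias: float
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_scales: dict[str, float] = field(default_factory=dict)

    def predict(self, sequence: str) -> float:
        validate_sequence(sequence)
        x = _pt_features([sequence])[0]
        z = self.bias
        for j, name in enumerate(PT_FEATURE_NAMES):
            mu = self.feature_means.get(name, 0.0)
            sd = self.feature_scales.get(name, 1.0)
            z += self.feature_weights[name] * (x[j] - mu) / sd
        return float(1.0 / (1.0 + np.exp(-z)))

    def to_dict(self) -> dict:
        return {
            "feature_weights": self.feature_weights,
            "bias": self.bias,
            "feature_means": self.feature_means,
            "feature_scales": self.feature_scales,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PTModel":
        return cls(
            feature_weights=dict(d["feature_weights"]),
            bias=d["bias"],
            feature_means=dict(d.get("feature_means", {})),
            feature_scales=dict(d.get("feature_scales", {})),
        )


def train_pt(
    positives: list[Peptide],
    negatives: list[Peptide],
    l2_strength: float = 1.0,
) -> PTModel:
    """Fit the logistic proteotypicity model.

    Classes below 1,000 examples each trigger a warning (performance
    degrades with small training sets); an empty class is an error.
    Features are z-scored with training-set statistics stored in the model.
    """
    from sklearn.linear_model import LogisticRegression

    if not positives or not negatives:
        raise ValidationError("PT training needs both positive and negative examples")
    if len(positives) < RECOMMENDED_PT_EXAMPLES or len(negatives) < RECOMMENDED_PT_EXAMPLES:
        warnings.warn(
            f"PT training below the recommended {RECOMMENDED_PT_EXAMPLES} "
            f"examples per class ({len(positives)} pos / {len(negatives)} neg)",
            stacklevel=2,
        )
    seqs = [p.sequence for p in positives] + [p.sequence for p in negatives]
    y = np.array([1] * len(positives) + [0] * len(negatives))
    X = _pt_features(seqs)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no information
    Xz = (X - mu) / sd
    clf = LogisticRegression(
        C=1.0 / l2_strength, solver="lbfgs", max_iter=2000, random_state=0
    )
    clf.fit(Xz, y)
    return PTModel(
        feature_weights={
            name: float(w) for name, w in zip(PT_FEATURE_NAMES, clf.coef_[0])
        },
        bias=float(clf.intercept_[0]),
        feature_means={name: float(m) for name, m in zip(PT_FEATURE_NAMES, mu)},
        feature_scales={name: float(s) for name, s in zip(PT_FEATURE_NAMES, sd)},
    )


def predict_pt(model: PTModel, sequence: str) -> float:
    """Proteotypicity probability in [0, 1]."""
    return model.predict(sequence)


# ---------------------------------------------------------------------------
# Fragment-ion intensities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentIon:
    series: str  # "b" or "y"
    position: int  # 1 .. len-1
    charge: int
    mz: float
    relative_intensity: float


# rule table: qualitative mobile-proton behaviour
BASE_INTENSITY = {"y": 1.0, "b": 0.5}
PROLINE_FACTOR = 3.0  # cleavage N-terminal to proline
ACIDIC_FACTOR = 2.0  # cleavage C-terminal to D/E when the proton is sequestered
_TIE_EPS = 1e-9


def predict_fragments(
    sequence: str,
    precursor_charge: int,
    *,
    carbamidomethyl: bool = True,
) -> list[FragmentIon]:
    """Singly-charged b/y ions with rule-table relative intensities.

    For cleavage site i (between residues i and i+1, 1-based) the b_i and
    y_{L-i} ions share site multipliers: x3 when residue i+1 is proline,
    x2 when residue i is D/E and the peptide's R+K+H count is at least the
    precursor charge (no mobile proton). Base intensities favour y over b;
    b1 is suppressed (rarely observed). A monotone length-fraction factor
    spreads the series so intensities are distinct, and intensities are
    normalised to max 1.0, with exactly one ion at 1.0 (ties broken toward
    the y series, then the lowest position).
    """
    validate_sequence(sequence)
    if precursor_charge < 1:
        raise ValidationError(f"precursor_charge must be >= 1, got {precursor_charge}")
    L = len(sequence)
    if L < 2:
        raise ValidationError("fragment prediction needs a peptide of length >= 2")

    def res_mass(aa: str) -> float:
        m = RESIDUE_MASSES[aa]
        if carbamidomethyl and aa == "C":
            m += CARBAMIDOMETHYL_DELTA
        return m

    basic_count = sum(sequence.count(aa) for aa in "RKH")
    proton_sequestered = basic_count >= precursor_charge

    raw: list[tuple[str, int, float, float]] = []  # series, position, mz, score
    prefix = 0.0
    for i in range(1, L):  # cleavage site after residue i (1-based)
        prefix += res_mass(sequence[i - 1])
        mult = 1.0
        if sequence[i] == "P":
            mult *= PROLINE_FACTOR
        if sequence[i - 1] in "DE" and proton_sequestered:
            mult *= ACIDIC_FACTOR
        # b_i ion: prefix of length i
        b_score = 0.0 if i == 1 else BASE_INTENSITY["b"] * mult
        b_score *= 0.6 + 0.4 * i / (L - 1)
        b_mz = prefix + PROTON_MASS
        if b_score > 0:
            raw.append(("b", i, b_mz, b_score))
        # y_{L-i} ion: suffix of length L-i
        y_pos = L - i
        y_score = BASE_INTENSITY["y"] * mult * (0.6 + 0.4 * y_pos / (L - 1))
        suffix_mass = monoisotopic_mass(sequence, carbamidomethyl=carbamidomethyl) \
            - WATER_MONO - prefix
        y_mz = suffix_mass + WATER_MONO + PROTON_MASS
        raw.append(("y", y_pos, y_mz, y_score))

    # designate the unique base peak: highest score, ties to y then low position
    raw.sort(key=lambda r: (-r[3], r[0] != "y", r[1]))
    max_score = raw[0][3]
    ions = []
    for rank, (se, po, mz, s) in enumerate(raw):
        rel = s / max_score
        if rank > 0 and rel >= 1.0:  # demote exact ties with the base peak
            rel = 1.0 - _TIE_EPS
        ions.append(
            FragmentIon(series=se, position=po, charge=1, mz=mz,
                        relative_intensity=rel)
        )
    return ions


# ---------------------------------------------------------------------------
# Prediction overrides and the pluggable predictor bundle
# ---------------------------------------------------------------------------

@dataclass
class PredictionOverrides:
    """Externally computed predictions that take precedence over models."""

    rt: dict[str, float] = field(default_factory=dict)
    pt: dict[str, float] = field(default_factory=dict)
    fragments: dict[str, list[FragmentIon]] = field(default_factory=dict)


def import_predictions(path) -> PredictionOverrides:
    """Read a tab-separated override table.

    Header must contain ``sequence`` plus any of ``rt``, ``pt``, or the
    fragment triple ``series``/``position``/``intensity``. Values from the
    table override model predictions for the listed peptides.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sequence" not in df.columns:
        raise ValidationError("override table lacks required 'sequence' column")
    has_frag = {"series", "position", "intensity"} <= set(df.columns)
    if not ({"rt", "pt"} & set(df.columns) or has_frag):
        raise ValidationError(
            "override table needs 'rt', 'pt', or series/position/intensity columns"
        )
    ov = PredictionOverrides()
    frag_raw: dict[str, list[tuple[str, int, float]]] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        seq = row["sequence"]
        try:
            validate_sequence(seq)
            if "rt" in df.columns and row["rt"] != "":
                ov.rt[seq] = float(row["rt"])
            if "pt" in df.columns and row["pt"] != "":
                pt = float(row["pt"])
                if not 0.0 <= pt <= 1.0:
                    raise ValidationError(f"pt value {pt} outside [0, 1]")
                ov.pt[seq] = pt
            if has_frag and row["series"] != "":
                series = row["series"]
                if series not in ("b", "y"):
                    raise ValidationError(f"unknown ion series {series!r}")
                frag_raw.setdefault(seq, []).append(
                    (series, int(row["position"]), float(row["intensity"]))
                )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"malformed override row at line {line_no}: {exc}") from exc
    for seq, triples in frag_raw.items():
        peak = max(inten for _, _, inten in triples)
        if peak <= 0:
            raise ValidationError(f"all fragment intensities non-positive for {seq}")
        ions = []
        for series, pos, inten in triples:
            mz = _fragment_mz(seq, series, pos)
            ions.append(FragmentIon(series, pos, 1, mz, inten / peak))
        ions.sort(key=lambda f: (-f.relative_intensity, f.series != "y", f.position))
        ov.fragments[seq] = ions
    return ov


def _fragment_mz(sequence: str, series: str, position: int, *,
                 carbamidomethyl: bool = True) -> float:
    sub = sequence[:position] if series == "b" else sequence[-position:]
    m = monoisotopic_mass(sub, carbamidomethyl=carbamidomethyl)
    if series == "b":
        return m - WATER_MONO + PROTON_MASS
    return m + PROTON_MASS


@dataclass
class PredictorSet:
    """Bundle of RT/PT/FI predictors with file-based overrides applied."""

    rt_model: RTModel | None = None
    pt_model: PTModel | None = None
    overrides: PredictionOverrides = field(default_factory=PredictionOverrides)

    def rt(self, sequence: str) -> float:
        if sequence in self.overrides.rt:
            return self.overrides.rt[sequence]
        if self.rt_model is None:
            raise ValidationError(
                f"no retention time available for {sequence}: "
                "train an RT model or provide an override table"
            )
        return self.rt_model.predict(sequence)

    def pt(self, sequence: str) -> float:
        if sequence in self.overrides.pt:
            return self.overrides.pt[sequence]
        if self.pt_model is None:
            raise ValidationError(
                f"no proteotypicity available for {sequence}: "
                "train a PT model or provide an override table"
            )
        return self.pt_model.predict(sequence)

    def fragments(self, sequence: str, precursor_charge: int) -> list[FragmentIon]:
        if sequence in self.overrides.fragments:
            return self.overrides.fragments[sequence]
        return predict_fragments(sequence, precursor_charge)
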