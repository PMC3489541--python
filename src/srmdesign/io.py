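"""Readers and writers for the formats the design pipeline speaks.

FASTA in; tab-separated transition lists and a simplified TraML subset in
and out; a YAML key-value configuration file; and a plain-text/JSON design
report. All writers are deterministic byte-for-byte for identical inputs:
fixed column order, fixed float formatting, no timestamps.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path

import yaml
from Bio import SeqIO
from lxml import etree

from .digest import ProteinRecord, ValidationError
from .scheduler import ScheduleConfig, ScheduleSolution
from .transitions import DesignConfig, Transition

logger = logging.getLogger(__name__)

TRAML_NS = "http://psi.hupo.org/ms/traml"

TRANSITION_LIST_COLUMNS = [
    "protein", "peptide", "precursor_mz", "precursor_charge",
    "product_mz", "ion_annotation", "rt_start", "rt_stop", "detectability",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; accession is the first token after ``>``.

    Wrapped sequence lines are concatenated; lowercase residues are
    upcased with a warning; duplicate accessions and malformed files are
    errors.
    """
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValidationError(
                    f"{path}: line {line_no}: expected a '>' header before "
                    "sequence data"
                )
            break
        else:
            raise ValidationError(f"{path}: empty FASTA file")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if not acc:
            raise ValidationError(f"{path}: record with empty accession")
        if acc in seen:
            raise ValidationError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(
                f"{path}: lowercase residues in {acc} upcased", stacklevel=2
            )
            seq = seq.upper()
        records.append(ProteinRecord(accession=acc, sequence=seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV transition lists
# ---------------------------------------------------------------------------

def _format_ion(annotation: tuple[str, int, int]) -> str:
    series, position, charge = annotation
    return f"{series}{position}/{charge}"

def _parse_ion(text: str) -> tuple[str, int, int]:
    body, _, charge = text.partition("/")
    series = body[0]
    if series not in ("b", "y") or not body[1:].isdigit():
        raise ValidationError(f"cannot parse ion annotation {text!r}")
    return (series, int(body[1:]), int(charge) if charge else 1)


def _scheduled_rows(
    solution: ScheduleSolution,
    transitions: list[Transition],
    config: ScheduleConfig,
) -> list[list[str]]:
    rows = []
    for t in transitions:
        if t.id not in solution.selected:
            continue
        rt_start = max(0.0, t.rt_center - config.delta)
        rt_stop = min(config.gradient_length, t.rt_center + config.delta)
        rows.append([
            ";".join(sorted(t.protein_accessions)),
            t.peptide_sequence,
            f"{t.precursor_mz:.4f}",
            str(t.precursor_charge),
            f"{t.product_mz:.4f}",
            _format_ion(t.ion_annotation),
            f"{rt_start:.2f}",
            f"{rt_stop:.2f}",
            f"{t.detectability:.6f}",
        ])
    rows.sort(key=lambda r: (float(r[6]), float(r[2]), r[1], r[5]))
    return rows


def write_transition_list(
    solution: ScheduleSolution,
    transitions: list[Transition],
    config: ScheduleConfig,
    path,
) -> None:
    """Write the scheduled transitions as a TSV document.

    m/z to 4 decimals, retention times to 2; rows sorted by rt_start then
    precursor m/z. RT windows are rt_center ± δ clipped to the gradient.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(TRANSITION_LIST_COLUMNS) + "\n")
        for row in _scheduled_rows(solution, transitions, config):
            fh.write("\t".join(row) + "\n")


def read_transition_list(path, source: str = "imported") -> list[Transition]:
    """Read a TSV transition list (own output or a repository export).

    Requires protein, peptide, precursor_mz, precursor_charge, product_mz
    and ion_annotation columns; retention time comes from an ``rt`` column
    or the midpoint of rt_start/rt_stop, else is left unset (NaN) for a
    later model fill. Missing detectability is NaN.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein", "peptide", "precursor_mz", "precursor_charge",
                "product_mz", "ion_annotation"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: transition list lacks columns {sorted(missing)}"
        )
    out: list[Transition] = []
    for idx, row in df.iterrows():
        line_no = idx + 2
        try:
            ion = _parse_ion(row["ion_annotation"])
            if "rt" in df.columns and row["rt"] != "":
                rt = float(row["rt"])
            elif (
                "rt_start" in df.columns
                and row.get("rt_start", "") != ""
                and row.get("rt_stop", "") != ""
            ):
                rt = (float(row["rt_start"]) + float(row["rt_stop"])) / 2.0
            else:
                rt = math.nan
            det = (
                float(row["detectability"])
                if "detectability" in df.columns and row["detectability"] != ""
                else math.nan
            )
            charge = int(row["precursor_charge"])
            accs = frozenset(a for a in row["protein"].split(";") if a)
            out.append(
                Transition(
                    id=f"{min(accs) if accs else 'NA'}_{row['peptide']}_"
                    f"{charge}_{ion[0]}{ion[1]}",
                    peptide_sequence=row["peptide"],
                    protein_accessions=accs,
                    precursor_mz=float(row["precursor_mz"]),
                    precursor_charge=charge,
                    product_mz=float(row["product_mz"]),
                    ion_annotation=ion,
                    detectability=det,
                    rt_center=rt,
                    source=source,
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(
                f"{path}: malformed transition row at line {line_no}: {exc}"
            ) from exc
    return out


# ---------------------------------------------------------------------------
# Simplified TraML subset
# ---------------------------------------------------------------------------
# The subset covers exactly what round-trips through this tool: a protein
# list, a peptide (compound) list with retention times, and transitions
# with precursor/product m/z cvParams plus userParams for the ion
# annotation, detectability and RT window. Vendor extensions outside the
# subset are ignored on read, with a warning.

def _cv(parent, accession: str, name: str, value: str) -> None:
    etree.SubElement(
        parent, f"{{{TRAML_NS}}}cvParam",
        cvRef="MS", accession=accession, name=name, value=value,
    )

def _user(parent, name: str, value: str) -> None:
    etree.SubElement(parent, f"{{{TRAML_NS}}}userParam", name=name, value=value)


def write_traml(
    solution: ScheduleSolution,
    transitions: list[Transition],
    config: ScheduleConfig,
    path,
) -> None:
    """Write selected transitions in the simplified TraML subset."""
    nsmap = {None: TRAML_NS}
    root = etree.Element(f"{{{TRAML_NS}}}TraML", nsmap=nsmap, version="1.0.0")
    selected = [t for t in transitions if t.id in solution.selected]
    selected.sort(key=lambda t: t.id)

    prot_list = etree.SubElement(root, f"{{{TRAML_NS}}}ProteinList")
    accessions = sorted({a for t in selected for a in t.protein_accessions})
    for acc in accessions:
        etree.SubElement(prot_list, f"{{{TRAML_NS}}}Protein", id=acc)

    comp_list = etree.SubElement(root, f"{{{TRAML_NS}}}CompoundList")
    seen_pep: dict[tuple[str, int], str] = {}
    for t in selected:
        key = (t.peptide_sequence, t.precursor_charge)
        if key in seen_pep:
            continue
        pep_id = f"pep_{t.peptide_sequence}_{t.precursor_charge}"
        seen_pep[key] = pep_id
        pep = etree.SubElement(
            comp_list, f"{{{TRAML_NS}}}Peptide",
            id=pep_id, sequence=t.peptide_sequence,
        )
        for acc in sorted(t.protein_accessions):
            etree.SubElement(pep, f"{{{TRAML_NS}}}ProteinRef", ref=acc)
        rt_el = etree.SubElement(
            etree.SubElement(pep, f"{{{TRAML_NS}}}RetentionTimeList"),
            f"{{{TRAML_NS}}}RetentionTime",
        )
        _cv(rt_el, "MS:1000895", "local retention time", f"{t.rt_center:.4f}")

    tr_list = etree.SubElement(root, f"{{{TRAML_NS}}}TransitionList")
    for t in selected:
        el = etree.SubElement(
            tr_list, f"{{{TRAML_NS}}}Transition",
            id=t.id, peptideRef=seen_pep[(t.peptide_sequence, t.precursor_charge)],
        )
        prec = etree.SubElement(el, f"{{{TRAML_NS}}}Precursor")
        _cv(prec, "MS:1000827", "isolation window target m/z",
            f"{t.precursor_mz:.4f}")
        _cv(prec, "MS:1000041", "charge state", str(t.precursor_charge))
        prod = etree.SubElement(el, f"{{{TRAML_NS}}}Product")
        _cv(prod, "MS:1000827", "isolation window target m/z",
            f"{t.product_mz:.4f}")
        _user(el, "ion_annotation", _format_ion(t.ion_annotation))
        _user(el, "detectability", f"{t.detectability:.6f}")
        rt_start = max(0.0, t.rt_center - config.delta)
        rt_stop = min(config.gradient_length, t.rt_center + config.delta)
        _user(el, "rt_start", f"{rt_start:.2f}")
        _user(el, "rt_stop", f"{rt_stop:.2f}")

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_traml(path) -> list[Transition]:
    """Read the simplified TraML subset back into transitions.

    Elements outside the subset are ignored with a warning; transitions
    come back with source="imported" and NaN retention time when the
    document carries none for their peptide.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    ns = {"t": TRAML_NS}

    pep_rt: dict[str, float] = {}
    pep_seq: dict[str, str] = {}
    pep_prots: dict[str, frozenset[str]] = {}
    for pep in root.findall(".//t:CompoundList/t:Peptide", ns):
        pid = pep.get("id")
        pep_seq[pid] = pep.get("sequence")
        pep_prots[pid] = frozenset(
            ref.get("ref") for ref in pep.findall("t:ProteinRef", ns)
        )
        for cv in pep.findall(".//t:RetentionTime/t:cvParam", ns):
            if cv.get("accession") == "MS:1000895":
                pep_rt[pid] = float(cv.get("value"))

    out: list[Transition] = []
    foreign = 0
    for el in root.findall(".//t:TransitionList/t:Transition", ns):
        pid = el.get("peptideRef")
        if pid not in pep_seq:
            raise ValidationError(
                f"{path}: transition {el.get('id')!r} references unknown "
                f"peptide {pid!r}"
            )
        prec_mz = charge = prod_mz = None
        for cv in el.findall("t:Precursor/t:cvParam", ns):
            if cv.get("accession") == "MS:1000827":
                prec_mz = float(cv.get("value"))
            elif cv.get("accession") == "MS:1000041":
                charge = int(cv.get("value"))
        for cv in el.findall("t:Product/t:cvParam", ns):
            if cv.get("accession") == "MS:1000827":
                prod_mz = float(cv.get("value"))
        if prec_mz is None or prod_mz is None or charge is None:
            raise ValidationError(
                f"{path}: transition {el.get('id')!r} lacks precursor/product "
                "m/z or charge cvParams"
            )
        params = {u.get("name"): u.get("value")
                  for u in el.findall("t:userParam", ns)}
        known = {"ion_annotation", "detectability", "rt_start", "rt_stop"}
        foreign += len(set(params) - known)
        ion = _parse_ion(params["ion_annotation"]) if "ion_annotation" in params \
            else ("y", 1, 1)
        det = float(params["detectability"]) if "detectability" in params \
            else math.nan
        rt = pep_rt.get(pid, math.nan)
        out.append(
            Transition(
                id=el.get("id"),
                peptide_sequence=pep_seq[pid],
                protein_accessions=pep_prots[pid],
                precursor_mz=prec_mz,
                precursor_charge=charge,
                product_mz=prod_mz,
                ion_annotation=ion,
                detectability=det,
                rt_center=rt,
                source="imported",
            )
        )
    if foreign:
        warnings.warn(
            f"{path}: ignored {foreign} vendor userParams outside the "
            "supported TraML subset",
            stacklevel=2,
        )
    return out


def validate_traml_subset(path) -> None:
    """Structural check of the simplified subset; raises on violation."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    if etree.QName(root).localname != "TraML":
        raise ValidationError(f"{path}: root element is not TraML")
    ns = {"t": TRAML_NS}
    pep_ids = {p.get("id") for p in root.findall(".//t:CompoundList/t:Peptide", ns)}
    prot_ids = {p.get("id") for p in root.findall(".//t:ProteinList/t:Protein", ns)}
    for pep in root.findall(".//t:CompoundList/t:Peptide", ns):
        if not pep.get("sequence"):
            raise ValidationError(f"{path}: peptide {pep.get('id')!r} lacks sequence")
        for ref in pep.findall("t:ProteinRef", ns):
            if ref.get("ref") not in prot_ids:
                raise ValidationError(
                    f"{path}: dangling ProteinRef {ref.get('ref')!r}"
                )
    for el in root.findall(".//t:TransitionList/t:Transition", ns):
        if el.get("peptideRef") not in pep_ids:
            raise ValidationError(
                f"{path}: dangling peptideRef {el.get('peptideRef')!r}"
            )
        if el.find("t:Precursor", ns) is None or el.find("t:Product", ns) is None:
            raise ValidationError(
                f"{path}: transition {el.get('id')!r} lacks Precursor/Product"
            )


# ---------------------------------------------------------------------------
# Configuration and design report
# ---------------------------------------------------------------------------

def load_config(path) -> tuple[DesignConfig, ScheduleConfig]:
    """Read a YAML config with optional ``design:`` and ``schedule:`` maps.

    Keys mirror the DesignConfig and ScheduleConfig field names; unknown
    keys are rejected so typos fail loudly.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    design_kw = dict(raw.get("design", {}))
    sched_kw = dict(raw.get("schedule", {}))
    for section, kw, cls in (
        ("design", design_kw, DesignConfig),
        ("schedule", sched_kw, ScheduleConfig),
    ):
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(
                f"{path}: unknown {section} config keys {sorted(unknown)}"
            )
    for key in ("q1_range", "q3_range", "charges"):
        if key in design_kw:
            design_kw[key] = tuple(design_kw[key])
    return DesignConfig(**design_kw), ScheduleConfig(**sched_kw)


def write_report(report: dict, path) -> None:
    """Write the design report as deterministic, sorted JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def format_report(report: dict) -> str:
    """Human-readable rendering of a design report."""
    lines = ["SRM design report", "================="]
    for key in sorted(report):
        value = report[key]
        if isinstance(value, dict):
            lines.append(f"{key}:")
            lines.extend(f"  {k}: {value[k]}" for k in sorted(value))
        elif isinstance(value, list):
            lines.append(f"{key}: {', '.join(map(str, value)) or '(none)'}")
        else:
            lines.append(f"{key}: {value}")
    return "\n".join(lines) + "\n"
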