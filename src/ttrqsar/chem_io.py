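"""Compound table I/O, curation, and endpoint derivation.

Reads tables of PFAS (id, CASRN, SMILES, assay values), canonicalizes the
structures, applies the curation rules used for QSAR-ready datasets (single
component, neutral, metal-free, non-polymeric, deduplicated in non-chiral
form), and derives the two modelling endpoints:

* binary activity class ``A`` (active) / ``I`` (weak/not active) from the
  median displacement activity of the ANSA competitive binding assay, with
  the active cutoff at a median activity >= 50%;
* ``Log RP``, the log10 relative competitive potency, defined from EC50
  values as log10(mean_j(EC50_T4 / EC50_compound,j)).  Positive Log RP means
  the compound binds hTTR more strongly than the natural ligand T4.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements accepted in a curated organic structure.  Anything else marks the
#: record as an organometal / inorganic and excludes it.
ORGANIC_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "F", "S", "P", "Cl", "Br", "I", "Si", "B"}
)

ACTIVE_CUTOFF = 50.0  # median activity (%) at or above which a compound is class A


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries the record id."""

    def __init__(self, smiles: str, record_id: Optional[str] = None):
        self.smiles = smiles
        self.record_id = record_id
        where = f" (record {record_id})" if record_id else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


class ClassificationConflictError(ValueError):
    """Replicate median-activity values straddle the 50% cutoff."""


@dataclass
class CompoundRecord:
    """One compound with optional assay data.

    ``median_activity`` holds replicate median-activity percentages (0-100);
    ``ec50`` holds replicate half-maximal effect concentrations in µM.
    """

    id: str
    smiles: str
    casrn: Optional[str] = None
    median_activity: Optional[list[float]] = None
    ec50: Optional[list[float]] = None
    activity_class: Optional[str] = None
    log_rp: Optional[float] = None


@dataclass
class CurationReport:
    kept: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"kept": self.kept, "excluded": [list(e) for e in self.excluded]},
            indent=2,
        )


@dataclass
class CurationRules:
    """Switches for the structure-curation policy."""

    strip_stereo: bool = True
    drop_duplicates: bool = True
    allowed_elements: frozenset[str] = ORGANIC_ELEMENTS


def canonicalize_smiles(
    smiles: str, strip_stereo: bool = True, record_id: Optional[str] = None
) -> str:
    """Return the canonical SMILES of ``smiles``.

    Deterministic and idempotent; with ``strip_stereo`` (default) all
    stereochemical markers are removed first, so stereoisomers map to one
    canonical non-chiral form.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, record_id)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol, canonical=True)


def _exclusion_reason(smiles: str, rules: CurationRules) -> Optional[str]:
    """Reason to exclude a single (parseable) structure, or None if it passes."""
    if "*" in smiles:
        return "polymer"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return "ambiguous_identifier"
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        # dot-disconnected: ionic/metal component => salt, otherwise mixture
        for frag in frags:
            atoms = list(frag.GetAtoms())
            if any(a.GetFormalCharge() != 0 for a in atoms):
                return "salt"
            if len(atoms) == 1 and atoms[0].GetSymbol() not in rules.allowed_elements:
                return "salt"
        return "mixture"
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in rules.allowed_elements:
            return "organometal"
    if Chem.GetFormalCharge(mol) != 0 or any(
        a.GetFormalCharge() != 0 for a in mol.GetAtoms()
    ):
        return "charged"
    return None


def curate(
    records: Sequence[CompoundRecord], rules: Optional[CurationRules] = None
) -> tuple[list[CompoundRecord], CurationReport]:
    """Apply the curation policy; problems become exclusion reasons, not errors.

    Output records carry canonical (stereo-stripped, by default) SMILES.
    Duplicates by canonical SMILES are collapsed to the first occurrence.
    """
    rules = rules or CurationRules()
    report = CurationReport()
    kept: list[CompoundRecord] = []
    seen: dict[str, str] = {}
    for rec in records:
        if not rec.smiles or not rec.smiles.strip():
            report.excluded.append((rec.id, "no_structure"))
            continue
        reason = _exclusion_reason(rec.smiles, rules)
        if reason is not None:
            report.excluded.append((rec.id, reason))
            continue
        canon = canonicalize_smiles(rec.smiles, strip_stereo=rules.strip_stereo)
        if rules.drop_duplicates and canon in seen:
            report.excluded.append((rec.id, "duplicate"))
            continue
        seen[canon] = rec.id
        out = CompoundRecord(
            id=rec.id,
            smiles=canon,
            casrn=rec.casrn,
            median_activity=rec.median_activity,
            ec50=rec.ec50,
            activity_class=rec.activity_class,
            log_rp=rec.log_rp,
        )
        if out.median_activity and out.activity_class is None:
            out.activity_class = assign_activity_class(out.median_activity)
        kept.append(out)
        report.kept.append(rec.id)
    return kept, report


def assign_activity_class(median_activity: Iterable[float]) -> str:
    """Class ``A`` if the median activity is >= 50%, else ``I``.

    Replicate values must agree on the side of the cutoff; values straddling
    50% raise :class:`ClassificationConflictError`.
    """
    values = [float(v) for v in median_activity]
    if not values:
        raise ValueError("at least one median-activity value required")
    for v in values:
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"median activity {v} outside [0, 100]")
    classes = {"A" if v >= ACTIVE_CUTOFF else "I" for v in values}
    if len(classes) > 1:
        raise ClassificationConflictError(
            f"replicate activities {values} straddle the {ACTIVE_CUTOFF}% cutoff"
        )
    return classes.pop()


def compute_log_rp(t4_ec50: float, pfas_ec50: Iterable[float]) -> float:
    """log10 relative competitive potency from EC50 values (µM).

    RP_j = EC50_T4 / EC50_j for each replicate j; the arithmetic mean of the
    RP values is log10-transformed.  A compound more potent than T4 (smaller
    EC50) gives Log RP > 0.
    """
    values = [float(v) for v in pfas_ec50]
    if t4_ec50 <= 0 or any(v <= 0 for v in values):
        raise ValueError("EC50 concentrations must be positive")
    if not values:
        raise ValueError("at least one EC50 value required")
    rp = [t4_ec50 / v for v in values]
    return math.log10(sum(rp) / len(rp))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_compound_csv(path: str) -> list[CompoundRecord]:
    """Read a compound table: columns id, casrn, smiles, median_activity,
    ec50_um; repeated assay values are semicolon-separated."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            med = row.get("median_activity") or ""
            ec = row.get("ec50_um") or ""
            records.append(
                CompoundRecord(
                    id=row["id"],
                    smiles=row.get("smiles", ""),
                    casrn=row.get("casrn") or None,
                    median_activity=[float(v) for v in med.split(";") if v] or None,
                    ec50=[float(v) for v in ec.split(";") if v] or None,
                )
            )
    return records


def read_smiles_file(path: str) -> list[CompoundRecord]:
    """Plain SMILES file: one per line, optional whitespace-separated id."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            rid = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(CompoundRecord(id=rid, smiles=smiles))
    return records


def write_compound_csv(records: Sequence[CompoundRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "casrn", "smiles", "median_activity", "ec50_um", "activity_class", "log_rp"]
        )
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.casrn or "",
                    r.smiles,
                    ";".join(str(v) for v in (r.median_activity or [])),
                    ";".join(str(v) for v in (r.ec50 or [])),
                    r.activity_class or "",
                    "" if r.log_rp is None else r.log_rp,
                ]
            )
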