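"""Structure and activity handling for the colchicine training library.

Canonicalization, randomized-SMILES augmentation, stereocenter assignment at
the colchicine C7 position, and reading/writing of the activity table
(SMILES + per-cell-line IC50 in nM).
"""

from __future__ import annotations

import csv
import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import rdCIPLabeler
from rdkit.Chem.rdchem import HybridizationType


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class SchemaError(ValueError):
    """Raised when an input table is missing required columns."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES of ``smiles``.

    The same molecule written under any atom ordering maps to one canonical
    form; stereochemistry markers are preserved.
    """
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def enumerate_random_smiles(smiles: str, n: int, seed: int) -> list[str]:
    """Enumerate up to ``n`` distinct SMILES renderings of one molecule.

    Randomized atom orderings give alternative, equivalent strings for the
    same structure — the augmentation trick that turns a 120-compound library
    into a corpus large enough for sequence-model training.  Output strings
    are pairwise distinct and all canonicalize back to ``canonicalize(smiles)``;
    fewer than ``n`` are returned when the molecule admits fewer renderings.
    Deterministic for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = _mol_from_smiles(smiles)
    # Over-request to compensate for duplicate renderings, then deduplicate
    # preserving first-seen order.
    raw = Chem.MolToRandomSmilesVect(mol, max(4 * n, n + 16), randomSeed=seed)
    seen: dict[str, None] = {}
    for s in raw:
        if s not in seen:
            seen[s] = None
        if len(seen) == n:
            break
    return list(seen)


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: raw SMILES, canonical form, and a validity flag."""

    id: str
    smiles: str
    canonical_smiles: str | None = None
    is_valid: bool = True

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "MoleculeRecord":
        try:
            canonical = canonicalize(smiles)
        except InvalidSmilesError:
            return cls(id=id or smiles, smiles=smiles, canonical_smiles=None, is_valid=False)
        return cls(id=id or canonical, smiles=smiles, canonical_smiles=canonical, is_valid=True)

    @property
    def mol(self) -> Chem.Mol:
        return _mol_from_smiles(self.smiles)


class CellLine(enum.Enum):
    """The five assay cell lines.

    LoVo/DX (doxorubicin-resistant) and LoVo form the fixed pair for the
    resistance index; BALB/3T3 is the normal line used by the selectivity
    index.
    """

    A549 = "A549"
    BALB3T3 = "BALB/3T3"
    LOVODX = "LoVo/DX"
    LOVO = "LoVo"
    MCF7 = "MCF-7"

    @property
    def label(self) -> str:
        return self.value

    @property
    def is_cancer(self) -> bool:
        return self is not CellLine.BALB3T3


#: Resistant/parental pair used by the resistance index.
RI_PAIR = (CellLine.LOVODX, CellLine.LOVO)


def to_pic50(ic50_nM: float) -> float:
    """Transform an IC50 in nM to pIC50 = -log10(IC50 [M]) = 9 - log10(nM)."""
    if not ic50_nM > 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def from_pic50(pic50: float) -> float:
    """Inverse of :func:`to_pic50`; returns IC50 in nM."""
    return 10.0 ** (9.0 - pic50)


@dataclass
class ActivityRecord:
    """A training compound with per-cell-line IC50 (nM) and derived pIC50."""

    molecule: MoleculeRecord
    ic50_nM: dict[CellLine, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for line, value in self.ic50_nM.items():
            if not value > 0:
                raise ValueError(f"non-positive IC50 for {line.label}: {value}")

    @property
    def pic50(self) -> dict[CellLine, float]:
        return {line: to_pic50(v) for line, v in self.ic50_nM.items()}

    @property
    def missing_lines(self) -> list[CellLine]:
        return [line for line in CellLine if line not in self.ic50_nM]


_PM_SPLIT = re.compile(r"\s*(?:±|\+/-|\+-)\s*")


def _parse_ic50_cell(cell: str) -> float | None:
    """Parse an IC50 cell like ``54.9 ± 22.0``; the spread is discarded."""
    text = str(cell).strip()
    if not text or text.lower() in {"nan", "na", "-", ""}:
        return None
    mean = _PM_SPLIT.split(text)[0].strip()
    return float(mean)


def read_activity_table(path: str | Path, smiles_column: str = "smiles") -> list[ActivityRecord]:
    """Read a CSV activity table into :class:`ActivityRecord` objects.

    The table must have a SMILES column and at least one recognized
    cell-line column (``A549``, ``BALB/3T3``, ``LoVo/DX``, ``LoVo``,
    ``MCF-7``).  ``± error`` suffixes are stripped to the mean.  Missing
    cell-line values are permitted and simply absent from the record.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if smiles_column not in header:
            raise SchemaError(f"missing SMILES column {smiles_column!r}; found {header}")
        by_label = {line.label: line for line in CellLine}
        line_columns = [c for c in header if c in by_label]
        if not line_columns:
            raise SchemaError(f"no recognized cell-line column among {header}")
        records: list[ActivityRecord] = []
        for i, row in enumerate(reader):
            mol = MoleculeRecord.from_smiles(row[smiles_column], id=f"row{i}")
            if not mol.is_valid:
                raise InvalidSmilesError(f"row {i}: unparseable SMILES {row[smiles_column]!r}")
            ic50: dict[CellLine, float] = {}
            for col in line_columns:
                value = _parse_ic50_cell(row[col])
                if value is None:
                    continue
                if not value > 0:
                    raise ValueError(f"row {i}: non-positive IC50 {value} for {col}")
                ic50[by_label[col]] = value
            records.append(ActivityRecord(molecule=mol, ic50_nM=ic50))
    return records


def write_activity_table(records: list[ActivityRecord], path: str | Path) -> None:
    """Write a normalized CSV: canonical SMILES plus IC50 and pIC50 columns."""
    path = Path(path)
    lines = list(CellLine)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "smiles"]
            + [line.label for line in lines]
            + [f"pIC50_{line.label}" for line in lines]
        )
        for rec in records:
            pic = rec.pic50
            writer.writerow(
                [rec.molecule.id, rec.molecule.canonical_smiles]
                + [rec.ic50_nM.get(line, "") for line in lines]
                + [round(pic[line], 6) if line in pic else "" for line in lines]
            )


def assign_c7_configuration(smiles: str) -> str:
    """CIP descriptor (``"S"``/``"R"``/``"undefined"``) of the colchicine C7 atom.

    C7 is located structurally rather than by atom index: the sp3 ring-B
    carbon (member of a seven-membered carbocycle fused to an aromatic ring)
    bearing an exocyclic nitrogen substituent.  Returns ``"undefined"`` when
    no such stereocenter exists or its configuration is unspecified.
    """
    mol = _mol_from_smiles(smiles)
    rdCIPLabeler.AssignCIPLabels(mol)
    ring_info = mol.GetRingInfo()
    aromatic_rings = [set(r) for r in ring_info.AtomRings()
                      if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)]
    candidates = []
    for ring in ring_info.AtomRings():
        if len(ring) != 7:
            continue
        ring_set = set(ring)
        fused_aromatic = any(len(ring_set & ar) >= 2 for ar in aromatic_rings)
        for idx in ring:
            atom = mol.GetAtomWithIdx(idx)
            if atom.GetSymbol() != "C" or atom.GetHybridization() != HybridizationType.SP3:
                continue
            if any(n.GetSymbol() == "N" and not n.IsInRing() for n in atom.GetNeighbors()):
                candidates.append((fused_aromatic, atom))
    if not candidates:
        return "undefined"
    # Prefer the benzylic position (ring fused to the aromatic A-ring).
    candidates.sort(key=lambda t: not t[0])
    atom = candidates[0][1]
    if atom.HasProp("_CIPCode"):
        return atom.GetProp("_CIPCode")
    return "undefined"


def build_augmented_corpus(
    smiles_list: list[str], n_per_molecule: int = 1200, seed: int = 0
) -> list[tuple[str, str]]:
    """Enumerate renderings for a whole library.

    Returns ``(canonical_smiles, rendering)`` pairs, distinct at the string
    level within each molecule.  Each molecule gets an independent stream
    derived from ``seed``.
    """
    corpus: list[tuple[str, str]] = []
    for k, smi in enumerate(smiles_list):
        canonical = canonicalize(smi)
        renderings = enumerate_random_smiles(smi, n_per_molecule, seed=(seed + k) % (2**31 - 1))
        corpus.extend((canonical, r) for r in renderings)
    return corpus
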