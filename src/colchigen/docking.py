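"""File-level adapter around an external docking engine.

The engine itself (an AutoDock-Vina-style command) is injected by
configuration and exchanged with through files: this module prepares 3D
ligands from SMILES, writes the search-box configuration, parses the
engine's tabular result logs, and summarizes best affinities against
reference energies (the docked colchicine and the receptor's native ligand).
Nothing here implements scoring or pose search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .corpus import InvalidSmilesError, _mol_from_smiles

#: Search box used for the tubulin colchicine site (receptor PDB 1SA0).
DEFAULT_BOX_CENTER = (119.743, 92.779, 10.765)
DEFAULT_BOX_SIZE = (44.0, 44.0, 60.0)

#: Reference best affinities (kcal/mol): redocked colchicine and the ligand
#: natively present in the receptor structure.
COLCHICINE_REF = -8.2
NATIVE_REF = -8.6


class ConformerError(RuntimeError):
    """Raised when 3D embedding of a ligand fails."""


class EngineLogError(ValueError):
    """Raised for malformed docking-engine output."""


@dataclass(frozen=True)
class DockingBox:
    center: tuple[float, float, float] = DEFAULT_BOX_CENTER
    size: tuple[float, float, float] = DEFAULT_BOX_SIZE

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.size):
            raise ValueError(f"box sizes must be positive, got {self.size}")

    def to_config(self, receptor: str | None = None, exhaustiveness: int = 8) -> str:
        """Engine configuration text (``center_x`` ... ``size_z``)."""
        lines = []
        if receptor:
            lines.append(f"receptor = {receptor}")
        for axis, c, s in zip("xyz", self.center, self.size):
            lines.append(f"center_{axis} = {c}")
        for axis, s in zip("xyz", self.size):
            lines.append(f"size_{axis} = {s}")
        lines.append(f"exhaustiveness = {exhaustiveness}")
        return "\n".join(lines) + "\n"


def prepare_ligand(smiles: str, seed: int = 0) -> str:
    """Embed one low-energy 3D conformer and return it as a PDB block.

    Hydrogens are added (neutral-pH protonation as written in the SMILES),
    the conformer is generated with a seeded distance-geometry embedding and
    relaxed with the MMFF94 force field.  The block converts to PDBQT with
    standard tools.  Deterministic given ``seed``.
    """
    mol = _mol_from_smiles(smiles)
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise ConformerError(f"3D embedding failed for {smiles!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol)
    except Exception:
        pass  # an unrelaxed conformer is still usable
    return Chem.MolToPDBBlock(mol)


@dataclass
class DockingResult:
    ligand_id: str
    best_affinity: float
    n_poses: int

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("a result with an affinity must have >= 1 pose")


def parse_engine_log(text: str, ligand_id: str = "") -> DockingResult:
    """Parse an engine result table (mode / affinity / RMSD columns).

    The best affinity is the mode-1 row; ``n_poses`` is the number of rows.
    """
    rows = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) >= 2 and parts[0].lstrip("+-").isdigit():
            try:
                rows.append((int(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise EngineLogError(f"malformed result row: {line!r}") from exc
    if not rows:
        raise EngineLogError("no result rows found in engine log")
    rows.sort(key=lambda r: r[0])
    return DockingResult(ligand_id=ligand_id, best_affinity=rows[0][1], n_poses=len(rows))


def synthesize_engine_log(result: DockingResult) -> str:
    """Render a result as the engine's log dialect (parse round-trips)."""
    header = (
        "mode |   affinity | dist from best mode\n"
        "     | (kcal/mol) | rmsd l.b.| rmsd u.b.\n"
        "-----+------------+----------+----------\n"
    )
    rows = []
    for mode in range(1, result.n_poses + 1):
        affinity = result.best_affinity if mode == 1 else result.best_affinity + 0.1 * (mode - 1)
        rows.append(f"{mode:>4}    {affinity:>8.1f}      0.000      0.000")
    return header + "\n".join(rows) + "\n"


@dataclass
class AffinitySummary:
    """Partition of best affinities against the two reference energies.

    Equality is judged at the engine's print resolution (0.1 kcal/mol).
    ``stronger`` counts more negative (more favorable) affinities;
    ``weaker_value`` / ``stronger_value`` give the complementary counts on
    the raw value scale so both reading conventions of "greater affinity"
    are visible.
    """

    n: int
    counts: dict[str, dict[str, int]]
    histogram_counts: list[int]
    histogram_edges: list[float]


def summarize_affinities(
    results: list[DockingResult],
    refs: dict[str, float] | None = None,
    resolution: float = 0.1,
    n_bins: int = 20,
) -> AffinitySummary:
    """Count results stronger than / equal to / weaker than each reference.

    For every reference, each result falls in exactly one of the three
    buckets; an empty result list yields an empty summary.
    """
    if refs is None:
        refs = {"colchicine": COLCHICINE_REF, "native": NATIVE_REF}
    for name, value in refs.items():
        if not math.isfinite(value):
            raise ValueError(f"reference {name} is not finite")
    affinities = np.array([r.best_affinity for r in results], dtype=float)
    counts: dict[str, dict[str, int]] = {}
    for name, ref in refs.items():
        rounded = np.round(affinities / resolution) * resolution
        ref_rounded = round(ref / resolution) * resolution
        equal = np.isclose(rounded, ref_rounded)
        stronger = (affinities < ref) & ~equal
        weaker = ~equal & ~stronger
        counts[name] = {
            "stronger": int(stronger.sum()),
            "equal": int(equal.sum()),
            "weaker": int(weaker.sum()),
        }
    if affinities.size:
        hist, edges = np.histogram(affinities, bins=n_bins)
        hist, edges = hist.tolist(), edges.tolist()
    else:
        hist, edges = [], []
    return AffinitySummary(
        n=len(results), counts=counts, histogram_counts=hist, histogram_edges=edges
    )
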