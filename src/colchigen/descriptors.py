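"""Molecular descriptor catalog for the QSAR models.

The catalog mixes the standard RDKit descriptor list with the handful of
electro-topological and charge descriptors the activity models rely on:

* ``AMID_O`` — averaged molecular ID restricted to oxygen atoms: the Randic
  path-weight identifier (each simple path contributes the product of
  ``1/sqrt(deg_u * deg_v)`` over its edges) summed over paths starting at O
  atoms, divided by the heavy-atom count.
* ``MDEO-12`` — molecular distance-edge between primary (degree-1) and
  secondary (degree-2) oxygens: ``n / dbar**2`` with ``dbar`` the geometric
  mean topological distance over all such O-O pairs.
* ``GATS2c`` / ``MATS2c`` — Geary and Moran spatial autocorrelations of lag 2
  weighted by Gasteiger charge (hydrogen charges summed onto their heavy
  atom).
* ``RNCG`` — relative negative charge, the largest negative atomic charge
  divided by the total negative charge.
* ``SaasC`` / ``NdssC`` — sum of E-state indices over aromatic ``aasC``
  carbons and the count of ``dssC`` carbons.
* ``EState_VSA5``, ``EState_VSA6``, ``VSA_EState5`` — hybrid E-state/surface
  bins, and ``TopoPSA(NO)`` — topological polar surface area counting only N
  and O contributions.

All values are computed on the canonical form of the molecule, so different
SMILES renderings of one structure give identical rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, rdmolops
from rdkit.Chem.EState import AtomTypes, EState_VSA, EStateIndices

from .corpus import MoleculeRecord

PROVENANCE = "colchigen-descriptors-1"


class CatalogError(KeyError):
    """Raised for descriptor names absent from the catalog."""


class DescriptorComputationError(ValueError):
    """Raised when descriptor values cannot be computed for a molecule."""


# ---------------------------------------------------------------------------
# charge helpers

def _group_charges(mol: Chem.Mol) -> np.ndarray:
    """Gasteiger charge per heavy atom, hydrogens folded into their neighbor."""
    molh = Chem.AddHs(mol)
    AllChem.ComputeGasteigerCharges(molh)
    charges = []
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        q += sum(
            float(n.GetDoubleProp("_GasteigerCharge"))
            for n in atom.GetNeighbors()
            if n.GetAtomicNum() == 1
        )
        charges.append(q)
    out = np.asarray(charges)
    if not np.isfinite(out).all():
        raise DescriptorComputationError("non-finite Gasteiger charges")
    return out


def geary_autocorrelation(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Geary coefficient c(lag) of atomic weights on the molecular graph."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    pairs = dist == lag
    n_pairs = int(pairs.sum())  # ordered pairs
    if n_pairs == 0 or n < 2:
        return float("nan")
    diff2 = (w[:, None] - w[None, :]) ** 2
    num = diff2[pairs].sum() / (2.0 * n_pairs)
    den = ((w - w.mean()) ** 2).sum() / (n - 1)
    return float(num / den) if den > 0 else float("nan")


def moran_autocorrelation(weights: np.ndarray, dist: np.ndarray, lag: int) -> float:
    """Moran coefficient I(lag) of atomic weights on the molecular graph."""
    w = np.asarray(weights, dtype=float)
    n = len(w)
    pairs = dist == lag
    n_pairs = int(pairs.sum())
    if n_pairs == 0 or n < 1:
        return float("nan")
    d = w - w.mean()
    num = (d[:, None] * d[None, :])[pairs].sum() / n_pairs
    den = (d**2).sum() / n
    return float(num / den) if den > 0 else float("nan")


def _gats2c(mol: Chem.Mol) -> float:
    return geary_autocorrelation(_group_charges(mol), rdmolops.GetDistanceMatrix(mol), 2)


def _mats2c(mol: Chem.Mol) -> float:
    return moran_autocorrelation(_group_charges(mol), rdmolops.GetDistanceMatrix(mol), 2)


def _rncg(mol: Chem.Mol) -> float:
    q = _group_charges(mol)
    neg = q[q < 0]
    if neg.size == 0:
        return 0.0
    return float(neg.min() / neg.sum())  # = |q_maxneg| / |total negative charge|


# ---------------------------------------------------------------------------
# path-identifier and distance-edge descriptors

def randic_path_weights_from(mol: Chem.Mol, start: int) -> float:
    """Sum of Randic path weights over simple paths starting at ``start``.

    Each path contributes the product over its bonds of
    ``1/sqrt(deg_u * deg_v)``; the empty path contributes 1 (the atom's own
    identity term).
    """
    deg = [a.GetDegree() for a in mol.GetAtoms()]
    adj = [[n.GetIdx() for n in a.GetNeighbors()] for a in mol.GetAtoms()]
    total = 1.0

    def walk(atom: int, weight: float, visited: set[int]) -> None:
        nonlocal total
        for nb in adj[atom]:
            if nb in visited:
                continue
            w = weight / math.sqrt(deg[atom] * deg[nb])
            total += w
            walk(nb, w, visited | {nb})

    walk(start, 1.0, {start})
    return total


def _amid_o(mol: Chem.Mol) -> float:
    n_atoms = mol.GetNumAtoms()
    if n_atoms == 0:
        return 0.0
    total = sum(
        randic_path_weights_from(mol, a.GetIdx())
        for a in mol.GetAtoms()
        if a.GetSymbol() == "O"
    )
    return total / n_atoms


def molecular_distance_edge(mol: Chem.Mol, symbol: str, degree_a: int, degree_b: int) -> float:
    """Distance-edge descriptor between atoms of one element at two degrees."""
    dist = rdmolops.GetDistanceMatrix(mol)
    class_a = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetSymbol() == symbol and a.GetDegree() == degree_a]
    class_b = [a.GetIdx() for a in mol.GetAtoms()
               if a.GetSymbol() == symbol and a.GetDegree() == degree_b]
    if degree_a == degree_b:
        pairs = [(i, j) for k, i in enumerate(class_a) for j in class_a[k + 1:]]
    else:
        pairs = [(i, j) for i in class_a for j in class_b]
    if not pairs:
        return 0.0
    log_prod = sum(math.log(dist[i, j]) for i, j in pairs)
    dbar = math.exp(log_prod / (2 * len(pairs)))
    return len(pairs) / dbar**2


def _mdeo_12(mol: Chem.Mol) -> float:
    return molecular_distance_edge(mol, "O", 1, 2)


# ---------------------------------------------------------------------------
# E-state descriptors

def _saasc(mol: Chem.Mol) -> float:
    types = AtomTypes.TypeAtoms(mol)
    indices = EStateIndices(mol)
    return float(sum(e for t, e in zip(types, indices) if t and t[0] == "aasC"))


def _ndssc(mol: Chem.Mol) -> float:
    types = AtomTypes.TypeAtoms(mol)
    return float(sum(1 for t in types if t and t[0] == "dssC"))


# ---------------------------------------------------------------------------
# catalog

NAMED_DESCRIPTORS: dict[str, callable] = {
    "AMID_O": _amid_o,
    "EState_VSA5": EState_VSA.EState_VSA5,
    "EState_VSA6": EState_VSA.EState_VSA6,
    "MDEO-12": _mdeo_12,
    "SaasC": _saasc,
    "NdssC": _ndssc,
    "VSA_EState5": EState_VSA.VSA_EState5,
    "GATS2c": _gats2c,
    "MATS2c": _mats2c,
    "RNCG": _rncg,
    "TopoPSA(NO)": Descriptors.TPSA,
}

#: Full catalog: the named set above plus the standard RDKit descriptor list.
DESCRIPTOR_CATALOG: dict[str, callable] = {
    **{name: fn for name, fn in Descriptors._descList},
    **NAMED_DESCRIPTORS,
}


@dataclass
class DescriptorMatrix:
    """Descriptor values per molecule, with bookkeeping of what was dropped."""

    values: pd.DataFrame
    provenance: str = PROVENANCE
    dropped_columns: list[str] = field(default_factory=list)
    failed_molecules: list[str] = field(default_factory=list)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)


def compute_descriptors(
    molecules: list[MoleculeRecord], names: list[str] | None = None
) -> DescriptorMatrix:
    """Compute a descriptor matrix for a list of molecules.

    ``names`` defaults to the full catalog.  Columns containing any
    non-finite value across the set are dropped and recorded in
    ``dropped_columns``; molecules whose descriptors cannot be computed at
    all are excluded and recorded in ``failed_molecules``.
    """
    if names is None:
        names = list(DESCRIPTOR_CATALOG)
    unknown = [n for n in names if n not in DESCRIPTOR_CATALOG]
    if unknown:
        raise CatalogError(f"unknown descriptor names: {unknown}")

    rows, ids, failed = [], [], []
    for rec in molecules:
        if not rec.is_valid:
            failed.append(rec.id)
            continue
        mol = Chem.MolFromSmiles(rec.canonical_smiles)
        row = []
        for name in names:
            try:
                row.append(float(DESCRIPTOR_CATALOG[name](mol)))
            except Exception:
                row.append(float("nan"))
        if not any(math.isfinite(v) for v in row):
            failed.append(rec.id)
            continue
        rows.append(row)
        ids.append(rec.id)

    frame = pd.DataFrame(rows, index=ids, columns=names)
    finite = np.isfinite(frame.to_numpy())
    keep = finite.all(axis=0)
    dropped = [c for c, k in zip(frame.columns, keep) if not k]
    return DescriptorMatrix(
        values=frame.loc[:, keep.tolist()],
        dropped_columns=dropped,
        failed_molecules=failed,
    )
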