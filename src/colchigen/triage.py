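"""Candidate triage: similarity, synthesizability, stereochemistry, RI/SI.

Generated structures pass through a fixed cascade:

1. Tanimoto similarity to the colchicine core must reach the lowest
   similarity observed among the training structures.
2. The additive fragment synthesizability score must reach the lowest score
   observed among the training structures.
3. The C7 stereocenter must be S-configured (R and unspecified structures
   are known to lose activity).
4. Optionally, predicted resistance and selectivity indices must meet the
   configured rule (by default: not strongly resistant, and tumor-selective
   for at least one cancer line).

Thresholds are training-set-derived minima ("keep everything at least as
good as the worst training compound") and are applied inclusively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE

from .corpus import CellLine, MoleculeRecord, assign_c7_configuration, canonicalize, _mol_from_smiles

#: The colchicine core used as the similarity reference (the structure the
#: docking reference energy of -8.2 kcal/mol belongs to).
COLCHICINE_SMILES = "CC(=O)N[C@H]1CCc2cc(OC)c(OC)c(OC)c2-c2ccc(OC)c(=O)cc21"


@dataclass(frozen=True)
class FingerprintSpec:
    """Hashed-fingerprint dialect, fixed per run and recorded in outputs.

    The default (2048-bit topological path fingerprint, maximum path length
    7) is the dialect calibrated once against the reference similarity table
    and then frozen.
    """

    kind: str = "topological-path"
    n_bits: int = 2048
    radius_or_pathlen: int = 7

    def __post_init__(self) -> None:
        if self.kind not in ("topological-path", "circular"):
            raise ValueError(f"unknown fingerprint kind {self.kind!r}")


def fingerprint(smiles_or_mol: str | Chem.Mol, spec: FingerprintSpec = FingerprintSpec()):
    mol = (
        _mol_from_smiles(smiles_or_mol)
        if isinstance(smiles_or_mol, str)
        else smiles_or_mol
    )
    if spec.kind == "topological-path":
        return Chem.RDKFingerprint(mol, maxPath=spec.radius_or_pathlen, fpSize=spec.n_bits)
    gen = AllChem.GetMorganGenerator(radius=spec.radius_or_pathlen, fpSize=spec.n_bits)
    return gen.GetFingerprint(mol)


def tanimoto_similarity(
    a: str, b: str, spec: FingerprintSpec = FingerprintSpec()
) -> float:
    """|A n B| / |A u B| over fingerprint on-bits; symmetric, T(x, x) = 1."""
    return float(
        DataStructs.TanimotoSimilarity(fingerprint(a, spec), fingerprint(b, spec))
    )


# ---------------------------------------------------------------------------
# fragment synthesizability score

@dataclass
class FragmentScoreTable:
    """Additive per-fragment contribution scores (SYBA-style).

    Keys are hashed circular-fragment identifiers (atom environments of
    radius 0..``radius``); unseen fragments contribute ``default_score``.
    Higher molecule totals indicate easier synthesis.
    """

    scores: dict[int, float]
    default_score: float = 0.0
    radius: int = 2
    version: str = "toy"

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "radius": self.radius,
            "default_score": self.default_score,
            "scores": {str(k): v for k, v in self.scores.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FragmentScoreTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            scores={int(k): float(v) for k, v in payload["scores"].items()},
            default_score=float(payload.get("default_score", 0.0)),
            radius=int(payload.get("radius", 2)),
            version=str(payload.get("version", "unknown")),
        )

    @classmethod
    def from_syba_file(cls, path: str | Path) -> "FragmentScoreTable":
        """Load the published SYBA score file (CSV of fragment id, score)."""
        scores: dict[int, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("ecfp"):
                continue
            key, value = line.replace(",", " ").split()[:2]
            scores[int(key)] = float(value)
        return cls(scores=scores, version="syba-file")


def molecule_fragments(smiles: str, radius: int = 2) -> dict[int, int]:
    """Circular fragment identifiers with counts (radius 0..``radius``)."""
    mol = _mol_from_smiles(smiles)
    gen = AllChem.GetMorganGenerator(radius=radius)
    sparse = gen.GetSparseCountFingerprint(mol)
    return dict(sparse.GetNonzeroElements())


def syba_score(smiles: str, table: FragmentScoreTable) -> float:
    """Sum of fragment contribution scores over the molecule's fragments."""
    if not table.scores:
        raise ValueError("fragment score table is empty")
    frags = molecule_fragments(smiles, radius=table.radius)
    return float(
        sum(count * table.scores.get(f, table.default_score) for f, count in frags.items())
    )


# ---------------------------------------------------------------------------
# indices

RI_BANDS = ("sensitive", "moderate", "strong")


def resistance_index(ic50_lovodx_nM: float, ic50_lovo_nM: float) -> tuple[float, str]:
    """RI = IC50(LoVo/DX) / IC50(LoVo) with its sensitivity band.

    Bands (closed-left/open-right at the boundaries): RI <= 2 sensitive,
    2 < RI <= 10 moderate, RI > 10 strong resistance.
    """
    if not (ic50_lovodx_nM > 0 and ic50_lovo_nM > 0):
        raise ValueError("IC50 values must be positive")
    ri = ic50_lovodx_nM / ic50_lovo_nM
    if ri <= 2:
        band = "sensitive"
    elif ri <= 10:
        band = "moderate"
    else:
        band = "strong"
    return ri, band


def selectivity_index(ic50_balb_nM: float, ic50_cancer_nM: float) -> float:
    """SI = IC50(normal BALB/3T3) / IC50(cancer line); SI > 1 is favorable."""
    if not (ic50_balb_nM > 0 and ic50_cancer_nM > 0):
        raise ValueError("IC50 values must be positive")
    return ic50_balb_nM / ic50_cancer_nM


def is_favorable_si(si: float) -> bool:
    return si > 1.0


# ---------------------------------------------------------------------------
# candidates and the cascade

@dataclass
class CandidateRecord:
    """A generated molecule with everything the cascade needs to judge it."""

    molecule: MoleculeRecord
    tanimoto_to_core: float | None = None
    syba: float | None = None
    c7: str = "undefined"
    predicted_ic50: dict[CellLine, float] = field(default_factory=dict)
    affinity_kcal_mol: float | None = None

    @property
    def ri(self) -> float | None:
        dx = self.predicted_ic50.get(CellLine.LOVODX)
        lovo = self.predicted_ic50.get(CellLine.LOVO)
        if dx is None or lovo is None:
            return None
        return resistance_index(dx, lovo)[0]

    @property
    def ri_class(self) -> str | None:
        dx = self.predicted_ic50.get(CellLine.LOVODX)
        lovo = self.predicted_ic50.get(CellLine.LOVO)
        if dx is None or lovo is None:
            return None
        return resistance_index(dx, lovo)[1]

    @property
    def si(self) -> dict[CellLine, float]:
        balb = self.predicted_ic50.get(CellLine.BALB3T3)
        if balb is None:
            return {}
        return {
            line: selectivity_index(balb, value)
            for line, value in self.predicted_ic50.items()
            if line.is_cancer
        }


def score_candidates(
    molecules: list[MoleculeRecord],
    table: FragmentScoreTable,
    core: str = COLCHICINE_SMILES,
    spec: FingerprintSpec = FingerprintSpec(),
    predictions: dict[tuple[str, CellLine], float] | None = None,
) -> list[CandidateRecord]:
    """Attach similarity, fragment score, C7 configuration and predictions."""
    records = []
    for mol in molecules:
        if not mol.is_valid:
            continue
        predicted = {}
        if predictions:
            predicted = {
                line: predictions[(mol.id, line)]
                for line in CellLine
                if (mol.id, line) in predictions
            }
        records.append(
            CandidateRecord(
                molecule=mol,
                tanimoto_to_core=tanimoto_similarity(mol.canonical_smiles, core, spec),
                syba=syba_score(mol.canonical_smiles, table),
                c7=assign_c7_configuration(mol.canonical_smiles),
                predicted_ic50=predicted,
            )
        )
    return records


def derive_thresholds(
    training: list[MoleculeRecord],
    core: str = COLCHICINE_SMILES,
    table: FragmentScoreTable | None = None,
    spec: FingerprintSpec = FingerprintSpec(),
) -> dict:
    """Training-set minima used as cascade thresholds.

    ``tanimoto_min`` is the lowest similarity of any training structure to
    the core; ``syba_min`` the lowest fragment score.  The arg-min molecule
    ids are recorded alongside.
    """
    training = [t for t in training if t.is_valid]
    if not training:
        raise ValueError("training set is empty")
    canonicalize(core)
    sims = [(tanimoto_similarity(t.canonical_smiles, core, spec), t.id) for t in training]
    tanimoto_min, tanimoto_argmin = min(sims)
    out = {
        "tanimoto_min": tanimoto_min,
        "tanimoto_argmin": tanimoto_argmin,
        "fingerprint_spec": spec,
    }
    if table is not None:
        scores = [(syba_score(t.canonical_smiles, table), t.id) for t in training]
        syba_min, syba_argmin = min(scores)
        out.update({"syba_min": syba_min, "syba_argmin": syba_argmin})
    return out


@dataclass
class StageLog:
    """Per-filter bookkeeping: (stage, entering count, surviving count)."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: survivors {n_out} exceed input {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name}: input {n_in} does not chain")
        self.stages.append((name, n_in, n_out))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([
                {"stage": s, "input": i, "surviving": o} for s, i, o in self.stages
            ], indent=1)
        )


@dataclass(frozen=True)
class CascadeConfig:
    require_s_configuration: bool = True
    apply_ri_si: bool = False
    #: candidates must not fall in this RI band
    reject_ri_class: str = "strong"
    #: at least one cancer line must show SI above this value
    si_min: float = 1.0


def apply_selection_cascade(
    candidates: list[CandidateRecord],
    thresholds: dict,
    config: CascadeConfig = CascadeConfig(),
) -> tuple[list[CandidateRecord], StageLog]:
    """Run the similarity -> synthesizability -> stereochemistry (-> RI/SI)
    cascade; thresholds are inclusive (>=)."""
    log = StageLog()
    current = list(candidates)

    survivors = [c for c in current if c.tanimoto_to_core is not None
                 and c.tanimoto_to_core >= thresholds["tanimoto_min"]]
    log.record("tanimoto", len(current), len(survivors))
    current = survivors

    if "syba_min" in thresholds:
        survivors = [c for c in current if c.syba is not None
                     and c.syba >= thresholds["syba_min"]]
        log.record("syba", len(current), len(survivors))
        current = survivors

    if config.require_s_configuration:
        survivors = [c for c in current if c.c7 == "S"]
        log.record("stereo", len(current), len(survivors))
        current = survivors

    if config.apply_ri_si:
        survivors = []
        for c in current:
            if c.ri_class is None or not c.si:
                continue
            if c.ri_class == config.reject_ri_class:
                continue
            if not any(v > config.si_min for v in c.si.values()):
                continue
            survivors.append(c)
        log.record("ri_si", len(current), len(survivors))
        current = survivors

    return current, log


def candidates_to_frame(candidates: list[CandidateRecord]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "id": c.molecule.id,
            "smiles": c.molecule.canonical_smiles,
            "tanimoto_to_core": c.tanimoto_to_core,
            "syba": c.syba,
            "c7": c.c7,
            "RI": c.ri,
            "RI_class": c.ri_class,
            "affinity_kcal_mol": c.affinity_kcal_mol,
        }
        for line, value in c.predicted_ic50.items():
            row[f"IC50_{line.label}"] = value
        for line, value in c.si.items():
            row[f"SI_{line.label}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def annotate_pubchem(
    frame: pd.DataFrame, lookup: "callable", smiles_column: str = "smiles"
) -> pd.DataFrame:
    """Add a ``found_in_pubchem`` column using an injected lookup client.

    ``lookup`` maps a canonical SMILES to a truthy value when the compound
    is already registered (e.g. a PubChemPy-backed callable).  The network
    client is always injected — nothing in the package performs live
    queries on its own.
    """
    out = frame.copy()
    out["found_in_pubchem"] = [bool(lookup(s)) for s in out[smiles_column]]
    return out


# ---------------------------------------------------------------------------
# chemical-space embedding

def embed_chemical_space(
    molecules: list[MoleculeRecord],
    spec: FingerprintSpec = FingerprintSpec(),
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2D t-SNE embedding of fingerprint space; one (x, y) row per molecule.

    Deterministic for a fixed seed.  Molecules with identical fingerprints
    are at distance 0 in the input space.
    """
    if len(molecules) < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} molecules for perplexity={perplexity}"
        )
    bits = np.zeros((len(molecules), spec.n_bits), dtype=bool)
    for i, mol in enumerate(molecules):
        fp = fingerprint(mol.canonical_smiles, spec)
        on = np.array(fp.GetOnBits(), dtype=np.int64)
        bits[i, on] = True
    # Jaccard distance = 1 - Tanimoto, the natural metric for bit fingerprints
    distances = squareform(pdist(bits, metric="jaccard"))
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed,
        metric="precomputed", init="random",
    )
    return tsne.fit_transform(distances)
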