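"""Synthetic data generators for the whole pipeline.

Everything downstream (augmentation, sequence model, QSAR tournament,
triage cascade, docking summary) is exercisable offline with these
generators: a library of colchicine-scaffold analogs, descriptor-driven
synthetic activities with known ground truth, and a toy fragment score
table.

The analog library is built from an allocolchicine-style template:
three methoxy groups on the aromatic A ring, the tropolone-like C ring with
a variable substituent (thio/amino/alkoxy methyl swaps), and an N-substituent
at the C7 position drawn from short alkyl/haloalkyl/amine chains — the kinds
of edits observed among the training compounds.  Activities are generated on
the pIC50 scale as a linear signal in named descriptors plus Gaussian noise
(hence lognormal on the nM scale), with per-cell-line offsets that place
IC50 values in the low-nM to µM range and make LoVo/DX systematically less
sensitive than LoVo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus import ActivityRecord, CellLine, MoleculeRecord, canonicalize, from_pic50
from .descriptors import compute_descriptors
from .triage import FragmentScoreTable, molecule_fragments

#: C-ring substituent pool (position of the thiomethyl in the first training
#: structure) and N-substituent pool at C7.
DEFAULT_RING_POOL = ("SC", "NC", "OC", "NCC")
DEFAULT_N_POOL = (
    "CC", "C", "CCC", "CCCC", "C(C)C", "C(C)CC", "CC(C)C",
    "CCO", "CCCO", "CCOC", "CCON", "CCONC",
    "CCCl", "CCCCl", "CCCCF", "CCCF", "CCBr",
    "CCN", "CCCN", "CCNC", "C(C)CO", "CCSC",
    "CC(C)O", "CCC(C)C", "CCCOC", "CCCNC", "CC(C)N",
    "CCCCO", "CCCCN", "CCCCC", "C(CC)CC", "CC(C)CC",
    "CCOCC", "CCNCC", "CCCCCl",
)

_TEMPLATE = "COC1=C2C3=CC=C({ring})C(=O)C=C3[C{stereo}](CCC2=CC(OC)=C1OC)N{nsub}"


class CapacityError(ValueError):
    """Raised when the substituent pools cannot yield enough distinct analogs."""


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 120
    ring_pool: tuple[str, ...] = DEFAULT_RING_POOL
    n_pool: tuple[str, ...] = DEFAULT_N_POOL
    seed: int = 15
    #: fraction of molecules carrying the mirrored (R) C7 tag
    r_fraction: float = 0.0
    #: fraction of molecules with the C7 chirality tag removed
    undefined_fraction: float = 0.0


def make_fixture_library(spec: FixtureSpec = FixtureSpec()) -> list[MoleculeRecord]:
    """Generate ``n_molecules`` distinct colchicine-scaffold analogs.

    Deterministic for a given spec.  All molecules share the scaffold; the
    requested fractions carry an R-configured or unspecified C7 center (the
    rest are S, like the training compounds).
    """
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not spec.ring_pool or not spec.n_pool:
        raise ValueError("substituent pools must be nonempty")
    combos = list(itertools.product(spec.ring_pool, spec.n_pool))
    if len(combos) < spec.n_molecules:
        raise CapacityError(
            f"pools admit only {len(combos)} analogs, {spec.n_molecules} requested"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(combos))

    n = spec.n_molecules
    n_r = int(round(spec.r_fraction * n))
    n_u = int(round(spec.undefined_fraction * n))
    stereo_tags = ["@@H"] * n_r + ["H"] * n_u + ["@H"] * (n - n_r - n_u)

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for k in order:
        if len(records) == n:
            break
        ring, nsub = combos[k]
        stereo = stereo_tags[len(records)]
        smiles = _TEMPLATE.format(ring=ring, stereo=stereo, nsub=nsub)
        canonical = canonicalize(smiles)
        if canonical in seen:
            continue
        seen.add(canonical)
        records.append(
            MoleculeRecord(
                id=f"fix{len(records):03d}", smiles=smiles, canonical_smiles=canonical
            )
        )
    if len(records) < n:
        raise CapacityError(
            f"pools yielded only {len(records)} distinct analogs of {n} requested"
        )
    return records


#: Default descriptor weights for synthetic activity: two weakly coupled
#: named descriptors carry the signal, with weights sized so each contributes
#: a comparable share of the pIC50 variance across the default library.
DEFAULT_BETAS = {"TopoPSA(NO)": -0.035, "GATS2c": 18.0}
#: Baseline pIC50 (~30 nM) and per-line shifts; LoVo/DX sits ~0.8 log units
#: less potent than LoVo so resistance indices are realistic.
DEFAULT_INTERCEPT = 7.5
DEFAULT_LINE_OFFSETS = {
    CellLine.A549: 0.0,
    CellLine.BALB3T3: -0.2,
    CellLine.LOVODX: -0.8,
    CellLine.LOVO: 0.0,
    CellLine.MCF7: -0.1,
}


@dataclass
class ActivityGroundTruth:
    betas: dict[str, float]
    intercept: float
    line_offsets: dict[CellLine, float]
    sigma: float
    descriptor_values: "object" = None  # pandas DataFrame of the signal descriptors
    descriptor_means: dict[str, float] = field(default_factory=dict)


def make_synthetic_activity(
    library: list[MoleculeRecord],
    betas: dict[str, float] | None = None,
    sigma: float = 0.1,
    seed: int = 42,
    intercept: float = DEFAULT_INTERCEPT,
    line_offsets: dict[CellLine, float] | None = None,
) -> tuple[list[ActivityRecord], ActivityGroundTruth]:
    """Synthesize per-cell-line activities with a known linear ground truth.

    pIC50 = intercept + line offset + sum(beta * (descriptor - mean)) +
    N(0, sigma), back-transformed to nM.  The descriptor signal is centered
    on the library so the intercept pins the median potency regardless of
    the weights; the ground-truth parameters, descriptor values and centering
    means are returned for recovery tests.
    """
    if betas is None:
        betas = dict(DEFAULT_BETAS)
    if line_offsets is None:
        line_offsets = dict(DEFAULT_LINE_OFFSETS)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    matrix = compute_descriptors(library, names=list(betas))
    missing = [name for name in betas if name not in matrix.values.columns]
    if missing:
        raise KeyError(f"betas reference uncomputable descriptors: {missing}")

    rng = np.random.default_rng(seed)
    D = matrix.values.to_numpy(dtype=float)
    means = D.mean(axis=0)
    signal = (D - means) @ np.array(list(betas.values()))
    by_id = {m.id: m for m in library}
    records: list[ActivityRecord] = []
    for i, mol_id in enumerate(matrix.values.index):
        ic50: dict[CellLine, float] = {}
        for line in CellLine:
            pic50 = intercept + line_offsets.get(line, 0.0) + signal[i]
            pic50 += rng.normal(0.0, sigma) if sigma > 0 else 0.0
            ic50[line] = from_pic50(pic50)
        records.append(ActivityRecord(molecule=by_id[mol_id], ic50_nM=ic50))
    truth = ActivityGroundTruth(
        betas=dict(betas),
        intercept=intercept,
        line_offsets=dict(line_offsets),
        sigma=sigma,
        descriptor_values=matrix.values,
        descriptor_means=dict(zip(betas, means)),
    )
    return records, truth


def make_fragment_table(
    library: list[MoleculeRecord],
    seed: int = 0,
    loc: float = 0.0,
    scale: float = 1.0,
    all_positive: bool = False,
) -> FragmentScoreTable:
    """Toy fragment score table covering every fragment in ``library``.

    Scores are drawn from a normal distribution (symmetric about ``loc``);
    with ``all_positive`` the draws are folded so every fixture molecule
    scores above zero.  Deterministic for a fixed seed.
    """
    fragment_ids: set[int] = set()
    for mol in library:
        fragment_ids.update(molecule_fragments(mol.canonical_smiles))
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc, scale, size=len(fragment_ids))
    if all_positive:
        draws = np.abs(draws)
    scores = {frag: float(s) for frag, s in zip(sorted(fragment_ids), draws)}
    return FragmentScoreTable(scores=scores, default_score=0.0, version=f"toy-seed{seed}")
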