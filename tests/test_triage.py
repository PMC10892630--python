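import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs

from colchigen.corpus import InvalidSmilesError, MoleculeRecord
from colchigen.fixtures import make_fixture_library, FixtureSpec
from colchigen.triage import (
    COLCHICINE_SMILES,
    CandidateRecord,
    CascadeConfig,
    FingerprintSpec,
    FragmentScoreTable,
    StageLog,
    apply_selection_cascade,
    derive_thresholds,
    embed_chemical_space,
    fingerprint,
    is_favorable_si,
    molecule_fragments,
    resistance_index,
    score_candidates,
    selectivity_index,
    syba_score,
    tanimoto_similarity,
)
from .conftest import NEW_AMINE, NEW_CHLORO, NEW_FLUORO, START_1, START_2


class TestTanimoto:
    def test_identity_symmetry_range(self, library):
        rng = np.random.default_rng(0)
        smiles = [m.canonical_smiles for m in library]
        fps = {s: fingerprint(s) for s in smiles}
        for _ in range(1000):
            a, b = rng.choice(smiles, size=2, replace=True)
            t_ab = DataStructs.TanimotoSimilarity(fps[a], fps[b])
            t_ba = DataStructs.TanimotoSimilarity(fps[b], fps[a])
            assert t_ab == t_ba
            assert 0.0 <= t_ab <= 1.0
        assert tanimoto_similarity(smiles[0], smiles[0]) == 1.0

    @pytest.mark.parametrize(
        ("new", "start", "printed"),
        [
            (NEW_AMINE, START_1, 0.844),
            (NEW_CHLORO, START_1, 0.983),
            (NEW_FLUORO, START_2, 0.978),
        ],
    )
    def test_reference_table_similarities(self, new, start, printed):
        """The frozen fingerprint spec reproduces the reference pairs."""
        assert round(tanimoto_similarity(new, start), 3) == printed

    def test_disjoint_fingerprints(self):
        assert tanimoto_similarity("CCCC", "NNN") == 0.0

    def test_invalid_smiles(self):
        with pytest.raises(InvalidSmilesError):
            tanimoto_similarity("C1CC", "CCO")

    def test_circular_spec_also_supported(self):
        spec = FingerprintSpec(kind="circular", n_bits=1024, radius_or_pathlen=2)
        assert tanimoto_similarity(START_1, START_1, spec) == 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            FingerprintSpec(kind="quantum")


class TestSybaScore:
    def test_counting_case_against_bond_set_enumeration(self, library):
        """With all fragment scores 1, the score equals the number of distinct
        atom environments (radius 0..2), counted independently by bond-set
        deduplication."""
        for mol in library[:5]:
            frags = molecule_fragments(mol.canonical_smiles)
            table = FragmentScoreTable(scores={f: 1.0 for f in frags}, default_score=1.0)
            rdmol = Chem.MolFromSmiles(mol.canonical_smiles)
            expected = rdmol.GetNumAtoms()
            seen = set()
            for radius in (1, 2):
                for atom in range(rdmol.GetNumAtoms()):
                    env = frozenset(Chem.FindAtomEnvironmentOfRadiusN(rdmol, radius, atom))
                    if env and env not in seen:
                        seen.add(env)
                        expected += 1
            assert syba_score(mol.canonical_smiles, table) == expected

    def test_score_is_weighted_fragment_sum(self, library, fragment_table):
        mol = library[3]
        frags = molecule_fragments(mol.canonical_smiles, radius=fragment_table.radius)
        expected = sum(
            count * fragment_table.scores.get(f, fragment_table.default_score)
            for f, count in frags.items()
        )
        assert syba_score(mol.canonical_smiles, fragment_table) == pytest.approx(expected)

    def test_unseen_fragments_use_default(self, fragment_table):
        table = FragmentScoreTable(scores={1: 5.0}, default_score=-2.0)
        # benzene's fragments are certainly not id 1
        score = syba_score("c1ccccc1", table)
        frags = molecule_fragments("c1ccccc1")
        assert score == pytest.approx(-2.0 * sum(frags.values()))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            syba_score("CCO", FragmentScoreTable(scores={}))

    def test_table_json_roundtrip(self, tmp_path, fragment_table):
        path = tmp_path / "table.json"
        fragment_table.save(path)
        loaded = FragmentScoreTable.load(path)
        assert loaded.scores == fragment_table.scores
        assert loaded.radius == fragment_table.radius


class TestThresholds:
    def test_core_as_only_training_molecule(self, fragment_table):
        core = MoleculeRecord.from_smiles(COLCHICINE_SMILES, id="core")
        out = derive_thresholds([core], table=fragment_table)
        assert out["tanimoto_min"] == 1.0
        assert out["syba_min"] == pytest.approx(
            syba_score(COLCHICINE_SMILES, fragment_table)
        )
        assert out["tanimoto_argmin"] == "core"

    def test_equals_brute_force_minimum(self, library, fragment_table):
        training = library[:50]
        out = derive_thresholds(training, table=fragment_table)
        sims = [tanimoto_similarity(t.canonical_smiles, COLCHICINE_SMILES) for t in training]
        scores = [syba_score(t.canonical_smiles, fragment_table) for t in training]
        assert out["tanimoto_min"] == min(sims)
        assert out["syba_min"] == min(scores)
        assert out["tanimoto_argmin"] == training[int(np.argmin(sims))].id

    def test_empty_training_set(self, fragment_table):
        with pytest.raises(ValueError):
            derive_thresholds([], table=fragment_table)


class TestIndices:
    def test_equal_inputs_sensitive(self):
        ri, band = resistance_index(10.0, 10.0)
        assert ri == 1.0 and band == "sensitive"

    def test_reference_quotients(self):
        # starting structure: 54.9 / 6.5; generated analog: 94.3 / 6.2
        ri, band = resistance_index(54.9, 6.5)
        assert ri == pytest.approx(8.446, abs=1e-3)
        assert band == "moderate"
        ri, band = resistance_index(94.3, 6.2)
        assert ri == pytest.approx(15.21, abs=1e-2)
        assert band == "strong"

    def test_band_boundaries(self):
        assert resistance_index(2.0, 1.0)[1] == "sensitive"
        assert resistance_index(10.0, 1.0)[1] == "moderate"
        assert resistance_index(10.0 + 1e-9, 1.0)[1] == "strong"

    def test_selectivity_reference_values(self):
        assert selectivity_index(10.2, 10.3) == pytest.approx(0.990, abs=1e-3)
        assert not is_favorable_si(selectivity_index(10.2, 10.3))
        assert selectivity_index(10.9, 8.3) == pytest.approx(1.313, abs=1e-3)
        assert is_favorable_si(selectivity_index(10.9, 8.3))

    def test_equal_inputs_not_favorable(self):
        assert not is_favorable_si(selectivity_index(5.0, 5.0))

    @given(
        a=st.floats(0.01, 1e6),
        b=st.floats(0.01, 1e6),
        c=st.floats(0.01, 1e4),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, a, b, c):
        ri1, band1 = resistance_index(a, b)
        ri2, band2 = resistance_index(a * c, b * c)
        assert ri1 == pytest.approx(ri2, rel=1e-9)
        assert band1 == band2
        assert selectivity_index(a, b) == pytest.approx(
            selectivity_index(a * c, b * c), rel=1e-9
        )

    @pytest.mark.parametrize("bad", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            resistance_index(*bad)
        with pytest.raises(ValueError):
            selectivity_index(*bad)


def _candidate(smiles, tanimoto, syba, c7):
    return CandidateRecord(
        molecule=MoleculeRecord.from_smiles(smiles),
        tanimoto_to_core=tanimoto,
        syba=syba,
        c7=c7,
    )


class TestCascade:
    def test_empty_candidates(self):
        survivors, log = apply_selection_cascade(
            [], {"tanimoto_min": 0.3, "syba_min": 0.0}
        )
        assert survivors == []
        assert log.stages == [("tanimoto", 0, 0), ("syba", 0, 0), ("stereo", 0, 0)]

    def test_pass_through_with_vacuous_thresholds(self, library, fragment_table):
        candidates = score_candidates(library[:10], fragment_table)
        survivors, log = apply_selection_cascade(
            candidates, {"tanimoto_min": 0.0, "syba_min": -np.inf}
        )
        assert survivors == candidates
        assert [s[2] for s in log.stages] == [10, 10, 10]

    def test_hand_countable_survivors(self):
        candidates = [
            _candidate("CCO", 0.9, 5.0, "S"),      # survives all three
            _candidate("CCN", 0.1, 5.0, "S"),      # fails similarity
            _candidate("CCC", 0.9, -5.0, "S"),     # fails synthesizability
            _candidate("CCF", 0.9, 5.0, "R"),      # fails stereochemistry
            _candidate("CCCl", 0.9, 5.0, "undefined"),  # fails stereochemistry
            _candidate("CCBr", 0.5, 0.0, "S"),     # survives (inclusive thresholds)
        ]
        survivors, log = apply_selection_cascade(
            candidates, {"tanimoto_min": 0.5, "syba_min": 0.0}
        )
        assert [c.molecule.smiles for c in survivors] == ["CCO", "CCBr"]
        assert log.stages == [("tanimoto", 6, 5), ("syba", 5, 4), ("stereo", 4, 2)]

    def test_counts_chain_and_subset(self, mixed_stereo_library, fragment_table):
        thresholds = derive_thresholds(mixed_stereo_library[:50], table=fragment_table)
        candidates = score_candidates(mixed_stereo_library, fragment_table)
        survivors, log = apply_selection_cascade(candidates, thresholds)
        ids = {c.molecule.id for c in candidates}
        assert {c.molecule.id for c in survivors} <= ids
        for (_, n_in, n_out), nxt in itertools.zip_longest(
            log.stages, log.stages[1:], fillvalue=None
        ):
            assert n_out <= n_in
            if nxt is not None:
                assert n_out == nxt[1]
        assert all(c.c7 == "S" for c in survivors)

    def test_ri_si_stage(self):
        from colchigen.corpus import CellLine

        good = _candidate("CCO", 0.9, 5.0, "S")
        good.predicted_ic50 = {
            CellLine.LOVODX: 20.0, CellLine.LOVO: 10.0,  # RI=2 sensitive
            CellLine.BALB3T3: 50.0, CellLine.A549: 10.0,  # SI=5 favorable
        }
        resistant = _candidate("CCN", 0.9, 5.0, "S")
        resistant.predicted_ic50 = {
            CellLine.LOVODX: 500.0, CellLine.LOVO: 10.0,  # RI=50 strong
            CellLine.BALB3T3: 50.0, CellLine.A549: 10.0,
        }
        unselective = _candidate("CCC", 0.9, 5.0, "S")
        unselective.predicted_ic50 = {
            CellLine.LOVODX: 20.0, CellLine.LOVO: 10.0,
            CellLine.BALB3T3: 5.0, CellLine.A549: 10.0,  # SI=0.5
        }
        survivors, log = apply_selection_cascade(
            [good, resistant, unselective],
            {"tanimoto_min": 0.0, "syba_min": -np.inf},
            CascadeConfig(apply_ri_si=True),
        )
        assert [c.molecule.smiles for c in survivors] == ["CCO"]
        assert log.stages[-1] == ("ri_si", 3, 1)

    def test_stage_log_rejects_bad_chains(self):
        log = StageLog()
        log.record("a", 10, 8)
        with pytest.raises(ValueError):
            log.record("b", 9, 5)  # does not chain
        with pytest.raises(ValueError):
            log.record("b", 8, 9)  # survivors exceed input


def test_pubchem_stub_uses_injected_client(library, fragment_table):
    from colchigen.triage import annotate_pubchem, candidates_to_frame

    frame = candidates_to_frame(score_candidates(library[:4], fragment_table))
    known = {library[0].canonical_smiles}
    annotated = annotate_pubchem(frame, lookup=lambda s: s in known)
    assert annotated["found_in_pubchem"].tolist() == [True, False, False, False]
    assert "found_in_pubchem" not in frame.columns  # input untouched


class TestEmbedding:
    def test_shape_and_determinism(self, small_library):
        mols = small_library + small_library  # 40 points, incl. duplicates
        coords = embed_chemical_space(mols, perplexity=5, seed=7)
        assert coords.shape == (40, 2)
        assert np.isfinite(coords).all()
        again = embed_chemical_space(mols, perplexity=5, seed=7)
        assert np.allclose(coords, again)

    def test_duplicates_coincide_in_fingerprint_space(self, small_library):
        a = fingerprint(small_library[0].canonical_smiles)
        b = fingerprint(small_library[0].canonical_smiles)
        assert DataStructs.TanimotoSimilarity(a, b) == 1.0

    def test_family_separation(self):
        scaffold = make_fixture_library(FixtureSpec(n_molecules=15, seed=1))
        alkanes = [
            MoleculeRecord.from_smiles("C" * n, id=f"alk{n}") for n in range(3, 18)
        ]
        coords = embed_chemical_space(scaffold + alkanes, perplexity=5, seed=0)
        a, b = coords[:15], coords[15:]
        intra = np.linalg.norm(a - a.mean(axis=0), axis=1).mean()
        intra_b = np.linalg.norm(b - b.mean(axis=0), axis=1).mean()
        inter = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
        assert inter > max(intra, intra_b)

    def test_too_few_molecules(self, small_library):
        with pytest.raises(ValueError):
            embed_chemical_space(small_library[:5], perplexity=30)
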