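"""Descriptor vectors, fingerprints, solvent encoding and fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from aiegen.dataset import Dataset, SpectralRecord
from aiegen.featurize import (
    DescriptorSpec,
    FeaturizationError,
    FingerprintSpec,
    N_QUANTITATIVE,
    QuantitativeScaler,
    SolventVocabularyError,
    atompair_fp,
    daylight_fp,
    encode_solvent,
    featurize_dataset,
    featurize_record,
    fingerprint,
    fuse,
    morgan_fp,
    preset,
    quantitative_descriptor_names,
    quantitative_descriptors,
    resolve_solvent,
    solvent_table,
    torsion_fp,
)


def random_smiles_renderings(smiles: str, n: int, seed: int) -> list[str]:
    """Distinct SMILES spellings of one molecule via random atom ordering."""
    mol = Chem.MolFromSmiles(smiles)
    out = []
    for i in range(n):
        out.append(Chem.MolToSmiles(mol, canonical=False, doRandom=True))
    return out


class TestQuantitativeDescriptors:
    def test_pinned_list_has_196_names_classed_106_plus_90(self):
        names = quantitative_descriptor_names()
        assert len(names) == 196
        assert len(set(names)) == 196
        from aiegen.featurize import _descriptor_table

        dims = _descriptor_table()["dimension"].value_counts().to_dict()
        assert dims == {1: 106, 2: 90}

    @pytest.mark.parametrize("smiles", ["c1ccccc1", "CCO", "N(c1ccccc1)(c1ccccc1)c1ccccc1"])
    def test_vector_length_is_196(self, smiles):
        assert quantitative_descriptors(smiles).shape == (N_QUANTITATIVE,)

    def test_spelling_invariance(self):
        a = quantitative_descriptors("c1ccccc1CCO")
        b = quantitative_descriptors("OCCc1ccccc1")
        np.testing.assert_array_equal(a, b)

    def test_benzene_molecular_weight_entry(self):
        # 6 x 12.011 + 6 x 1.008 = 78.11
        vec = quantitative_descriptors("c1ccccc1")
        mw = vec[quantitative_descriptor_names().index("MolWt")]
        assert mw == pytest.approx(78.11, abs=0.01)

    def test_all_finite(self, tiny_molecules):
        for smi in tiny_molecules:
            assert np.all(np.isfinite(quantitative_descriptors(smi)))

    def test_unparseable_raises(self):
        with pytest.raises(FeaturizationError):
            quantitative_descriptors("C1CC")


class TestFingerprintSpec:
    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError):
            FingerprintSpec("morgan", n_bits=1000)

    def test_rejects_radius_beyond_six(self):
        with pytest.raises(ValueError):
            FingerprintSpec("morgan", radius=7)

    def test_rejects_zero_max_path(self):
        with pytest.raises(ValueError):
            FingerprintSpec("daylight", max_path=0)


class TestFingerprintExamples:
    """Exact set-bit counts derived from substructure enumeration."""

    def test_morgan_benzene_three_environments(self):
        assert morgan_fp("c1ccccc1").sum() == 3

    def test_morgan_methane_single_environment(self):
        assert morgan_fp("C").sum() == 1

    def test_daylight_default_length_2048(self):
        assert daylight_fp("c1ccccc1").shape == (2048,)

    def test_daylight_methane_all_zero(self):
        assert daylight_fp("C").sum() == 0

    def test_daylight_ethane_single_path(self):
        assert daylight_fp("CC").sum() == 1

    def test_atompair_methane_all_zero(self):
        assert atompair_fp("C").sum() == 0

    def test_atompair_ethane_single_pair(self):
        assert atompair_fp("CC").sum() == 1

    def test_atompair_chain_nesting(self):
        assert atompair_fp("CCC").sum() >= atompair_fp("CC").sum()

    def test_torsion_propane_all_zero(self):
        assert torsion_fp("CCC").sum() == 0

    def test_torsion_butane_single_torsion(self):
        assert torsion_fp("CCCC").sum() == 1

    def test_torsion_benzene_single_torsion_class(self):
        assert torsion_fp("c1ccccc1").sum() == 1

    def test_binary_values_only(self, tiny_molecules):
        for smi in tiny_molecules[:8]:
            for fp in (morgan_fp, daylight_fp, atompair_fp, torsion_fp):
                assert set(np.unique(fp(smi))) <= {0, 1}


class TestSpellingInvariance:
    @pytest.mark.parametrize("kind", ["morgan", "daylight", "atompair", "torsion"])
    def test_popcount_and_bits_invariant_to_atom_order(self, kind):
        spec = FingerprintSpec(kind)
        targets = ["N(c1ccccc1)(c1ccccc1)c1ccc(C=Cc2ccccc2)cc1", "CCOC(C)=O", "c1ccncc1"]
        for smi in targets:
            ref = fingerprint(smi, spec)
            for variant in random_smiles_renderings(smi, 5, seed=0):
                np.testing.assert_array_equal(fingerprint(variant, spec), ref)


class TestSolvents:
    def test_table_has_24_solvents(self):
        assert len(solvent_table()) == 24

    def test_thf_resolves_to_oxolane(self):
        assert resolve_solvent("THF") == "C1CCOC1"

    def test_synonyms_and_case(self):
        assert resolve_solvent("DMSO") == resolve_solvent("dimethyl sulfoxide")
        assert resolve_solvent("EA") == "CCOC(C)=O"

    def test_unknown_name_raises(self):
        with pytest.raises(SolventVocabularyError):
            resolve_solvent("unobtainium")

    def test_record_smiles_takes_precedence(self):
        rec = SpectralRecord("CCO", solvent_smiles="O", solvent_name="thf", lambda_abs=400.0)
        assert resolve_solvent(rec) == "O"


class TestEncodeSolvent:
    def test_water_daylight_block_all_zero(self):
        spec = DescriptorSpec(molecule_blocks=(FingerprintSpec("daylight"),))
        rec = SpectralRecord("c1ccccc1", solvent_name="water", lambda_abs=400.0)
        blocks = encode_solvent(rec, spec)
        assert len(blocks) == 1
        assert blocks[0][1].sum() == 0  # single heavy atom: no paths

    def test_one_hot_over_vocabulary(self):
        vocab = tuple(solvent_table()["name"])
        spec = DescriptorSpec(
            molecule_blocks=(FingerprintSpec("morgan"),),
            solvent_encoding="one_hot",
            solvent_vocabulary=vocab,
        )
        rec = SpectralRecord("c1ccccc1", solvent_name="toluene", lambda_abs=400.0)
        (_, vec), = encode_solvent(rec, spec)
        assert vec.shape == (24,)
        assert vec.sum() == 1
        assert vec[vocab.index("toluene")] == 1

    def test_one_hot_unknown_solvent_raises(self):
        spec = DescriptorSpec(
            molecule_blocks=(FingerprintSpec("morgan"),),
            solvent_encoding="one_hot",
            solvent_vocabulary=("water",),
        )
        rec = SpectralRecord("c1ccccc1", solvent_name="toluene", lambda_abs=400.0)
        with pytest.raises(SolventVocabularyError):
            encode_solvent(rec, spec)


class TestFuse:
    def test_lengths_add(self):
        fv = fuse([("a", np.zeros(2048)), ("b", np.ones(2048))])
        assert fv.values.shape == (4096,)
        assert [b.length for b in fv.layout] == [2048, 2048]

    def test_single_block_identity(self):
        x = np.arange(5.0)
        fv = fuse([("only", x)])
        np.testing.assert_array_equal(fv.values, x)

    def test_block_readback_bit_for_bit(self):
        rng = np.random.default_rng(3)
        blocks = [(f"b{i}", (rng.random(64) < 0.3).astype(float)) for i in range(4)]
        fv = fuse(blocks)
        for name, values in blocks:
            np.testing.assert_array_equal(fv.block(name), values)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fuse([])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=64), min_size=1, max_size=6))
    def test_length_is_sum_over_random_specs(self, lengths):
        blocks = [(f"b{i}", np.zeros(n)) for i, n in enumerate(lengths)]
        assert fuse(blocks).values.shape == (sum(lengths),)


class TestDescriptorSpec:
    def test_fused_preset_record_width_8192_with_four_blocks(self):
        spec = preset("toptorsion-daylight")
        rec = SpectralRecord("c1ccccc1", solvent_name="thf", lambda_abs=400.0)
        fv = featurize_record(rec, spec)
        assert fv.values.shape == (8192,)
        assert [b.name for b in fv.layout] == [
            "mol:torsion",
            "mol:daylight",
            "solv:torsion",
            "solv:daylight",
        ]

    def test_json_round_trip(self):
        spec = preset("atompair-daylight")
        again = DescriptorSpec.from_json(spec.to_json())
        assert again == spec

    def test_yaml_round_trip(self):
        import yaml

        spec = DescriptorSpec(
            molecule_blocks=("quantitative", FingerprintSpec("morgan", n_bits=1024)),
            solvent_encoding="quantitative_only",
        )
        again = DescriptorSpec.from_yaml(yaml.safe_dump(spec.to_dict()))
        assert again == spec

    def test_duplicate_blocks_rejected(self):
        with pytest.raises(ValueError):
            DescriptorSpec(molecule_blocks=(FingerprintSpec("morgan"), FingerprintSpec("morgan")))


class TestFeaturizeDataset:
    def _dataset(self, smiles_list):
        return Dataset(
            records=[
                SpectralRecord(s, solvent_name="thf", lambda_abs=400.0) for s in smiles_list
            ]
        )

    def test_matrix_shape_fused(self):
        ds = self._dataset(["c1ccccc1"] * 2 + ["CCO"] * 8)
        fm = featurize_dataset(ds, preset("toptorsion-daylight"))
        assert fm.X.shape == (10, 8192)

    def test_quantitative_spec_width_is_392(self):
        ds = self._dataset(["c1ccccc1", "CCO"])
        spec = DescriptorSpec(molecule_blocks=("quantitative",))
        fm = featurize_dataset(ds, spec)
        assert fm.X.shape == (2, 2 * N_QUANTITATIVE)

    def test_identical_records_identical_rows(self):
        ds = self._dataset(["c1ccccc1", "C1=CC=CC=C1"])
        fm = featurize_dataset(ds, preset("morgan-daylight"))
        np.testing.assert_array_equal(fm.X[0], fm.X[1])

    def test_failing_record_reports_row(self):
        ds = self._dataset(["c1ccccc1"])
        ds.records.append(
            SpectralRecord("c1ccccc1", solvent_name="unobtainium", lambda_abs=400.0)
        )
        with pytest.raises(FeaturizationError, match="rows"):
            featurize_dataset(ds, preset("morgan"))


class TestQuantitativeScaler:
    def test_scales_quantitative_blocks_with_train_stats_only(self):
        ds = Dataset(
            records=[
                SpectralRecord(s, solvent_name="thf", lambda_abs=400.0)
                for s in ["c1ccccc1", "CCO", "CCCCO", "c1ccncc1"]
            ]
        )
        spec = DescriptorSpec(molecule_blocks=("quantitative", FingerprintSpec("morgan")))
        fm = featurize_dataset(ds, spec)
        train_idx = np.array([0, 1])
        scaler = QuantitativeScaler.fit(fm, train_idx=train_idx)
        Xs = scaler.transform(fm.X)
        cols = fm.quantitative_columns()
        sub = Xs[train_idx][:, cols]
        varying = fm.X[train_idx][:, cols].std(axis=0) > 0
        np.testing.assert_allclose(sub.mean(axis=0)[varying], 0.0, atol=1e-5)
        # fingerprint columns untouched
        fp_cols = np.setdiff1d(np.arange(fm.X.shape[1]), cols)
        np.testing.assert_array_equal(Xs[:, fp_cols], fm.X[:, fp_cols])
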