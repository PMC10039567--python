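"""Metrics, fold plans, cross-validation, error and scalability analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aiegen.dataset import Dataset, SpectralRecord
from aiegen.evaluate import (
    benchmark_grid,
    cross_validate,
    error_distribution,
    mae,
    make_folds,
    make_group_folds,
    r2,
    rmse,
    scalability_study,
)
from aiegen.featurize import DescriptorSpec, preset
from aiegen.models import ModelSpec


class TestMetrics:
    def test_mae_example(self):
        assert mae([400, 500], [410, 490]) == pytest.approx(10.0)

    def test_rmse_example(self):
        assert rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))

    def test_identity_inputs_zero(self):
        v = np.arange(5.0)
        assert mae(v, v) == 0.0
        assert rmse(v, v) == 0.0

    def test_r2_perfect_mean_and_worse(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2(y, y) == pytest.approx(1.0)
        assert r2(y, np.full(4, y.mean())) == pytest.approx(0.0)
        assert r2(y, -y) < 0

    def test_r2_constant_truth_undefined(self):
        with pytest.raises(ValueError):
            r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])

    def test_mae_invariant_to_pair_permutation(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 50))
        perm = rng.permutation(50)
        assert mae(a, b) == pytest.approx(mae(a[perm], b[perm]))

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y_true = rng.normal(500, 50, n)
            y_pred = y_true + rng.normal(0, 10, n)
            brute_mae = sum(abs(a - b) for a, b in zip(y_true, y_pred)) / n
            brute_rmse = (sum((a - b) ** 2 for a, b in zip(y_true, y_pred)) / n) ** 0.5
            ss_res = sum((a - b) ** 2 for a, b in zip(y_true, y_pred))
            mean = sum(y_true) / n
            ss_tot = sum((a - mean) ** 2 for a in y_true)
            assert mae(y_true, y_pred) == pytest.approx(brute_mae, abs=1e-10)
            assert rmse(y_true, y_pred) == pytest.approx(brute_rmse, abs=1e-10)
            assert r2(y_true, y_pred) == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.normal(size=20)
            p = rng.normal(size=20)
            assert rmse(y, p) >= mae(y, p) - 1e-12


class TestFolds:
    def test_even_split(self):
        plan = make_folds(100, k=10, seed=0)
        sizes = np.bincount(plan.assignments, minlength=10)
        assert sizes.tolist() == [10] * 10

    def test_remainder_distribution(self):
        plan = make_folds(103, k=10, seed=0)
        sizes = sorted(np.bincount(plan.assignments, minlength=10).tolist())
        assert sizes == [10] * 7 + [11] * 3

    def test_deterministic(self):
        a = make_folds(57, k=10, seed=4)
        b = make_folds(57, k=10, seed=4)
        np.testing.assert_array_equal(a.assignments, b.assignments)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(9, k=10)

    @settings(max_examples=120, deadline=None)
    @given(st.integers(min_value=10, max_value=500), st.integers(min_value=0, max_value=10))
    def test_fold_invariants_over_n(self, n, seed):
        plan = make_folds(n, k=10, seed=seed)
        sizes = np.bincount(plan.assignments, minlength=10)
        assert sizes.sum() == n  # exhaustive
        assert sizes.max() - sizes.min() <= 1  # balanced
        all_idx = np.concatenate([plan.fold_indices(f) for f in range(10)])
        assert len(np.unique(all_idx)) == n  # mutually exclusive

    def test_group_folds_keep_molecules_together(self):
        groups = [f"m{i % 17}" for i in range(60)]
        plan = make_group_folds(groups, k=10, seed=1)
        for g in set(groups):
            idx = [i for i, gi in enumerate(groups) if gi == g]
            assert len(set(plan.assignments[idx])) == 1


def _linear_quantitative_dataset(n=120):
    """Targets are an exact linear function of one quantitative descriptor."""
    from aiegen.featurize import quantitative_descriptor_names, quantitative_descriptors
    from aiegen.fixtures import generate_molecules

    mols = generate_molecules(n, seed=21)
    idx = quantitative_descriptor_names().index("MolWt")
    records = [
        SpectralRecord(
            smi,
            solvent_name="tetrahydrofuran",
            lambda_abs=300.0 + 0.5 * float(quantitative_descriptors(smi)[idx]),
        )
        for smi in mols
    ]
    return Dataset(records=records)


class TestCrossValidate:
    def test_noiseless_linear_signal_recovered(self):
        ds = _linear_quantitative_dataset()
        spec = DescriptorSpec(molecule_blocks=("quantitative",), name="quantitative")
        report = cross_validate(
            ModelSpec("gbrt", {"n_estimators": 200}), spec, ds, "absorption", seed=0
        )
        assert report.r2 > 0.99

    def test_bit_identical_reports_for_fixed_seed(self, small_fixture):
        ds = small_fixture.dataset
        a = cross_validate(ModelSpec("xgb", {"n_estimators": 30}), preset("toptorsion"), ds, "absorption", seed=3)
        b = cross_validate(ModelSpec("xgb", {"n_estimators": 30}), preset("toptorsion"), ds, "absorption", seed=3)
        np.testing.assert_array_equal(a.residuals, b.residuals)
        assert a.mae == b.mae

    def test_permutation_null_destroys_signal(self, small_fixture):
        # shuffling targets should leave nothing learnable
        rng = np.random.default_rng(0)
        ds = small_fixture.dataset
        y = ds.targets("absorption")
        shuffled = rng.permutation(y)
        records = [
            SpectralRecord(
                r.molecule_smiles,
                solvent_name=r.solvent_name,
                lambda_abs=float(s),
            )
            for r, s in zip(ds, shuffled)
        ]
        null_ds = Dataset(records=records)
        report = cross_validate(
            ModelSpec("xgb", {"n_estimators": 50}), preset("toptorsion"), null_ds, "absorption", seed=0
        )
        assert report.r2 <= 0.1

    def test_aggregate_is_mean_of_folds_and_residuals_complete(self, small_fixture):
        report = cross_validate(
            ModelSpec("knn"), preset("toptorsion"), small_fixture.dataset, "emission", seed=1
        )
        assert report.mae == pytest.approx(float(np.mean(report.fold_mae)))
        assert report.residuals.shape == (len(small_fixture.dataset),)

    def test_no_leakage_from_test_fold_targets(self, small_fixture):
        """Corrupting one fold's targets never changes that fold's predictions."""
        ds = small_fixture.dataset
        spec = ModelSpec("xgb", {"n_estimators": 30})
        base = cross_validate(spec, preset("toptorsion"), ds, "absorption", seed=5)
        plan_fold = 0
        from aiegen.evaluate import make_folds

        plan = make_folds(len(ds), k=10, seed=5)
        corrupt_idx = plan.fold_indices(plan_fold)
        records = list(ds.records)
        for i in corrupt_idx:
            r = records[i]
            records[i] = SpectralRecord(
                r.molecule_smiles,
                solvent_name=r.solvent_name,
                lambda_abs=r.lambda_abs + 500.0,
                lambda_em=r.lambda_em,
            )
        corrupted = cross_validate(
            spec, preset("toptorsion"), Dataset(records=records), "absorption", seed=5
        )
        y = ds.targets("absorption")
        y_bad = y.copy()
        y_bad[corrupt_idx] += 500.0
        pred_base = y + base.residuals
        pred_corrupt = y_bad + corrupted.residuals
        np.testing.assert_allclose(pred_base[corrupt_idx], pred_corrupt[corrupt_idx], rtol=1e-6)


class TestErrorDistribution:
    def test_direct_binning(self):
        dist = error_distribution(np.array([1.0, -5.0, 15.0, 25.0]))
        assert dist.counts == (2, 1, 1)
        assert dist.fractions == (0.5, 0.25, 0.25)

    def test_all_zero_residuals(self):
        dist = error_distribution(np.zeros(7))
        assert dist.counts == (7, 0, 0)

    def test_sign_invariant(self):
        a = error_distribution(np.array([3.0, 12.0, 30.0]))
        b = error_distribution(np.array([-3.0, -12.0, -30.0]))
        assert a.counts == b.counts

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        dist = error_distribution(rng.normal(0, 15, 500))
        assert sum(dist.fractions) == pytest.approx(1.0)


class TestScalability:
    def test_single_fraction_point(self, small_fixture):
        curve = scalability_study(
            ModelSpec("knn"),
            preset("toptorsion"),
            small_fixture.dataset,
            "absorption",
            fractions=[0.5],
            seed=0,
            repeats=2,
        )
        assert len(curve.points) == 1
        assert curve.points[0].train_fraction == 0.5

    def test_deterministic_given_seed(self, small_fixture):
        args = (ModelSpec("knn"), preset("toptorsion"), small_fixture.dataset, "absorption")
        a = scalability_study(*args, fractions=[0.3, 0.6], seed=2, repeats=2)
        b = scalability_study(*args, fractions=[0.3, 0.6], seed=2, repeats=2)
        assert [p.mean_mae for p in a] == [p.mean_mae for p in b]

    def test_invalid_fractions_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            scalability_study(
                ModelSpec("knn"), preset("toptorsion"), small_fixture.dataset,
                "absorption", fractions=[0.9, 0.2], seed=0,
            )
        with pytest.raises(ValueError):
            scalability_study(
                ModelSpec("knn"), preset("toptorsion"), small_fixture.dataset,
                "absorption", fractions=[1.5], seed=0,
            )


class TestBenchmarkGrid:
    def test_two_by_two_grid_counts(self, small_fixture):
        result = benchmark_grid(
            ["knn", "xgb"],
            ["toptorsion", "daylight"],
            small_fixture.dataset,
            targets=("absorption",),
            seed=0,
            model_hyperparameters={"xgb": {"n_estimators": 30}},
        )
        assert len(result.table) == 4
        assert set(result.winners) == {"absorption"}
        model, descriptor = result.winners["absorption"]
        best_row = result.table.iloc[0]
        assert (best_row["model"], best_row["descriptor"]) == (model, descriptor)

    def test_reproducible_with_fixed_seed(self, small_fixture):
        kwargs = dict(targets=("absorption",), seed=1, model_hyperparameters={"xgb": {"n_estimators": 20}})
        a = benchmark_grid(["xgb"], ["toptorsion"], small_fixture.dataset, **kwargs)
        b = benchmark_grid(["xgb"], ["toptorsion"], small_fixture.dataset, **kwargs)
        assert a.table.equals(b.table)

    def test_empty_grid_rejected(self, small_fixture):
        with pytest.raises(ValueError):
            benchmark_grid([], ["toptorsion"], small_fixture.dataset)
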