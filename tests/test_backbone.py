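"""Descriptor regressor: invariances, force contract, ensembles, training."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pesuq.backbone import (
    DescriptorConfig,
    DescriptorRegressor,
    TrainConfig,
    ensemble_predict,
    ensemble_statistics,
    featurize,
    select_committee,
    train_ensemble,
    train_model,
)
from pesuq.chemio import Structure
from pesuq.evidential import NIGParams


class TestFeaturize:
    def test_eight_atoms_give_28_pair_features(self, rng):
        coords = rng.normal(0, 2, (8, 3)) + 4 * np.arange(8)[:, None]
        assert featurize(coords).shape == (28,)

    def test_rotation_translation_invariance(self, rng):
        coords = rng.normal(0, 2, (5, 3)) + 4 * np.arange(5)[:, None]
        rot = Rotation.random(random_state=0).as_matrix()
        moved = coords @ rot.T + np.array([3.0, -1.0, 2.0])
        assert np.allclose(featurize(coords), featurize(moved), atol=1e-10)

    def test_coincident_atoms_raise(self):
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="singular"):
            featurize(coords)

    def test_gaussian_expansion_dimensions_and_jacobian(self, rng):
        coords = rng.normal(0, 2, (4, 3)) + 4 * np.arange(4)[:, None]
        config = DescriptorConfig(n_gaussians=8)
        feat, jac = featurize(coords, config, with_jacobian=True)
        assert feat.shape == (6 * 8,)
        assert jac.shape == (48, 12)
        # Jacobian against finite differences
        h = 1e-6
        k = 5
        cp = coords.copy()
        cp.ravel()[k] += h
        cm = coords.copy()
        cm.ravel()[k] -= h
        num = (featurize(cp, config) - featurize(cm, config)) / (2 * h)
        assert np.allclose(jac[:, k], num, atol=1e-6)


class TestEnsembleStatistics:
    def test_identical_members_have_zero_std(self):
        out = ensemble_statistics([1.0, 1.0, 1.0])
        assert out.mean == 1.0 and out.std == 0.0

    def test_two_member_population_normalization(self):
        out = ensemble_statistics([0.0, 2.0])
        assert out.mean == 1.0 and out.std == 1.0

    def test_three_member_value(self):
        # population std of (1,2,3) is sqrt(2/3)
        out = ensemble_statistics([1.0, 2.0, 3.0])
        assert np.isclose(out.std, np.sqrt(2.0 / 3.0))

    def test_permutation_invariance(self, rng):
        e = rng.normal(size=6)
        a = ensemble_statistics(e)
        b = ensemble_statistics(rng.permutation(e))
        assert np.isclose(a.std, b.std) and np.isclose(a.mean, b.mean)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            ensemble_statistics([1.0])


class TestPredictionContract:
    def test_forces_are_negative_energy_gradient(self, trained_scalar_model,
                                                 small_benchmark):
        _, test, _ = small_benchmark
        s = test[0]
        rec = trained_scalar_model.predict(s)
        h = 1e-4
        num = np.zeros_like(s.coordinates)
        for i in range(s.n_atoms):
            for k in range(3):
                xp = s.coordinates.copy()
                xp[i, k] += h
                xm = s.coordinates.copy()
                xm[i, k] -= h
                ep = trained_scalar_model.predict(
                    Structure(s.atomic_numbers, xp)
                ).energy
                em = trained_scalar_model.predict(
                    Structure(s.atomic_numbers, xm)
                ).energy
                num[i, k] = -(ep - em) / (2 * h)
        rel = np.abs(num - rec.forces).max() / np.abs(num).max()
        assert rel < 1e-4

    def test_energy_invariant_forces_covariant(self, trained_scalar_model,
                                               small_benchmark):
        _, test, _ = small_benchmark
        s = test[1]
        rot = Rotation.random(random_state=3).as_matrix()
        rec = trained_scalar_model.predict(s)
        rec_rot = trained_scalar_model.predict(
            Structure(s.atomic_numbers, s.coordinates @ rot.T)
        )
        assert np.isclose(rec.energy, rec_rot.energy, atol=1e-8)
        assert np.abs(rec_rot.forces @ rot - rec.forces).max() < 1e-8

    def test_duplicate_structures_get_identical_records(
        self, trained_scalar_model, small_benchmark
    ):
        _, test, _ = small_benchmark
        recs = trained_scalar_model.predict([test[2], test[2]])
        assert recs[0].energy == recs[1].energy
        assert np.array_equal(recs[0].forces, recs[1].forces)

    def test_composition_mismatch_rejected(self, trained_scalar_model):
        s = Structure([6, 1], [[0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="composition"):
            trained_scalar_model.predict(s)

    def test_features_have_hidden_width(self, trained_scalar_model,
                                        small_benchmark):
        _, test, _ = small_benchmark
        rec = trained_scalar_model.predict(test[0])
        assert rec.features.shape == (32,)


class TestTraining:
    def test_learning_beats_untrained_baseline(self, small_benchmark,
                                               trained_scalar_model):
        trainval, _, _ = small_benchmark
        val = [trainval[i] for i in trainval.indices("validation")]
        e_ref = np.array([s.energy for s in val])
        e_pred = np.array(
            [r.energy for r in trained_scalar_model.predict(val)]
        )
        mae = np.abs(e_pred - e_ref).mean()
        baseline = np.abs(e_ref - e_ref.mean()).mean()
        assert mae < 0.5 * baseline

    def test_same_seed_reproduces_validation_loss(self, small_benchmark):
        trainval, _, _ = small_benchmark
        config = TrainConfig(
            hidden=(16, 16), max_epochs=20, batch_size=64,
            learning_rate=3e-3, early_stopping_patience=100,
        )
        a = train_model(trainval, config, head="scalar", seed=11)
        b = train_model(trainval, config, head="scalar", seed=11)
        assert a.best_val_loss == b.best_val_loss

    def test_quadratic_slice_fit_nearly_exact(self):
        # a pure quadratic along one bond is inside the model class
        from pesuq.chemio import Dataset, split_dataset

        rng = np.random.default_rng(0)
        structures = []
        for _ in range(300):
            r = rng.uniform(0.8, 1.3)
            coords = np.array([[0.0, 0, 0], [r, 0, 0]])
            e = 50.0 * (r - 1.0) ** 2
            f = np.array([[100.0 * (r - 1.0), 0, 0],
                          [-100.0 * (r - 1.0), 0, 0]])
            structures.append(
                Structure([1, 1], coords, energy=e, forces=f)
            )
        ds = split_dataset(Dataset(structures), 0.8, seed=0)
        config = TrainConfig(
            hidden=(16, 16), max_epochs=500, batch_size=32,
            learning_rate=3e-3, early_stopping_patience=100,
        )
        model = train_model(ds, config, head="scalar", seed=0)
        val = [ds[i] for i in ds.indices("validation")]
        e_pred = np.array([r.energy for r in model.predict(val)])
        e_ref = np.array([s.energy for s in val])
        assert np.abs(e_pred - e_ref).mean() <= 0.1

    def test_nig_head_contract(self, small_benchmark):
        trainval, test, _ = small_benchmark
        config = TrainConfig(
            hidden=(16, 16), max_epochs=30, batch_size=64,
            learning_rate=3e-3, early_stopping_patience=100,
        )
        model = train_model(trainval, config, head="nig", seed=1)
        rec = model.predict(test[0])
        p = rec.head_outputs
        assert isinstance(p, NIGParams)
        assert p.nu > 0 and p.alpha > 1 and p.beta > 0
        assert rec.energy == p.gamma


def test_mae_improves_with_training_set_size(toy_pes):
    """Held-out in-distribution MAE drops as training data doubles 250->1000."""
    from pesuq.toysystem import SamplerConfig, make_benchmark

    config = TrainConfig(
        hidden=(32, 32), max_epochs=250, batch_size=32,
        learning_rate=3e-3, early_stopping_patience=100,
    )
    maes = {}
    for n in (250, 1000):
        trainval, test, _ = make_benchmark(
            toy_pes, SamplerConfig(n_samples=n, seed=21),
            n_test_id=120, n_test_ood=0, test_temperatures=(300.0,),
        )
        model = train_model(trainval, config, head="scalar", seed=5)
        e_pred = np.array([r.energy for r in model.predict(list(test))])
        maes[n] = np.abs(e_pred - test.energies()).mean()
    assert maes[1000] < maes[250]


class TestEnsembles:
    def test_six_members_differ(self, small_benchmark):
        trainval, test, _ = small_benchmark
        config = TrainConfig(
            hidden=(16, 16), max_epochs=20, batch_size=64,
            learning_rate=3e-3, early_stopping_patience=100,
        )
        models = train_ensemble(trainval, config, n_members=6, seed=2)
        assert len(models) == 6
        energies = [m.predict(test[0]).energy for m in models]
        assert len(set(np.round(energies, 10))) > 1

        ens3 = select_committee(models, "ens3")
        assert [id(m) for m in ens3] == [id(models[i]) for i in (0, 2, 4)]

        stats = ensemble_predict(models, [test[0], test[1]])
        assert len(stats) == 2 and stats[0].std >= 0

    def test_single_member_committee_rejected(self, small_benchmark):
        trainval, _, _ = small_benchmark
        with pytest.raises(ValueError):
            train_ensemble(trainval, n_members=1, seed=0)


class TestPersistence:
    def test_checkpoint_round_trip(self, trained_scalar_model, small_benchmark,
                                   tmp_path):
        _, test, _ = small_benchmark
        path = tmp_path / "model.npz"
        trained_scalar_model.save(path)
        back = DescriptorRegressor.load(path)
        a = trained_scalar_model.predict(test[0])
        b = back.predict(test[0])
        assert a.energy == b.energy
        assert np.array_equal(a.forces, b.forces)
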