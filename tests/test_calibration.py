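"""MLP training, winner-takes-all prediction and grouped cross-validation."""

import numpy as np
import pandas as pd
import pytest

from phylis.calibration import (
    LabeledSpectrumSet,
    MLPCalibration,
    MLPHyper,
    make_folds,
    predict_winner,
    run_classification_cv,
    train_mlp,
)
from phylis.errors import TooFewGroups
from phylis.evaluation import cohens_kappa
from phylis.synthetic_data import ClassModel, generate_crop_dataset


def _logit(p):
    return np.log(p / (1 - p))


class TestMakeFolds:
    def test_field_design_partition_and_pair_integrity(self):
        groups = [f"g{i:02d}" for i in range(48) for _ in range(2)]
        plan = make_folds(groups, k=10, seed=3)
        sizes = [len({groups[i] for i in f}) for f in plan.folds]
        assert sorted(sizes) == [4, 4, 5, 5, 5, 5, 5, 5, 5, 5]
        all_idx = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(all_idx, np.arange(96))
        for f in plan.folds:  # both twins of a group in the same fold
            for i in f:
                assert plan.fold_of_group[groups[i]] == plan.fold_of_group[groups[f[0]]]

    def test_k_equals_groups_is_leave_one_group_out(self):
        groups = [f"g{i}" for i in range(12)]
        plan = make_folds(groups, k=12, seed=0)
        assert all(len(f) == 1 for f in plan.folds)

    def test_same_seed_reproduces_plan(self):
        groups = [f"g{i}" for i in range(20) for _ in range(2)]
        a = make_folds(groups, k=10, seed=7)
        b = make_folds(groups, k=10, seed=7)
        assert a.fold_of_group == b.fold_of_group

    def test_too_few_groups(self):
        with pytest.raises(TooFewGroups):
            make_folds(["a", "b"], k=10)


class TestTraining:
    def test_xor_becomes_separable(self):
        """The classic non-linear toy: backprop must fit XOR exactly."""
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        labels = ["lo", "hi", "hi", "lo"]
        X = np.tile(pts, (4, 1))
        crop = labels * 4
        ds = LabeledSpectrumSet(spectra=X, crop=crop,
                                group_ids=[str(i) for i in range(len(crop))])
        model = train_mlp(ds, "classify", MLPHyper(epochs=8000), seed=1)
        preds = [predict_winner(model, x)[0] for x in X]
        assert preds == crop

    def test_constant_target_regression_converges_to_constant(self):
        rng = np.random.default_rng(2)
        X = rng.random((20, 30))
        soil = pd.DataFrame({"NO3": np.full(20, 55.5)})
        ds = LabeledSpectrumSet(spectra=X, crop=["c"] * 20,
                                group_ids=[str(i) for i in range(20)], soil=soil)
        model = train_mlp(ds, "regress", MLPHyper(epochs=10), seed=0)
        preds = model.predict_scaled_targets(X)
        np.testing.assert_allclose(preds, 55.5)

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.random((12, 10))
        ds = LabeledSpectrumSet(spectra=X, crop=["a", "b"] * 6,
                                group_ids=[str(i) for i in range(12)])
        m1 = train_mlp(ds, "classify", MLPHyper(epochs=20), seed=9)
        m2 = train_mlp(ds, "classify", MLPHyper(epochs=20), seed=9)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)


class TestPredictWinner:
    def _fixed_output_model(self, outputs):
        """A network whose outputs are constant, set via final-layer biases."""
        n_out = len(outputs)
        model = MLPCalibration(
            layer_sizes=[3, 2, 2, n_out],
            weights=[np.zeros((2, 3)), np.zeros((2, 2)), np.zeros((n_out, 2))],
            biases=[np.zeros(2), np.zeros(2), _logit(np.asarray(outputs))],
            seed=0,
            crop_classes=["c1", "c2", "c3", "c4"],
            system_classes=["s1", "s2"],
        )
        return model

    def test_argmax_within_blocks(self):
        model = self._fixed_output_model([0.9, 0.1, 0.1, 0.1, 0.2, 0.8])
        assert predict_winner(model, np.zeros(3)) == ("c1", "s2")

    def test_tie_broken_to_lowest_index(self):
        model = self._fixed_output_model([0.5, 0.5, 0.1, 0.1, 0.5, 0.5])
        assert predict_winner(model, np.zeros(3)) == ("c1", "s1")

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            outs = rng.uniform(0.05, 0.95, 6)
            model = self._fixed_output_model(outs)
            crop, system = predict_winner(model, np.zeros(3))
            best_crop = max(range(4), key=lambda i: outs[i])
            best_sys = max(range(2), key=lambda i: outs[4 + i])
            assert crop == model.crop_classes[best_crop]
            assert system == model.system_classes[best_sys]


@pytest.fixture(scope="module")
def small_design():
    curves = []
    for i in range(4):  # well-separated block curves
        c = np.zeros(1000)
        c[i * 250:(i + 1) * 250] = 0.8
        curves.append(c)
    classes = [ClassModel(f"crop{i}", c, within_sd=0.02)
               for i, c in enumerate(curves)]
    return generate_crop_dataset(classes, n_per_class=8, twins=True, seed=6,
                                 systems=("sustainable", "conventional"))


class TestClassificationCV:

    def test_marginals_match_design_and_each_sample_validated_once(self, small_design):
        cm_crop, cm_sys = run_classification_cv(
            small_design, hyper=MLPHyper(epochs=60), seed=2, k=10)
        assert cm_crop.n == 32
        np.testing.assert_array_equal(cm_crop.counts.sum(axis=0), [8, 8, 8, 8])
        assert cm_sys.n == 32
        np.testing.assert_array_equal(cm_sys.counts.sum(axis=0), [16, 16])

    def test_separable_classes_recovered(self, small_design):
        cm_crop, _ = run_classification_cv(
            small_design, hyper=MLPHyper(epochs=400), seed=2, k=10)
        acc = np.trace(cm_crop.counts) / cm_crop.n
        assert acc >= 0.9

    def test_shuffled_labels_give_near_zero_kappa(self, small_design):
        kappas = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            # permute crop labels at the group level (twins keep equal labels)
            groups = list(dict.fromkeys(small_design.group_ids))
            glabel = {g: small_design.crop[small_design.group_ids.index(g)]
                      for g in groups}
            shuffled = rng.permutation(list(glabel.values()))
            relabel = dict(zip(groups, shuffled))
            null_ds = LabeledSpectrumSet(
                spectra=small_design.spectra,
                crop=[relabel[g] for g in small_design.group_ids],
                group_ids=small_design.group_ids,
                system=small_design.system)
            cm, _ = run_classification_cv(null_ds, hyper=MLPHyper(epochs=150),
                                          seed=seed, k=10)
            kappas.append(cohens_kappa(cm))
        assert abs(np.mean(kappas)) < 0.15
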