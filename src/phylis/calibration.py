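"""Backpropagation MLP calibration with pair-preserving 10-fold cross-validation.

Two calibration tasks share one network shape and training procedure:

* **classification** — one network with one output per crop class plus one
  per cropping system (six outputs for the four-crop, two-system field
  design); the target vector is one-hot within each block, and prediction is
  winner-takes-all *within each block* independently.
* **regression** — one network with one output per soil property (eighteen
  in the field design); targets are min–max scaled to [0, 1] using
  training-fold statistics only, and predictions are inverse-scaled back to
  physical units before any metric is computed.

The network is a feed-forward perceptron with two hidden layers of 20
logistic-sigmoid nodes, trained by plain online (per-sample) stochastic
gradient descent on squared error at a fixed learning rate of 0.05 —
deliberately the classical backpropagation recipe, not a modern optimiser.

Spectra captured in duplicate at one sample location ("twins") share a
``group_id``; :func:`make_folds` always keeps a group's members in the same
fold, because splitting twins across train and validation leaks
near-duplicate samples and inflates validation scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import NonFiniteLoss, TooFewGroups
from .preprocessing import PreprocessSpec, apply_preprocess


@dataclass
class LabeledSpectrumSet:
    """Spectra with crop/system labels, optional soil properties and group ids.

    ``spectra`` is an (n_samples, n_positions) array; ``soil`` (if present)
    is an (n_samples, n_properties) DataFrame in original physical units.
    """

    spectra: np.ndarray
    crop: list[str]
    group_ids: list[str]
    system: list[str] | None = None
    soil: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        n = self.spectra.shape[0]
        if len(self.crop) != n or len(self.group_ids) != n:
            raise ValueError("label lists must match number of spectra")
        if self.system is not None and len(self.system) != n:
            raise ValueError("system labels must match number of spectra")
        if self.soil is not None and len(self.soil) != n:
            raise ValueError("soil table must match number of spectra")

    @property
    def n(self) -> int:
        return self.spectra.shape[0]

    @property
    def crop_classes(self) -> list[str]:
        return sorted(set(self.crop))

    @property
    def system_classes(self) -> list[str]:
        return sorted(set(self.system)) if self.system is not None else []

    def subset(self, idx) -> "LabeledSpectrumSet":
        idx = np.asarray(idx)
        return LabeledSpectrumSet(
            spectra=self.spectra[idx],
            crop=[self.crop[i] for i in idx],
            group_ids=[self.group_ids[i] for i in idx],
            system=[self.system[i] for i in idx] if self.system is not None else None,
            soil=self.soil.iloc[idx].reset_index(drop=True) if self.soil is not None else None,
        )

    def preprocessed(self, spec: PreprocessSpec | None) -> np.ndarray:
        if spec is None:
            return self.spectra
        return np.vstack([apply_preprocess(row, spec) for row in self.spectra])


@dataclass
class CrossValPlan:
    """Fold assignment for grouped k-fold cross-validation."""

    k: int
    fold_of_group: dict[str, int]
    folds: list[np.ndarray]  # sample indices per fold

    def train_indices(self, fold: int) -> np.ndarray:
        return np.concatenate([f for j, f in enumerate(self.folds) if j != fold])


def make_folds(group_ids: list[str], k: int = 10, seed: int = 0) -> CrossValPlan:
    """Deal sample-location groups into k folds, keeping twins together.

    Distinct groups (in order of first appearance) are shuffled by a seeded
    RNG and dealt round-robin, so fold sizes differ by at most one group and
    every member of a group lands in the same fold.
    """
    groups = list(dict.fromkeys(group_ids))
    if len(groups) < k:
        raise TooFewGroups(f"{len(groups)} groups cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = [groups[i] for i in rng.permutation(len(groups))]
    fold_of_group = {g: i % k for i, g in enumerate(order)}
    folds = [
        np.array([j for j, g in enumerate(group_ids) if fold_of_group[g] == f], dtype=int)
        for f in range(k)
    ]
    return CrossValPlan(k=k, fold_of_group=fold_of_group, folds=folds)


@dataclass
class MLPHyper:
    """Training hyperparameters for the backpropagation network."""

    hidden: tuple[int, int] = (20, 20)
    learning_rate: float = 0.05
    epochs: int = 5000
    init_scale: float = 0.5  # weights drawn uniform(-scale, +scale)


@dataclass
class MLPCalibration:
    """A trained feed-forward network (all layers logistic sigmoid).

    ``weights[l]`` maps layer l activations to layer l+1 pre-activations.
    Task-specific metadata (class blocks or target scaling) is attached by
    the training wrappers.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    seed: int
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    crop_classes: list[str] | None = None
    system_classes: list[str] | None = None
    property_names: list[str] | None = None
    target_min: np.ndarray | None = None
    target_range: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network outputs (sigmoid activations) for rows of X."""
        A = np.atleast_2d(np.asarray(X, dtype=float))
        for W, b in zip(self.weights, self.biases):
            A = expit(A @ W.T + b)
        return A

    def predict_scaled_targets(self, X: np.ndarray) -> np.ndarray:
        """Regression predictions mapped back to original physical units."""
        if self.target_min is None or self.target_range is None:
            raise ValueError("model was not trained for regression")
        return self.forward(X) * self.target_range + self.target_min

    def to_json(self, path) -> None:
        payload = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "seed": self.seed,
            "crop_classes": self.crop_classes,
            "system_classes": self.system_classes,
            "property_names": self.property_names,
            "target_min": None if self.target_min is None else self.target_min.tolist(),
            "target_range": None if self.target_range is None else self.target_range.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            layer_sizes=d["layer_sizes"],
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            seed=d["seed"],
            crop_classes=d.get("crop_classes"),
            system_classes=d.get("system_classes"),
            property_names=d.get("property_names"),
            target_min=None if d.get("target_min") is None else np.asarray(d["target_min"]),
            target_range=None if d.get("target_range") is None else np.asarray(d["target_range"]),
        )


def _fit_network(X: np.ndarray, T: np.ndarray, hyper: MLPHyper,
                 seed: int) -> MLPCalibration:
    """Online backpropagation on squared error; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    n, n_in = X.shape
    n_out = T.shape[1]
    sizes = [n_in, *hyper.hidden, n_out]
    rng = np.random.default_rng(seed)
    Ws = [rng.uniform(-hyper.init_scale, hyper.init_scale, (sizes[i + 1], sizes[i]))
          for i in range(len(sizes) - 1)]
    bs = [rng.uniform(-hyper.init_scale, hyper.init_scale, sizes[i + 1])
          for i in range(len(sizes) - 1)]
    lr = hyper.learning_rate
    losses = np.empty(hyper.epochs)
    for epoch in range(hyper.epochs):
        sse = 0.0
        for i in rng.permutation(n):
            x = X[i]
            # forward
            acts = [x]
            for W, b in zip(Ws, bs):
                acts.append(expit(W @ acts[-1] + b))
            err = acts[-1] - T[i]
            sse += float(err @ err)
            # backward: deltas computed against pre-update weights
            delta = err * acts[-1] * (1 - acts[-1])
            for l in range(len(Ws) - 1, -1, -1):
                grad_W = np.outer(delta, acts[l])
                grad_b = delta
                if l > 0:
                    delta = (Ws[l].T @ delta) * acts[l] * (1 - acts[l])
                Ws[l] -= lr * grad_W
                bs[l] -= lr * grad_b
        losses[epoch] = sse / n
        if not np.isfinite(losses[epoch]):
            raise NonFiniteLoss(f"training loss non-finite at epoch {epoch}")
    if hyper.epochs > 1 and losses[-1] > losses[0]:
        warnings.warn("training loss increased over the run; model may not have converged",
                      stacklevel=2)
    return MLPCalibration(layer_sizes=sizes, weights=Ws, biases=bs, seed=seed,
                          loss_history=losses)


def classification_targets(dataset: LabeledSpectrumSet) -> tuple[np.ndarray, list[str], list[str]]:
    """Block one-hot targets: crop block followed by system block (if any)."""
    crops = dataset.crop_classes
    systems = dataset.system_classes
    n_out = len(crops) + len(systems)
    T = np.zeros((dataset.n, n_out))
    for i in range(dataset.n):
        T[i, crops.index(dataset.crop[i])] = 1.0
        if systems:
            T[i, len(crops) + systems.index(dataset.system[i])] = 1.0
    return T, crops, systems


def train_mlp(dataset: LabeledSpectrumSet, task: str, hyper: MLPHyper | None = None,
              seed: int = 0, preprocess: PreprocessSpec | None = None) -> MLPCalibration:
    """Train one calibration network on a labelled spectrum set.

    ``task`` is ``"classify"`` (crop + system block outputs) or ``"regress"``
    (one output per soil property, min–max scaled from this training set).
    """
    hyper = hyper or MLPHyper()
    X = dataset.preprocessed(preprocess)
    if task == "classify":
        if len(dataset.crop_classes) < 2:
            raise ValueError("classification needs at least 2 crop classes")
        T, crops, systems = classification_targets(dataset)
        model = _fit_network(X, T, hyper, seed)
        model.crop_classes = crops
        model.system_classes = systems
        return model
    if task == "regress":
        if dataset.soil is None or dataset.soil.shape[1] < 1:
            raise ValueError("regression needs at least one soil property column")
        Y = dataset.soil.to_numpy(dtype=float)
        tmin = Y.min(axis=0)
        trange = Y.max(axis=0) - tmin
        safe_range = np.where(trange > 0, trange, 1.0)
        T = np.where(trange > 0, (Y - tmin) / safe_range, 0.5)
        model = _fit_network(X, T, hyper, seed)
        model.property_names = list(dataset.soil.columns)
        model.target_min = tmin
        # degenerate (constant) targets inverse-map to the constant
        model.target_range = np.where(trange > 0, trange, 0.0)
        return model
    raise ValueError(f"unknown task {task!r}")


def predict_winner(model: MLPCalibration, spectrum) -> tuple[str, str | None]:
    """Winner-takes-all prediction: argmax within the crop and system blocks.

    Ties go to the lowest output index.
    """
    out = model.forward(np.atleast_2d(spectrum))[0]
    if model.crop_classes is None:
        raise ValueError("model was not trained for classification")
    n_crop = len(model.crop_classes)
    crop = model.crop_classes[int(np.argmax(out[:n_crop]))]
    system = None
    if model.system_classes:
        system = model.system_classes[int(np.argmax(out[n_crop:]))]
    return crop, system


def run_classification_cv(dataset: LabeledSpectrumSet,
                          preprocess: PreprocessSpec | None = None,
                          hyper: MLPHyper | None = None,
                          seed: int = 0, k: int = 10):
    """Grouped k-fold CV for crop/system classification.

    Returns a pair of confusion matrices (crop, system), rows = predicted
    class and columns = true class, with counts accumulated over the k
    held-out folds so every sample is validated exactly once.  The system
    matrix is None when the dataset has no system labels.
    """
    from .evaluation import ConfusionMatrix

    hyper = hyper or MLPHyper()
    plan = make_folds(dataset.group_ids, k=k, seed=seed)
    X = dataset.preprocessed(preprocess)
    crops = dataset.crop_classes
    systems = dataset.system_classes
    cm_crop = np.zeros((len(crops), len(crops)), dtype=int)
    cm_sys = np.zeros((len(systems), len(systems)), dtype=int) if systems else None
    for fold in range(plan.k):
        train_idx = plan.train_indices(fold)
        train = dataset.subset(train_idx)
        T, _, _ = classification_targets(train)
        # classes must agree across folds for the block layout to line up
        if train.crop_classes != crops or train.system_classes != systems:
            raise ValueError("a fold lost an entire class; use more samples per class")
        model = _fit_network(X[train_idx], T, hyper, seed + fold)
        model.crop_classes = crops
        model.system_classes = systems
        for i in plan.folds[fold]:
            pred_crop, pred_sys = predict_winner(model, X[i])
            cm_crop[crops.index(pred_crop), crops.index(dataset.crop[i])] += 1
            if cm_sys is not None:
                cm_sys[systems.index(pred_sys), systems.index(dataset.system[i])] += 1
    crop_cm = ConfusionMatrix(counts=cm_crop, class_names=crops)
    sys_cm = ConfusionMatrix(counts=cm_sys, class_names=systems) if cm_sys is not None else None
    return crop_cm, sys_cm


def run_regression_cv(dataset: LabeledSpectrumSet,
                      preprocess: PreprocessSpec | None = None,
                      hyper: MLPHyper | None = None,
                      seed: int = 0, k: int = 10,
                      group_folds: bool = True):
    """Grouped k-fold CV for multi-output soil-property regression.

    Out-of-fold predictions are inverse-scaled to original units before
    computing per-property r² and RMSE.  ``group_folds=False`` deliberately
    ignores the twin structure (each sample is its own group), the leaky
    design that pair-preserving folds exist to prevent; it is provided for
    ablation studies.

    Returns a :class:`~phylis.evaluation.RegressionEval`.
    """
    from .evaluation import RegressionEval

    hyper = hyper or MLPHyper()
    if dataset.soil is None:
        raise ValueError("dataset has no soil property table")
    ids = dataset.group_ids if group_folds else [str(i) for i in range(dataset.n)]
    plan = make_folds(ids, k=k, seed=seed)
    X = dataset.preprocessed(preprocess)
    Y = dataset.soil.to_numpy(dtype=float)
    preds = np.full_like(Y, np.nan, dtype=float)
    for fold in range(plan.k):
        train_idx = plan.train_indices(fold)
        train_ds = LabeledSpectrumSet(
            spectra=X[train_idx],
            crop=[dataset.crop[i] for i in train_idx],
            group_ids=[dataset.group_ids[i] for i in train_idx],
            soil=dataset.soil.iloc[train_idx].reset_index(drop=True),
        )
        model = train_mlp(train_ds, "regress", hyper, seed=seed + fold)
        preds[plan.folds[fold]] = model.predict_scaled_targets(X[plan.folds[fold]])
    return RegressionEval.from_predictions(
        dataset.soil, pd.DataFrame(preds, columns=dataset.soil.columns))
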