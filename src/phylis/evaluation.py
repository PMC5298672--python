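"""Confusion-matrix and regression statistics for calibration evaluation.

Conventions match remote-sensing accuracy assessment: confusion matrices are
oriented with *rows = predicted* class and *columns = true* class, so user's
accuracy (reliability of a prediction) is the diagonal over the row margin
and producer's accuracy (how well a true class is recovered) is the diagonal
over the column margin.  Cohen's kappa corrects the overall accuracy for
chance agreement implied by the margins.

Regression calibrations are scored per property by the r² of the linear
regression between targets and predictions (squared Pearson correlation, so
it is invariant to an affine miscalibration of the predictions) and by the
RMSE in the property's original physical units (which is not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateMatrix


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_names)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, predicted, true, class_names=None) -> "ConfusionMatrix":
        names = class_names or sorted(set(true) | set(predicted))
        idx = {c: i for i, c in enumerate(names)}
        m = np.zeros((len(names), len(names)), dtype=int)
        for p, t in zip(predicted, true):
            m[idx[p], idx[t]] += 1
        return cls(counts=m, class_names=list(names))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)
        df.index.name = "predicted"
        df.columns.name = "true"
        return df


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total: the fraction of samples classified correctly."""
    return float(np.trace(cm.counts) / cm.n)


def users_producers_accuracy(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class user's (row-wise) and producer's (column-wise) accuracy.

    A zero margin yields NaN for the corresponding accuracy (no predictions
    were made for, or no true samples exist of, that class).
    """
    diag = np.diag(cm.counts).astype(float)
    row_tot = cm.counts.sum(axis=1).astype(float)
    col_tot = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(row_tot > 0, diag / row_tot, np.nan)
        producers = np.where(col_tot > 0, diag / col_tot, np.nan)
    return pd.DataFrame(
        {"users_accuracy": users, "producers_accuracy": producers},
        index=cm.class_names,
    )


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement: κ = (p_o − p_e) / (1 − p_e).

    p_o is the observed agreement (trace/n) and p_e the agreement expected
    from the row and column margins alone.
    """
    n = cm.n
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(row @ col) / n**2
    if p_e == 1.0:
        raise DegenerateMatrix("expected agreement is 1; kappa undefined")
    return float((p_o - p_e) / (1 - p_e))


def r_squared(targets, predictions, method: str = "correlation") -> float:
    """Coefficient of determination between targets and predictions.

    ``method="correlation"`` (default) is the r² of the fitted linear
    regression of targets on predictions — the squared Pearson correlation,
    invariant to affine transformation of the predictions.
    ``method="residual"`` is 1 − SSE/SST about the identity line, which
    penalises bias and miscalibrated slope.
    """
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if method == "correlation":
        st, sp = t.std(), p.std()
        if st == 0 or sp == 0:
            return 0.0
        r = float(np.corrcoef(t, p)[0, 1])
        return r * r
    if method == "residual":
        sst = float(((t - t.mean()) ** 2).sum())
        if sst == 0:
            return 0.0
        return 1.0 - float(((t - p) ** 2).sum()) / sst
    raise ValueError(f"unknown r² method {method!r}")


def rmse(targets, predictions) -> float:
    """Root mean squared error, in the targets' original units."""
    t = np.asarray(targets, dtype=float)
    p = np.asarray(predictions, dtype=float)
    return float(np.sqrt(np.mean((t - p) ** 2)))


@dataclass
class RegressionEval:
    """Per-property regression evaluation table.

    One row per soil property with the target min/max/mean (original units),
    the correlation-based r² and the RMSE in original units.
    """

    table: pd.DataFrame

    @classmethod
    def from_predictions(cls, targets: pd.DataFrame,
                         predictions: pd.DataFrame) -> "RegressionEval":
        rows = []
        for col in targets.columns:
            t = targets[col].to_numpy(dtype=float)
            p = predictions[col].to_numpy(dtype=float)
            rows.append({
                "property": col,
                "minimum": float(t.min()),
                "maximum": float(t.max()),
                "mean": float(t.mean()),
                "r_squared": r_squared(t, p),
                "rmse": rmse(t, p),
            })
        return cls(table=pd.DataFrame(rows).set_index("property"))

    def __getitem__(self, prop: str) -> pd.Series:
        return self.table.loc[prop]


def format_confusion_report(cm: ConfusionMatrix) -> str:
    """Human-readable confusion matrix with margins and summary statistics."""
    df = cm.to_frame().astype(object)
    acc = users_producers_accuracy(cm)
    df["users_accuracy"] = [f"{v:.2f}" for v in acc["users_accuracy"]]
    df["total"] = cm.counts.sum(axis=1)
    lines = [df.to_string()]
    producers = " ".join(f"{v:.2f}" for v in acc["producers_accuracy"])
    lines.append(f"producers_accuracy: {producers}")
    lines.append(f"overall_accuracy: {overall_accuracy(cm):.2f}")
    lines.append(f"cohens_kappa: {cohens_kappa(cm):.2f}")
    return "\n".join(lines)
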