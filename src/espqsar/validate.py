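"""Validation statistics for per-subset QSAR models.

Two statistics are reported on the denormalized pIC50 scale:

* the coefficient of determination R^2 = 1 - SSE/SST, computed separately
  for the training and test sets with each set's own mean in SST (the
  field often calls this a squared correlation, but for biased predictions
  the two differ — what is implemented is the 1 - SSE/SST form);
* the external predictivity r2_pred = 1 - SSE_test / SST*, whose
  denominator measures test deviations around the TRAINING-set mean, so
  the training set's location enters the assessment of the model.

A model qualifies when r2_pred >= 0.6, the conventional threshold for
statistical QSAR prediction models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricsReport",
    "coefficient_of_determination",
    "r2_pred",
    "evaluate",
]

QUALIFICATION_THRESHOLD = 0.6


@dataclass
class MetricsReport:
    """Per-subset validation summary."""

    subset_index: int
    r2_train: float
    r2_test: float
    r2_pred: float
    residuals: pd.DataFrame  # columns: id, split, experimental, calculated, residual

    @property
    def overtraining_gap(self) -> float:
        return self.r2_train - self.r2_test

    @property
    def qualified(self) -> bool:
        return self.r2_pred >= QUALIFICATION_THRESHOLD

    def worst_residuals(self, k: int = 2) -> pd.DataFrame:
        order = self.residuals["residual"].abs().sort_values(ascending=False)
        return self.residuals.loc[order.index[:k]]

    def to_dict(self) -> dict:
        worst = self.worst_residuals(2)
        return {
            "subset_index": self.subset_index,
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "r2_pred": self.r2_pred,
            "overtraining_gap": self.overtraining_gap,
            "qualified": bool(self.qualified),
            "largest_abs_residuals": [
                {"id": r.id, "residual": float(r.residual)}
                for r in worst.itertuples()
            ],
        }


def coefficient_of_determination(y, yhat) -> float:
    """1 - SSE/SST with the mean of ``y`` itself in SST; can be negative."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be equal-length vectors of length >= 2")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("y is constant; R^2 is undefined (zero denominator)")
    sse = float(np.sum((y - yhat) ** 2))
    return 1.0 - sse / sst


def r2_pred(y_test, yhat_test, ybar_train: float) -> float:
    """External predictivity: 1 - SSE_test / sum (y_test - ybar_train)^2."""
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(yhat_test, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("y_test and yhat_test must be equal-length, non-empty")
    denom = float(np.sum((y - ybar_train) ** 2))
    if denom == 0.0:
        raise ValueError(
            "all test activities equal the training mean; r2_pred undefined"
        )
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def evaluate(
    model,
    pca,
    train_set: list[tuple[str, np.ndarray, float]],
    test_set: list[tuple[str, np.ndarray, float]],
    subset_index: int = 0,
) -> MetricsReport:
    """Score a fitted model on (id, descriptor, experimental pIC50) triples.

    Predictions are made on the denormalized pIC50 scale. The report
    carries every residual; the two largest absolute residuals (with
    molecule ids) are surfaced by ``worst_residuals``/``to_dict``.
    """
    from .qsarnet import predict_pic50

    for name, part in (("train", train_set), ("test", test_set)):
        missing = [mid for mid, _, y in part if y is None or not np.isfinite(y)]
        if missing:
            raise ValueError(f"{name} molecules without experimental pIC50: {missing}")
        if not part:
            raise ValueError(f"{name} set is empty")

    rows = []
    preds = {}
    for split, part in (("train", train_set), ("test", test_set)):
        ids = [mid for mid, _, _ in part]
        X = np.array([d for _, d, _ in part])
        y = np.array([v for _, _, v in part], dtype=float)
        yhat = np.atleast_1d(predict_pic50(model, pca, X))
        preds[split] = (y, yhat)
        for mid, yi, yhi in zip(ids, y, yhat):
            rows.append(
                {"id": mid, "split": split, "experimental": float(yi),
                 "calculated": float(yhi), "residual": float(yhi - yi)}
            )
    y_tr, yhat_tr = preds["train"]
    y_te, yhat_te = preds["test"]
    return MetricsReport(
        subset_index=subset_index,
        r2_train=coefficient_of_determination(y_tr, yhat_tr),
        r2_test=coefficient_of_determination(y_te, yhat_te),
        r2_pred=r2_pred(y_te, yhat_te, float(y_tr.mean())),
        residuals=pd.DataFrame(rows),
    )
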