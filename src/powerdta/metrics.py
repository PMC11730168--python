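"""Evaluation mathematics for affinity regression: the pKd transform,
the concordance index with tie handling, and mean squared error."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["pkd_transform", "step_function", "concordance_index",
           "mean_squared_error", "EvaluationReport", "evaluate_predictions"]


@dataclass
class EvaluationReport:
    """CI and MSE of one set of predictions.

    n_pairs_compared is the concordance normalizer Z: the number of index
    pairs whose true affinities are strictly ordered.
    """

    mse: float
    ci: float
    n_pairs_compared: int
    n_samples: int

    def to_dict(self) -> dict:
        return {"mse": self.mse, "ci": self.ci,
                "n_pairs_compared": self.n_pairs_compared,
                "n_samples": self.n_samples}


def pkd_transform(kd) -> float | np.ndarray:
    """pKd = -log10(Kd / 1e9) for Kd in nM.

    Maps raw dissociation constants onto the log scale the Davis-style
    benchmarks regress (Kd = 1e9 nM -> 0, Kd = 1 nM -> 9).
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be strictly positive (nM)")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def step_function(x) -> float | np.ndarray:
    """h(x) = 1 if x > 0, 0.5 if x = 0, 0 if x < 0 (exact equality)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, 1.0, np.where(x == 0, 0.5, 0.0))
    return float(out) if out.ndim == 0 else out


def concordance_index(y_true, y_pred) -> float:
    """CI = (1/Z) * sum over pairs with y_i > y_j of h(p_i - p_j).

    Only pairs with strictly ordered true affinities enter the sum and
    the normalizer Z; tied-truth pairs are excluded from both.  Raises
    if every true value is identical (Z = 0 leaves CI undefined).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 2:
        raise ValueError("need at least two samples")
    greater = y_true[:, None] > y_true[None, :]
    z = int(greater.sum())
    if z == 0:
        raise ValueError("all true affinities tied: concordance undefined")
    h = step_function(y_pred[:, None] - y_pred[None, :])
    return float(h[greater].sum() / z)


def mean_squared_error(y_true, y_pred) -> float:
    """(1/n) * sum (P_i - Y_i)^2."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((y_pred - y_true) ** 2))


def evaluate_predictions(y_true, y_pred) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=float)
    greater = y_true[:, None] > y_true[None, :]
    return EvaluationReport(
        mse=mean_squared_error(y_true, y_pred),
        ci=concordance_index(y_true, y_pred),
        n_pairs_compared=int(greater.sum()),
        n_samples=int(y_true.size),
    )
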