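"""Evaluation metrics for affinity regression: MSE, concordance index,
rm^2 and Pearson correlation.

The concordance index is the probability that, over all ordered pairs
whose true affinities differ, the predictions rank them the same way;
tied predictions receive half credit.  rm^2 combines the squared
correlation of the least-squares fit with intercept (r^2) and of the fit
through the origin (r0^2) as r^2 * (1 - sqrt(r^2 - r0^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np


def _validate_pair(predictions, labels, min_n: int = 1):
    p = np.asarray(predictions, dtype=np.float64).ravel()
    y = np.asarray(labels, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} predictions vs {y.shape[0]} labels")
    if p.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} observations, got {p.shape[0]}")
    return p, y


def mse(predictions, labels) -> float:
    """Mean squared difference between predictions and ground truth."""
    p, y = _validate_pair(predictions, labels, min_n=1)
    return float(np.mean((p - y) ** 2))


def concordance_index(predictions, labels, _chunk: int = 512) -> float:
    """Pairwise concordance: 1 for correct order, 0.5 for prediction ties.

    Only ordered pairs with distinct labels count toward the normaliser Z.
    """
    p, y = _validate_pair(predictions, labels, min_n=2)
    if np.all(y == y[0]):
        raise ValueError("all labels identical: no comparable pairs (Z = 0)")
    credit = 0.0
    z = 0
    for start in range(0, len(y), _chunk):
        sl = slice(start, start + _chunk)
        dy = y[sl, None] - y[None, :]
        comparable = dy > 0
        dp = p[sl, None] - p[None, :]
        credit += np.sum((dp > 0) & comparable) + 0.5 * np.sum((dp == 0) & comparable)
        z += int(comparable.sum())
    return float(credit / z)


def pearson(predictions, labels) -> float:
    """Sample covariance over the product of sample standard deviations."""
    p, y = _validate_pair(predictions, labels, min_n=2)
    if np.std(p) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in predictions or labels")
    pc = p - p.mean()
    yc = y - y.mean()
    return float((pc @ yc) / np.sqrt((pc @ pc) * (yc @ yc)))


def rm_squared(predictions, labels, printed_form: bool = False) -> float:
    """External-validity index combining fits with and without intercept.

    r^2 is the squared Pearson correlation (the least-squares fit with
    intercept); r0^2 is the squared correlation coefficient of the fit
    through the origin, 1 - SS_res(origin)/SS_tot.  The default combines
    them as r^2 * (1 - sqrt(max(r^2 - r0^2, 0))).  ``printed_form=True``
    selects the variant r^2 * (1 - (r^2 - r0^2)), kept for auditability.
    """
    p, y = _validate_pair(predictions, labels, min_n=3)
    if np.std(p) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in predictions or labels")
    r2 = pearson(p, y) ** 2
    k = float(p @ y) / float(p @ p)  # through-origin least-squares slope
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    if printed_form:
        return float(r2 * (1.0 - (r2 - r02)))
    return float(r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0))))


@dataclass
class EvaluationReport:
    """All four metrics for one prediction set (optionally per CV fold)."""

    mse: float
    ci: float
    rm2: float
    pearson: float
    n: int
    folds: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.ci <= 1.0:
            raise ValueError("CI must lie in [0, 1]")
        if not -1.0 <= self.pearson <= 1.0 + 1e-12:
            raise ValueError("Pearson must lie in [-1, 1]")
        if self.mse < 0:
            raise ValueError("MSE must be nonnegative")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_predictions(predictions, labels) -> EvaluationReport:
    p, y = _validate_pair(predictions, labels, min_n=2)
    return EvaluationReport(
        mse=mse(p, y),
        ci=concordance_index(p, y),
        rm2=rm_squared(p, y),
        pearson=pearson(p, y),
        n=len(y),
    )
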