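"""Regression metrics for binding-affinity models: MSE, concordance index, r_m^2.

The concordance index (CI) is computed over all pairs of samples whose true
affinities differ strictly.  A pair is concordant when the predictions are
ordered like the true values; prediction ties receive half credit through the
step function h (1 if >0, 0.5 if =0, 0 if <0):

    CI = (1/Z) * sum_{d_x > d_y} h(b_x - b_y)

with Z the number of strictly ordered true pairs.  True-value ties contribute
to neither the numerator nor Z.

r_m^2 is the external-validation statistic r^2 * (1 - sqrt(|r^2 - r0^2|)),
where r^2 is the squared Pearson correlation between true and predicted
values and r0^2 is the through-origin coefficient computed with the QSAR
convention: k = sum(y * yhat) / sum(yhat^2) and
r0^2 = 1 - sum((y - k * yhat)^2) / sum((y - mean(y))^2).  The absolute value
inside the square root guards the rare case r0^2 > r^2; both r^2 and r0^2 are
reported alongside r_m^2 so either convention can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "mse", "concordance_index",
           "concordance_index_with_pairs", "rm2", "compute_report"]


@dataclass(frozen=True)
class MetricsReport:
    """Bundle of the three affinity-regression metrics."""

    mse: float
    ci: float
    ci_pairs: int
    rm2: float
    r_squared: float
    r0_squared: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=np.float64)
    yp = np.asarray(y_pred, dtype=np.float64)
    if yt.ndim != 1 or yp.ndim != 1:
        raise ValueError("metric inputs must be one-dimensional")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted")
    if yt.size == 0:
        raise ValueError("metric inputs must be non-empty")
    return yt, yp


def mse(y_true, y_pred) -> float:
    """Mean squared error, summed in index-ascending order in double precision."""
    yt, yp = _as_arrays(y_true, y_pred)
    return float(np.mean((yp - yt) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Concordance index over all ordered pairs with y_true[i] > y_true[j].

    Raises if no strictly ordered true pair exists (CI undefined).
    """
    ci, _ = concordance_index_with_pairs(y_true, y_pred)
    return ci


def concordance_index_with_pairs(y_true, y_pred) -> tuple[float, int]:
    """Concordance index and the comparable-pair count Z."""
    yt, yp = _as_arrays(y_true, y_pred)
    if yt.size < 2:
        raise ValueError("concordance index needs at least two samples")
    # pairwise sign matrices; only the upper structure d_x > d_y contributes
    true_greater = yt[:, None] > yt[None, :]
    z = int(true_greater.sum())
    if z == 0:
        raise ValueError("all true values tied: concordance index undefined")
    diff = yp[:, None] - yp[None, :]
    h = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(h[true_greater].sum() / z), z


def _pearson_r2(yt: np.ndarray, yp: np.ndarray) -> float:
    r = np.corrcoef(yt, yp)[0, 1]
    return float(r * r)


def _r0_squared(yt: np.ndarray, yp: np.ndarray) -> float:
    k = float(np.sum(yt * yp) / np.sum(yp * yp))
    ss_res = float(np.sum((yt - k * yp) ** 2))
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def rm2(y_true, y_pred) -> tuple[float, float, float]:
    """r_m^2 with its components (r_m^2, r^2, r0^2)."""
    yt, yp = _as_arrays(y_true, y_pred)
    if yt.size < 3:
        raise ValueError("rm2 needs at least three samples")
    if np.ptp(yt) == 0 or np.ptp(yp) == 0:
        raise ValueError("rm2 undefined for constant inputs")
    r2 = _pearson_r2(yt, yp)
    r02 = _r0_squared(yt, yp)
    value = r2 * (1.0 - np.sqrt(abs(r2 - r02)))
    return float(value), r2, r02


def compute_report(y_true, y_pred) -> MetricsReport:
    yt, yp = _as_arrays(y_true, y_pred)
    ci, z = concordance_index_with_pairs(yt, yp)
    rm2_val, r2, r02 = rm2(yt, yp)
    return MetricsReport(mse=mse(yt, yp), ci=ci, ci_pairs=z,
                         rm2=rm2_val, r_squared=r2, r0_squared=r02, n=int(yt.size))
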