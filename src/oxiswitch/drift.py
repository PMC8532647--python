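"""Per-feature QC-based support-vector-regression drift correction.

Each feature's QC intensities are regressed on injection order with an
epsilon-insensitive RBF-kernel SVR.  (epsilon, gamma) are selected by
leave-one-out RMSE over a grid (epsilon in [2.5, 7.5], gamma in
[1, 1e5]); ties prefer smaller gamma, then smaller epsilon.  Fitting is
done on the percent-of-QC-median intensity scale, where the feature's
median QC value is 100 by construction: this makes the fixed epsilon
range meaningful across a 1e3-1e7 intensity dynamic range, and the
regularization constant C -- defined as the median value in QCs -- equals
100 on that scale.  The correction is multiplicative and anchored to the
QC median:

    corrected(i) = raw(i) / max(pred(i), floor) * median_QC
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oxiswitch._svr import _loo_rmse_grid, rbf_kernel, solve_svr
from oxiswitch.errors import ValidationError
from oxiswitch.peaktable import CONDITIONING, QC, FeatureTable, PipelineConfig

#: minimum number of (non-conditioning) QC injections required for a fit
MIN_QCS = 4

#: relative floor applied to drift predictions before division
PRED_FLOOR = 1e-6

#: C on the percent-of-median scale (the QC median itself)
C_SCALED = 100.0

_SVR_TOL = 1e-3
_SVR_MAX_ITER = 100000


@dataclass
class DriftModel:
    """Fitted per-feature drift model over QC injections."""

    epsilon: float
    gamma: float
    c: float  # median QC intensity (original scale)
    loo_rmse: float
    feature_id: str | None = None
    degenerate: bool = False
    # fit internals (percent scale)
    beta: np.ndarray | None = None
    intercept: float = 0.0
    qc_x: np.ndarray | None = None  # scaled QC orders
    x_scale: float = 1.0

    def predict(self, orders: np.ndarray) -> np.ndarray:
        """Predicted drifted intensity at the given injection orders."""
        orders = np.asarray(orders, dtype=float)
        if self.degenerate:
            return np.full(orders.shape, self.c)
        x = orders / self.x_scale
        pct = rbf_kernel(x, self.qc_x, self.gamma) @ self.beta + self.intercept
        return pct / 100.0 * self.c


def fit_qcsvr(
    orders,
    intensities,
    grid: tuple[tuple[float, ...], tuple[float, ...]] | None = None,
    c: float | None = None,
    feature_id: str | None = None,
) -> DriftModel:
    """Fit the QC-SVR drift model for one feature.

    Parameters
    ----------
    orders, intensities:
        Injection orders and intensities of the (non-conditioning) QC
        injections; at least :data:`MIN_QCS` points, nonnegative.
    grid:
        ``(epsilon_grid, gamma_grid)``; defaults to the
        :class:`~oxiswitch.peaktable.PipelineConfig` grids.
    c:
        Median QC intensity; computed from ``intensities`` if omitted.
    """
    orders = np.asarray(orders, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if orders.shape != y.shape or orders.ndim != 1:
        raise ValidationError("orders and intensities must be equal-length vectors")
    if orders.size < MIN_QCS:
        raise ValidationError(f"need at least {MIN_QCS} QC injections, got {orders.size}")
    if np.any(y < 0):
        raise ValidationError("QC intensities must be nonnegative")
    cfg = PipelineConfig()
    eps_grid, gamma_grid = grid if grid is not None else (cfg.svr_epsilon_grid, cfg.svr_gamma_grid)
    if c is None:
        c = float(np.median(y))
    if c <= 0:
        return DriftModel(float("nan"), float("nan"), c, float("nan"), feature_id, degenerate=True)

    x_scale = float(orders.max())
    x = orders / x_scale
    y_pct = y / c * 100.0
    gammas = np.asarray(gamma_grid, dtype=float)
    epss = np.asarray(eps_grid, dtype=float)
    Kg = np.stack([rbf_kernel(x, x, g) for g in gammas])
    rmse = _loo_rmse_grid(Kg, y_pct, epss, C_SCALED, _SVR_TOL, _SVR_MAX_ITER)
    ei, gi = _select(rmse, epss, gammas)
    beta, b = solve_svr(x, y_pct, gammas[gi], epss[ei], C_SCALED, tol=_SVR_TOL)
    return DriftModel(
        epsilon=float(epss[ei]),
        gamma=float(gammas[gi]),
        c=c,
        loo_rmse=float(rmse[ei, gi]),
        feature_id=feature_id,
        beta=beta,
        intercept=b,
        qc_x=x,
        x_scale=x_scale,
    )


def _select(rmse: np.ndarray, epss: np.ndarray, gammas: np.ndarray) -> tuple[int, int]:
    """Minimum-RMSE cell; ties broken by smaller gamma, then smaller epsilon."""
    best = None
    key = None
    for gi in np.argsort(gammas, kind="stable"):
        for ei in np.argsort(epss, kind="stable"):
            k = (rmse[ei, gi], gammas[gi], epss[ei])
            if key is None or k < key:
                key = k
                best = (int(ei), int(gi))
    return best


def apply_correction(series, orders, model: DriftModel):
    """Divide a full intensity series by its predicted drift, re-anchored
    to the QC median; degenerate models return the series unchanged."""
    series = np.asarray(series, dtype=float)
    orders = np.asarray(orders, dtype=float)
    if series.shape != orders.shape:
        raise ValidationError("series and orders length mismatch")
    if model.degenerate:
        return series.copy()
    pred = model.predict(orders)
    floor = PRED_FLOOR * model.c
    return series / np.maximum(pred, floor) * model.c


def rsd_vector(matrix: np.ndarray) -> np.ndarray:
    """Row-wise RSD%% (100 * sd[n-1] / mean); nonpositive mean -> inf."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    out = np.full(mean.shape, np.inf)
    ok = mean > 0
    out[ok] = 100.0 * sd[ok] / mean[ok]
    return out


def correct_batch(
    table: FeatureTable, config: PipelineConfig | None = None
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drift-correct every feature of a batch independently.

    Conditioning injections are excluded from fitting and dropped from the
    output (data acquired during system conditioning are discarded).
    Returns the corrected table and a per-feature report with the selected
    hyperparameters and pre/post QC RSD%%.
    """
    config = config or PipelineConfig()
    qc_mask = table.role_mask(QC)
    keep_mask = ~table.role_mask(CONDITIONING)
    n_qc = int(qc_mask.sum())
    if n_qc < MIN_QCS:
        raise ValidationError(
            f"drift correction needs at least {MIN_QCS} non-conditioning QCs, got {n_qc}"
        )
    orders = table.orders.astype(float)
    qc_orders = orders[qc_mask]
    out_orders = orders[keep_mask]
    qc_out_mask = qc_mask[keep_mask]

    x_scale = float(qc_orders.max())
    x = qc_orders / x_scale
    gammas = np.asarray(config.svr_gamma_grid, dtype=float)
    epss = np.asarray(config.svr_epsilon_grid, dtype=float)
    Kg = np.stack([rbf_kernel(x, x, g) for g in gammas])
    Kq = np.stack([rbf_kernel(out_orders / x_scale, x, g) for g in gammas])

    corrected = np.empty((len(table.features), int(keep_mask.sum())))
    rows = []
    for i, feat in enumerate(table.features):
        qc_y = table.intensities[i, qc_mask]
        c = float(np.median(qc_y))
        raw = table.intensities[i, keep_mask]
        if c <= 0:
            corrected[i] = raw
            rows.append((feat.feature_id, np.nan, np.nan, c, np.nan, True))
            continue
        y_pct = qc_y / c * 100.0
        rmse = _loo_rmse_grid(Kg, y_pct, epss, C_SCALED, _SVR_TOL, _SVR_MAX_ITER)
        ei, gi = _select(rmse, epss, gammas)
        beta, b = solve_svr(x, y_pct, gammas[gi], epss[ei], C_SCALED, tol=_SVR_TOL)
        pred = (Kq[gi] @ beta + b) / 100.0 * c
        corrected[i] = raw / np.maximum(pred, PRED_FLOOR * c) * c
        rows.append((feat.feature_id, float(epss[ei]), float(gammas[gi]), c, float(rmse[ei, gi]), False))

    out = FeatureTable(
        list(table.features),
        [inj for inj, k in zip(table.injections, keep_mask) if k],
        corrected,
    )
    report = pd.DataFrame(
        rows, columns=["feature_id", "epsilon", "gamma", "c", "loo_rmse", "degenerate"]
    )
    report["pre_rsd"] = rsd_vector(table.intensities[:, qc_mask])
    report["post_rsd"] = rsd_vector(corrected[:, qc_out_mask])
    return out, report
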