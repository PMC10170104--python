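"""Per-feature intensity-drift correction anchored on repeated pooled-QC injections.

For each feature, the QC areas are regressed on injection order (LOWESS on the
log scale by default, linear fit when few QCs are available), the fitted curve
is normalized to median 1 over the QC injections, and every sample's area is
divided by the curve evaluated at its injection order.  Extrapolation beyond
the first/last QC holds the boundary value constant.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .feature_io import FeatureTable

__all__ = ["DriftFit", "fit_drift", "correct_table", "NoQCError"]

logger = logging.getLogger(__name__)


class NoQCError(ValueError):
    """Raised when correction is requested on a table without QC samples."""


@dataclass
class DriftFit:
    """Fitted drift curve for one feature.

    ``curve`` maps every injection order of the run to a strictly positive
    multiplier with median 1 over the QC injections used for the fit.
    ``qc_cv_before``/``qc_cv_after`` are percent CVs on the same QC areas.
    """

    feature_id: str
    method: str                  # LOWESS | LINEAR | NONE
    curve: pd.Series             # injection_order -> multiplier
    qc_cv_before: float
    qc_cv_after: float


def _cv_pct(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    if len(values) < 2 or values.mean() == 0:
        return float("nan")
    return float(values.std(ddof=1) / values.mean() * 100.0)


def fit_drift(qc_areas: Sequence[tuple[int, float]],
              orders: Sequence[int] | None = None,
              method: str = "auto",
              feature_id: str = "",
              min_qc_lowess: int = 5,
              warn: bool = True) -> DriftFit:
    """Fit a drift curve from (injection_order, area) QC observations.

    ``orders`` lists every injection order the curve must cover; defaults to
    ``1..max(qc order)``.  Fewer than 2 usable (positive, non-missing) QC
    points fall back to the identity curve with method NONE and a warning.
    """
    if method not in ("auto", "lowess", "linear", "none"):
        raise ValueError(f"unknown method {method!r}")
    pts = [(int(o), float(a)) for o, a in qc_areas]
    usable = [(o, a) for o, a in pts if not np.isnan(a) and a > 0]
    usable.sort()
    if orders is None:
        orders = range(1, (max((o for o, _ in pts), default=1)) + 1)
    orders = np.asarray(sorted(set(int(o) for o in orders)))
    before = np.array([a for _, a in usable], dtype=float)
    cv_before = _cv_pct(before)

    def identity() -> DriftFit:
        curve = pd.Series(1.0, index=pd.Index(orders, name="injection_order"))
        return DriftFit(feature_id, "NONE", curve, cv_before, cv_before)

    if method == "none" or len(usable) < 2:
        if method != "none" and len(usable) < 2 and warn:
            logger.warning("feature %s: fewer than 2 usable QC points; correction skipped",
                           feature_id or "<unnamed>")
        return identity()

    x = np.array([o for o, _ in usable], dtype=float)
    logy = np.log([a for _, a in usable])
    n_qc = len(usable)
    use_lowess = (method == "lowess") or (method == "auto" and n_qc >= min_qc_lowess)
    if use_lowess and n_qc >= 3:
        frac = min(1.0, max(0.5, 4.0 / n_qc))
        # no robustness iterations: with few QC points the reweighting can
        # leave residual variance above the uncorrected spread
        fitted = _sm_lowess(logy, x, frac=frac, it=0, return_sorted=True)
        fit_x, fit_y = fitted[:, 0], fitted[:, 1]
        used = "LOWESS"
    else:
        slope, intercept = np.polyfit(x, logy, 1)
        fit_x, fit_y = x, slope * x + intercept
        used = "LINEAR"
    # piecewise-linear in log space, constant beyond the outermost QCs
    log_curve = np.interp(orders.astype(float), fit_x, fit_y)
    curve_vals = np.exp(log_curve)
    qc_curve = np.exp(np.interp(x, fit_x, fit_y))
    anchor = np.median(qc_curve)
    if anchor <= 0 or not np.isfinite(anchor):
        return identity()
    curve_vals = curve_vals / anchor
    curve = pd.Series(curve_vals, index=pd.Index(orders, name="injection_order"))
    after = before / np.exp(np.interp(x, orders.astype(float), np.log(curve_vals)))
    return DriftFit(feature_id, used, curve, cv_before, _cv_pct(after))


def correct_table(table: FeatureTable, method: str = "auto",
                  min_qc_lowess: int = 5) -> tuple[FeatureTable, list[DriftFit]]:
    """Drift-correct every feature of ``table`` using its QC injections.

    Missing areas stay missing and QC samples are retained in the output.
    Raises :class:`NoQCError` when the table has no QC samples; skipping
    correction must then be an explicit caller decision.
    """
    qc_ids = table.qc_sample_ids
    if not qc_ids:
        raise NoQCError(
            "table contains no QC samples; pass --skip-correction (or call the "
            "downstream stages directly) to analyze uncorrected areas"
        )
    orders_all = table.samples["injection_order"].astype(int)
    qc_orders = orders_all.loc[qc_ids].to_numpy()
    order_range = sorted(set(orders_all))
    corrected = table.areas.copy()
    fits: list[DriftFit] = []
    qc_matrix = table.areas[qc_ids].to_numpy(dtype=float)
    sample_orders = orders_all.to_numpy()
    for i, fid in enumerate(table.feature_ids):
        fit = fit_drift(list(zip(qc_orders, qc_matrix[i])), orders=order_range,
                        method=method, feature_id=fid, min_qc_lowess=min_qc_lowess,
                        warn=False)
        fits.append(fit)
        if fit.method != "NONE":
            divisor = fit.curve.loc[sample_orders].to_numpy()
            corrected.iloc[i] = table.areas.iloc[i].to_numpy() / divisor
    n_skipped = sum(1 for f in fits if f.method == "NONE" and method != "none")
    if n_skipped:
        logger.warning("%d feature(s) had fewer than 2 usable QC points and were "
                       "left uncorrected", n_skipped)
    out = FeatureTable(corrected, table.features.copy(), table.samples.copy())
    return out, fits


def drift_report(fits: Sequence[DriftFit]) -> pd.DataFrame:
    """Per-feature correction report (feature_id, method, QC CV before/after)."""
    return pd.DataFrame({
        "feature_id": [f.feature_id for f in fits],
        "method": [f.method for f in fits],
        "qc_cv_before": [f.qc_cv_before for f in fits],
        "qc_cv_after": [f.qc_cv_after for f in fits],
    }).set_index("feature_id")
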