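"""Regional kinetic feature extraction.

Each region of a dynamic scan is summarized by four parameters that jointly
index tracer delivery and target expression: standardized uptake values at
1.25, 13.5 and 50 minutes post-injection (early, intermediate and late
uptake) and the blood-to-tissue influx rate K1 from a single irreversible
compartment fit against the supplied input function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .io import RegionalTacSet, SubjectRecord

__all__ = [
    "FEATURE_NAMES", "FeatureTable", "interpolate_tac", "compute_suv",
    "fit_k1_irreversible", "extract_features",
]

FEATURE_NAMES = ("suv_1.25", "suv_13.5", "suv_50", "k1")

DEFAULT_SUV_TIMES = (1.25, 13.5, 50.0)   # minutes post-injection
DEFAULT_K1_WINDOW = 3.0                  # minutes; early, flow-dominated


@dataclass
class FeatureTable:
    """Per-scan [n_roi x 4] kinetic feature matrix.

    ``values`` columns are ordered as :data:`FEATURE_NAMES`. SUV is
    dimensionless (1 g/mL tissue-density convention); K1 is a per-minute
    uptake coefficient (mL cm^-3 min^-1 equivalent). ``standardized``
    flags whether the robust z-score has been applied — raw and
    standardized tables must never be mixed.
    """

    scan_id: str
    values: np.ndarray
    roi_names: tuple = ()
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"feature matrix must be [n_roi x {len(FEATURE_NAMES)}]")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if not self.standardized and np.any(self.values[:, :3] < 0):
            raise ValueError("raw SUV features must be non-negative")
        if self.roi_names and len(self.roi_names) != self.values.shape[0]:
            raise ValueError("roi_names length does not match feature rows")

    def to_frame(self) -> pd.DataFrame:
        idx = list(self.roi_names) if self.roi_names else None
        return pd.DataFrame(self.values, index=idx, columns=list(FEATURE_NAMES))


def interpolate_tac(times, values, target_times):
    """Linear interpolation of a TAC with linear extrapolation outside the
    sampled range (from the two nearest samples on each side)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    target_times = np.atleast_1d(np.asarray(target_times, dtype=float))
    if times.size < 2:
        raise ValueError("need at least 2 samples to interpolate")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    out = np.interp(target_times, times, values)
    lo = target_times < times[0]
    if lo.any():
        slope = (values[1] - values[0]) / (times[1] - times[0])
        out[lo] = values[0] + slope * (target_times[lo] - times[0])
    hi = target_times > times[-1]
    if hi.any():
        slope = (values[-1] - values[-2]) / (times[-1] - times[-2])
        out[hi] = values[-1] + slope * (target_times[hi] - times[-1])
    return out


def compute_suv(conc, dose: float, weight: float):
    """Standardized uptake value: activity concentration divided by injected
    dose per body weight (1 g/mL density convention, so kBq/mL over MBq/kg
    is treated as dimensionless)."""
    if dose <= 0:
        raise ValueError("injected dose must be positive")
    if weight <= 0:
        raise ValueError("body weight must be positive")
    return np.asarray(conc, dtype=float) / (dose / weight)


def fit_k1_irreversible(tissue_tac, input_curve, times, t_fit: float = DEFAULT_K1_WINDOW):
    """Influx rate from a single irreversible compartment: C_t(t) = K1 * int_0^t C_p.

    The cumulated input X(t) is a trapezoid integral from t=0 (with
    C_p(0)=0 assumed), and K1 is the closed-form least-squares slope
    sum(C_t * X) / sum(X^2) over frames with mid-time <= ``t_fit``.
    """
    tissue_tac = np.asarray(tissue_tac, dtype=float)
    input_curve = np.asarray(input_curve, dtype=float)
    times = np.asarray(times, dtype=float)
    sel = times <= t_fit
    if not sel.any():
        raise ValueError(f"no frames with mid-time <= {t_fit} min")
    t0 = np.concatenate([[0.0], times])
    cp0 = np.concatenate([[0.0], input_curve])
    cum = cumulative_trapezoid(cp0, t0)      # X at each frame mid-time
    x = cum[sel]
    denom = float(np.sum(x * x))
    if denom <= 0:
        raise ValueError("input curve is zero throughout the fit window")
    return float(np.sum(tissue_tac[sel] * x) / denom)


def extract_features(scan: RegionalTacSet, record: SubjectRecord | None = None,
                     *, suv_times=DEFAULT_SUV_TIMES,
                     k1_window: float = DEFAULT_K1_WINDOW) -> FeatureTable:
    """Build the per-region 4-feature table for one scan.

    Each regional TAC is linearly interpolated at the SUV target times
    (extrapolating if the scan ends before 50 min), converted to SUV with
    the scan's dose and weight, and augmented with the irreversible-uptake
    K1 fitted over the early window.
    """
    dose = record.injected_dose if record is not None else scan.injected_dose
    weight = record.body_weight if record is not None else scan.body_weight
    mids = scan.frame_mid_times
    n_roi = scan.n_roi
    out = np.empty((n_roi, len(suv_times) + 1), dtype=float)
    for r in range(n_roi):
        tac = scan.activity[:, r]
        conc = interpolate_tac(mids, tac, suv_times)
        out[r, : len(suv_times)] = compute_suv(conc, dose, weight)
        out[r, -1] = fit_k1_irreversible(tac, scan.input_curve, mids, k1_window)
    # late-frame extrapolation can dip slightly below zero on noisy TACs
    out[:, : len(suv_times)] = np.clip(out[:, : len(suv_times)], 0.0, None)
    return FeatureTable(scan_id=scan.scan_id, values=out,
                        roi_names=tuple(scan.roi_names))
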