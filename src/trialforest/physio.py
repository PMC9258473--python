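"""Derived cardiovascular quantities from per-minute haemodynamic values.

Inputs are one-minute ensemble-averaged values of mean arterial pressure
(MAP, mmHg), cardiac output (CO, L/min), stroke volume (SV, ml) and
pre-ejection period (PEP, ms), labelled by Trier Social Stress Test epoch
(baseline, preparation, speech, maths, recovery).  Raw waveform processing
(ECG/ICG scoring, ensemble averaging) happens upstream; this module derives
total peripheral resistance, per-minute reactivity scores relative to each
person's baseline-epoch mean, and per-epoch summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

EPOCH_ORDER = ("baseline", "preparation", "speech", "maths", "recovery")

#: CSV schema for per-minute physiology files
SCHEMA = ("unit_id", "minute", "epoch", "MAP", "CO", "SV", "PEP")


def compute_tpr(MAP, CO):
    """Total peripheral resistance: (MAP / CO) x 80, in dyn·s·cm^-5.

    MAP in mmHg, CO in L/min; both must be positive.  Accepts scalars or
    arrays.
    """
    MAP = np.asarray(MAP, dtype=float)
    CO = np.asarray(CO, dtype=float)
    if np.any(CO <= 0):
        raise ValueError("cardiac output must be positive to derive TPR")
    if np.any(MAP <= 0):
        raise ValueError("mean arterial pressure must be positive")
    out = (MAP / CO) * 80.0
    return float(out) if out.ndim == 0 else out


def load_epoch_series(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-minute physiology table and derive TPR when absent."""
    missing = [c for c in SCHEMA if c not in frame.columns]
    if missing:
        raise ValueError(f"physiology table is missing columns: {missing}")
    out = frame.copy()
    bad = set(out["epoch"]) - set(EPOCH_ORDER)
    if bad:
        raise ValueError(f"unknown epoch labels: {sorted(bad)}")
    for uid, g in out.groupby("unit_id"):
        if not (g["epoch"] == "baseline").any():
            raise ValueError(f"unit {uid!r} has no baseline epoch")
        m = g["minute"].to_numpy()
        if np.any(np.diff(m) <= 0):
            raise ValueError(f"minutes must be strictly increasing for unit {uid!r}")
    if "TPR" not in out.columns:
        out["TPR"] = compute_tpr(out["MAP"], out["CO"])
    return out


def reactivity_scores(series: pd.DataFrame, measure: str) -> pd.Series:
    """Per-minute reactivity: value minus the unit's baseline-epoch mean.

    Baseline minutes yield deviations from their own mean (mean zero by
    construction), so the per-unit baseline reactivity averages exactly 0.
    """
    if measure not in series.columns:
        raise ValueError(f"unknown measure {measure!r}")
    out = pd.Series(np.nan, index=series.index, name=f"{measure}_reactivity")
    for uid, g in series.groupby("unit_id"):
        base = g.loc[g["epoch"] == "baseline", measure]
        if base.empty:
            raise ValueError(f"unit {uid!r} has no baseline epoch for {measure!r}")
        out.loc[g.index] = g[measure] - base.mean()
    return out


def epoch_means(series: pd.DataFrame, values: pd.Series,
                epochs: tuple[str, ...] = EPOCH_ORDER) -> dict[str, float]:
    """Unweighted mean of per-minute values within each requested epoch.

    Empty epochs are omitted with a warning rather than raising.
    """
    out: dict[str, float] = {}
    for epoch in epochs:
        mask = series["epoch"] == epoch
        if not mask.any():
            warnings.warn(f"epoch {epoch!r} has no minutes; omitted", stacklevel=2)
            continue
        out[epoch] = float(values[mask].mean())
    return out
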