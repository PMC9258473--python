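"""Causal-forest extensions: multi-arm trials and targeted smoothing.

Two extensions of the two-arm causal forest:

* :func:`fit_multiarm_bcf` — one conservative moderator forest per treated
  arm, fitted jointly with a shared prognostic forest, so the posterior
  supports per-arm effects and pairwise arm contrasts (used for four-cell
  designs that compare component treatments to their combination).

* :func:`fit_tsbcf` — targeted smoothing for repeated-measures series: every
  leaf of both forests holds a smooth function of recording time, expressed
  in a cubic penalized-spline basis, so the treatment effect tau(w, t) is a
  continuous curve over the recording rather than a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .bcf import BCFConfig, BCFPosterior, _run_gibbs
from .datasets import TrialDataset
from .trees import snapshot_raw_prediction


@dataclass
class TimeBasis:
    """Penalized cubic-spline basis over standardized recording time.

    ``smoothness_scale`` is a shrinkage strength: spline-deviation weights
    receive prior s.d. ``leaf_scale / smoothness_scale``, so larger values
    give smoother (flatter-in-time) leaf functions and the limit
    ``smoothness_scale -> inf`` recovers the time-constant model.

    ``knots`` are interior knot locations in original time units; when None
    they are placed at quantiles of the observed times.
    """

    kind: str = "penalized_spline"
    knots: np.ndarray | None = None
    n_knots: int = 4
    degree: int = 3
    smoothness_scale: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("penalized_spline", "low_rank_smooth"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.smoothness_scale <= 0:
            raise ValueError("smoothness_scale must be positive")

    def resolve_knots(self, times: np.ndarray) -> np.ndarray:
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if np.any(np.diff(k) <= 0):
                raise ValueError("knots must be strictly increasing")
            if k.min() < times.min() or k.max() > times.max():
                raise ValueError("knots must lie within the observed time range")
            return k
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        return np.unique(np.quantile(times, qs))


def _design(times_std: np.ndarray, knots_std: np.ndarray, degree: int) -> np.ndarray:
    t = np.concatenate(
        [np.zeros(degree + 1), knots_std, np.ones(degree + 1)]
    )
    x = np.clip(times_std, 0.0, 1.0)
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


@dataclass
class EffectCurve:
    """Posterior draws of the treatment-effect curve tau(w, t) on a grid."""

    time_grid: np.ndarray
    draws: np.ndarray  # draws x grid points, outcome units

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.draws.shape[1] != self.time_grid.size:
            raise ValueError("draws and grid are inconsistent")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite curve draws")

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def window_average(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Per-draw average of the curve over grid points in [t_lo, t_hi]."""
        mask = (self.time_grid >= t_lo) & (self.time_grid <= t_hi)
        if not mask.any():
            raise ValueError("no grid points in the requested window")
        return self.draws[:, mask].mean(axis=1)


def fit_multiarm_bcf(dataset: TrialDataset, config: BCFConfig | None = None) -> BCFPosterior:
    """Fit the multi-arm causal forest (K >= 1 treated arms plus control).

    Each treated arm gets its own moderator forest with the same conservative
    prior; the prognostic forest is shared.  With K = 1 this reduces exactly
    to the two-arm model.
    """
    config = config or BCFConfig()
    return _run_gibbs(dataset, config)


def fit_tsbcf(
    dataset: TrialDataset,
    config: BCFConfig | None = None,
    time_basis: TimeBasis | None = None,
) -> BCFPosterior:
    """Fit the targeted-smoothing causal forest over recording time.

    Every row must carry a time value and units must have repeated
    observations; leaf parameters of both forests become smooth functions of
    standardized time, so tau(w, t) is continuous in t.
    """
    config = config or BCFConfig()
    time_basis = time_basis or TimeBasis()
    if dataset.time is None:
        raise ValueError("fit_tsbcf requires a time column")
    times = dataset.times
    if np.unique(times).size < 2:
        raise ValueError(
            "only one distinct time point; use fit_bcf for cross-sectional data"
        )

    def basis_builder(ds: TrialDataset):
        t = ds.times
        t_min, t_max = float(t.min()), float(t.max())
        t_std = (t - t_min) / (t_max - t_min)
        knots = time_basis.resolve_knots(t)
        knots_std = (knots - t_min) / (t_max - t_min)
        spline = _design(t_std, knots_std, time_basis.degree)
        col_means = spline.mean(axis=0)
        basis = np.column_stack([np.ones(len(t)), spline - col_means])
        k = spline.shape[1]
        wiggle = 1.0 / time_basis.smoothness_scale
        leaf_cov = np.diag(np.concatenate([[1.0], np.full(k, wiggle**2)]))
        time_info = {
            "t_min": t_min,
            "t_max": t_max,
            "knots_std": knots_std,
            "degree": time_basis.degree,
            "col_means": col_means,
            "basis": time_basis,
        }
        return basis, basis, leaf_cov, leaf_cov, time_info

    return _run_gibbs(dataset, config, basis_builder=basis_builder)


def effect_curve(
    posterior: BCFPosterior,
    moderator_row,
    time_grid,
    arm: int = 1,
) -> EffectCurve:
    """Evaluate the fitted effect curve tau(w, t) on a time grid.

    ``moderator_row`` is a mapping / Series / single-row DataFrame of
    moderator values.  The grid must lie within the fitted time range (no
    extrapolation); per-epoch summaries are window averages of grid points.
    """
    if posterior.time_info is None:
        raise ValueError("posterior was not fitted with targeted smoothing")
    if posterior._moderator_snapshots is None:
        raise ValueError("fit was run without keep_moderator_forests")
    if arm not in posterior.tau_draws:
        raise ValueError(f"unknown arm {arm!r}")
    info = posterior.time_info
    grid = np.asarray(time_grid, dtype=float)
    if grid.min() < info["t_min"] or grid.max() > info["t_max"]:
        raise ValueError("time grid outside the fitted range; no extrapolation")

    if isinstance(moderator_row, pd.DataFrame):
        row_frame = moderator_row.iloc[[0]]
    else:
        row_frame = pd.DataFrame([dict(moderator_row)])
    cov = posterior._moderator_cov
    values, unseen = cov.encode_like(row_frame)
    g = grid.size
    values = np.repeat(values, g, axis=0)
    unseen = np.repeat(unseen, g, axis=0)

    t_std = (grid - info["t_min"]) / (info["t_max"] - info["t_min"])
    spline = _design(t_std, info["knots_std"], info["degree"])
    basis = np.column_stack([np.ones(g), spline - info["col_means"]])

    scale = info.get("snapshot_scale", 1.0)
    draws = np.empty((posterior.n_draws, g))
    for d, snap in enumerate(posterior._moderator_snapshots[arm]):
        draws[d] = scale * snapshot_raw_prediction(snap, values, unseen, basis=basis)
    return EffectCurve(time_grid=grid, draws=draws)
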