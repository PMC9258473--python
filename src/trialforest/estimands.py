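"""Posterior summaries and study-level estimands.

Turns posterior draws into the quantities a trial report needs: average
treatment effects (ATEs), subgroup conditional ATEs (CATEs), percentile
intervals (10th/90th with 2.5th/97.5th), directional posterior
probabilities, pooled-s.d. standardization, manipulation checks, an
outcome-blinded subgroup cut-point search, and an ordinary-least-squares
frequentist cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bcf import BCFPosterior
from .datasets import TrialDataset


@dataclass(frozen=True)
class EffectSummary:
    """Point estimate, percentile interval and directional probability."""

    mean: float
    pct_2_5: float
    pct_10: float
    pct_90: float
    pct_97_5: float
    prob_direction: float
    direction: int  # +1 or -1: the direction prob_direction refers to
    scale: str = "raw"  # raw | standardized

    def __post_init__(self) -> None:
        if not (self.pct_2_5 <= self.pct_10 <= self.pct_90 <= self.pct_97_5):
            raise ValueError("percentiles are not ordered")
        if not (0.0 <= self.prob_direction <= 1.0):
            raise ValueError("prob_direction must lie in [0, 1]")

    def interval(self, level: float = 0.8) -> tuple[float, float]:
        if level == 0.8:
            return (self.pct_10, self.pct_90)
        if level == 0.95:
            return (self.pct_2_5, self.pct_97_5)
        raise ValueError("stored levels are 0.8 and 0.95")


def summarize_draws(draws: np.ndarray, direction: int | None = None,
                    scale: str = "raw") -> EffectSummary:
    """Summarize a vector of posterior draws into an :class:`EffectSummary`.

    ``direction`` picks the sign whose posterior probability is reported;
    by default the sign of the posterior mean.  Exact ties (draws equal to
    zero) contribute half.
    """
    d = np.asarray(draws, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("draws must be a non-empty vector")
    mean = float(d.mean())
    if direction is None:
        direction = -1 if mean < 0 else 1
    prob = float(np.mean(np.sign(d) == direction) + 0.5 * np.mean(d == 0.0))
    q = np.percentile(d, [2.5, 10, 90, 97.5])
    return EffectSummary(
        mean=mean, pct_2_5=float(q[0]), pct_10=float(q[1]), pct_90=float(q[2]),
        pct_97_5=float(q[3]), prob_direction=prob, direction=direction, scale=scale,
    )


def average_effect(
    posterior: BCFPosterior,
    arm: int = 1,
    row_subset: np.ndarray | None = None,
    direction: int | None = None,
) -> EffectSummary:
    """ATE (full sample) or subgroup CATE summary for one treated arm.

    Per draw, the per-row effect surface is averaged over the subset rows;
    the draw vector is then summarized with 10th/90th (and 2.5th/97.5th)
    percentiles and the directional posterior probability.
    """
    return summarize_draws(posterior.ate_draws(arm, row_subset), direction)


def prob_difference(
    posterior: BCFPosterior, arm_a: int, arm_b: int, direction: int = -1
) -> float:
    """Posterior probability that ATE(arm_a) - ATE(arm_b) has the given sign.

    Exact ties split evenly.
    """
    diff = posterior.ate_draws(arm_a) - posterior.ate_draws(arm_b)
    return float(np.mean(np.sign(diff) == direction) + 0.5 * np.mean(diff == 0.0))


def standardize(summary: EffectSummary, dataset: TrialDataset,
                outcome: str | None = None) -> EffectSummary:
    """Express a raw-scale summary in pooled-s.d. units.

    The pooled s.d. is the square root of the equally weighted average of
    arm-level observation variances of the outcome.
    """
    if summary.scale == "standardized":
        raise ValueError("summary is already standardized")
    if outcome is not None and outcome != dataset.outcome:
        dataset = dataset.with_frame(dataset.frame, outcome=outcome)
    sd = dataset.pooled_sd()
    return replace(
        summary,
        mean=summary.mean / sd,
        pct_2_5=summary.pct_2_5 / sd,
        pct_10=summary.pct_10 / sd,
        pct_90=summary.pct_90 / sd,
        pct_97_5=summary.pct_97_5 / sd,
        scale="standardized",
    )


def manipulation_check(
    posterior: BCFPosterior,
    dataset: TrialDataset,
    arm: int = 1,
    beneficial_direction: int = -1,
    threshold_sd: float = 0.25,
) -> tuple[EffectSummary, bool]:
    """Treatment effect on the post-intervention negative-mindset index.

    Returns the standardized ATE summary and a pass flag: the check passes
    when the 10th-90th interval excludes 0 in the beneficial direction, or
    when the standardized effect magnitude reaches ``threshold_sd``.
    """
    raw = average_effect(posterior, arm, direction=beneficial_direction)
    std = standardize(raw, dataset)
    lo, hi = std.interval(0.8)
    if beneficial_direction < 0:
        excludes = hi < 0.0
    else:
        excludes = lo > 0.0
    beneficial = std.mean * beneficial_direction > 0
    passed = bool(excludes or (beneficial and abs(std.mean) >= threshold_sd))
    return std, passed


def subgroup_cutpoint_search(
    dataset: TrialDataset,
    posterior: BCFPosterior,
    moderator: str,
    n_grid: int = 50,
    min_units: int = 10,
):
    """Outcome-blinded subgroup construction on a continuous moderator.

    Scans a grid of candidate cut-points and picks the one maximizing the
    posterior-expected difference in the *control-condition* outcome surface
    (intercept + prognostic surface) between the two groups it induces.  The
    search never reads the treatment-effect draws, so subgroups are formed
    without using information about effect magnitudes.

    Returns ``(cut, labels, objective, weak_signal)`` where ``labels`` is a
    per-row "above"/"below" array and ``weak_signal`` flags an objective
    below a quarter of the outcome s.d. (little real separation).
    """
    if moderator not in dataset.frame.columns:
        raise ValueError(f"unknown moderator {moderator!r}")
    w = dataset.frame[moderator].to_numpy(dtype=float)
    # posterior-mean control-condition outcome per row: alpha + mu
    control_surface = (
        posterior.alpha_draws.mean(axis=0)[posterior.unit_codes]
        + posterior.mu_draws.mean(axis=0)
    )
    units = dataset.frame[dataset.unit]
    grid = np.unique(np.quantile(w, np.linspace(0, 1, n_grid + 2)[1:-1]))
    best = None
    for cut in grid:
        above = w > cut
        if units[above].nunique() < min_units or units[~above].nunique() < min_units:
            continue
        obj = abs(float(control_surface[above].mean() - control_surface[~above].mean()))
        if best is None or obj > best[1]:
            best = (float(cut), obj)
    if best is None:
        raise ValueError("no candidate cut-point leaves enough units on both sides")
    cut, objective = best
    labels = np.where(w > cut, "above", "below")
    weak = objective < 0.25 * float(np.std(dataset.y))
    if weak:
        warnings.warn(
            "moderator shows little control-outcome separation; subgroups may "
            "be arbitrary",
            stacklevel=2,
        )
    return cut, labels, objective, weak


def frequentist_crosscheck(
    dataset: TrialDataset,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
):
    """OLS treatment coefficient with a robust interval, for sanity checks.

    Uses heteroskedasticity-robust (HC2) standard errors, or cluster-robust
    by unit when units have repeated observations.  Perfectly collinear
    covariates are dropped with a warning.  Returns a dict with ``coef``,
    ``conf_int``, ``se`` and ``tvalue``.
    """
    if dataset.n_arms != 1:
        raise ValueError("the cross-check is defined for two-arm data")
    y = dataset.y
    z = dataset.arm_codes.astype(float)
    cols = {"const": np.ones(y.size), "treatment": z}
    dropped = []
    for c in covariates or []:
        v = dataset.frame[c].to_numpy(dtype=float)
        trial = np.column_stack(list(cols.values()) + [v])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            dropped.append(c)
            continue
        cols[c] = v
    if dropped:
        warnings.warn(f"dropped collinear covariates: {dropped}", stacklevel=2)
    X = pd.DataFrame(cols)
    repeated = dataset.n_rows > dataset.n_units
    if repeated:
        fit = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": dataset.unit_codes}
        )
    else:
        fit = sm.OLS(y, X).fit(cov_type="HC2")
    ci = fit.conf_int(alpha=alpha)
    return {
        "coef": float(fit.params["treatment"]),
        "se": float(fit.bse["treatment"]),
        "tvalue": float(fit.tvalues["treatment"]),
        "conf_int": (float(ci.loc["treatment", 0]), float(ci.loc["treatment", 1])),
        "dropped": dropped,
    }
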