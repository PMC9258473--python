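"""Synthetic randomized-trial generators with exposed ground truth.

Three designs are emulated, matching the structures the model layer is used
on:

* cross-sectional post-intervention outcomes moderated by baseline mindsets
  (one observation per unit),
* twice-daily diary outcomes with thrice-daily cortisol over a school week,
  with person random intercepts, and
* minute-level cardiovascular series across the epochs of a Trier Social
  Stress Test (TSST), with a smooth time-varying treatment effect.

Every generator is deterministic given its seed and returns the
:class:`GeneratorTruth` it simulated from, so parameter-recovery tests are
self-contained.  Outcomes are scaled so that the marginal s.d. is ~1 under a
null truth; effects are therefore on the standardized (Cohen's d) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import TrialDataset

# default study conditions: simple random assignment with equal probabilities;
# mindset indices on 1-6 Likert scales entered with their product as moderators.

#: default standardized effect for the single treated arm (appraisal-outcome
#: scale of the larger quiz experiment)
DEFAULT_ATE = -0.39

#: standardized per-epoch treatment-effect profile for the TSST generator,
#: proportional to the reported per-epoch contrasts with the speech epoch at
#: the replication study's speech ATE of -0.44 s.d.
TSST_EPOCH_EFFECTS = {
    "baseline": 0.0,
    "preparation": -0.33,
    "speech": -0.44,
    "maths": -0.25,
    "recovery": -0.18,
}

#: control-condition epoch profile (standardized): speech is the most extreme
#: active epoch
TSST_EPOCH_PROFILE = {
    "baseline": 0.0,
    "preparation": 0.9,
    "speech": 1.6,
    "maths": 1.1,
    "recovery": 0.5,
}

DEFAULT_EPOCH_MINUTES = {
    "baseline": 5,
    "preparation": 5,
    "speech": 5,
    "maths": 5,
    "recovery": 3,
}


@dataclass
class GeneratorTruth:
    """Ground truth a generator simulated from (standardized units)."""

    true_ate_per_arm: tuple[float, ...] = (DEFAULT_ATE,)
    moderation_function: Callable[[pd.DataFrame], np.ndarray] | None = None
    intercept_sd: float = 0.0
    residual_sd: float = 0.9
    time_effect_curve: Callable[[np.ndarray], np.ndarray] | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        self.true_ate_per_arm = tuple(float(a) for a in self.true_ate_per_arm)

    def row_effects(self, arm_k: int, moderators: pd.DataFrame) -> np.ndarray:
        """Per-row treatment effect of arm ``arm_k`` (1-based) vs control."""
        base = np.full(len(moderators), self.true_ate_per_arm[arm_k - 1])
        if self.moderation_function is not None:
            base = base + np.asarray(self.moderation_function(moderators), dtype=float)
        return base


def mindset_moderation(strength: float = 0.3, midpoint: float = 12.25):
    """Effect stronger above the midpoint of the negative-mindset product term.

    The product of two 1-6 mindset indices has midpoint 3.5 * 3.5 = 12.25;
    units above it (more negative prior mindsets) get ``strength`` s.d. more
    benefit in the beneficial (negative) direction.
    """

    def fn(w: pd.DataFrame) -> np.ndarray:
        prod = w["mindset_product"].to_numpy(dtype=float)
        return -strength * (prod > midpoint).astype(float)

    return fn


def _mindset_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Baseline fixed-mindset and stress-mindset indices on 1-6 scales."""
    fixed = np.clip(rng.normal(3.5, 1.0, n), 1.0, 6.0)
    stress = np.clip(rng.normal(3.5, 1.0, n), 1.0, 6.0)
    return pd.DataFrame(
        {
            "fixed_mindset": fixed,
            "stress_mindset": stress,
            "mindset_product": fixed * stress,
        }
    )


def gen_cross_sectional(
    n_units: int,
    n_arms: int = 1,
    truth: GeneratorTruth | None = None,
    seed: int | None = None,
) -> tuple[TrialDataset, GeneratorTruth]:
    """Cross-sectional trial: one post-intervention outcome per unit.

    Arms are assigned by simple random assignment with equal probabilities
    over the ``n_arms + 1`` cells.  Covariates and moderators are the two
    baseline mindset indices and their product; the prognostic surface loads
    on both indices so the covariates are informative (pass a truth with
    ``extras={'prognostic_strength': 0.0}`` for pure-noise covariates).
    """
    if n_arms < 1:
        raise ValueError("n_arms (treated arms K) must be >= 1")
    if n_units < 2 * (n_arms + 1):
        raise ValueError("need at least two units per cell")
    truth = truth or GeneratorTruth()
    if len(truth.true_ate_per_arm) != n_arms:
        raise ValueError("truth.true_ate_per_arm must have one entry per treated arm")
    if seed is not None:
        truth.seed = int(seed)
    rng = np.random.default_rng(truth.seed)

    w = _mindset_covariates(n_units, rng)
    arm = rng.integers(0, n_arms + 1, size=n_units)
    b = float(truth.extras.get("prognostic_strength", 0.3))
    prog = b * (w["fixed_mindset"] - 3.5) + b * (w["stress_mindset"] - 3.5)
    y = prog.to_numpy() + truth.residual_sd * rng.standard_normal(n_units)
    for k in range(1, n_arms + 1):
        mask = arm == k
        y[mask] += truth.row_effects(k, w)[mask]

    frame = w.copy()
    frame.insert(0, "unit_id", np.arange(n_units))
    frame["arm"] = arm
    frame["y"] = y
    cols = ["fixed_mindset", "stress_mindset", "mindset_product"]
    ds = TrialDataset(
        frame=frame, outcome="y", arm="arm", unit="unit_id",
        covariates=cols, moderators=cols,
    )
    return ds, truth


def diary_truth(seed: int = 0) -> GeneratorTruth:
    """Default daily-diary conditions: self-regard ATE -0.19 s.d., control
    stress-intensity correlation 0.38 halved under treatment, cortisol ATE
    -0.23 s.d., person intercept s.d. 0.6."""
    return GeneratorTruth(
        true_ate_per_arm=(-0.19,),
        intercept_sd=0.6,
        residual_sd=0.8,
        seed=seed,
        extras={
            "control_intensity_corr": 0.38,
            "treated_intensity_corr": 0.19,
            "cortisol_ate": -0.23,
            "no_stressor_prob": 0.30,
        },
    )


def gen_daily_diary(
    n_students: int,
    days: int = 5,
    truth: GeneratorTruth | None = None,
    seed: int | None = None,
) -> tuple[TrialDataset, GeneratorTruth]:
    """Daily-diary trial: two self-regard reports per school day plus a
    cortisol series, with person random intercepts.

    The negative self-regard outcome (1-7, higher = worse) responds to daily
    stressor intensity (1-5, point mass at 1 on no-stressor days) with a
    treatment x intensity interaction: the treated slope is attenuated so the
    pooled observation-level correlations match the target values in the
    truth.  Cortisol (log scale, standardized) declines within day and has a
    negative treatment main effect unrelated to stressor intensity.
    """
    if n_students < 20:
        raise ValueError("need at least 20 students")
    if not (1 <= days <= 7):
        raise ValueError("days must be between 1 and 7")
    truth = truth or diary_truth()
    if seed is not None:
        truth.seed = int(seed)
    rng = np.random.default_rng(truth.seed)
    ex = truth.extras

    w = _mindset_covariates(n_students, rng)
    arm = rng.integers(0, 2, size=n_students)
    alpha = truth.intercept_sd * rng.standard_normal(n_students)

    # day-level stressor intensity: 1 with prob p0 (no stressor), else 2-5
    p0 = float(ex.get("no_stressor_prob", 0.30))
    rated = np.array([0.25, 0.30, 0.28, 0.17])  # P(2), P(3), P(4), P(5)
    probs = np.concatenate([[p0], (1 - p0) * rated])
    intensity = rng.choice(np.arange(1, 6), size=(n_students, days), p=probs)
    s_sd = float(np.sqrt(np.sum(probs * (np.arange(1, 6) - np.sum(probs * np.arange(1, 6))) ** 2)))

    def slope_for(r_target: float) -> float:
        # pooled corr r = b*s_sd / sqrt(sd_alpha^2 + sd_e^2 + b^2 s_sd^2)
        denom = truth.intercept_sd**2 + truth.residual_sd**2
        return float(np.sqrt(r_target**2 * denom / (1 - r_target**2)) / s_sd)

    b_c = slope_for(float(ex.get("control_intensity_corr", 0.38)))
    b_t = slope_for(float(ex.get("treated_intensity_corr", 0.19)))

    rows = []
    sd_y = float(np.sqrt(truth.intercept_sd**2 + truth.residual_sd**2))
    cort_ate = float(ex.get("cortisol_ate", -0.23))
    alpha_c = 0.5 * truth.intercept_sd * rng.standard_normal(n_students)
    for i in range(n_students):
        b = b_t if arm[i] else b_c
        for d in range(days):
            s = intensity[i, d]
            for rep, tod in enumerate(("lunch", "afternoon")):
                e = truth.residual_sd * rng.standard_normal()
                yc = 4.0 + alpha[i] + b * (s - 3.0) + truth.true_ate_per_arm[0] * sd_y * arm[i] + e
                rows.append(
                    (i, arm[i], d + 1, tod, s, float(np.clip(yc, 1.0, 7.0)))
                )
            # cortisol: three samples, within-day decline, standardized log scale
            for si, when in enumerate(("morning", "lunch", "afternoon")):
                c = (
                    0.6 - 0.45 * si
                    + alpha_c[i]
                    + cort_ate * arm[i]
                    + 0.7 * rng.standard_normal()
                )
                rows.append((i, arm[i], d + 1, f"cortisol_{when}", s, np.nan, c))

    diary = pd.DataFrame(
        [r for r in rows if len(r) == 6],
        columns=["unit_id", "arm", "day", "slot", "stressor_intensity", "self_regard"],
    )
    cort = pd.DataFrame(
        [r for r in rows if len(r) == 7],
        columns=["unit_id", "arm", "day", "slot", "stressor_intensity", "_drop", "cortisol"],
    ).drop(columns="_drop")

    frame = diary.merge(w.assign(unit_id=np.arange(n_students)), on="unit_id")
    cols = ["fixed_mindset", "stress_mindset", "mindset_product"]
    ds = TrialDataset(
        frame=frame, outcome="self_regard", arm="arm", unit="unit_id", time="day",
        covariates=cols + ["stressor_intensity"], moderators=cols,
    )
    truth.extras["cortisol_frame"] = cort
    truth.extras["realized_slopes"] = (b_c, b_t)
    return ds, truth


def tsst_truth(seed: int = 0) -> GeneratorTruth:
    """Default TSST conditions: per-epoch effect profile with the speech
    epoch most affected, unit intercept s.d. 0.5, residual s.d. 0.5."""
    return GeneratorTruth(
        true_ate_per_arm=(TSST_EPOCH_EFFECTS["speech"],),
        intercept_sd=0.5,
        residual_sd=0.5,
        seed=seed,
    )


def _epoch_effect_curve(epochs: dict[str, int]) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-linear standardized effect over cumulative minutes, through
    the default per-epoch effect values at epoch midpoints."""
    mids, vals = [], []
    t0 = 0
    for name, m in epochs.items():
        mids.append(t0 + m / 2.0)
        vals.append(TSST_EPOCH_EFFECTS.get(name, 0.0))
        t0 += m
    mids, vals = np.array(mids), np.array(vals)

    def curve(t: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), mids, vals)

    return curve


def gen_tsst(
    n_units: int,
    epochs: dict[str, int] | None = None,
    truth: GeneratorTruth | None = None,
    seed: int | None = None,
) -> tuple[TrialDataset, GeneratorTruth]:
    """Minute-level TSST-style cardiovascular series (standardized units).

    Outcome per minute = unit intercept + control epoch profile (speech most
    extreme) + arm-specific smooth effect curve + noise.  Both the raw value
    and the baseline-subtracted reactivity are emitted; the effect curve is
    zero during the pre-randomization baseline epoch.
    """
    epochs = dict(epochs or DEFAULT_EPOCH_MINUTES)
    if "baseline" not in epochs or epochs["baseline"] < 1:
        raise ValueError("a baseline epoch with at least one minute is required")
    truth = truth or tsst_truth()
    if seed is not None:
        truth.seed = int(seed)
    if truth.time_effect_curve is None:
        truth.time_effect_curve = _epoch_effect_curve(epochs)
    rng = np.random.default_rng(truth.seed)

    w = _mindset_covariates(n_units, rng)
    n_arms = len(truth.true_ate_per_arm)
    arm = rng.integers(0, n_arms + 1, size=n_units)
    alpha = truth.intercept_sd * rng.standard_normal(n_units)

    minute_epoch = []
    minute_index = []
    t = 0
    for name, m in epochs.items():
        for _ in range(int(m)):
            t += 1
            minute_index.append(t)
            minute_epoch.append(name)
    minute_index = np.array(minute_index, dtype=float)
    profile = np.array([TSST_EPOCH_PROFILE.get(e, 0.0) for e in minute_epoch])
    base_mask = np.array([e == "baseline" for e in minute_epoch])

    curve = truth.time_effect_curve(minute_index)
    curve = np.where(base_mask, 0.0, curve)

    rows = []
    for i in range(n_units):
        noise = truth.residual_sd * rng.standard_normal(minute_index.size)
        eff = curve * (arm[i] >= 1)
        if truth.moderation_function is not None and arm[i] >= 1:
            eff = eff + float(truth.moderation_function(w.iloc[[i]])[0])
        y = alpha[i] + profile + eff + noise
        react = y - y[base_mask].mean()
        for j in range(minute_index.size):
            rows.append(
                (i, arm[i], minute_index[j], minute_epoch[j], y[j], react[j])
            )
    frame = pd.DataFrame(
        rows, columns=["unit_id", "arm", "minute", "epoch", "value", "reactivity"]
    ).merge(w.assign(unit_id=np.arange(n_units)), on="unit_id")
    cols = ["fixed_mindset", "stress_mindset", "mindset_product"]
    ds = TrialDataset(
        frame=frame, outcome="reactivity", arm="arm", unit="unit_id", time="minute",
        covariates=cols, moderators=cols,
    )
    return ds, truth


def apply_missingness(
    dataset: TrialDataset,
    covariate_rate: float,
    outcome_rate: float,
    rng: np.random.Generator,
) -> TrialDataset:
    """Blank covariate cells completely at random and drop outcome rows.

    Arm and unit columns are never blanked; outcome non-response removes the
    whole row (intent-to-treat analyses use units that provided outcomes).
    """
    for r in (covariate_rate, outcome_rate):
        if not (0.0 <= r < 1.0):
            raise ValueError("rates must lie in [0, 1)")
    frame = dataset.frame.copy()
    cols = list(dict.fromkeys(dataset.covariates + dataset.moderators))
    if covariate_rate > 0:
        for c in cols:
            mask = rng.random(len(frame)) < covariate_rate
            frame.loc[mask, c] = np.nan
    if outcome_rate > 0:
        keep = rng.random(len(frame)) >= outcome_rate
        frame = frame[keep]
    return dataset.with_frame(frame.reset_index(drop=True))
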