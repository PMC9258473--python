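"""Long-format trial data container.

A :class:`TrialDataset` is a thin, validated wrapper around a pandas
DataFrame in long format: one row per observation, with a unit identifier,
an arm assignment (0 = control), an outcome, optional observation time, and
named covariate / moderator columns.  Moderators are measured before
randomization and must therefore be constant within unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class TrialDataset:
    """Long-format randomized-trial observations.

    Parameters
    ----------
    frame
        The observation table.  Row order is preserved by every operation.
    outcome, arm, unit
        Column names for the outcome (real), arm assignment (integers
        ``0..K`` with 0 the control) and unit identifier.
    time
        Optional column of observation times (minutes of recording or a
        day index) for repeated-measures designs.
    covariates, moderators
        Names of prognostic covariate columns and candidate treatment-effect
        moderator columns (these may overlap).
    """

    frame: pd.DataFrame
    outcome: str
    arm: str
    unit: str
    time: str | None = None
    covariates: list[str] = field(default_factory=list)
    moderators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.covariates = list(self.covariates)
        self.moderators = list(self.moderators)
        cols = [self.outcome, self.arm, self.unit] + (
            [self.time] if self.time else []
        ) + self.covariates + self.moderators
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        y = self.frame[self.outcome]
        if y.isna().any() or not np.all(np.isfinite(y.to_numpy(dtype=float))):
            raise ValueError("outcome must be finite on all analysis rows")
        z = self.frame[self.arm]
        if z.isna().any():
            raise ValueError("arm assignment must be complete")
        zv = z.to_numpy()
        if not np.array_equal(zv, zv.astype(int)):
            raise ValueError("arm must be integer-coded with 0 = control")
        if (zv.astype(int) < 0).any():
            raise ValueError("arm codes must be non-negative")
        by_unit = self.frame.groupby(self.unit, sort=False)
        if (by_unit[self.arm].nunique() > 1).any():
            raise ValueError("arm assignment must be constant within unit")
        for m in self.moderators:
            if (by_unit[m].nunique(dropna=False) > 1).any():
                raise ValueError(
                    f"moderator {m!r} varies within unit; moderators are "
                    "pre-randomization measurements"
                )
        if self.n_arms < 1:
            raise ValueError("need at least one treated arm (K >= 1)")

    # -- convenient views ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_units(self) -> int:
        return self.frame[self.unit].nunique()

    @property
    def n_arms(self) -> int:
        """Number of treated arms K (arms are 0..K with 0 = control)."""
        return int(self.frame[self.arm].max())

    @property
    def arm_codes(self) -> np.ndarray:
        return self.frame[self.arm].to_numpy(dtype=int)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.outcome].to_numpy(dtype=float)

    @property
    def unit_codes(self) -> np.ndarray:
        codes, _ = pd.factorize(self.frame[self.unit], sort=False)
        return codes

    @property
    def unit_labels(self) -> list:
        _, labels = pd.factorize(self.frame[self.unit], sort=False)
        return list(labels)

    @property
    def times(self) -> np.ndarray | None:
        if self.time is None:
            return None
        return self.frame[self.time].to_numpy(dtype=float)

    def covariate_frame(self) -> pd.DataFrame:
        return self.frame[self.covariates]

    def moderator_frame(self) -> pd.DataFrame:
        return self.frame[self.moderators]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean per-cell missingness of covariate and moderator columns."""
        cols = list(dict.fromkeys(self.covariates + self.moderators))
        return self.frame[cols].isna()

    def has_missing(self) -> bool:
        return bool(self.missing_mask().to_numpy().any())

    def with_frame(self, frame: pd.DataFrame, **updates) -> "TrialDataset":
        return replace(self, frame=frame, **updates)

    def pooled_sd(self) -> float:
        """Across-arm outcome s.d.: sqrt of the equally weighted average of
        arm-level observation variances."""
        variances = [
            float(np.var(g.to_numpy(dtype=float), ddof=1))
            for _, g in self.frame.groupby(self.arm)[self.outcome]
        ]
        sd = float(np.sqrt(np.mean(variances)))
        if sd <= 0:
            raise ValueError("pooled outcome s.d. is zero")
        return sd
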