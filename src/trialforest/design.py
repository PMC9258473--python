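"""Power and sample-size calculations for two-sample comparisons.

Two computation methods are exposed because published design
determinations mix exact noncentral-t software output with
normal-approximation figures:

* ``noncentral_t`` — power of the two-sample t test from the noncentral t
  distribution with df = 2n - 2 and noncentrality d * sqrt(n / 2);
* ``normal_approx`` — n = 2 * ((z_{1-a} + z_{1-b}) / d)^2, rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

_N_CAP = 10_000_000


@dataclass(frozen=True)
class PowerSpec:
    """A two-sample t-test design target."""

    effect_size_d: float
    alpha: float = 0.05
    tails: int = 2
    target_power: float = 0.80
    method: str = "noncentral_t"

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.target_power < 1):
            raise ValueError("alpha and target power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.method not in ("noncentral_t", "normal_approx"):
            raise ValueError(f"unknown method {self.method!r}")


def achieved_power(n_per_group: int, spec: PowerSpec) -> float:
    """Power of the two-sample t test with ``n_per_group`` per arm."""
    n = int(n_per_group)
    if n < 2:
        raise ValueError("need at least 2 per group")
    d, alpha = spec.effect_size_d, spec.alpha
    nc = d * math.sqrt(n / 2.0)
    if spec.method == "normal_approx":
        z = stats.norm.ppf(1 - alpha / spec.tails)
        power = 1 - stats.norm.cdf(z - nc)
        if spec.tails == 2:
            power += stats.norm.cdf(-z - nc)
        return float(power)
    df = 2 * n - 2
    tcrit = stats.t.ppf(1 - alpha / spec.tails, df)
    power = stats.nct.sf(tcrit, df, nc)
    if math.isnan(power):  # far-tail instability at extreme noncentrality
        power = float(stats.norm.sf(tcrit - nc))
    if spec.tails == 2:
        other = stats.nct.cdf(-tcrit, df, nc)
        power += 0.0 if math.isnan(other) else other
    return float(min(power, 1.0))


def required_n_per_group(spec: PowerSpec) -> int:
    """Smallest equal per-group n whose achieved power reaches the target."""
    if spec.method == "normal_approx":
        za = stats.norm.ppf(1 - spec.alpha / spec.tails)
        zb = stats.norm.ppf(spec.target_power)
        n = math.ceil(2.0 * ((za + zb) / spec.effect_size_d) ** 2)
        return max(n, 2)
    if achieved_power(2, spec) >= spec.target_power:
        return 2
    # bracket by doubling, then binary-search the monotone power curve
    lo, hi = 2, 4
    while achieved_power(hi, spec) < spec.target_power:
        lo, hi = hi, hi * 2
        if hi > _N_CAP:
            raise ValueError(
                f"target power unreachable below n = {_N_CAP} per group"
            )
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(mid, spec) >= spec.target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo
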