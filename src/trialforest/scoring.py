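"""Deterministic scale and index construction.

Questionnaire items are combined into indices by unweighted averaging (with
reverse-coding where declared), the GAD-7 anxiety screener is summed, the
demand/resource appraisal items form a threat-versus-challenge ratio index,
transcript pass records form on-track indicators, and daily stressor
intensity follows the no-stressor-day coding rule.  Shipped
:class:`ScaleSpec` definitions live in the package's ``scales/`` JSON files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping


@dataclass(frozen=True)
class ScaleSpec:
    """A questionnaire scale: items, response range, reversals, aggregation."""

    name: str
    item_labels: tuple[str, ...]
    response_range: tuple[int, int]
    reverse_coded: frozenset[str] = frozenset()
    aggregation: str = "unweighted_mean"  # unweighted_mean | sum

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_labels", tuple(self.item_labels))
        object.__setattr__(self, "reverse_coded", frozenset(self.reverse_coded))
        lo, hi = self.response_range
        if lo >= hi:
            raise ValueError("response range minimum must be below maximum")
        if not self.reverse_coded <= set(self.item_labels):
            raise ValueError("reverse_coded items must be a subset of the items")
        if self.aggregation not in ("unweighted_mean", "sum"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def load(cls, name: str) -> "ScaleSpec":
        """Load one of the shipped scale definitions by name."""
        path = resources.files("trialforest").joinpath(f"scales/{name}.json")
        spec = json.loads(path.read_text())
        return cls(
            name=spec["name"],
            item_labels=tuple(spec["item_labels"]),
            response_range=tuple(spec["response_range"]),
            reverse_coded=frozenset(spec.get("reverse_coded", [])),
            aggregation=spec.get("aggregation", "unweighted_mean"),
        )


def unweighted_index(responses: Mapping[str, float], spec: ScaleSpec) -> float:
    """Unweighted average (or sum) of the scale items after reverse-coding.

    Reverse-coded items are mapped v -> (min + max - v).  Every item must be
    answered and within the response range.
    """
    lo, hi = spec.response_range
    total = 0.0
    for item in spec.item_labels:
        if item not in responses or responses[item] is None:
            raise ValueError(f"missing response for item {item!r}")
        v = float(responses[item])
        if not (lo <= v <= hi):
            raise ValueError(
                f"response {v} for item {item!r} outside range [{lo}, {hi}]"
            )
        if item in spec.reverse_coded:
            v = lo + hi - v
        total += v
    if spec.aggregation == "sum":
        return total
    return total / len(spec.item_labels)


def gad7_total(responses: Iterable[float]) -> int:
    """GAD-7 total: seven items each in {0..3}, summed to 0-21."""
    vals = list(responses)
    if len(vals) != 7:
        raise ValueError(f"GAD-7 requires exactly 7 responses, got {len(vals)}")
    out = 0
    for v in vals:
        if v not in (0, 1, 2, 3):
            raise ValueError(f"GAD-7 responses must be integers 0-3, got {v!r}")
        out += int(v)
    return out


def threat_challenge_index(
    demand_items: Iterable[float],
    resource_items: Iterable[float],
    threat_item: float,
    challenge_item: float,
) -> float:
    """Threat-versus-challenge appraisal index.

    The mean of two ratio scores: (mean demand / mean resources) and
    (threat rating / challenge rating).  Higher values indicate appraising
    the situation's demands as exceeding one's resources (threat).
    """
    demand = list(map(float, demand_items))
    resources_ = list(map(float, resource_items))
    if not demand or not resources_:
        raise ValueError("demand and resource item lists must be non-empty")
    res_mean = sum(resources_) / len(resources_)
    if res_mean <= 0:
        raise ValueError("mean of resource items must be positive")
    if float(challenge_item) <= 0:
        raise ValueError("challenge rating must be positive")
    ratio1 = (sum(demand) / len(demand)) / res_mean
    ratio2 = float(threat_item) / float(challenge_item)
    return (ratio1 + ratio2) / 2.0


_CORE_SUBJECTS = ("math", "science", "social_studies", "ela")


def on_track_indices(passes: Mapping[str, bool]) -> tuple[int, int, int]:
    """(overall, STEM, non-STEM) on-track indicators from core-class passes.

    overall = passed all four core classes; STEM = passed mathematics and
    science; non-STEM = passed social studies and English/language arts.
    """
    missing = [s for s in _CORE_SUBJECTS if s not in passes]
    if missing:
        raise ValueError(f"missing core subjects: {missing}")
    p = {s: bool(passes[s]) for s in _CORE_SUBJECTS}
    overall = int(all(p.values()))
    stem = int(p["math"] and p["science"])
    non_stem = int(p["social_studies"] and p["ela"])
    return overall, stem, non_stem


def stressor_intensity(checked_stressors: Iterable[str] | set,
                       rating: int | None = None) -> int:
    """Daily stressor-intensity code.

    Days with no social-evaluative stressor listed are coded 1 (the lowest
    value) rather than dropped; otherwise the 1-5 intensity rating passes
    through.
    """
    stressors = set(checked_stressors)
    if not stressors:
        return 1
    if rating is None:
        raise ValueError("stressors were listed but no intensity rating given")
    r = int(rating)
    if not (1 <= r <= 5):
        raise ValueError("intensity rating must be in 1..5")
    return r
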