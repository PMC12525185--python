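"""Correlation-weight tables, the DCW descriptor and the calibration line.

The model is a one-variable linear regression

    pLC50 = C0 + C1 * DCW(T, N)

where DCW(T, N) is the sum of the correlation weights of all *active*
attributes of a molecule: attributes occurring in at least T compounds of the
active training set.  Rare attributes are blocked (weight pinned to zero) and
never contribute to the descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

import numpy as np

from .errors import DatasetError, DegenerateDescriptorError
from .tokenizer import AttributeProfile

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .applicability import DomainModel
    from .optimizer import OptimizationConfig

__all__ = [
    "CorrelationWeightTable",
    "FittedModel",
    "active_attributes",
    "dcw",
    "fit_calibration_line",
    "predict",
]


@dataclass(frozen=True)
class CorrelationWeightTable:
    """Attribute → weight map plus the blocked set and rarity threshold T."""

    weights: Mapping[str, float]
    blocked: frozenset
    threshold_T: int

    def weight(self, attribute: str) -> float:
        if attribute in self.blocked:
            return 0.0
        return float(self.weights.get(attribute, 0.0))


@dataclass
class FittedModel:
    """A calibrated correlation-weight model with its applicability domain."""

    table: CorrelationWeightTable
    c0: float
    c1: float
    config: "OptimizationConfig"
    domain: Optional["DomainModel"] = None
    metadata: dict = field(default_factory=dict)


def active_attributes(
    profiles: Iterable[AttributeProfile],
    threshold_T: int,
    count: str = "compounds",
) -> set:
    """Attributes occurring at least T times in the active training set.

    ``count="compounds"`` (default) counts the number of compounds containing
    the attribute; ``count="occurrences"`` counts total occurrences.  The two
    readings coincide at T = 1.
    """
    if threshold_T < 1:
        raise ValueError(f"threshold_T must be >= 1, got {threshold_T}")
    if count not in ("compounds", "occurrences"):
        raise ValueError(f"unknown counting mode {count!r}")
    profiles = list(profiles)
    if not profiles:
        raise DatasetError("active training set is empty")
    tally: dict = {}
    for profile in profiles:
        merged = profile.merged()
        if count == "compounds":
            for attr in merged:
                tally[attr] = tally.get(attr, 0) + 1
        else:
            for attr, cnt in merged.items():
                tally[attr] = tally.get(attr, 0) + cnt
    return {attr for attr, total in tally.items() if total >= threshold_T}


def dcw(profile: AttributeProfile, table: CorrelationWeightTable) -> float:
    """Descriptor value: sum of counts times correlation weights.

    Blocked and unseen attributes contribute zero.
    """
    total = 0.0
    for counts in (profile.sk_counts, profile.ssk_counts):
        for attr, cnt in counts.items():
            if attr in table.blocked:
                continue
            w = table.weights.get(attr)
            if w is not None:
                total += cnt * float(w)
    return total


def fit_calibration_line(dcw_values, endpoints) -> tuple:
    """Ordinary least squares of endpoint on descriptor; returns (c0, c1)."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dcw_values and endpoints must be 1-D and equal length")
    if x.size < 3:
        raise DatasetError(f"need at least 3 points to calibrate, got {x.size}")
    xc = x - x.mean()
    ssx = float(xc @ xc)
    if ssx == 0.0:
        raise DegenerateDescriptorError("descriptor has zero variance")
    c1 = float(xc @ (y - y.mean())) / ssx
    c0 = float(y.mean() - c1 * x.mean())
    return c0, c1


def predict(model: FittedModel, profile: AttributeProfile) -> float:
    """Model prediction C0 + C1 * DCW for one compound."""
    return model.c0 + model.c1 * dcw(profile, model.table)
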