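"""Applicability domain via statistical defects of SMILES attributes.

An attribute that appears with very different frequencies in the active
training, passive training and calibration sets is statistically unreliable.
Its defect is

    dk = |pA − pP|/(nA + nP) + |pA − pC|/(nA + nC) + |pP − pC|/(nP + nC)

where n are compound frequencies and p = n/size the corresponding
probabilities per set.  An attribute absent from any one of the three sets
gets the maximal defect 1.0.  A compound's defect Dj sums dk over its
non-blocked attributes (once per occurrence); the compound is inside the
applicability domain iff Dj < 2·D̄, with D̄ the mean defect over the active
training set.  Compounds failing the rule are the model's outliers.

Attributes never seen in any of the three modeling sets (possible at
prediction time, or for validation-only fragments) contribute 1.0 per
occurrence to Dj: a fragment invisible to the whole modeling process is
maximally unreliable.  Attributes seen but blocked as rare contribute
nothing, since the defect sum runs over non-blocked attributes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DatasetError, UnknownAttributeError
from .tokenizer import AttributeProfile, profile_from_smiles
from .weights import FittedModel

__all__ = [
    "DefectRecord",
    "DomainModel",
    "attribute_defect",
    "build_domain",
    "compound_defect",
    "in_domain",
    "find_outliers",
]

#: Defect assigned to an attribute missing from at least one modeling set.
ABSENT_DEFECT = 1.0


@dataclass(frozen=True)
class DefectRecord:
    attribute: str
    nA: int
    nP: int
    nC: int
    pA: float
    pP: float
    pC: float
    dk: float


@dataclass
class DomainModel:
    """Defect table over non-blocked attributes plus the domain threshold."""

    defects: Mapping[str, DefectRecord]
    dbar: float
    set_sizes: Mapping[str, int]
    known: frozenset  # every attribute seen in A ∪ P ∪ C, blocked or not
    mean_set: str = "A"


def attribute_defect(nA, nP, nC, sizeA, sizeP, sizeC) -> float:
    """Statistical defect of one attribute from its per-set frequencies."""
    for n, size in ((nA, sizeA), (nP, sizeP), (nC, sizeC)):
        if size <= 0:
            raise ValueError("set sizes must be positive")
        if n < 0 or n > size:
            raise ValueError(f"frequency {n} outside [0, {size}]")
    if nA + nP + nC == 0:
        raise UnknownAttributeError("attribute absent from all three sets")
    if min(nA, nP, nC) == 0:
        return ABSENT_DEFECT
    pA, pP, pC = nA / sizeA, nP / sizeP, nC / sizeC
    return (
        abs(pA - pP) / (nA + nP)
        + abs(pA - pC) / (nA + nC)
        + abs(pP - pC) / (nP + nC)
    )


def _compound_frequency(profiles: Sequence[AttributeProfile]) -> dict:
    freq: dict = {}
    for profile in profiles:
        for attr in profile.merged():
            freq[attr] = freq.get(attr, 0) + 1
    return freq


def build_domain(
    profiles_a: Sequence[AttributeProfile],
    profiles_p: Sequence[AttributeProfile],
    profiles_c: Sequence[AttributeProfile],
    active: set,
    mean_set: str = "A",
) -> DomainModel:
    """Defect table and mean defect D̄ for a fitted split.

    ``active`` is the set of non-blocked attributes; ``mean_set`` selects the
    compounds D̄ averages over ("A" or "APC").
    """
    if not profiles_a or not profiles_p or not profiles_c:
        raise DatasetError("all three modeling sets must be non-empty")
    if mean_set not in ("A", "APC"):
        raise ValueError(f"mean_set must be 'A' or 'APC', got {mean_set!r}")
    freq_a = _compound_frequency(profiles_a)
    freq_p = _compound_frequency(profiles_p)
    freq_c = _compound_frequency(profiles_c)
    sizes = {"A": len(profiles_a), "P": len(profiles_p), "C": len(profiles_c)}
    defects = {}
    for attr in sorted(active):
        nA = freq_a.get(attr, 0)
        nP = freq_p.get(attr, 0)
        nC = freq_c.get(attr, 0)
        dk = attribute_defect(nA, nP, nC, sizes["A"], sizes["P"], sizes["C"])
        defects[attr] = DefectRecord(
            attribute=attr, nA=nA, nP=nP, nC=nC,
            pA=nA / sizes["A"], pP=nP / sizes["P"], pC=nC / sizes["C"], dk=dk,
        )
    known = frozenset(freq_a) | frozenset(freq_p) | frozenset(freq_c)
    domain = DomainModel(
        defects=defects, dbar=0.0, set_sizes=sizes, known=known, mean_set=mean_set,
    )
    pool = list(profiles_a) if mean_set == "A" else (
        list(profiles_a) + list(profiles_p) + list(profiles_c)
    )
    domain.dbar = float(np.mean([compound_defect(p, domain) for p in pool]))
    return domain


def compound_defect(profile: AttributeProfile, domain: DomainModel) -> float:
    """Dj: sum of attribute defects over the compound, once per occurrence."""
    total = 0.0
    for counts in (profile.sk_counts, profile.ssk_counts):
        for attr, cnt in counts.items():
            record = domain.defects.get(attr)
            if record is not None:
                total += cnt * record.dk
            elif attr not in domain.known:
                total += cnt * ABSENT_DEFECT
            # seen-but-blocked attributes contribute nothing
    return total


def in_domain(dj: float, dbar: float) -> bool:
    """Domain rule: inside iff Dj < 2·D̄ (strict at the boundary)."""
    if dbar <= 0:
        raise ValueError(f"mean defect must be positive, got {dbar}")
    return dj < 2.0 * dbar


def find_outliers(model: FittedModel, records, split) -> dict:
    """Compounds failing the domain rule, grouped by split membership."""
    if model.domain is None:
        raise DatasetError("model carries no domain statistics")
    domain = model.domain
    outliers: dict = {label: [] for label in ("A", "P", "C", "V")}
    for record in records:
        label = split.assignment.get(record.id)
        if label is None:
            continue
        dj = compound_defect(profile_from_smiles(record.smiles), domain)
        if domain.dbar > 0 and not in_domain(dj, domain.dbar):
            outliers[label].append(record.id)
    outliers["total"] = sum(len(v) for v in outliers.values())
    return outliers
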