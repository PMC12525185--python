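"""Mechanistic interpretation via multi-probe sign stability.

A single Monte Carlo run yields one weight per attribute, but those weights
are stochastic.  Repeating the optimization with independent seeds ("probes")
and keeping only attributes whose weight sign is stable across all probes
separates genuine promoters of endpoint increase (all weights positive) or
decrease (all negative) from noise (mixed signs → unstable).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DatasetError
from .optimizer import OptimizationConfig, optimize
from .partition import FourWaySplit
from .tokenizer import SmilesRecord
from .weights import CorrelationWeightTable

__all__ = ["PromoterRecord", "run_probes", "classify_promoters", "promoter_analysis"]

_CLASS_ORDER = {"increase": 0, "decrease": 1, "unstable": 2}


@dataclass(frozen=True)
class PromoterRecord:
    attribute: str
    weights: tuple
    classification: str  # "increase" | "decrease" | "unstable"
    nA: int = 0
    nP: int = 0
    nC: int = 0
    dk: Optional[float] = None


def run_probes(
    records: Sequence[SmilesRecord],
    split: FourWaySplit,
    config: OptimizationConfig,
    n_probes: int = 3,
) -> list:
    """Independent optimization runs over the same split with derived seeds."""
    if n_probes < 2:
        raise ValueError(f"need at least 2 probes, got {n_probes}")
    probe_seeds = np.random.SeedSequence(config.seed).generate_state(n_probes)
    tables = []
    for seed in probe_seeds:
        probe_config = dataclasses.replace(config, seed=int(seed))
        model, _ = optimize(records, split, probe_config)
        tables.append(model.table)
    return tables


def _classify(weights: tuple) -> str:
    if all(w > 0 for w in weights):
        return "increase"
    if all(w < 0 for w in weights):
        return "decrease"
    return "unstable"  # mixed signs, or any exactly-zero weight


def classify_promoters(
    tables: Sequence[CorrelationWeightTable],
    frequencies: Optional[dict] = None,
    defects: Optional[dict] = None,
) -> list:
    """Sign-stability classification of every attribute in the common active set.

    ``frequencies`` maps attribute → (nA, nP, nC); ``defects`` maps attribute
    → dk.  Records are sorted by classification (increase, decrease,
    unstable), then active-training frequency descending, then attribute.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 probe tables")
    attr_sets = [set(t.weights) for t in tables]
    if any(s != attr_sets[0] for s in attr_sets[1:]):
        raise DatasetError("probe tables cover different attribute sets")
    records = []
    for attr in sorted(attr_sets[0]):
        ws = tuple(float(t.weights[attr]) for t in tables)
        nA, nP, nC = (frequencies or {}).get(attr, (0, 0, 0))
        records.append(
            PromoterRecord(
                attribute=attr,
                weights=ws,
                classification=_classify(ws),
                nA=nA, nP=nP, nC=nC,
                dk=(defects or {}).get(attr),
            )
        )
    records.sort(
        key=lambda r: (_CLASS_ORDER[r.classification], -r.nA, r.attribute)
    )
    return records


def promoter_analysis(
    records: Sequence[SmilesRecord],
    split: FourWaySplit,
    config: OptimizationConfig,
    n_probes: int = 3,
) -> list:
    """Probes + classification with frequencies/defects from the first run."""
    probe_config = dataclasses.replace(config)
    model, _ = optimize(records, split, probe_config)
    tables = run_probes(records, split, config, n_probes=n_probes)
    frequencies = {
        attr: (rec.nA, rec.nP, rec.nC) for attr, rec in model.domain.defects.items()
    }
    defects = {attr: rec.dk for attr, rec in model.domain.defects.items()}
    return classify_promoters(tables, frequencies, defects)
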