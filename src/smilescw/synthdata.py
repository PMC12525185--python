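"""Synthetic SMILES-like compounds with a known linear ground truth.

The generator assembles syntactically valid SMILES-like strings from a small
closed vocabulary of chain atoms, branch units, double-bond units and ring
templates, then assigns the endpoint as a linear function of the attribute
counts plus Gaussian noise:

    endpoint = c0* + Σ_attr w*(attr) · count(attr) + Normal(0, σ)

Because the generating model lives inside the correlation-weight model
class, a perfect optimizer can reach R² = 1 at σ = 0, which makes the
generator the ground-truth harness for parameter-recovery and overtraining
experiments.  Every emitted string is balanced before the ``)`` → ``(``
normalization and has paired ring-closure digits, so all strings tokenize
without error.

The default ("identifiable") vocabulary is chosen so that no attribute count
is an exact linear function of the others: ``=`` occurs both in branch units
and chain double-bond units, ``Cl`` both bare and branched, ring digits come
from several templates.  A "brackets" preset adds bracket atoms and ``%NN``
ring closures purely to exercise the tokenizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tokenizer import SmilesRecord, profile_from_smiles

__all__ = ["SyntheticSpec", "generate_compound", "generate_dataset", "signal_value"]

CHAIN_ATOMS = ("C", "C", "C", "N", "O", "S", "Cl")  # multiplicity = draw weight
BRANCH_UNITS = ("(C)", "(Cl)")
EXTRA_BRANCH_UNITS = ("(=O)", "(N)")
#: two distinct double-bond units so that the '=' count is not an exact
#: multiple of any single pair count (full-column-rank requirement)
DOUBLE_BOND_UNITS = ("C=C", "C=O")
RING_UNITS = ("c1ccccc1", "C1CCC1", "c1ccncc1", "C2CCCC2")
BRACKET_RING_UNITS = ("[NH3+]", "C%11CCC%11", "[O-]")

PRESETS = ("identifiable", "rings", "brackets")

#: True attribute weights of the generating model, spanning roughly the
#: magnitude range seen in fitted weight tables.
TRUE_WEIGHTS = {
    "C": 0.12, "c": 0.08, "N": -0.22, "O": -0.28, "S": 0.50, "Cl": 0.55,
    "=": 0.15, "1": -0.05, "2": -0.02, "(": 0.04,
    "CC": 0.10, "cc": 0.06, "Cl(": 0.25, "C=": 0.07, "NC": -0.15, "O=": -0.10,
}
TRUE_INTERCEPT = 1.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_compounds: int = 200
    seed: int = 0
    #: absolute noise SD; if None, noise_fraction × SD(signal) is used
    noise_sd: Optional[float] = None
    #: noise SD as a fraction of the noiseless-signal SD
    noise_fraction: Optional[float] = 0.1
    chain_len: tuple = (4, 10)
    branch_prob: float = 0.25
    double_bond_prob: float = 0.15
    max_rings: int = 3
    preset: str = "identifiable"  # see PRESETS
    #: fraction of compounds given a constant endpoint offset (atypical
    #: compounds, producing a two-cluster observed-vs-predicted pattern)
    atypical_fraction: float = 0.0
    atypical_offset: float = 2.0
    true_weights: dict = field(default_factory=lambda: dict(TRUE_WEIGHTS))
    intercept: float = TRUE_INTERCEPT


def generate_compound(spec: SyntheticSpec, rng: np.random.Generator) -> SmilesRecord:
    """One random compound.

    Noise is added only when the spec fixes an absolute ``noise_sd``;
    fraction-of-signal noise needs the whole dataset and is handled by
    :func:`generate_dataset`.
    """
    smiles = _random_smiles(spec, rng)
    endpoint = signal_value(smiles, spec)
    if spec.noise_sd is not None and spec.noise_sd > 0:
        endpoint += float(rng.normal(0.0, spec.noise_sd))
    return SmilesRecord(id="", smiles=smiles, endpoint=endpoint)


def _vocabulary(preset: str) -> tuple:
    """(branch units, double-bond units, ring units) for a preset.

    The identifiable preset omits double bonds: a ``=`` token never occurs
    at a string boundary, so its pair counts always sum to exactly twice its
    own count — an exact linear dependency that would defeat the preset's
    full-column-rank guarantee.
    """
    if preset == "identifiable":
        return BRANCH_UNITS, (), ()
    if preset == "rings":
        return BRANCH_UNITS + EXTRA_BRANCH_UNITS, DOUBLE_BOND_UNITS, RING_UNITS
    if preset == "brackets":
        return (
            BRANCH_UNITS + EXTRA_BRANCH_UNITS,
            DOUBLE_BOND_UNITS,
            RING_UNITS + BRACKET_RING_UNITS,
        )
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def _random_smiles(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    branch_pool, dbl_pool, ring_pool = _vocabulary(spec.preset)
    lo, hi = spec.chain_len
    n_chain = int(rng.integers(lo, hi + 1))
    segments = []
    for _ in range(n_chain):
        u = rng.random()
        if dbl_pool and u < spec.double_bond_prob:
            segments.append(dbl_pool[rng.integers(len(dbl_pool))])
        else:
            segments.append(CHAIN_ATOMS[rng.integers(len(CHAIN_ATOMS))])
        if rng.random() < spec.branch_prob:
            segments.append(branch_pool[rng.integers(len(branch_pool))])
    if ring_pool:
        n_rings = int(rng.integers(0, spec.max_rings + 1))
        for _ in range(n_rings):
            unit = ring_pool[rng.integers(len(ring_pool))]
            pos = int(rng.integers(0, len(segments) + 1))
            segments.insert(pos, unit)
    return "".join(segments)


def signal_value(smiles: str, spec: SyntheticSpec) -> float:
    """Noiseless endpoint: intercept plus weighted attribute counts."""
    profile = profile_from_smiles(smiles)
    total = spec.intercept
    for attr, cnt in profile.merged().items():
        total += cnt * spec.true_weights.get(attr, 0.0)
    return total


def generate_dataset(spec: SyntheticSpec) -> tuple:
    """Seeded dataset plus a truth sidecar for recovery tests.

    Returns ``(records, truth)`` where ``truth`` records the generating
    weights, intercept, realized noise SD and any atypical compounds.
    """
    if spec.n_compounds < 20:
        raise ValueError(f"n_compounds must be >= 20, got {spec.n_compounds}")
    rng = np.random.default_rng(spec.seed)
    smiles_list = [_random_smiles(spec, rng) for _ in range(spec.n_compounds)]
    signals = np.array([signal_value(s, spec) for s in smiles_list])
    if spec.noise_sd is not None:
        sigma = float(spec.noise_sd)
    elif spec.noise_fraction is not None:
        sigma = float(spec.noise_fraction) * float(signals.std())
    else:
        sigma = 0.0
    noise = rng.normal(0.0, sigma, size=spec.n_compounds) if sigma > 0 else np.zeros(
        spec.n_compounds
    )
    offsets = np.zeros(spec.n_compounds)
    atypical_ids = []
    if spec.atypical_fraction > 0:
        n_atypical = int(round(spec.atypical_fraction * spec.n_compounds))
        chosen = rng.choice(spec.n_compounds, size=n_atypical, replace=False)
        offsets[chosen] = spec.atypical_offset
        atypical_ids = sorted(int(i) for i in chosen)
    width = len(str(spec.n_compounds))
    records = [
        SmilesRecord(
            id=f"SYN-{i + 1:0{width}d}",
            smiles=s,
            endpoint=float(signals[i] + noise[i] + offsets[i]),
        )
        for i, s in enumerate(smiles_list)
    ]
    truth = {
        "true_weights": dict(spec.true_weights),
        "intercept": spec.intercept,
        "noise_sd": sigma,
        "seed": spec.seed,
        "n_compounds": spec.n_compounds,
        "preset": spec.preset,
        "atypical_ids": [records[i].id for i in atypical_ids],
        "atypical_offset": spec.atypical_offset if atypical_ids else 0.0,
    }
    return records, truth
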