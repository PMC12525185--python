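"""Random four-way data splits: active training / passive training /
calibration / validation.

Each compound is assigned independently with the given probabilities
(default 25% each), so set sizes fluctuate binomially around n/4 — matching
how repeated random splits of the same dataset yield slightly unequal set
sizes.  Draws are repeated until every set is non-empty.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DatasetError

__all__ = ["SET_LABELS", "FourWaySplit", "make_split", "make_splits"]

#: A = active training, P = passive training, C = calibration, V = validation.
SET_LABELS = ("A", "P", "C", "V")


@dataclass(frozen=True)
class FourWaySplit:
    """Disjoint assignment of every compound id to one of the four sets."""

    split_id: int
    assignment: Mapping[str, str]

    def members(self, label: str) -> list:
        if label not in SET_LABELS:
            raise ValueError(f"unknown set label {label!r}")
        return [cid for cid, lab in self.assignment.items() if lab == label]

    def sizes(self) -> dict:
        out = {label: 0 for label in SET_LABELS}
        for lab in self.assignment.values():
            out[lab] += 1
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "set"])
            for cid, lab in self.assignment.items():
                writer.writerow([cid, lab])

    @classmethod
    def from_csv(cls, path, split_id: int = 0) -> "FourWaySplit":
        assignment = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["id", "set"]:
                raise DatasetError(f"split file {path} must have header 'id,set'")
            for row in reader:
                if not row:
                    continue
                cid, lab = row[0], row[1]
                if lab not in SET_LABELS:
                    raise DatasetError(f"unknown set label {lab!r} in {path}")
                if cid in assignment:
                    raise DatasetError(f"duplicate id {cid!r} in split file {path}")
                assignment[cid] = lab
        return cls(split_id=split_id, assignment=assignment)


def make_split(
    ids: Sequence[str],
    proportions: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    split_id: int = 1,
    max_tries: int = 1000,
) -> FourWaySplit:
    """Assign each compound independently to A/P/C/V with the given probabilities.

    Resamples (from the same seeded stream) if any set would be empty.
    """
    ids = list(ids)
    if len(ids) != len(set(ids)):
        raise DatasetError("compound ids must be unique")
    if len(ids) < 8:
        raise DatasetError(f"need at least 8 compounds to split, got {len(ids)}")
    props = np.asarray(proportions, dtype=float)
    if props.shape != (4,) or np.any(props <= 0):
        raise ValueError("proportions must be four strictly positive numbers")
    props = props / props.sum()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        draws = rng.choice(4, size=len(ids), p=props)
        if len(np.unique(draws)) == 4:
            assignment = {cid: SET_LABELS[d] for cid, d in zip(ids, draws)}
            return FourWaySplit(split_id=split_id, assignment=assignment)
    raise DatasetError("could not draw a split with all four sets non-empty")


def make_splits(ids: Sequence[str], k: int, base_seed: int = 0) -> list:
    """k independent splits with distinct seeds derived from ``base_seed``."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    child_seeds = np.random.SeedSequence(base_seed).generate_state(k)
    splits = []
    for i, child in enumerate(child_seeds):
        split = make_split(ids, seed=int(child), split_id=i + 1)
        splits.append(split)
    # Independent draws over >= 8 ids virtually never coincide; guard anyway.
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if splits[i].assignment == splits[j].assignment:
                bumped = make_split(ids, seed=int(child_seeds[j]) + 1, split_id=j + 1)
                splits[j] = bumped
    return splits
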