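"""Class-balancing subset scheme and per-subset cross-validation folds.

Binary-outcome PET cohorts are typically dominated by non-progressors
(TTP0).  Rather than class weights, the training design balances classes by
construction: the TTP0 majority is divided into five near-equal strata
(subsets A-E), each stratum is topped up to the TTP1 count by borrowing a
few TTP0 patients from *distinct* other strata, and every TTP1 patient
joins all five subsets.  For the canonical (244 TTP0, 52 TTP1) cohort this
yields subsets of 104/104/104/104/103 patients at ~50% prevalence, with
52/52/52/52/51 TTP0.  Each subset is then trained with label-stratified
five-fold cross-validation (80% train / 20% internal validation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .volume_io import PatientRecord, TTP0, TTP1

SUBSET_IDS = ("A", "B", "C", "D", "E")


@dataclass
class CohortPartition:
    """Balanced subsets A-E plus their 5-fold CV splits.

    ``subsets`` maps subset id to an ordered list of patient ids;
    ``labels`` maps patient id to its binary label; ``folds`` maps subset id
    to five (train_ids, validation_ids) pairs.
    """

    subsets: dict[str, list[str]]
    labels: dict[str, int]
    folds: dict[str, list[tuple[list[str], list[str]]]] = field(default_factory=dict)
    strata: list[list[str]] = field(default_factory=list)   # base TTP0 strata A-E
    seed: int = 0

    def subset_labels(self, subset_id: str) -> list[int]:
        return [self.labels[pid] for pid in self.subsets[subset_id]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "subsets": self.subsets,
            "labels": self.labels,
            "strata": self.strata,
            "folds": {s: [[tr, va] for tr, va in fl] for s, fl in self.folds.items()},
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "CohortPartition":
        d = json.loads(Path(path).read_text())
        return CohortPartition(
            subsets=d["subsets"],
            labels={k: int(v) for k, v in d["labels"].items()},
            folds={s: [(tr, va) for tr, va in fl] for s, fl in d["folds"].items()},
            strata=d.get("strata", []),
            seed=d["seed"],
        )


def build_subsets(records: Sequence[PatientRecord], seed: int = 0,
                  with_folds: bool = True) -> CohortPartition:
    """Build the five balanced subsets from an imbalanced binary cohort.

    The TTP0 patients are shuffled and split into 5 near-equal strata (the
    first strata take the remainder, e.g. 244 -> 49/49/49/49/48).  Each
    subset then consists of its base stratum, augmented by a fixed number of
    TTP0 patients — the TTP1 count minus the largest stratum size (3 for the
    244/52 cohort) — borrowed one-per-donor-stratum from distinct other
    strata (cycling over donors only if more than four are needed), plus all
    TTP1 patients.  A patient may be borrowed by several subsets but never
    twice into the same subset.  Deterministic given ``seed``.
    """
    ids0 = [r.patient_id for r in records if r.label == TTP0]
    ids1 = [r.patient_id for r in records if r.label == TTP1]
    n0, n1 = len(ids0), len(ids1)
    if not (n0 > n1 > 0):
        raise ValueError(
            f"scheme assumes a TTP0 majority and both classes present, got {n0} TTP0 / {n1} TTP1")
    rng = np.random.Generator(np.random.Philox(seed))
    order = rng.permutation(n0)
    strata = [[ids0[i] for i in part] for part in np.array_split(order, 5)]
    if n1 < max(len(s) for s in strata):
        raise ValueError(
            "scheme undefined: a TTP0 stratum exceeds the TTP1 count, so subsets "
            f"cannot be balanced by augmentation ({n0} TTP0 / {n1} TTP1)")
    # Every subset receives the same number of borrowed patients, set by the
    # largest stratum (3 for the 244/52 cohort); subsets with a smaller base
    # stratum therefore end up slightly below the TTP1 count (subset E: 51).
    n_borrow = n1 - max(len(s) for s in strata)

    subsets: dict[str, list[str]] = {}
    for si, sid in enumerate(SUBSET_IDS):
        members = list(strata[si])
        need = n_borrow
        donors = [d for d in range(5) if d != si and len(strata[d]) > 0]
        donor_order = rng.permutation(len(donors))
        picks: list[str] = []
        di = 0
        while len(picks) < need:
            donor = strata[donors[donor_order[di % len(donors)]]]
            candidates = [p for p in donor if p not in picks]
            if candidates:
                picks.append(candidates[int(rng.integers(len(candidates)))])
            di += 1
            if di > 5 * need + 25:
                raise ValueError("cannot borrow enough distinct TTP0 patients")
        members.extend(picks)
        members.extend(ids1)
        subsets[sid] = members

    labels = {pid: TTP0 for pid in ids0}
    labels.update({pid: TTP1 for pid in ids1})
    partition = CohortPartition(subsets=subsets, labels=labels, strata=strata, seed=seed)
    if with_folds:
        for sid in SUBSET_IDS:
            partition.folds[sid] = make_folds(partition, sid, seed=seed)
    return partition


def make_folds(partition: CohortPartition, subset_id: str, k: int = 5,
               seed: int = 0) -> list[tuple[list[str], list[str]]]:
    """Label-stratified k-fold splits of one subset (~80% train / 20% validation).

    Every patient appears in the validation split of exactly one fold;
    stratification preserves the ~50% prevalence in both splits.
    """
    if subset_id not in partition.subsets:
        raise KeyError(f"unknown subset {subset_id!r}")
    ids = partition.subsets[subset_id]
    y = np.array([partition.labels[p] for p in ids])
    if len(ids) < k:
        raise ValueError(f"subset {subset_id} has {len(ids)} patients < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    folds = []
    for tr_idx, va_idx in skf.split(np.zeros(len(ids)), y):
        folds.append(([ids[i] for i in tr_idx], [ids[i] for i in va_idx]))
    return folds
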