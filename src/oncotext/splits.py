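"""Patient-level train/validation/test splitting and cross-validation folds.

Randomization is at the patient level: every document of a patient shares
the patient's partition and fold, so no patient's text can appear on both
sides of any train/evaluate boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    partition: dict[str, str]  # patient_id -> train|validation|test
    fold: dict[str, int]  # train patients only -> fold index 0..n_folds-1
    n_folds: int

    def patients_in(self, partition: str) -> list[str]:
        return sorted(p for p, part in self.partition.items() if part == partition)

    def fold_members(self, fold_index: int) -> list[str]:
        return sorted(p for p, f in self.fold.items() if f == fold_index)

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "patient_id": pid,
                "partition": part,
                "fold": self.fold.get(pid, ""),
            }
            for pid, part in sorted(self.partition.items())
        ]
        return pd.DataFrame(rows, columns=["patient_id", "partition", "fold"])


def assign_splits(
    patient_ids,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    n_folds: int = 10,
    seed: int = 0,
) -> SplitAssignment:
    """Assign patients to train/validation/test and train patients to folds.

    Counts for validation and test are floored; the remainder goes to train.
    Fold sizes differ by at most one.  Deterministic for a given seed.
    """
    patient_ids = sorted(set(map(str, patient_ids)))
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("split proportions must sum to 1")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = len(patient_ids)
    n_val = int(np.floor(n * proportions[1]))
    n_test = int(np.floor(n * proportions[2]))
    n_train = n - n_val - n_test
    if n_train < n_folds:
        raise ValueError(
            f"{n_train} training patients cannot populate {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [patient_ids[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val :]
    partition = {p: "train" for p in train}
    partition.update({p: "validation" for p in val})
    partition.update({p: "test" for p in test})
    # round-robin over the shuffled order keeps fold sizes within one
    fold = {p: i % n_folds for i, p in enumerate(train)}
    return SplitAssignment(partition=partition, fold=fold, n_folds=n_folds)
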