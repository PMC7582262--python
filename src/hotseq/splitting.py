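"""Per-amino-acid stratified splitting of labeled residues.

The labeled residues are first divided into one subset per (amino acid,
class) pair — up to 40 subsets for 20 amino acids x {HS, NS}. Each subset
with both classes represented for its amino acid is split 60:40 into train
and test; amino acids seen in only one class go entirely to train, because a
test set could never score them fairly against both outcomes. The pooled 40%
test residues are then randomly halved into a tuning half (used to fit the
per-amino-acid probability correction) and an independent half (touched only
for the final evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd

HS = "HS"
NS = "NS"

#: Hot-spot definition: alanine mutation raising binding free energy by more
#: than this many kcal/mol.
DDG_HS_THRESHOLD = 2.0


class SplitValidationError(ValueError):
    """Raised on unlabeled residues or inconsistent labels."""


@dataclass(frozen=True)
class LabeledResidue:
    """One experimentally characterised interface residue."""

    chain_id: str
    position: int
    amino_acid: str
    label: str
    ddg: float | None = None  # kcal/mol, informational

    def __post_init__(self) -> None:
        if self.label not in (HS, NS):
            raise SplitValidationError(
                f"residue {self.chain_id}:{self.position} has label {self.label!r}, expected HS or NS"
            )
        if self.ddg is not None and self.ddg >= DDG_HS_THRESHOLD and self.label != HS:
            raise SplitValidationError(
                f"residue {self.chain_id}:{self.position}: ddg {self.ddg} >= "
                f"{DDG_HS_THRESHOLD} kcal/mol requires label HS"
            )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train / tuning-test / independent-test partition."""

    train: tuple[LabeledResidue, ...]
    tuning_test: tuple[LabeledResidue, ...]
    independent_test: tuple[LabeledResidue, ...]
    seed: int

    @property
    def all_residues(self) -> tuple[LabeledResidue, ...]:
        return self.train + self.tuning_test + self.independent_test


def _test_count(n: int) -> int:
    """Residues sent to the 40% test pool from a subset of size n.

    Round-half-up of 0.4*n, floored at 1 when n >= 2; singleton subsets stay
    in train.
    """
    if n < 2:
        return 0
    return max(1, floor(0.4 * n + 0.5))


def stratified_split(residues: list[LabeledResidue], seed: int) -> DatasetSplit:
    """Split labeled residues 60:40 per (amino acid, class), then halve the test pool.

    Amino acids represented by a single class contribute all their residues to
    train and none to either test half. All randomness derives from ``seed``;
    the per-subset counts are seed-invariant, only membership varies.
    """
    if not residues:
        raise SplitValidationError("no residues to split")
    rng = np.random.default_rng(seed)

    by_aa: dict[str, dict[str, list[LabeledResidue]]] = {}
    for residue in residues:
        by_aa.setdefault(residue.amino_acid, {HS: [], NS: []})[residue.label].append(residue)

    train: list[LabeledResidue] = []
    test_pool: list[LabeledResidue] = []
    for aa in sorted(by_aa):
        classes = by_aa[aa]
        single_class = not (classes[HS] and classes[NS])
        for label in (HS, NS):
            subset = classes[label]
            if not subset:
                continue
            if single_class:
                train.extend(subset)
                continue
            n_test = _test_count(len(subset))
            order = rng.permutation(len(subset))
            test_pool.extend(subset[i] for i in order[:n_test])
            train.extend(subset[i] for i in order[n_test:])

    order = rng.permutation(len(test_pool))
    half = (len(test_pool) + 1) // 2  # tuning gets the extra residue
    tuning = tuple(test_pool[i] for i in order[:half])
    independent = tuple(test_pool[i] for i in order[half:])
    return DatasetSplit(train=tuple(train), tuning_test=tuning, independent_test=independent, seed=seed)


def split_report(split: DatasetSplit) -> pd.DataFrame:
    """Per-amino-acid HS/NS counts in each partition.

    One row per amino acid present in the input; columns train_HS, train_NS,
    tuning_HS, tuning_NS, independent_HS, independent_NS. Row sums equal the
    input counts, so the 60:40 bookkeeping is auditable.
    """
    partitions = {
        "train": split.train,
        "tuning": split.tuning_test,
        "independent": split.independent_test,
    }
    counts: dict[str, dict[str, int]] = {}
    for part_name, residues in partitions.items():
        for residue in residues:
            row = counts.setdefault(residue.amino_acid, {})
            key = f"{part_name}_{residue.label}"
            row[key] = row.get(key, 0) + 1
    columns = [f"{p}_{lbl}" for p in partitions for lbl in (HS, NS)]
    frame = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=columns).fillna(0).astype(int)
    frame.index.name = "amino_acid"
    return frame.sort_index()


def residues_from_frame(frame: pd.DataFrame) -> list[LabeledResidue]:
    """Build labeled residues from a table with columns chain_id, position, amino_acid, label[, ddg]."""
    has_ddg = "ddg" in frame.columns
    return [
        LabeledResidue(
            chain_id=str(row.chain_id),
            position=int(row.position),
            amino_acid=str(row.amino_acid),
            label=str(row.label),
            ddg=float(row.ddg) if has_ddg and pd.notna(row.ddg) else None,
        )
        for row in frame.itertuples(index=False)
    ]


def residues_to_frame(residues: tuple[LabeledResidue, ...] | list[LabeledResidue]) -> pd.DataFrame:
    """Inverse of :func:`residues_from_frame`."""
    return pd.DataFrame(
        {
            "chain_id": [r.chain_id for r in residues],
            "position": [r.position for r in residues],
            "amino_acid": [r.amino_acid for r in residues],
            "label": [r.label for r in residues],
            "ddg": [r.ddg for r in residues],
        }
    )
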