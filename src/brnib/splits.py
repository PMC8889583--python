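"""Seeded random training/test division of labelled compound sets.

Benchmark protocols divide the actives and decoys of a target into a
training set (used to guide model optimization) and a held-out test set, at
ratios such as 70:30 or 10:90.  Splitting is stratified by class: actives
and decoys are shuffled and divided independently with a seeded Mersenne
Twister, so class proportions are preserved and the split is reproducible
from (labels, fraction, seed) alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import BrnibError
from .mol_io import ActivitySet, write_id_list


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


@dataclass(frozen=True)
class Split:
    train: ActivitySet
    test: ActivitySet


def _train_count(n: int, fraction: float) -> int:
    # nearest integer, but at least 1 from a non-empty class
    return max(1, int(np.floor(n * fraction + 0.5))) if n else 0


def random_split(labels: ActivitySet, spec: SplitSpec) -> Split:
    """Stratified seeded split; deterministic for a given (labels, spec).

    Class members are sorted before shuffling so the split depends only on
    the IDs, not on set iteration order.  Skipped flags carry over.
    """
    if not labels.actives or not labels.decoys:
        raise BrnibError("random_split requires both classes to be non-empty")
    rng = np.random.Generator(np.random.MT19937(spec.seed))

    def divide(ids: frozenset[str]) -> tuple[set[str], set[str]]:
        arr = np.array(sorted(ids))
        rng.shuffle(arr)
        k = _train_count(len(arr), spec.train_fraction)
        return set(arr[:k]), set(arr[k:])

    if spec.stratified:
        train_a, test_a = divide(labels.actives)
        train_d, test_d = divide(labels.decoys)
    else:
        train_all, test_all = divide(labels.all_ids)
        train_a, test_a = train_all & labels.actives, test_all & labels.actives
        train_d, test_d = train_all & labels.decoys, test_all & labels.decoys

    def subset(actives: set[str], decoys: set[str]) -> ActivitySet:
        members = actives | decoys
        return ActivitySet(
            actives=frozenset(actives),
            decoys=frozenset(decoys),
            skipped=frozenset(labels.skipped & members),
        )

    return Split(train=subset(train_a, train_d), test=subset(test_a, test_d))


def write_split(split: Split, spec: SplitSpec, outdir: str | Path) -> None:
    """Four ID-list files plus a JSON manifest recording seed and fractions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_id_list(split.train.actives, outdir / "train_actives.txt")
    write_id_list(split.train.decoys, outdir / "train_decoys.txt")
    write_id_list(split.test.actives, outdir / "test_actives.txt")
    write_id_list(split.test.decoys, outdir / "test_decoys.txt")
    manifest = {
        "train_fraction": spec.train_fraction,
        "test_fraction": 1.0 - spec.train_fraction,
        "seed": spec.seed,
        "stratified": spec.stratified,
        "n_train_actives": len(split.train.actives),
        "n_train_decoys": len(split.train.decoys),
        "n_test_actives": len(split.test.actives),
        "n_test_decoys": len(split.test.decoys),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
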