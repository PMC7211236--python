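"""Projection-metric nearest-neighbour classification and experiment grids.

The evaluation protocol mirrors the standard Bonn EEG study design:
five task definitions over the groups A-E, stratified random splits at
training ratios {0.1, 0.2, 0.4, 0.6, 0.8}, a grid of reduced dimensions,
several repeats per cell, and mean accuracy tables with rows = ratio and
columns = dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .discriminant import ConfigurationError, FMGDAConfig, fit, transform_set
from .grassmann import (
    EmptyInputError,
    GrassmannPoint,
    LabeledGrassmannSet,
    pairwise_projection_distances,
)

#: Named task -> group letter -> class id.  Groups absent from a mapping
#: are dropped from the experiment.
TASKS: dict[str, dict[str, int]] = {
    "five_class": {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4},
    "binary_AB": {"A": 0, "B": 1},
    "healthy_vs_epileptic": {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1},
    "abcd_vs_e": {"A": 0, "B": 0, "C": 0, "D": 0, "E": 1},
    "cde": {"C": 0, "D": 1, "E": 2},
    "ab_vs_e": {"A": 0, "B": 0, "E": 1},
}

DEFAULT_RATIOS = (0.1, 0.2, 0.4, 0.6, 0.8)
DEFAULT_DIMS = (4, 6, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment grid: task, training ratios, target dims, repeats."""

    task: str = "five_class"
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    dims: tuple[int, ...] = DEFAULT_DIMS
    repeats: int = 10
    seed: int = 0
    baseline: bool = True  # also run no-reduction 1-NN per split

    def __post_init__(self) -> None:
        if not all(0.0 < r < 1.0 for r in self.ratios):
            raise ConfigurationError("ratios must lie in (0, 1)")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if self.task not in TASKS:
            raise ConfigurationError(
                f"unknown task {self.task!r}; choose from {sorted(TASKS)}"
            )


@dataclass(frozen=True)
class AccuracyTable:
    """Mean accuracy per (ratio, dim) plus the raw per-repeat records.

    ``mean`` is a DataFrame with rows indexed by training ratio and one
    column per reduced dimension; ``raw`` has one row per
    (ratio, dim, repeat) with the accuracy and split sizes; ``baseline``
    (optional) holds the per-ratio mean accuracy of no-reduction 1-NN.
    """

    mean: pd.DataFrame
    raw: pd.DataFrame
    baseline: pd.Series | None = None

    def to_csv(self, path, raw_path=None) -> None:
        self.mean.to_csv(path, index_label="ratio")
        if raw_path is not None:
            self.raw.to_csv(raw_path, index=False)


def select_task(
    features: LabeledGrassmannSet, task: str | dict[str, int]
) -> LabeledGrassmannSet:
    """Restrict a featurized set to a task's groups and relabel 0..K-1.

    ``task`` is a named task from :data:`TASKS` or an explicit mapping from
    group name to class id.  The feature set must carry ``label_names``.
    """
    mapping = TASKS[task] if isinstance(task, str) else dict(task)
    if features.label_names is None:
        raise ConfigurationError("feature set has no label_names to map groups by")
    missing = [g for g in mapping if g not in features.label_names]
    if missing:
        raise ConfigurationError(f"groups {missing} absent from features")
    ids = sorted(set(mapping.values()))
    if ids != list(range(len(ids))):
        raise ConfigurationError(f"task class ids must be 0..K-1, got {ids}")
    keep = np.zeros(features.n_points, dtype=bool)
    new_labels = np.zeros(features.n_points, dtype=int)
    for group, cls in mapping.items():
        sel = features.labels == features.label_names.index(group)
        keep |= sel
        new_labels[sel] = cls
    names = tuple(
        "+".join(g for g in sorted(mapping) if mapping[g] == cls) for cls in ids
    )
    return LabeledGrassmannSet(features.bases[keep], new_labels[keep], names)


def _knn_vote(
    dists: np.ndarray, train_labels: np.ndarray, k: int, n_classes: int
) -> int:
    """Label of one query given its distances to all training points.

    Majority among the k nearest; ties broken by smallest summed distance
    within those k, then by lowest label id.
    """
    order = np.argsort(dists, kind="stable")[:k]
    votes = np.zeros(n_classes, dtype=int)
    sums = np.zeros(n_classes)
    for idx in order:
        lab = train_labels[idx]
        votes[lab] += 1
        sums[lab] += dists[idx]
    best = np.flatnonzero(votes == votes.max())
    if best.size > 1:
        best = best[sums[best] == sums[best].min()]
    return int(best[0])


def knn_predict(
    train: LabeledGrassmannSet, query: GrassmannPoint, k: int = 1
) -> int:
    """Projection-metric k-NN label of one query point."""
    if k > train.n_points:
        raise ConfigurationError(f"k={k} exceeds training size {train.n_points}")
    dists = pairwise_projection_distances(
        query.basis[None, :, :], train.bases
    )[0]
    return _knn_vote(dists, train.labels, k, train.n_classes)


def knn_predict_set(
    train: LabeledGrassmannSet, queries: LabeledGrassmannSet, k: int = 1
) -> np.ndarray:
    """Vectorized k-NN labels for every point of a query set."""
    if k > train.n_points:
        raise ConfigurationError(f"k={k} exceeds training size {train.n_points}")
    D = pairwise_projection_distances(queries.bases, train.bases)
    return np.array(
        [_knn_vote(row, train.labels, k, train.n_classes) for row in D]
    )


def knn_accuracy(
    train: LabeledGrassmannSet, test: LabeledGrassmannSet, k: int = 1
) -> float:
    pred = knn_predict_set(train, test, k)
    return float(np.mean(pred == test.labels))


def stratified_split(
    data: LabeledGrassmannSet, ratio: float, seed: int | np.random.Generator
) -> tuple[LabeledGrassmannSet, LabeledGrassmannSet]:
    """Per-class random split: round-half-up of ratio*n_k items train.

    Sampling is without replacement and deterministic for a given seed.
    Every class must keep at least one training and one test item.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for k in range(data.n_classes):
        idx = np.flatnonzero(data.labels == k)
        n_train = int(np.floor(ratio * idx.size + 0.5))
        if n_train < 1 or n_train >= idx.size:
            raise EmptyInputError(
                f"class {k} ({idx.size} items) cannot be split at ratio {ratio}"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        data.subset(np.sort(np.concatenate(train_idx))),
        data.subset(np.sort(np.concatenate(test_idx))),
    )


def run_grid(
    features: LabeledGrassmannSet,
    spec: ExperimentSpec,
    fmgda_config: FMGDAConfig | None = None,
) -> AccuracyTable:
    """Run the full (ratio x dim x repeat) FMGDA + 1-NN experiment grid.

    Per cell: stratified split, FMGDA fit at d = dim on the training
    points, transform of both splits, projection-metric 1-NN accuracy on
    the test points.  Splits are shared across dims within one
    (ratio, repeat) so dimensions are compared on identical data.  With
    ``spec.baseline`` a no-reduction 1-NN accuracy is recorded per split.
    """
    data = select_task(features, spec.task)
    p = data.subspace_dim
    bad = [d for d in spec.dims if d < p]
    if bad:
        raise ConfigurationError(
            f"subspace dimension p={p} exceeds target dim(s) {bad}; "
            f"refeaturize with smaller p or drop those dims"
        )
    base = fmgda_config or FMGDAConfig(target_dim=max(spec.dims))
    records = []
    baseline_records = []
    ss = np.random.SeedSequence(spec.seed)
    for ratio in spec.ratios:
        for rep in range(spec.repeats):
            child = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(int(round(ratio * 1000)), rep)
            )
            rng = np.random.default_rng(child)
            train, test = stratified_split(data, ratio, rng)
            if spec.baseline:
                baseline_records.append(
                    {
                        "ratio": ratio,
                        "repeat": rep,
                        "accuracy": knn_accuracy(train, test, k=1),
                    }
                )
            for dim in spec.dims:
                model = fit(train, replace(base, target_dim=dim))
                acc = knn_accuracy(
                    transform_set(model, train), transform_set(model, test), k=1
                )
                records.append(
                    {
                        "ratio": ratio,
                        "dim": dim,
                        "repeat": rep,
                        "accuracy": acc,
                        "n_train": train.n_points,
                        "n_test": test.n_points,
                    }
                )
    raw = pd.DataFrame.from_records(records)
    mean = raw.pivot_table(index="ratio", columns="dim", values="accuracy")
    mean = mean.reindex(index=list(spec.ratios), columns=list(spec.dims))
    baseline = None
    if spec.baseline:
        bdf = pd.DataFrame.from_records(baseline_records)
        baseline = bdf.groupby("ratio")["accuracy"].mean()
    return AccuracyTable(mean=mean, raw=raw, baseline=baseline)
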