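"""Greedy benchmark-driven optimization of cavity negative-image models.

Starting from a full cavity model, each generation evaluates every
single-atom-removal variant of the current model by rescoring the docked
training library and computing a target enrichment metric (BEDROC with
α = 20 by default).  The best variant is accepted if and only if it strictly
improves on the current model; the loop terminates when no removal improves
the metric, when a generation cap is hit, or when the model reaches the
minimum allowed size.  The search is deterministic: exact floating-point
comparison, ties among equally good variants broken by the lowest
removed-atom index, and results independent of the worker count.

A *cut-and-go* variant accelerates the first step: every atom whose
individual deletion improves the metric is removed in one pass, after which
the standard greedy loop resumes on the pruned model.

The module also provides the evaluation-count formulas contrasting the greedy
search with a true exhaustive subset search, and merging of models that
describe different sub-pockets of one cavity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

from .errors import BrnibError, UndefinedMetricError
from .enrichment import bedroc, efd, auc, make_ranking
from .mol_io import ActivitySet, NIBModel, PoseLibrary, write_nib_model
from .similarity import PreparedLibrary, SimilarityWeights, score_library


# ---------------------------------------------------------------------------
# Target metrics


@dataclass(frozen=True)
class TargetMetric:
    """Objective guiding the greedy search: AUC, EFd@fraction or BEDROC@α."""

    kind: str  # "auc" | "efd" | "bedroc"
    param: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("auc", "efd", "bedroc"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind != "auc" and self.param is None:
            raise ValueError(f"{self.kind} requires a parameter")

    @classmethod
    def parse(cls, text: str) -> "TargetMetric":
        """Parse ``auc``, ``efd:0.01`` or ``bedroc:20``."""
        kind, _, param = text.partition(":")
        kind = kind.lower()
        if kind == "auc":
            return cls("auc")
        return cls(kind, float(param))

    def __str__(self) -> str:
        return self.kind if self.kind == "auc" else f"{self.kind}:{self.param:g}"

    def evaluate(self, ranking) -> float:
        if self.kind == "auc":
            return auc(ranking)[0]
        if self.kind == "efd":
            return efd(ranking, self.param)
        return bedroc(ranking, self.param)


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the greedy search; defaults follow common benchmarking practice."""

    target_metric: TargetMetric = TargetMetric("bedroc", 20.0)
    weights: SimilarityWeights = SimilarityWeights()
    min_model_size: int = 3
    max_generations: int | None = None
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.min_model_size < 1:
            raise ValueError("min_model_size must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


@dataclass(frozen=True)
class GenerationRecord:
    """One round of the greedy search."""

    generation: int
    parent_size: int
    variants: tuple[tuple[int, float], ...]  # (removed-atom index, metric)
    accepted_removal: int | None
    best_metric: float  # best metric so far (parent's if nothing accepted)

    def to_json(self) -> str:
        return json.dumps(
            {
                "generation": self.generation,
                "parent_size": self.parent_size,
                "variants": [[i, m] for i, m in self.variants],
                "accepted_removal": self.accepted_removal,
                "best_metric": self.best_metric,
            }
        )


@dataclass(eq=False)
class OptimizationResult:
    final_model: NIBModel
    generations: list[GenerationRecord]
    models: list[NIBModel]  # model after each generation, index 0 = input
    total_evaluations: int
    initial_metric: float
    prepass: tuple[tuple[int, float], ...] = ()  # cut-and-go single-pass metrics
    post_prune_metric: float | None = None  # metric right after the bulk prune

    @property
    def final_metric(self) -> float:
        accepted = [g.best_metric for g in self.generations if g.accepted_removal is not None]
        if accepted:
            return accepted[-1]
        if self.post_prune_metric is not None:
            return self.post_prune_metric
        return self.initial_metric


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_model(
    model: NIBModel,
    library: PoseLibrary | PreparedLibrary,
    labels: ActivitySet,
    config: OptimizationConfig = OptimizationConfig(),
) -> float:
    """Score the library against ``model`` and return the target metric."""
    table = score_library(model, library, labels, config.weights)
    ranking = make_ranking(table, seed=config.seed)
    return config.target_metric.evaluate(ranking)


def _check_classes(labels: ActivitySet) -> None:
    if not labels.actives or not labels.decoys:
        raise UndefinedMetricError("training set must contain both actives and decoys")


def _variant_metrics(
    model: NIBModel,
    prepared: PreparedLibrary,
    labels: ActivitySet,
    config: OptimizationConfig,
) -> list[float]:
    """Metric of every single-atom-removal variant, in removed-index order.

    Variants are independent; with ``workers > 1`` they are evaluated in
    parallel but always collected in index order, so the result — and hence
    the whole search — never depends on scheduling.
    """
    evaluate = lambda i: evaluate_model(model.without_atom(i), prepared, labels, config)
    if config.workers == 1 or len(model) == 1:
        return [evaluate(i) for i in range(len(model))]
    parallel = Parallel(n_jobs=config.workers, prefer="threads")
    return list(parallel(delayed(evaluate)(i) for i in range(len(model))))


ProgressCallback = Callable[[GenerationRecord, NIBModel], None]


def brnib_optimize(
    model: NIBModel,
    library: PoseLibrary | PreparedLibrary,
    labels: ActivitySet,
    config: OptimizationConfig = OptimizationConfig(),
    outdir: str | Path | None = None,
    on_generation: ProgressCallback | None = None,
) -> OptimizationResult:
    """Iterative single-atom pruning guided by the target enrichment metric.

    Per generation all single-atom-removal variants of the current model are
    scored; the best one is accepted iff its metric strictly exceeds the
    current model's (ties broken by lowest removed-atom index).  Terminates
    when no removal improves, ``max_generations`` is reached, or the model
    would shrink below ``min_model_size``.  If ``outdir`` is given, every
    generation's model is written as ``gen_NNNN.mol2`` alongside a
    ``log.jsonl`` generation log and a ``summary.json``.
    """
    _check_classes(labels)
    prepared = (
        library if isinstance(library, PreparedLibrary) else PreparedLibrary.from_library(library)
    )
    sink = _OutputSink(outdir, reset_log=True)
    current = model
    current_metric = evaluate_model(current, prepared, labels, config)
    initial_metric = current_metric
    generations: list[GenerationRecord] = []
    models = [current]
    total_evals = 0
    sink.write_model(0, current)

    generation = 0
    while len(current) > config.min_model_size and (
        config.max_generations is None or generation < config.max_generations
    ):
        metrics = _variant_metrics(current, prepared, labels, config)
        total_evals += len(metrics)
        best_idx = int(np.argmax(metrics))  # argmax returns the first maximum
        best_metric = metrics[best_idx]
        if best_metric > current_metric:
            current = current.without_atom(best_idx)
            current_metric = best_metric
            record = GenerationRecord(
                generation=generation,
                parent_size=len(metrics),
                variants=tuple((i, m) for i, m in enumerate(metrics)),
                accepted_removal=best_idx,
                best_metric=best_metric,
            )
            generations.append(record)
            models.append(current)
            sink.write_model(len(models) - 1, current)
            sink.write_record(record)
            if on_generation:
                on_generation(record, current)
            generation += 1
        else:
            record = GenerationRecord(
                generation=generation,
                parent_size=len(metrics),
                variants=tuple((i, m) for i, m in enumerate(metrics)),
                accepted_removal=None,
                best_metric=current_metric,
            )
            generations.append(record)
            sink.write_record(record)
            if on_generation:
                on_generation(record, current)
            break

    result = OptimizationResult(
        final_model=current,
        generations=generations,
        models=models,
        total_evaluations=total_evals,
        initial_metric=initial_metric,
    )
    sink.write_summary(result, config)
    return result


def cut_and_go(
    model: NIBModel,
    library: PoseLibrary | PreparedLibrary,
    labels: ActivitySet,
    config: OptimizationConfig = OptimizationConfig(),
    outdir: str | Path | None = None,
    on_generation: ProgressCallback | None = None,
) -> OptimizationResult:
    """Accelerated variant: bulk-prune, then run the standard greedy loop.

    One pass evaluates every single-atom deletion of the input model; all
    atoms whose individual deletion strictly improves the metric are removed
    simultaneously (if that would undershoot ``min_model_size``, the atoms
    with the smallest individual improvements are kept).  The standard greedy
    search then resumes from the pruned model.
    """
    _check_classes(labels)
    prepared = (
        library if isinstance(library, PreparedLibrary) else PreparedLibrary.from_library(library)
    )
    base_metric = evaluate_model(model, prepared, labels, config)
    metrics = _variant_metrics(model, prepared, labels, config)
    improving = [i for i, m in enumerate(metrics) if m > base_metric]
    max_removable = len(model) - config.min_model_size
    if len(improving) > max_removable:
        # keep the atoms with the smallest individual improvements
        improving.sort(key=lambda i: (-(metrics[i] - base_metric), i))
        improving = sorted(improving[:max_removable])
    if improving:
        pruned_atoms = [a for i, a in enumerate(model.atoms) if i not in set(improving)]
        pruned = NIBModel(name=model.name, atoms=pruned_atoms)
    else:
        pruned = model
    result = brnib_optimize(pruned, prepared, labels, config, outdir, on_generation)
    result.prepass = tuple((i, m) for i, m in enumerate(metrics))
    result.total_evaluations += len(model)
    result.post_prune_metric = result.initial_metric
    result.initial_metric = base_metric
    result.models.insert(0, model)
    _OutputSink(outdir).write_summary(result, config)  # refresh with prepass counts
    return result


# ---------------------------------------------------------------------------
# Model merging


def merge_models(
    models: list[NIBModel],
    collapse_duplicates: bool = True,
    merge_tolerance: float = 0.25,
) -> NIBModel:
    """Concatenate models of one cavity (shared frame) into a hybrid model.

    With ``collapse_duplicates``, atoms of equal element within
    ``merge_tolerance`` Å of an earlier atom collapse to the first occurrence.
    """
    if not models:
        raise BrnibError("merge_models requires at least one model")
    atoms = []
    for m in models:
        for a in m.atoms:
            if collapse_duplicates and any(
                a.element == b.element
                and float(np.linalg.norm(a.position - b.position)) <= merge_tolerance
                for b in atoms
            ):
                continue
            atoms.append(a)
    name = "+".join(m.name for m in models)
    return NIBModel(name=name, atoms=atoms)


# ---------------------------------------------------------------------------
# Evaluation-count formulas


def exhaustive_count(n: int, a1: int) -> int:
    """Number of candidate models an exhaustive subset search would score.

    All subsets of the ``n`` input atoms of size ``a1`` or larger:
    Σ_{k=a1}^{n} C(n, k), exact integer.
    """
    _check_counts(n, a1)
    return sum(math.comb(n, k) for k in range(a1, n + 1))


def greedy_count(n: int, a1: int) -> int:
    """Variant evaluations of a greedy run shrinking ``n`` atoms to ``a1``.

    Each accepted generation at size m scores m variants (m = n … a1+1), and
    the terminating generation scores the final model's a1 variants:
    Σ_{k=a1}^{n} k.
    """
    _check_counts(n, a1)
    return sum(range(a1, n + 1))


def _check_counts(n: int, a1: int) -> None:
    if not 1 <= a1 <= n:
        raise ValueError(f"need 1 <= a1 <= n, got n={n}, a1={a1}")


# ---------------------------------------------------------------------------
# Persistence


class _OutputSink:
    """Writes per-generation models, a JSONL log and the final summary."""

    def __init__(self, outdir: str | Path | None, reset_log: bool = False):
        self.outdir = Path(outdir) if outdir else None
        if self.outdir:
            self.outdir.mkdir(parents=True, exist_ok=True)
            self.log_path = self.outdir / "log.jsonl"
            if reset_log:
                self.log_path.write_text("")

    def write_model(self, index: int, model: NIBModel) -> None:
        if self.outdir:
            write_nib_model(model, self.outdir / f"gen_{index:04d}.mol2")

    def write_record(self, record: GenerationRecord) -> None:
        if self.outdir:
            with self.log_path.open("a") as fh:
                fh.write(record.to_json() + "\n")

    def write_summary(self, result: OptimizationResult, config: OptimizationConfig) -> None:
        if self.outdir:
            summary = {
                "target_metric": str(config.target_metric),
                "w_shape": config.weights.w_shape,
                "seed": config.seed,
                "initial_size": len(result.models[0]),
                "final_size": len(result.final_model),
                "initial_metric": result.initial_metric,
                "final_metric": result.final_metric,
                "generations": len(result.generations),
                "total_evaluations": result.total_evaluations,
            }
            (self.outdir / "summary.json").write_text(json.dumps(summary, indent=2))
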