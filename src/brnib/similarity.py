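"""Rigid shape and electrostatic-potential similarity of poses to cavity models.

Docked poses are compared against the cavity negative image exactly where the
docking engine left them — no realignment or optimization of any kind.  Two
channels are scored:

* **Shape** — each atom is a spherical Gaussian of amplitude ``p = 2.7`` whose
  integral equals the atom's hard-sphere volume (4/3)πR³, the classical
  volume-overlap formulation used by Gaussian shape-comparison programs.  The
  shape score is the Hodgkin index 2·O_AB/(O_AA + O_BB) of the two densities,
  1 for identical atom sets and → 0 as the structures separate.

* **ESP** — the softened Coulomb potentials V(x) = Σ q/√(|x−r|² + ε²) of the
  two partial-charge sets (ε = 0.5 Å) are sampled at the union of both
  structures' atom centers and compared with the Hodgkin index h ∈ [−1, 1],
  mapped to [0, 1] as (1 + h)/2 so the two channels blend on a common scale.
  The Plummer softening keeps every term finite and smooth, so all sources —
  including each structure's own atom at an observer point — contribute
  identically for both structures; a pose carrying the model's charges at
  the model's positions scores exactly 1, a charge-negated copy exactly 0.

The combined score is the linear blend ``w_shape·shape + (1−w_shape)·esp``
(default 50/50); a compound with several poses is represented by its
best-scoring pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptyModelError, MissingCompoundsError
from .mol_io import ActivitySet, CavityAtom, NIBModel, Pose, PoseLibrary

#: Gaussian amplitude of the atomic density (ROCS-style convention).
GAUSSIAN_AMPLITUDE = 2.7

#: Plummer softening length (Å) of the Coulomb potential; keeps the
#: potential finite and smooth at and near source positions.
ESP_SOFTENING = 0.5


@dataclass(frozen=True)
class SimilarityWeights:
    """Shape/ESP blend; ``w_esp = 1 - w_shape``."""

    w_shape: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_shape <= 1.0:
            raise ValueError(f"w_shape must be in [0, 1], got {self.w_shape}")

    @property
    def w_esp(self) -> float:
        return 1.0 - self.w_shape


#: Shape-only scoring (the paper's alternative to the default 50/50 blend).
SHAPE_ONLY = SimilarityWeights(1.0)


@dataclass(frozen=True)
class SimilarityScore:
    shape: float
    esp: float
    combined: float


# ---------------------------------------------------------------------------
# Array-level kernels.  Poses and models are reduced to plain arrays once and
# reused across the optimizer's many variant evaluations.


def _gaussian_alpha(radii: np.ndarray) -> np.ndarray:
    """Width α such that ∫ p·exp(−α r²) d³r = (4/3)πR³."""
    p = GAUSSIAN_AMPLITUDE
    return np.pi * (3.0 * p / (4.0 * np.pi * radii**3)) ** (2.0 / 3.0)


@dataclass(eq=False)
class _Struct:
    """Prepared structure: coordinates, Gaussian widths, charges, self-overlap."""

    pos: np.ndarray  # (n, 3)
    alpha: np.ndarray  # (n,)
    charge: np.ndarray  # (n,)
    self_overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.self_overlap == 0.0:
            self.self_overlap = _overlap_arrays(self.pos, self.alpha, self.pos, self.alpha)


def _prepare(atoms: Sequence[CavityAtom]) -> _Struct:
    if len(atoms) == 0:
        raise EmptyModelError("cannot score an empty atom list")
    pos = np.array([a.position for a in atoms])
    radii = np.array([a.radius for a in atoms])
    charge = np.array([a.charge for a in atoms])
    return _Struct(pos=pos, alpha=_gaussian_alpha(radii), charge=charge)


def _overlap_arrays(
    pos_a: np.ndarray, alpha_a: np.ndarray, pos_b: np.ndarray, alpha_b: np.ndarray
) -> float:
    p = GAUSSIAN_AMPLITUDE
    d2 = cdist(pos_a, pos_b, metric="sqeuclidean")
    asum = alpha_a[:, None] + alpha_b[None, :]
    aprod = alpha_a[:, None] * alpha_b[None, :]
    terms = p * p * (np.pi / asum) ** 1.5 * np.exp(-aprod * d2 / asum)
    return float(terms.sum())


def _potentials(observers: np.ndarray, struct: _Struct) -> np.ndarray:
    """Softened Coulomb potential of ``struct`` at the observer points."""
    d2 = cdist(observers, struct.pos, metric="sqeuclidean")
    contrib = struct.charge[None, :] / np.sqrt(d2 + ESP_SOFTENING**2)
    return contrib.sum(axis=1)


def _shape_hodgkin(a: _Struct, b: _Struct) -> float:
    o_ab = _overlap_arrays(a.pos, a.alpha, b.pos, b.alpha)
    return 2.0 * o_ab / (a.self_overlap + b.self_overlap)


def _esp_hodgkin01(a: _Struct, b: _Struct) -> float:
    observers = np.vstack([a.pos, b.pos])
    va = _potentials(observers, a)
    vb = _potentials(observers, b)
    denom = float(va @ va + vb @ vb)
    if denom == 0.0 or float(va @ va) == 0.0 or float(vb @ vb) == 0.0:
        return 0.5  # one or both fields identically zero: neutral (h := 0)
    h = 2.0 * float(va @ vb) / denom
    return 0.5 * (1.0 + h)


def _score_structs(a: _Struct, b: _Struct, weights: SimilarityWeights) -> SimilarityScore:
    shape = _shape_hodgkin(a, b)
    if weights.w_esp == 0.0:
        esp = _esp_hodgkin01(a, b)  # still reported, just unweighted
        combined = shape
    else:
        esp = _esp_hodgkin01(a, b)
        combined = weights.w_shape * shape + weights.w_esp * esp
    return SimilarityScore(shape=shape, esp=esp, combined=combined)


# ---------------------------------------------------------------------------
# Public atom/pose-level API


def gaussian_overlap(atoms_a: Sequence[CavityAtom], atoms_b: Sequence[CavityAtom]) -> float:
    """First-order pairwise Gaussian volume overlap (Å³) of two atom sets.

    Symmetric, non-negative, invariant under a common rigid motion.
    """
    a, b = _prepare(atoms_a), _prepare(atoms_b)
    return _overlap_arrays(a.pos, a.alpha, b.pos, b.alpha)


def shape_similarity(pose: Pose, model: NIBModel) -> float:
    """Hodgkin shape index 2·O_AB/(O_AA + O_BB) ∈ (0, 1]; 1 for identical sets."""
    return _shape_hodgkin(_prepare(pose.atoms), _prepare(model.atoms))


def esp_similarity(pose: Pose, model: NIBModel) -> float:
    """Electrostatic Hodgkin similarity mapped to [0, 1]; 0.5 is neutral."""
    return _esp_hodgkin01(_prepare(pose.atoms), _prepare(model.atoms))


def combined_score(
    pose: Pose, model: NIBModel, weights: SimilarityWeights = SimilarityWeights()
) -> SimilarityScore:
    """Shape, ESP and their weighted blend for one pose against one model."""
    return _score_structs(_prepare(pose.atoms), _prepare(model.atoms), weights)


# ---------------------------------------------------------------------------
# Library scoring


@dataclass(eq=False)
class PreparedLibrary:
    """Pose library reduced to arrays for repeated scoring against model variants."""

    compound_ids: list[str]  # library order
    poses: dict[str, list[_Struct]]

    @classmethod
    def from_library(cls, library: PoseLibrary) -> "PreparedLibrary":
        return cls(
            compound_ids=list(library.source_order),
            poses={
                cid: [_prepare(p.atoms) for p in library.poses[cid]]
                for cid in library.source_order
            },
        )


#: ScoreTable columns, in serialization order.
SCORE_COLUMNS = ["compound_id", "label", "skipped", "shape", "esp", "combined", "best_pose_index"]


def score_library(
    model: NIBModel,
    library: PoseLibrary | PreparedLibrary,
    labels: ActivitySet,
    weights: SimilarityWeights = SimilarityWeights(),
) -> pd.DataFrame:
    """Best-pose similarity score for every labelled compound.

    Returns the ScoreTable: one row per labelled compound with columns
    ``compound_id, label, skipped, shape, esp, combined, best_pose_index``.
    Skipped compounds are flagged and carry no score.  Poses are never moved.

    Raises :class:`MissingCompoundsError` if a labelled, non-skipped compound
    has no pose in the library.
    """
    prepared = (
        library
        if isinstance(library, PreparedLibrary)
        else PreparedLibrary.from_library(library)
    )
    needed = labels.all_ids - labels.skipped
    missing = needed - set(prepared.compound_ids)
    if missing:
        raise MissingCompoundsError(missing)

    model_struct = _prepare(model.atoms)
    rows = []
    for cid in prepared.compound_ids:
        if cid not in needed:
            continue
        label = "active" if cid in labels.actives else "decoy"
        best: SimilarityScore | None = None
        best_idx = -1
        for idx, pose_struct in enumerate(prepared.poses[cid]):
            s = _score_structs(pose_struct, model_struct, weights)
            if best is None or s.combined > best.combined:
                best, best_idx = s, idx
        rows.append((cid, label, False, best.shape, best.esp, best.combined, best_idx))
    for cid in sorted(labels.skipped):
        label = "active" if cid in labels.actives else "decoy"
        rows.append((cid, label, True, np.nan, np.nan, np.nan, -1))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
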