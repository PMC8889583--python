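"""Synthetic benchmark fixtures with planted, recoverable structure.

The generator emulates the three inputs of a rescoring benchmark — a cavity
negative-image model, a multi-pose docked library, and active/decoy ID lists
— with a known ground truth, so every pipeline stage is testable without any
external download.

Construction
------------
* The cavity model is the union of a compact **signal** cluster (the "true"
  sub-pocket the actives occupy) and a compact peripheral **noise** patch — a
  secondary sub-pocket centred ``decoy_displacement`` Å away, at least 2 Å
  outside the active-pose envelope (the over-generated cavity volume a real
  cavity-filling tool produces).
* Each **active** occupies the complete signal cluster, jittered by
  ``jitter_sd`` independently per pose — a well-docked ligand filling the
  true sub-pocket.  Actives differ only in their jitter draws, so every
  signal atom is equally load-bearing for every active.
* **Decoys** come in two flavors, alternating.  *Shape-mismatched* decoys
  occupy a random mix of noise and signal atoms (pose size fixed at the
  cluster size, noise count drawn per decoy from one atom up to three
  quarters of the pose) with matching charges — poses that exploit the
  over-generated cavity volume to a varying degree.  Noise atoms are used
  round-robin as anchors so that every noise atom supports many decoys
  across the whole composition range, including single-noise-atom decoys
  that stay competitive with actives until that atom is pruned.  *Charge-mismatched*
  decoys sit on the signal cluster but with negated partial charges (good
  shape, wrong electrostatics).

Under the full model the shape-mismatched decoys score at least as well as
actives (every atom they carry is matched), so enrichment is poor; each
noise-atom removal demotes the decoys leaning on it, and because the noise
fraction varies continuously some decoys stay competitive until the last
noise atom is gone.  Pruning the full noise patch collapses their scores
while improving the actives' — the planted optimum the greedy search must
find.
Ground truth (which cavity atoms are signal vs noise) is recorded in a truth
JSON.  All randomness flows from the single seed; identical specs produce
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .mol_io import (
    ActivitySet,
    CavityAtom,
    NIBModel,
    Pose,
    PoseLibrary,
    write_id_list,
    write_nib_model,
    write_pose_library,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of the synthetic benchmark."""

    n_signal_atoms: int = 8
    n_noise_atoms: int = 8
    n_actives: int = 30
    n_decoys: int = 300
    poses_per_compound: int = 3
    jitter_sd: float = 0.3  # Å, per-coordinate jitter of active poses
    decoy_displacement: float = 6.0  # Å, noise-shell / decoy distance from cluster
    charged_fraction: float = 0.5  # fraction of charged cavity atoms
    charge_magnitude: float = 0.3  # e
    skip_fraction: float = 0.0  # fraction of compounds skipped by "docking"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_signal_atoms", "n_noise_atoms", "n_actives", "n_decoys",
                     "poses_per_compound"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("jitter_sd", "decoy_displacement", "charge_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("charged_fraction", "skip_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(eq=False)
class Fixture:
    """In-memory fixture: model, docked library, labels and ground truth."""

    spec: FixtureSpec
    model: NIBModel
    library: PoseLibrary
    labels: ActivitySet
    truth: dict

    def signal_only_model(self) -> NIBModel:
        """The planted optimum: cavity model restricted to the signal atoms."""
        atoms = [self.model.atoms[i] for i in self.truth["signal_indices"]]
        return NIBModel(name=self.model.name + "_signal", atoms=atoms)


_CLUSTER_RADIUS = 2.0  # Å, radius of the signal cluster
_MIN_SEPARATION = 1.2  # Å, between cavity pseudo-atoms


def _charged_cluster(
    positions: list[np.ndarray], rng: np.random.Generator, spec: FixtureSpec
) -> list[CavityAtom]:
    """Cavity pseudo-atoms with a charge-balanced scheme.

    ``charged_fraction`` of the atoms carry ±``charge_magnitude``, split as
    evenly as possible between positive (N) and negative (O) points and
    placed at random; the rest are neutral (C).  Balancing the charges within
    each cluster keeps the cluster's far field free of a monopole term, as in
    real cavity images whose donor/acceptor points roughly compensate.
    """
    n = len(positions)
    n_charged = int(round(spec.charged_fraction * n))
    charges = [0.0] * n
    order = rng.permutation(n)
    for k in range(n_charged):
        sign = 1.0 if k % 2 == 0 else -1.0
        charges[order[k]] = sign * spec.charge_magnitude
    elements = ["N" if q > 0 else "O" if q < 0 else "C" for q in charges]
    return [CavityAtom(e, p, q) for e, p, q in zip(elements, positions, charges)]


def _cluster_positions(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Points in a sphere of radius _CLUSTER_RADIUS with minimum separation."""
    points: list[np.ndarray] = []
    while len(points) < n:
        p = rng.uniform(-_CLUSTER_RADIUS, _CLUSTER_RADIUS, size=3)
        if np.linalg.norm(p) > _CLUSTER_RADIUS:
            continue
        if any(np.linalg.norm(p - q) < _MIN_SEPARATION for q in points):
            continue
        points.append(p)
    return points


def _patch_positions(n: int, radius: float, rng: np.random.Generator) -> list[np.ndarray]:
    """Compact patch (secondary sub-pocket) centred ``radius`` Å from the origin."""
    v = rng.normal(size=3)
    center = v / np.linalg.norm(v) * radius
    return [center + p for p in _cluster_positions(n, rng)]


def _subset_pose(
    cid: str,
    pose_index: int,
    source_atoms: list[CavityAtom],
    indices: np.ndarray,
    jitter_sd: float,
    rng: np.random.Generator,
    charges: np.ndarray | None = None,
) -> Pose:
    atoms = []
    for j, i in enumerate(indices):
        src = source_atoms[i]
        jitter = rng.normal(0.0, jitter_sd, size=3) if jitter_sd > 0 else np.zeros(3)
        charge = src.charge if charges is None else float(charges[j])
        element = src.element if charges is None else ("N" if charge > 0 else "O" if charge < 0 else "C")
        atoms.append(CavityAtom(element, src.position + jitter, charge))
    return Pose(cid, pose_index, atoms)


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the fixture in memory; all randomness from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # --- cavity model: signal cluster + peripheral noise shell
    envelope = _CLUSTER_RADIUS + 3.0 * spec.jitter_sd
    noise_radius = max(spec.decoy_displacement, envelope + 2.0)
    signal_atoms = _charged_cluster(_cluster_positions(spec.n_signal_atoms, rng), rng, spec)
    noise_atoms = _charged_cluster(_patch_positions(spec.n_noise_atoms, noise_radius, rng), rng, spec)
    model = NIBModel(name="synthetic_cavity", atoms=signal_atoms + noise_atoms)
    signal_indices = list(range(spec.n_signal_atoms))
    noise_indices = list(range(spec.n_signal_atoms, spec.n_signal_atoms + spec.n_noise_atoms))

    poses: dict[str, list[Pose]] = {}
    order: list[str] = []
    flavors: dict[str, str] = {}

    # --- actives: jittered near-complete signal subsets
    for i in range(spec.n_actives):
        cid = f"ACT{i:04d}"
        idx = np.arange(spec.n_signal_atoms)
        poses[cid] = [
            _subset_pose(cid, k, signal_atoms, idx, spec.jitter_sd, rng)
            for k in range(spec.poses_per_compound)
        ]
        order.append(cid)
        flavors[cid] = "active"

    # --- decoys: alternate shape-mismatched / charge-mismatched flavors
    for i in range(spec.n_decoys):
        cid = f"DEC{i:04d}"
        if i % 2 == 0 and spec.n_noise_atoms > 0:
            n_atoms = spec.n_signal_atoms  # same pose size as actives
            k_max = min(spec.n_noise_atoms, max(1, int(round(0.75 * n_atoms))))
            k_noise = int(rng.integers(1, k_max + 1))
            anchor = (i // 2) % spec.n_noise_atoms
            others = [j for j in range(spec.n_noise_atoms) if j != anchor]
            picked = [anchor] + (
                list(rng.choice(others, size=k_noise - 1, replace=False)) if k_noise > 1 else []
            )
            source = [noise_atoms[j] for j in picked]
            k_sig = min(n_atoms - k_noise, spec.n_signal_atoms)
            if k_sig > 0:
                source += [signal_atoms[j] for j in rng.choice(spec.n_signal_atoms, size=k_sig, replace=False)]
            idx = np.arange(len(source))
            poses[cid] = [
                _subset_pose(cid, k, source, idx, spec.jitter_sd, rng)
                for k in range(spec.poses_per_compound)
            ]
            flavors[cid] = "shape_mismatch"
        else:
            idx = np.arange(spec.n_signal_atoms)
            negated = -np.array([signal_atoms[j].charge for j in idx])
            poses[cid] = [
                _subset_pose(cid, k, signal_atoms, idx, spec.jitter_sd, rng, charges=negated)
                for k in range(spec.poses_per_compound)
            ]
            flavors[cid] = "charge_mismatch"
        order.append(cid)

    actives = frozenset(c for c in order if c.startswith("ACT"))
    decoys = frozenset(c for c in order if c.startswith("DEC"))

    # --- skipped compounds: dropped from the pose file entirely
    n_skip = int(round(spec.skip_fraction * len(order)))
    skipped = frozenset(rng.choice(np.array(order), size=n_skip, replace=False)) if n_skip else frozenset()
    for cid in skipped:
        del poses[cid]
    order = [c for c in order if c not in skipped]

    labels = ActivitySet(actives=actives, decoys=decoys, skipped=skipped)
    truth = {
        "spec": asdict(spec),
        "signal_indices": signal_indices,
        "noise_indices": noise_indices,
        "noise_patch_distance": noise_radius,
        "decoy_flavors": flavors,
    }
    return Fixture(spec=spec, model=model, library=PoseLibrary(poses=poses, source_order=order),
                   labels=labels, truth=truth)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture to ``outdir``; returns the paths written.

    Files: ``model.mol2``, ``poses.mol2``, ``actives.txt``, ``decoys.txt``,
    ``skipped.txt`` and ``truth.json``.  Same spec (incl. seed) → identical
    bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(spec)
    paths = {
        "model": outdir / "model.mol2",
        "poses": outdir / "poses.mol2",
        "actives": outdir / "actives.txt",
        "decoys": outdir / "decoys.txt",
        "skipped": outdir / "skipped.txt",
        "truth": outdir / "truth.json",
    }
    write_nib_model(fx.model, paths["model"])
    write_pose_library(fx.library, paths["poses"])
    write_id_list(fx.labels.actives, paths["actives"])
    write_id_list(fx.labels.decoys, paths["decoys"])
    write_id_list(fx.labels.skipped, paths["skipped"])
    paths["truth"].write_text(json.dumps(fx.truth, indent=2, sort_keys=True))
    return paths
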