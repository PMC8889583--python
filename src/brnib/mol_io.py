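"""TRIPOS MOL2 I/O for cavity negative-image models and docked-pose libraries.

The dialect read here is the one cavity-mapping and ligand-preparation tools
emit: an ``@<TRIPOS>MOLECULE`` record header, an ``@<TRIPOS>ATOM`` section
whose lines carry ``id name x y z type [subst_id subst_name charge]``, and a
partial charge in the ninth column (SYBYL ``USER_CHARGES`` convention).  All
other sections are ignored.  Coordinates are Å throughout; charges are read
verbatim, never derived.

A cavity model is a single MOL2 record of pseudo-atoms: by convention neutral
points are carbon, positively charged points nitrogen and negatively charged
points oxygen, but any element is accepted.  A pose library is a multi-record
MOL2 file, one record per rigid docking pose; repeated molecule names are
additional poses of the same compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyModelError, LabelOverlapError, Mol2FormatError

#: Bondi van der Waals radii (Å).  Only relative overlaps matter for the
#: similarity scores, so a compact standard table suffices.
BONDI_RADII: Mapping[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_RADIUS = 1.70


def assign_radius(element: str, default: float = DEFAULT_RADIUS) -> float:
    """Van der Waals radius (Å) for an element symbol; unknown -> ``default``."""
    return BONDI_RADII.get(element.upper(), default)


@dataclass(eq=False)
class CavityAtom:
    """One pseudo-atom (or ligand atom): element, position (Å), charge (e)."""

    element: str
    position: np.ndarray  # shape (3,), Å
    charge: float
    radius: float = 0.0  # assigned from element if left at 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.radius <= 0.0:
            self.radius = assign_radius(self.element)


@dataclass(eq=False)
class NIBModel:
    """Negative-image model: an ordered, non-empty list of cavity pseudo-atoms."""

    name: str
    atoms: list[CavityAtom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError(f"model {self.name!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    def without_atom(self, index: int) -> "NIBModel":
        """Copy of the model with one atom removed (greedy-search variant)."""
        atoms = [a for i, a in enumerate(self.atoms) if i != index]
        return NIBModel(name=self.name, atoms=atoms)


@dataclass(eq=False)
class Pose:
    """One rigid 3D placement of a compound, hydrogens included as read."""

    compound_id: str
    pose_index: int
    atoms: list[CavityAtom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyModelError(
                f"pose {self.pose_index} of {self.compound_id!r} has no atoms"
            )


@dataclass(eq=False)
class PoseLibrary:
    """Compound-keyed pose collection preserving file order."""

    poses: dict[str, list[Pose]]
    source_order: list[str]

    def __len__(self) -> int:
        return sum(len(v) for v in self.poses.values())

    def compounds(self) -> list[str]:
        return list(self.source_order)


@dataclass(frozen=True)
class ActivitySet:
    """Active / decoy / skipped compound-ID partition.

    ``skipped`` are labelled compounds with no docked pose (the docking engine
    skipped them); they must be a subset of ``actives | decoys``.
    """

    actives: frozenset[str]
    decoys: frozenset[str]
    skipped: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "actives", frozenset(self.actives))
        object.__setattr__(self, "decoys", frozenset(self.decoys))
        object.__setattr__(self, "skipped", frozenset(self.skipped))
        overlap = self.actives & self.decoys
        if overlap:
            raise LabelOverlapError(
                "IDs labelled both active and decoy: " + ", ".join(sorted(overlap))
            )
        stray = self.skipped - (self.actives | self.decoys)
        if stray:
            raise LabelOverlapError(
                "skipped IDs not present in labels: " + ", ".join(sorted(stray))
            )

    @property
    def all_ids(self) -> frozenset[str]:
        return self.actives | self.decoys


# ---------------------------------------------------------------------------
# MOL2 parsing


def _element_from_type(atom_type: str) -> str:
    """SYBYL atom type -> element symbol (``C.3`` -> ``C``, ``N.ar`` -> ``N``)."""
    return atom_type.split(".")[0]


def _split_records(text: str, path: str) -> list[list[str]]:
    lines = text.splitlines()
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "@<TRIPOS>MOLECULE"]
    if not starts:
        raise Mol2FormatError(f"{path}: no @<TRIPOS>MOLECULE record found")
    starts.append(len(lines))
    return [lines[starts[i] : starts[i + 1]] for i in range(len(starts) - 1)]


def _parse_record(record: list[str], path: str, index: int) -> tuple[str, list[CavityAtom]]:
    # record[0] is the @<TRIPOS>MOLECULE line; record[1] the molecule name.
    if len(record) < 2 or not record[1].strip():
        raise Mol2FormatError(f"{path}: record {index}: missing molecule name")
    name = record[1].strip()
    try:
        atom_start = next(
            i for i, ln in enumerate(record) if ln.strip() == "@<TRIPOS>ATOM"
        )
    except StopIteration:
        raise Mol2FormatError(f"{path}: record {index} ({name}): no @<TRIPOS>ATOM section")
    atoms: list[CavityAtom] = []
    for ln in record[atom_start + 1 :]:
        stripped = ln.strip()
        if stripped.startswith("@<TRIPOS>"):
            break
        if not stripped:
            continue
        cols = stripped.split()
        if len(cols) < 9:
            raise Mol2FormatError(
                f"{path}: record {index} ({name}): atom line has {len(cols)} columns; "
                "expected >= 9 (charge column required)"
            )
        try:
            x, y, z = float(cols[2]), float(cols[3]), float(cols[4])
            charge = float(cols[8])
        except ValueError as exc:
            raise Mol2FormatError(
                f"{path}: record {index} ({name}): unparseable atom line: {stripped!r}"
            ) from exc
        atoms.append(CavityAtom(_element_from_type(cols[5]), np.array([x, y, z]), charge))
    if not atoms:
        raise EmptyModelError(f"{path}: record {index} ({name}) has zero atoms")
    return name, atoms


def read_nib_model(path: str | Path) -> NIBModel:
    """Read a cavity model from a single-record TRIPOS MOL2 file."""
    path = Path(path)
    records = _split_records(path.read_text(), str(path))
    if len(records) != 1:
        raise Mol2FormatError(
            f"{path}: cavity models are single-record MOL2; found {len(records)} records"
        )
    name, atoms = _parse_record(records[0], str(path), 0)
    return NIBModel(name=name, atoms=atoms)


def read_pose_library(path: str | Path) -> PoseLibrary:
    """Read a multi-record MOL2 pose file; repeated names = poses of one compound."""
    path = Path(path)
    records = _split_records(path.read_text(), str(path))
    poses: dict[str, list[Pose]] = {}
    order: list[str] = []
    for i, rec in enumerate(records):
        name, atoms = _parse_record(rec, str(path), i)
        if name not in poses:
            poses[name] = []
            order.append(name)
        poses[name].append(Pose(name, pose_index=len(poses[name]), atoms=atoms))
    return PoseLibrary(poses=poses, source_order=order)


# ---------------------------------------------------------------------------
# MOL2 writing

_SYBYL_TYPES = {"C": "C.3", "N": "N.3", "O": "O.3", "H": "H", "S": "S.3", "P": "P.3"}


def _format_record(name: str, atoms: Sequence[CavityAtom]) -> str:
    lines = [
        "@<TRIPOS>MOLECULE",
        name,
        f"{len(atoms):>5d} 0 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "",
        "@<TRIPOS>ATOM",
    ]
    for i, a in enumerate(atoms, start=1):
        sybyl = _SYBYL_TYPES.get(a.element.upper(), a.element)
        lines.append(
            f"{i:>7d} {a.element}{i:<4d} {a.position[0]:>10.4f} {a.position[1]:>10.4f} "
            f"{a.position[2]:>10.4f} {sybyl:<6s} 1 UNL1 {a.charge:>9.4f}"
        )
    return "\n".join(lines) + "\n"


def write_nib_model(model: NIBModel, path: str | Path) -> None:
    """Write a cavity model as single-record MOL2 (positions/charges to 1e-4)."""
    Path(path).write_text(_format_record(model.name, model.atoms))


def write_pose_library(library: PoseLibrary, path: str | Path) -> None:
    """Write a pose library as multi-record MOL2, preserving compound order."""
    chunks = []
    for cid in library.source_order:
        for pose in library.poses[cid]:
            chunks.append(_format_record(cid, pose.atoms))
    Path(path).write_text("".join(chunks))


# ---------------------------------------------------------------------------
# ID lists


def read_id_list(path: str | Path) -> set[str]:
    """One compound ID per line; blanks and ``#`` comment lines ignored."""
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        ids.add(line)
    return ids


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_activity_set(
    actives_path: str | Path,
    decoys_path: str | Path,
    skipped_path: str | Path | None = None,
) -> ActivitySet:
    """Assemble an :class:`ActivitySet` from plain-text ID lists."""
    skipped = read_id_list(skipped_path) if skipped_path else set()
    return ActivitySet(
        actives=frozenset(read_id_list(actives_path)),
        decoys=frozenset(read_id_list(decoys_path)),
        skipped=frozenset(skipped),
    )


def models_close(a: NIBModel, b: NIBModel, tol: float = 1e-4) -> bool:
    """Element-wise model equality with positional/charge tolerance (round-trips)."""
    if len(a) != len(b):
        return False
    for x, y in zip(a.atoms, b.atoms):
        if x.element != y.element:
            return False
        if np.max(np.abs(x.position - y.position)) > tol:
            return False
        if abs(x.charge - y.charge) > tol:
            return False
    return True
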