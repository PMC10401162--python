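"""Feature-space data model and I/O.

A *feature space* is an ordered collection of tasks, each holding the
embeddings of its samples as an ``m × d`` matrix in a dimension ``d``
shared by every task.  This is the object the OTFRM scores: each task is
treated as an empirical measure over the embedding space.

Two on-disk formats are supported:

* tabular — a TSV with columns ``sample_id``, ``task_id``, ``stage``,
  then ``e1 .. ed``.  Human-inspectable and diff-friendly; values are
  written with 17 significant digits so a roundtrip is faithful well
  beyond 12 significant digits.
* array container — an HDF5 file with one group per task holding an
  ``embeddings`` dataset and ``task_id`` / ``stage`` attributes.
  Roundtrips are bitwise exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Sequence

import h5py
import numpy as np

from .exceptions import ParseError

__all__ = [
    "STAGES",
    "Stage",
    "TaskEmbeddingSet",
    "FeatureSpace",
    "read_feature_space",
    "write_feature_space",
]

STAGES = ("randomly_initialized", "pretrained", "fine_tuned", "unspecified")
Stage = Literal["randomly_initialized", "pretrained", "fine_tuned", "unspecified"]


def _as_embedding_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"embeddings must be 2-D (m × d), got shape {arr.shape}")
    m, d = arr.shape
    if m < 1 or d < 1:
        raise ValueError(f"embeddings need m ≥ 1 and d ≥ 1, got {m} × {d}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("embeddings contain non-finite entries")
    return arr


@dataclass
class TaskEmbeddingSet:
    """One task's sample embeddings plus its training-stage label."""

    task_id: str
    embeddings: np.ndarray
    stage: Stage = "unspecified"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.task_id:
            raise ValueError("task_id must be non-empty")
        if self.stage not in STAGES:
            raise ValueError(f"stage {self.stage!r} not in {STAGES}")
        self.embeddings = _as_embedding_matrix(self.embeddings)
        if self.sample_ids is not None and len(self.sample_ids) != self.m:
            raise ValueError("sample_ids length does not match sample count")

    @property
    def m(self) -> int:
        return self.embeddings.shape[0]

    @property
    def d(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class FeatureSpace:
    """An ordered set of tasks sharing one embedding dimension."""

    tasks: list[TaskEmbeddingSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("a FeatureSpace needs at least one task")
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate task_ids: {ids}")
        dims = {t.d for t in self.tasks}
        if len(dims) != 1:
            raise ValueError(f"tasks disagree on embedding dimension: {sorted(dims)}")

    @property
    def K(self) -> int:
        return len(self.tasks)

    @property
    def d(self) -> int:
        return self.tasks[0].d

    @property
    def task_ids(self) -> list[str]:
        return [t.task_id for t in self.tasks]

    def __iter__(self) -> Iterator[TaskEmbeddingSet]:
        return iter(self.tasks)

    def __getitem__(self, task_id: str) -> TaskEmbeddingSet:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)

    def __contains__(self, task_id: str) -> bool:
        return any(t.task_id == task_id for t in self.tasks)


# ---------------------------------------------------------------------------
# tabular (TSV) format


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tabular", "array_container"):
            raise ValueError(f"unknown format {fmt!r}")
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "array_container"
    return "tabular"


def _read_tabular(path: Path) -> FeatureSpace:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        has_stage = "stage" in header
        expected_prefix = ["sample_id", "task_id"] + (["stage"] if has_stage else [])
        if header[: len(expected_prefix)] != expected_prefix:
            raise ParseError(
                f"{path}: line 1: header must start with {expected_prefix}, got {header[:3]}"
            )
        d = len(header) - len(expected_prefix)
        if d < 1:
            raise ParseError(f"{path}: line 1: no embedding columns found")

        order: list[str] = []
        rows: dict[str, list[np.ndarray]] = {}
        stages: dict[str, str] = {}
        ids: dict[str, list[str]] = {}
        seen: set[tuple[str, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(header)} columns, got {len(row)}"
                )
            sample_id, task_id = row[0], row[1]
            stage = row[2] if has_stage else "unspecified"
            if stage not in STAGES:
                raise ParseError(f"{path}: line {lineno}: unknown stage {stage!r}")
            key = (task_id, sample_id)
            if key in seen:
                raise ParseError(
                    f"{path}: line {lineno}: duplicate (task_id, sample_id) = {key}"
                )
            seen.add(key)
            try:
                vec = np.array([float(v) for v in row[len(expected_prefix):]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if not np.all(np.isfinite(vec)):
                raise ParseError(f"{path}: line {lineno}: non-finite embedding value")
            if task_id not in rows:
                order.append(task_id)
                rows[task_id] = []
                ids[task_id] = []
                stages[task_id] = stage
            elif stages[task_id] != stage:
                raise ParseError(
                    f"{path}: line {lineno}: task {task_id!r} has conflicting stages"
                )
            rows[task_id].append(vec)
            ids[task_id].append(sample_id)

        if not order:
            raise ParseError(f"{path}: no data rows")
        tasks = [
            TaskEmbeddingSet(
                task_id=tid,
                embeddings=np.vstack(rows[tid]),
                stage=stages[tid],  # type: ignore[arg-type]
                sample_ids=ids[tid],
            )
            for tid in order
        ]
        try:
            return FeatureSpace(tasks)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None


def _write_tabular(fs: FeatureSpace, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["sample_id", "task_id", "stage"] + [f"e{i + 1}" for i in range(fs.d)]
        )
        for task in fs:
            for i in range(task.m):
                sid = task.sample_ids[i] if task.sample_ids else f"{task.task_id}_{i}"
                writer.writerow(
                    [sid, task.task_id, task.stage]
                    + [format(v, ".17g") for v in task.embeddings[i]]
                )


# ---------------------------------------------------------------------------
# HDF5 array container


def _read_h5(path: Path) -> FeatureSpace:
    tasks = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):  # groups are task_0000, task_0001, ...
            grp = f[name]
            tasks.append(
                TaskEmbeddingSet(
                    task_id=str(grp.attrs["task_id"]),
                    embeddings=grp["embeddings"][()],
                    stage=str(grp.attrs.get("stage", "unspecified")),  # type: ignore[arg-type]
                    sample_ids=[s.decode() for s in grp["sample_ids"][()]]
                    if "sample_ids" in grp
                    else None,
                )
            )
    try:
        return FeatureSpace(tasks)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _write_h5(fs: FeatureSpace, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["task_order"] = [t.task_id for t in fs]
        for i, task in enumerate(fs):
            grp = f.create_group(f"task_{i:04d}")
            grp.attrs["task_id"] = task.task_id
            grp.attrs["stage"] = task.stage
            grp.create_dataset("embeddings", data=task.embeddings)
            if task.sample_ids is not None:
                grp.create_dataset(
                    "sample_ids", data=np.array(task.sample_ids, dtype="S")
                )


def read_feature_space(path: str | Path, format: str | None = None) -> FeatureSpace:
    """Load a :class:`FeatureSpace`; the format is inferred from the
    extension (``.h5``/``.hdf5`` → array container) unless given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_h5(path) if fmt == "array_container" else _read_tabular(path)


def write_feature_space(
    fs: FeatureSpace, path: str | Path, format: str | None = None
) -> None:
    """Write a :class:`FeatureSpace` to ``path`` in the chosen format."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "array_container":
        _write_h5(fs, path)
    else:
        _write_tabular(fs, path)
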