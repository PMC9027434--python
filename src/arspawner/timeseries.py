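"""Domain containers for labelled multivariate sequences and raw skeletons.

A :class:`TimeSeries` is one variable-length multivariate sequence (an
``L x M`` float matrix) carrying a class label, a subject identifier and a
unique series id.  A :class:`Dataset` is an ordered collection of such
series sharing the feature dimension ``M``.  A :class:`SkeletonSequence`
holds raw 3-D joint positions per frame for a named joint layout; it is the
input to the skeletal descriptors, which turn it into a ``TimeSeries``.

On-disk formats
---------------
Series are stored as long-form CSV with columns
``series_id,label,subject,frame_index,f1..fM`` (UTF-8, ``.`` decimal
separator, 0-based frame indices).  Skeleton sequences are stored as JSON::

    {"layout": "kinect20", "joints": [...], "sequences": [
        {"label": "a01", "subject": "s01", "series_id": "...",
         "frames": [[[x, y, z], ...], ...]}, ...]}

Both round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError, ParseError


@dataclass(frozen=True)
class TimeSeries:
    """One labelled multivariate sequence of shape ``(L, M)``."""

    values: np.ndarray
    label: str
    subject: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(
                f"series {self.series_id!r}: values must be a non-empty L x M matrix, "
                f"got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.series_id!r}: non-finite values")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


@dataclass
class Dataset:
    """Ordered collection of :class:`TimeSeries` with a shared dimension."""

    series: list[TimeSeries] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate series ids: {dupes}")
        dims = {s.dimension for s in self.series}
        if len(dims) > 1:
            raise DimensionMismatchError(
                f"dataset {self.name!r}: inconsistent feature dimensions {sorted(dims)}"
            )

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[TimeSeries]:
        return iter(self.series)

    def __getitem__(self, i: int) -> TimeSeries:
        return self.series[i]

    @property
    def classes(self) -> list[str]:
        """Sorted distinct labels present in the dataset."""
        return sorted({s.label for s in self.series})

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject for s in self.series})

    @property
    def dimension(self) -> int:
        if not self.series:
            raise ValueError("empty dataset has no dimension")
        return self.series[0].dimension

    def by_class(self) -> dict[str, list[TimeSeries]]:
        out: dict[str, list[TimeSeries]] = {}
        for s in self.series:
            out.setdefault(s.label, []).append(s)
        return out


@dataclass(frozen=True)
class SkeletonLayout:
    """Named, ordered joint set (e.g. the 20-joint Kinect v1 skeleton)."""

    name: str
    joints: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.joints)) != len(self.joints):
            raise ValueError(f"layout {self.name!r} has duplicate joint names")

    def index(self, joint: str) -> int:
        try:
            return self.joints.index(joint)
        except ValueError:
            raise KeyError(
                f"joint {joint!r} not in layout {self.name!r}"
            ) from None


@dataclass
class SkeletonSequence:
    """Frames of named 3-D joints: an ``(L, J, 3)`` position array."""

    frames: np.ndarray
    layout: SkeletonLayout
    label: str = ""
    subject: str = ""
    series_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        J = len(self.layout.joints)
        if frames.ndim != 3 or frames.shape[1] != J or frames.shape[2] != 3:
            raise ValueError(
                f"sequence {self.series_id!r}: frames must have shape (L, {J}, 3), "
                f"got {frames.shape}"
            )
        if not np.all(np.isfinite(frames)):
            raise ValueError(f"sequence {self.series_id!r}: non-finite joint positions")
        self.frames = frames

    def __len__(self) -> int:
        return self.frames.shape[0]

    def joint(self, name: str) -> np.ndarray:
        """Trajectory of one named joint, shape ``(L, 3)``."""
        return self.frames[:, self.layout.index(name), :]

    def frame_dict(self, t: int) -> Mapping[str, np.ndarray]:
        return {j: self.frames[t, k] for k, j in enumerate(self.layout.joints)}


# ---------------------------------------------------------------------------
# series-csv I/O


def write_dataset(data: Dataset, path: str | Path) -> None:
    """Write a dataset to long-form CSV (re-readable by :func:`read_dataset`)."""
    path = Path(path)
    if data.series:
        M = data.dimension
        chunks = []
        for s in data.series:
            df = pd.DataFrame(s.values, columns=[f"f{m + 1}" for m in range(M)])
            df.insert(0, "frame_index", np.arange(s.length))
            df.insert(0, "subject", s.subject)
            df.insert(0, "label", s.label)
            df.insert(0, "series_id", s.series_id)
            chunks.append(df)
        out = pd.concat(chunks, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["series_id", "label", "subject", "frame_index", "f1"]
        )
    # 17 significant digits guarantee an exact float64 round trip
    out.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path, name: str | None = None) -> Dataset:
    """Read a long-form series CSV written by :func:`write_dataset`.

    Malformed files raise :class:`~arspawner.errors.ParseError` naming the
    offending column or line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path,
            dtype={"series_id": str, "label": str, "subject": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # malformed CSV (ragged rows, bad tokens)
        raise ParseError(f"{path}: {exc}") from exc
    required = ["series_id", "label", "subject", "frame_index"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    if df.empty:
        return Dataset([], name=name or path.stem)
    if not feat_cols:
        raise ParseError(f"{path}: no feature columns f1..fM found")
    if list(range(1, len(feat_cols) + 1)) != [int(c[1:]) for c in feat_cols]:
        raise ParseError(f"{path}: feature columns are not contiguous f1..fM: {feat_cols}")
    bad = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    nonfinite = ~np.isfinite(bad.to_numpy(dtype=np.float64, na_value=np.nan))
    if nonfinite.any():
        row = int(np.argwhere(nonfinite.any(axis=1))[0][0])
        raise ParseError(
            f"{path}: non-finite or non-numeric feature value at data line {row + 2}"
        )
    series = []
    for sid, grp in df.groupby("series_id", sort=False):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(grp))):
            raise ParseError(
                f"{path}: series {sid!r} frame_index is not contiguous 0..L-1"
            )
        labels = grp["label"].unique()
        subjects = grp["subject"].unique()
        if len(labels) != 1 or len(subjects) != 1:
            raise ParseError(f"{path}: series {sid!r} has inconsistent label/subject")
        series.append(
            TimeSeries(
                values=grp[feat_cols].to_numpy(dtype=np.float64),
                label=str(labels[0]),
                subject=str(subjects[0]),
                series_id=str(sid),
            )
        )
    return Dataset(series, name=name or path.stem)


# ---------------------------------------------------------------------------
# skeleton-json I/O


def write_skeletons(sequences: Sequence[SkeletonSequence], path: str | Path) -> None:
    if not sequences:
        raise ValueError("no sequences to write")
    layout = sequences[0].layout
    for s in sequences:
        if s.layout != layout:
            raise ValueError("all sequences in one file must share a layout")
    doc = {
        "layout": layout.name,
        "joints": list(layout.joints),
        "sequences": [
            {
                "series_id": s.series_id,
                "label": s.label,
                "subject": s.subject,
                "frames": s.frames.tolist(),
            }
            for s in sequences
        ],
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_skeletons(path: str | Path) -> list[SkeletonSequence]:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    for key in ("layout", "joints", "sequences"):
        if key not in doc:
            raise ParseError(f"{path}: missing top-level key {key!r}")
    layout = SkeletonLayout(doc["layout"], tuple(doc["joints"]))
    out = []
    for k, rec in enumerate(doc["sequences"]):
        try:
            out.append(
                SkeletonSequence(
                    frames=np.asarray(rec["frames"], dtype=np.float64),
                    layout=layout,
                    label=str(rec.get("label", "")),
                    subject=str(rec.get("subject", "")),
                    series_id=str(rec.get("series_id", f"seq-{k}")),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}: sequence #{k}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------


def split_by_subject(
    data: Dataset,
    train_subjects: Iterable[str],
    test_subjects: Iterable[str] | None = None,
) -> tuple[Dataset, Dataset]:
    """Partition a dataset into subject-disjoint train and test halves.

    The test side defaults to every subject not listed in ``train_subjects``.
    When ``test_subjects`` is given explicitly, every subject in the data
    must appear on exactly one side; orphans raise ``ValueError``.
    """
    train_subjects = set(train_subjects)
    orphans = train_subjects - set(data.subjects)
    if orphans:
        raise ValueError(f"train subjects not present in dataset: {sorted(orphans)}")
    if test_subjects is None:
        test_set = set(data.subjects) - train_subjects
    else:
        test_set = set(test_subjects)
        overlap = train_subjects & test_set
        if overlap:
            raise ValueError(f"subjects on both sides: {sorted(overlap)}")
        neither = set(data.subjects) - train_subjects - test_set
        if neither:
            raise ValueError(f"subjects assigned to neither side: {sorted(neither)}")
    train = [s for s in data.series if s.subject in train_subjects]
    test = [s for s in data.series if s.subject in test_set]
    return (
        Dataset(train, name=f"{data.name}-train"),
        Dataset(test, name=f"{data.name}-test"),
    )
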