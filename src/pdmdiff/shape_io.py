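"""Ordered point-set shape representations and their file formats.

A shape is an ordered list of N three-dimensional points (a point
distribution model, PDM): point index i marks the *same* anatomical locus
in every shape of a population, so row order is semantic and reordering a
shape's rows is not a no-op.

Formats handled here:

* ShapeWorks-style ``.particles`` text files — one ``x y z`` row per point,
  ``#`` comment lines skipped;
* CSV manifests with columns ``id,path,side,label`` (paths relative to the
  manifest's directory);
* packed HDF5 containers with datasets ``coords`` (S, N, 3), ``ids``,
  ``labels`` and ``side``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PointSet",
    "ShapeDataset",
    "NormalizationParams",
    "ParticlesParseError",
    "read_particles",
    "write_particles",
    "flip_lateral",
    "mean_shape",
    "normalize_dataset",
    "denormalize_dataset",
    "read_manifest",
    "write_manifest",
    "save_dataset_h5",
    "load_dataset_h5",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class ParticlesParseError(ValueError):
    """Raised when a ``.particles`` file is malformed."""


@dataclass(frozen=True)
class PointSet:
    """One subject's ordered N-by-3 shape representation.

    ``coords[i]`` is the position of correspondence index ``i``; the row
    order carries the anatomical correspondence across subjects.
    """

    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("a PointSet needs at least one point")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class ShapeDataset:
    """A population of PointSets sharing N and index semantics.

    Stored densely as a (S, N, 3) array; ``labels``/``ids``/``side`` align
    1:1 with the first axis when present.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    ids: np.ndarray | None = None
    side: np.ndarray | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (S, N, 3), got {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("dataset must contain at least one shape")
        self.coords = coords
        for name in ("labels", "ids", "side"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != coords.shape[0]:
                    raise ValueError(f"{name} must align 1:1 with shapes")
                setattr(self, name, v)

    @classmethod
    def from_shapes(
        cls,
        shapes: Sequence[PointSet],
        labels: Iterable | None = None,
        ids: Iterable | None = None,
        side: Iterable | None = None,
    ) -> "ShapeDataset":
        if len(shapes) == 0:
            raise ValueError("dataset must contain at least one shape")
        ns = {s.n_points for s in shapes}
        if len(ns) != 1:
            raise ValueError(f"all shapes must share N, got point counts {sorted(ns)}")
        return cls(
            np.stack([s.coords for s in shapes]),
            labels=None if labels is None else np.asarray(list(labels)),
            ids=None if ids is None else np.asarray(list(ids)),
            side=None if side is None else np.asarray(list(side)),
        )

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __getitem__(self, i: int) -> PointSet:
        return PointSet(self.coords[i])

    @property
    def shapes(self) -> list[PointSet]:
        return [PointSet(c) for c in self.coords]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def subset(self, index) -> "ShapeDataset":
        index = np.asarray(index)
        return ShapeDataset(
            self.coords[index],
            labels=None if self.labels is None else self.labels[index],
            ids=None if self.ids is None else self.ids[index],
            side=None if self.side is None else self.side[index],
        )


@dataclass(frozen=True)
class NormalizationParams:
    """Global centering/scaling applied uniformly to a whole population."""

    center: np.ndarray
    scale: float

    def __post_init__(self):
        center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "scale", float(self.scale))


# ---------------------------------------------------------------------------
# .particles I/O
# ---------------------------------------------------------------------------

def read_particles(path) -> PointSet:
    """Read a ``.particles`` file: one ``x y z`` row per correspondence index."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise ParticlesParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParticlesParseError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc
    if not rows:
        raise ParticlesParseError(f"{path}: no points found")
    return PointSet(np.array(rows))


def write_particles(shape: PointSet, path) -> None:
    """Write a ``.particles`` file with 9 significant digits per coordinate."""
    if not isinstance(shape, PointSet):
        shape = PointSet(np.asarray(shape))
    with open(path, "w") as fh:
        for row in shape.coords:
            fh.write(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}\n")


# ---------------------------------------------------------------------------
# geometry utilities
# ---------------------------------------------------------------------------

def flip_lateral(shape: PointSet, axis: str = "x") -> PointSet:
    """Mirror a shape across a coordinate plane (e.g. to pool left and
    flipped-right structures); point ordering is unchanged."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    coords = shape.coords.copy()
    coords[:, _AXES[axis]] *= -1.0
    return PointSet(coords)


def mean_shape(data: ShapeDataset) -> PointSet:
    """Index-wise arithmetic mean: point i of the result is the mean of
    point i over subjects (correspondence-aware, not nearest-neighbor)."""
    return PointSet(data.coords.mean(axis=0))


def normalize_dataset(
    data: ShapeDataset, scale_floor: float = 1e-12
) -> tuple[ShapeDataset, NormalizationParams]:
    """Center by the grand centroid and divide by the RMS point norm.

    The *same* parameters are applied to every shape so that correspondence
    and relative geometry are untouched.
    """
    center = data.coords.reshape(-1, 3).mean(axis=0)
    centered = data.coords - center
    scale = float(np.sqrt(np.mean(np.sum(centered ** 2, axis=-1))))
    if scale < scale_floor:
        warnings.warn(
            "degenerate dataset (all points identical); applying scale floor",
            RuntimeWarning,
            stacklevel=2,
        )
        scale = scale_floor
    out = ShapeDataset(
        centered / scale, labels=data.labels, ids=data.ids, side=data.side
    )
    return out, NormalizationParams(center=center, scale=scale)


def denormalize_dataset(data: ShapeDataset, params: NormalizationParams) -> ShapeDataset:
    return ShapeDataset(
        data.coords * params.scale + params.center,
        labels=data.labels,
        ids=data.ids,
        side=data.side,
    )


# ---------------------------------------------------------------------------
# manifests and HDF5 containers
# ---------------------------------------------------------------------------

def read_manifest(path) -> ShapeDataset:
    """Load a dataset from a CSV manifest with columns ``id,path,side,label``."""
    path = Path(path)
    df = pd.read_csv(path)
    if "path" not in df.columns:
        raise ValueError(f"{path}: manifest needs a 'path' column")
    shapes = [read_particles(path.parent / p) for p in df["path"]]
    return ShapeDataset.from_shapes(
        shapes,
        labels=df["label"] if "label" in df.columns else None,
        ids=df["id"] if "id" in df.columns else None,
        side=df["side"] if "side" in df.columns else None,
    )


def write_manifest(data: ShapeDataset, directory, prefix: str = "shape") -> Path:
    """Write one ``.particles`` file per shape plus ``manifest.csv``; returns
    the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = (
        data.ids
        if data.ids is not None
        else np.array([f"{prefix}_{i:05d}" for i in range(len(data))])
    )
    rel_paths = []
    for i in range(len(data)):
        rel = f"{ids[i]}.particles"
        write_particles(data[i], directory / rel)
        rel_paths.append(rel)
    df = pd.DataFrame(
        {
            "id": ids,
            "path": rel_paths,
            "side": data.side if data.side is not None else [""] * len(data),
            "label": data.labels if data.labels is not None else [""] * len(data),
        }
    )
    manifest = directory / "manifest.csv"
    df.to_csv(manifest, index=False)
    return manifest


def save_dataset_h5(data: ShapeDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=data.coords, track_times=False)
        for name in ("labels", "ids", "side"):
            v = getattr(data, name)
            if v is not None:
                f.create_dataset(name, data=np.asarray(v, dtype="S"), track_times=False)


def load_dataset_h5(path) -> ShapeDataset:
    with h5py.File(path, "r") as f:
        coords = f["coords"][()]
        extras = {}
        for name in ("labels", "ids", "side"):
            if name in f:
                extras[name] = f[name][()].astype(str)
    return ShapeDataset(coords, **extras)
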