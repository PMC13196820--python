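"""PCA generative baseline for ordered point sets.

Each shape is flattened to a 3N-vector, a truncated PCA basis is fit by
SVD on the mean-centered data, and new shapes are generated by drawing
independent Gaussian scores with the empirical per-component variances and
inverting the projection. Because the flattening respects point order, the
baseline preserves correspondence by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .shape_io import ShapeDataset

__all__ = ["PCAModel", "pca_fit", "pca_sample", "pca_reconstruct"]


@dataclass(frozen=True)
class PCAModel:
    mean_vector: np.ndarray          # (3N,)
    components: np.ndarray           # (n_components, 3N), row-orthonormal
    variances: np.ndarray            # per-component score variances, nonincreasing
    explained_variance_ratio: float  # cumulative fraction captured
    n_points: int

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["meta"] = json.dumps(
                {"n_points": self.n_points, "evr": self.explained_variance_ratio}
            )
            f.create_dataset("mean_vector", data=self.mean_vector, track_times=False)
            f.create_dataset("components", data=self.components, track_times=False)
            f.create_dataset("variances", data=self.variances, track_times=False)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            return cls(
                mean_vector=f["mean_vector"][()],
                components=f["components"][()],
                variances=f["variances"][()],
                explained_variance_ratio=meta["evr"],
                n_points=meta["n_points"],
            )


def pca_fit(data: ShapeDataset, n_components: int = 128) -> PCAModel:
    """Fit PCA on flattened shapes; deterministic sign convention (the
    largest-magnitude entry of each component is positive)."""
    flat = data.coords.reshape(len(data), -1)
    s_count, dim = flat.shape
    max_comp = min(s_count - 1, dim) if s_count > 1 else 1
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(S-1, 3N)={max_comp}"
        )
    mean = flat.mean(axis=0)
    centered = flat - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:n_components]
    # sign convention for reproducibility
    flips = np.sign(comps[np.arange(len(comps)), np.abs(comps).argmax(axis=1)])
    flips[flips == 0] = 1.0
    comps = comps * flips[:, None]
    all_var = svals ** 2 / max(s_count - 1, 1)
    variances = all_var[:n_components]
    total = all_var.sum()
    evr = float(variances.sum() / total) if total > 0 else 1.0
    return PCAModel(
        mean_vector=mean,
        components=comps,
        variances=variances,
        explained_variance_ratio=evr,
        n_points=data.n_points,
    )


def pca_sample(model: PCAModel, n: int, rng=None) -> ShapeDataset:
    """Draw scores ~ N(0, variance_j) per component and invert the PCA."""
    rng = np.random.default_rng(rng)
    scores = rng.standard_normal((n, model.n_components)) * np.sqrt(model.variances)
    flat = model.mean_vector + scores @ model.components
    return ShapeDataset(flat.reshape(n, model.n_points, 3))


def pca_reconstruct(model: PCAModel, data: ShapeDataset) -> ShapeDataset:
    """Project onto the retained basis and back (for reconstruction checks)."""
    flat = data.coords.reshape(len(data), -1)
    scores = (flat - model.mean_vector) @ model.components.T
    rec = model.mean_vector + scores @ model.components
    return ShapeDataset(rec.reshape(len(data), model.n_points, 3), labels=data.labels)
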