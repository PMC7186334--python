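"""Build fiber-count / FA / length connectivity matrices from streamlines.

A streamline contributes an edge (i, j) when its first and last points fall
inside voxels carrying two distinct non-background parcellation labels; all
other streamlines (endpoint in background, endpoint off-grid, both endpoints
in one region) are discarded. Three symmetric matrices are tallied per
subject:

* ``fn``          — number of streamlines linking the pair,
* ``fa_mean``     — mean over those streamlines of the per-streamline mean
  FA, sampling FA at every point's voxel,
* ``length_mean`` — mean polyline arc length (mm).

The analyzed network keeps edges with ``fn`` strictly above a fiber-count
threshold (default 3, i.e. FN >= 4 survives) and weights each surviving edge
by ``fn * fa_mean``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import WeightedGraph
from .tracking import Streamline


@dataclass
class Parcellation:
    """Integer label volume (0 = background, 1..N = nodes) with node names."""

    label_volume: np.ndarray
    node_names: list[str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("labels must be integers")
        n = len(self.node_names)
        labels = np.unique(self.label_volume)
        if labels.min() < 0 or labels.max() > n:
            raise ValueError(
                f"labels must lie in 0..{n}, found range "
                f"[{labels.min()}, {labels.max()}]")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


@dataclass
class Connectome:
    """Per-subject fiber-number, mean-FA, and mean-length matrices."""

    node_names: list[str]
    fn: np.ndarray
    fa_mean: np.ndarray
    length_mean: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_names)
        for name in ("fn", "fa_mean", "length_mean"):
            M = np.asarray(getattr(self, name), dtype=float)
            if M.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}, got {M.shape}")
            if not np.allclose(M, M.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
            if np.any(np.diag(M) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
            setattr(self, name, M)
        support = self.fn > 0
        for name in ("fa_mean", "length_mean"):
            M = getattr(self, name)
            if np.any((M != 0) != support):
                raise ValueError(f"{name} support does not match fn support")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


def assign_endpoints(streamline: Streamline, parcellation: Parcellation):
    """Node pair (i, j), 1-based, linked by a streamline — or ``None``.

    Returns ``None`` when either endpoint lies off-grid or in background,
    or both endpoints fall in the same region.
    """
    vs = np.asarray(parcellation.voxel_size)
    grid = np.asarray(parcellation.label_volume.shape)
    labels = []
    for point in (streamline.points[0], streamline.points[-1]):
        idx = np.floor(point / vs).astype(int)
        if np.any(idx < 0) or np.any(idx >= grid):
            return None
        labels.append(int(parcellation.label_volume[tuple(idx)]))
    i, j = labels
    if i == 0 or j == 0 or i == j:
        return None
    return (i, j)


def build_connectome(streamlines, parcellation: Parcellation,
                     fa_volume: np.ndarray) -> Connectome:
    """Tally the three weighted matrices from a set of streamlines."""
    fa_volume = np.asarray(fa_volume, dtype=float)
    if fa_volume.shape != parcellation.label_volume.shape:
        raise ValueError(
            f"FA grid {fa_volume.shape} does not match parcellation grid "
            f"{parcellation.label_volume.shape}")
    n = parcellation.n_nodes
    vs = np.asarray(parcellation.voxel_size)
    grid = np.asarray(parcellation.label_volume.shape)

    fn = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    len_sum = np.zeros((n, n))
    for sl in streamlines:
        pair = assign_endpoints(sl, parcellation)
        if pair is None:
            continue
        i, j = pair[0] - 1, pair[1] - 1
        idx = np.floor(sl.points / vs).astype(int)
        idx = np.clip(idx, 0, grid - 1)  # interior points at the boundary
        fa_mean_sl = fa_volume[idx[:, 0], idx[:, 1], idx[:, 2]].mean()
        length = sl.arc_length()
        for a, b in ((i, j), (j, i)):
            fn[a, b] += 1
            fa_sum[a, b] += fa_mean_sl
            len_sum[a, b] += length

    with np.errstate(invalid="ignore"):
        fa_mean = np.where(fn > 0, fa_sum / np.maximum(fn, 1), 0.0)
        length_mean = np.where(fn > 0, len_sum / np.maximum(fn, 1), 0.0)
    return Connectome(node_names=list(parcellation.node_names), fn=fn,
                      fa_mean=fa_mean, length_mean=length_mean)


def threshold_and_weight(connectome: Connectome,
                         fn_threshold: int = 3) -> WeightedGraph:
    """FN-thresholded, FA x FN weighted network.

    Edges with ``fn <= fn_threshold`` are removed (strict reading: a count
    of exactly ``fn_threshold`` does not survive); surviving edges are
    weighted ``fn * fa_mean``.
    """
    if fn_threshold < 0:
        raise ValueError("fn_threshold must be non-negative")
    keep = connectome.fn > fn_threshold
    weights = np.where(keep, connectome.fn * connectome.fa_mean, 0.0)
    return WeightedGraph(weights=weights, node_names=list(connectome.node_names))
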