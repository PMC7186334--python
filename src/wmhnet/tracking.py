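"""Deterministic FACT streamline tracking on a voxel direction field.

Fiber Assignment by Continuous Tracking follows the principal diffusion
direction of whichever voxel the streamline currently occupies, with no
interpolation. Tracking launches from each seed voxel in both signs of the
seed direction and the two half-tracks are concatenated. A half-track
terminates when

* the entered voxel's fractional anisotropy falls below ``fa_threshold``
  (default 0.2),
* the turning angle between successive step directions exceeds
  ``angle_threshold`` (default 45 degrees, strict),
* the track leaves the grid, or
* ``max_steps`` steps have been taken.

Eigenvector sign is arbitrary, so at every step the voxel direction is
flipped if needed to keep the angle with the previous step at most 90
degrees before the angle test is applied. Physical positions are voxel
centers: ``(index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DirectionField:
    """Principal diffusion direction and FA per voxel.

    ``directions`` has shape ``grid + (3,)`` with unit-norm vectors wherever
    ``fa > 0``; ``fa`` lies in [0, 1].
    """

    directions: np.ndarray
    fa: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.directions.ndim != 4 or self.directions.shape[-1] != 3:
            raise ValueError("directions must have shape (nx, ny, nz, 3)")
        if self.fa.shape != self.directions.shape[:3]:
            raise ValueError("fa grid does not match directions grid")
        if np.any(self.fa < 0) or np.any(self.fa > 1):
            raise ValueError("fa must lie in [0, 1]")
        norms = np.linalg.norm(self.directions, axis=-1)
        bad = (self.fa > 0) & ~np.isclose(norms, 1.0, atol=1e-6)
        if np.any(bad):
            idx = tuple(int(v[0]) for v in np.nonzero(bad))
            raise ValueError(f"direction at voxel {idx} is not unit norm")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fa.shape


@dataclass
class Streamline:
    """Ordered polyline in physical (mm) coordinates."""

    points: np.ndarray
    seed_voxel: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("a streamline needs at least one 3-D point")

    def __len__(self) -> int:
        return self.points.shape[0]

    def arc_length(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class TrackingParams:
    fa_threshold: float = 0.2
    angle_threshold: float = 45.0
    step_size: float | None = None  # defaults to half the smallest voxel dim
    max_steps: int = 500

    def __post_init__(self) -> None:
        if not 0 < self.fa_threshold < 1:
            raise ValueError("fa_threshold must lie in (0, 1)")
        if not 0 < self.angle_threshold < 180:
            raise ValueError("angle_threshold must lie in (0, 180)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")


def compute_fa(eigenvalues) -> float:
    """Fractional anisotropy of a diffusion tensor from its eigenvalues.

    FA = sqrt( 1/2 * ((l1-l2)^2 + (l2-l3)^2 + (l1-l3)^2) / (l1^2+l2^2+l3^2) ).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise ValueError("exactly three eigenvalues required")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be non-negative")
    denom = np.sum(lam**2)
    if denom == 0:
        raise ValueError("FA undefined for an all-zero tensor")
    l1, l2, l3 = lam
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    return float(np.sqrt(0.5 * num / denom))


def _voxel_of(pos: np.ndarray, voxel_size: np.ndarray,
              grid: tuple[int, int, int]):
    idx = np.floor(pos / voxel_size).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(grid)):
        return None
    return tuple(idx)


def _half_track(field: DirectionField, params: TrackingParams,
                start: np.ndarray, init_dir: np.ndarray,
                step: float, cos_limit: float) -> list[np.ndarray]:
    """Points visited after the seed point, following `init_dir` outward."""
    vs = np.asarray(field.voxel_size)
    pts: list[np.ndarray] = []
    pos = start.copy()
    v_prev = init_dir
    for _ in range(params.max_steps):
        vox = _voxel_of(pos, vs, field.grid_shape)
        if vox is None:
            break
        d = field.directions[vox].copy()
        if np.dot(d, v_prev) < 0:
            d = -d
        # strict termination when turning angle exceeds the threshold
        if np.dot(d, v_prev) < cos_limit - 1e-12:
            break
        new_pos = pos + step * d
        new_vox = _voxel_of(new_pos, vs, field.grid_shape)
        if new_vox is None:
            break
        if field.fa[new_vox] < params.fa_threshold:
            break
        pts.append(new_pos)
        pos = new_pos
        v_prev = d
    return pts


def track_fact(field: DirectionField, params: TrackingParams | None = None,
               seeds=None) -> list[Streamline]:
    """Track one bidirectional streamline from each seed voxel.

    ``seeds`` is an iterable of voxel index triples; all must lie inside the
    grid. Each streamline contains at least the seed-voxel center and at most
    ``2 * max_steps + 1`` points.
    """
    if params is None:
        params = TrackingParams()
    if seeds is None:
        raise ValueError("at least one seed voxel is required")
    vs = np.asarray(field.voxel_size)
    step = params.step_size if params.step_size is not None else 0.5 * vs.min()
    cos_limit = np.cos(np.radians(params.angle_threshold))
    grid = np.asarray(field.grid_shape)

    streamlines = []
    for seed in seeds:
        seed = tuple(int(s) for s in seed)
        if np.any(np.asarray(seed) < 0) or np.any(np.asarray(seed) >= grid):
            raise ValueError(f"seed voxel {seed} lies outside the grid")
        center = (np.asarray(seed) + 0.5) * vs
        if field.fa[seed] < params.fa_threshold:
            streamlines.append(Streamline(points=center[None, :], seed_voxel=seed))
            continue
        d0 = field.directions[seed]
        fwd = _half_track(field, params, center, d0, step, cos_limit)
        bwd = _half_track(field, params, center, -d0, step, cos_limit)
        pts = bwd[::-1] + [center] + fwd
        streamlines.append(Streamline(points=np.vstack(pts), seed_voxel=seed))
    return streamlines
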