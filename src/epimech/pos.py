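"""Photoreceptor-outer-segment (POS) internalisation analysis on 3D stacks.

The apical actin channel defines a surface; its mean z is the cut-off height
separating internalised fragments (centroid below) from surface-bound ones
(centroid at or above). Fragment counts, volumes, per-cell normalisation and
the apical actin surface area are derived from that partition.

Axis convention: stacks are (z, y, x) with z increasing apically. A column's
surface height is the top face of its uppermost supra-threshold voxel,
z = (iz + 1)·dz; particle centroids use voxel centers, z = (iz + 0.5)·dz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .monolayer import resolve_threshold

__all__ = [
    "Stack3D",
    "ApicalSurface",
    "InternalisationSummary",
    "build_apical_surface",
    "segment_particles",
    "classify_particles",
    "summarize_internalisation",
    "triangulated_area",
    "apical_actin_area",
]


@dataclass
class Stack3D:
    """Two-channel confocal z-stack with physical voxel sizes (dz, dy, dx)."""

    channels: dict[str, np.ndarray]
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels are not congruent: {shapes}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        self.channels = {k: np.asarray(v, float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape


@dataclass
class ApicalSurface:
    """Per-column surface height map (µm, NaN where no actin was found) and
    its mean — the cut-off height."""

    height_map_um: np.ndarray
    cutoff_um: float


@dataclass
class InternalisationSummary:
    n_internalised: int
    n_bound: int
    mean_internalised_volume_um3: float
    mean_bound_volume_um3: float
    internalised_per_cell: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_internalised + self.n_bound


def _height_map(channel: np.ndarray, dz: float, threshold) -> np.ndarray:
    thr = resolve_threshold(channel, threshold)
    above = channel > thr
    any_col = above.any(axis=0)
    # uppermost supra-threshold voxel per column; top-face convention
    top = channel.shape[0] - 1 - np.argmax(above[::-1], axis=0)
    heights = (top + 1).astype(float) * dz
    heights[~any_col] = np.nan
    return heights


def build_apical_surface(stack: Stack3D, actin_channel: str = "actin",
                         threshold_method="otsu",
                         max_missing_fraction: float = 0.5) -> ApicalSurface:
    """Build the apical surface from the actin channel.

    Per (x, y) column the surface sits at the top face of the uppermost
    supra-threshold voxel; columns without signal are missing and excluded
    from the mean. The cut-off is the arithmetic mean of the finite heights.
    """
    channel = stack.channels[actin_channel]
    if not np.any(channel > 0):
        raise ValueError("actin channel is empty")
    heights = _height_map(channel, stack.voxel_size_um[0], threshold_method)
    missing = np.isnan(heights).mean()
    if missing > max_missing_fraction:
        raise ValueError(f"{missing:.0%} of columns lack actin signal: "
                         "surface unreliable")
    return ApicalSurface(heights, float(np.nanmean(heights)))


def segment_particles(stack: Stack3D, pos_channel: str = "pos",
                      threshold_method="otsu",
                      min_voxels: int = 4) -> pd.DataFrame:
    """Segment POS fragments as 26-connected supra-threshold components.

    Returns one row per particle of at least ``min_voxels`` voxels with its
    center-of-mass centroid (µm, voxel-center convention) and volume
    (voxel count × voxel volume, µm³).
    """
    channel = stack.channels[pos_channel]
    if not np.any(channel > 0):
        return pd.DataFrame(columns=["particle_id", "x_um", "y_um", "z_um",
                                     "volume_um3", "n_voxels"])
    thr = resolve_threshold(channel, threshold_method)
    mask = channel > thr
    structure = np.ones((3, 3, 3), bool)  # 26-connectivity
    labels, n = ndi.label(mask, structure=structure)
    dz, dy, dx = stack.voxel_size_um
    voxel_volume = dz * dy * dx
    rows = []
    if n:
        ids = np.arange(1, n + 1)
        sizes = ndi.sum_labels(np.ones_like(labels), labels, ids)
        centroids = ndi.center_of_mass(mask, labels, ids)
        pid = 0
        for size, (cz, cy, cx) in zip(sizes, centroids):
            if size < min_voxels:
                continue
            pid += 1
            rows.append({
                "particle_id": pid,
                "x_um": (cx + 0.5) * dx,
                "y_um": (cy + 0.5) * dy,
                "z_um": (cz + 0.5) * dz,
                "volume_um3": float(size) * voxel_volume,
                "n_voxels": int(size),
            })
    return pd.DataFrame(rows, columns=["particle_id", "x_um", "y_um", "z_um",
                                       "volume_um3", "n_voxels"])


def classify_particles(particles: pd.DataFrame,
                       surface: ApicalSurface) -> pd.DataFrame:
    """Partition particles by centroid z against the cut-off height.

    Centroid strictly below the cut-off → ``internalised``; at or above →
    ``bound`` (the tie goes to bound, conservative against over-counting
    internalisation). Classes are exhaustive and exclusive.
    """
    if not np.isfinite(surface.cutoff_um):
        raise ValueError("cut-off height is not finite")
    out = particles.copy()
    out["class"] = np.where(out["z_um"] < surface.cutoff_um,
                            "internalised", "bound")
    return out


def summarize_internalisation(particles: pd.DataFrame,
                              cell_count: int | None = None,
                              ) -> InternalisationSummary:
    """Per-field counts, mean volumes and per-cell normalised count.

    Mean volumes of an empty class are reported as NaN.
    """
    internal = particles[particles["class"] == "internalised"]
    bound = particles[particles["class"] == "bound"]
    per_cell = None
    if cell_count is not None:
        if cell_count <= 0:
            raise ValueError("cell count must be positive")
        per_cell = len(internal) / cell_count
    return InternalisationSummary(
        n_internalised=len(internal),
        n_bound=len(bound),
        mean_internalised_volume_um3=(
            float(internal["volume_um3"].mean()) if len(internal) else np.nan),
        mean_bound_volume_um3=(
            float(bound["volume_um3"].mean()) if len(bound) else np.nan),
        internalised_per_cell=per_cell,
    )


def triangulated_area(height_map_um: np.ndarray, dy_um: float,
                      dx_um: float) -> float:
    """Surface area (µm²) of a height map triangulated on its grid.

    Each grid cell between four neighbouring nodes is split into two
    triangles; the area is the sum of the triangle areas. For a flat map this
    equals the lateral footprint spanned by the nodes.
    """
    h = np.asarray(height_map_um, float)
    if h.ndim != 2 or min(h.shape) < 2:
        raise ValueError("height map must be 2D with at least 2×2 nodes")
    if np.isnan(h).any():
        raise ValueError("height map contains missing nodes")
    p00 = h[:-1, :-1]
    p01 = h[:-1, 1:]
    p10 = h[1:, :-1]
    p11 = h[1:, 1:]

    def tri(ha, hb, hc, va, vb, vc):
        # cross product of the two edge vectors; (x, y) offsets from va
        e1 = (vb[0] - va[0], vb[1] - va[1], hb - ha)
        e2 = (vc[0] - va[0], vc[1] - va[1], hc - ha)
        cx = e1[1] * e2[2] - e1[2] * e2[1]
        cy = e1[2] * e2[0] - e1[0] * e2[2]
        cz = e1[0] * e2[1] - e1[1] * e2[0]
        return 0.5 * np.sqrt(cx ** 2 + cy ** 2 + cz ** 2)

    a = tri(p00, p01, p10, (0, 0), (dx_um, 0), (0, dy_um))
    b = tri(p11, p10, p01, (dx_um, dy_um), (0, dy_um), (dx_um, 0))
    return float(np.sum(a) + np.sum(b))


def apical_actin_area(stack: Stack3D, slice_range: tuple[int, int],
                      actin_channel: str = "actin",
                      threshold_method="otsu") -> float:
    """Apical actin surface area within a fixed z-slice subset (µm²).

    A height map is built from the uppermost supra-threshold voxel per column
    restricted to slices [z0, z1) and triangulated. Columns without signal in
    the subset take the subset's bottom face as height (flat floor), so a
    rougher apical surface always reports a larger area than a flat one.
    """
    z0, z1 = slice_range
    channel = stack.channels[actin_channel]
    if not (0 <= z0 < z1 <= channel.shape[0]):
        raise ValueError("slice range outside the stack")
    sub = channel[z0:z1]
    if not np.any(sub > 0):
        raise ValueError("no actin signal in the slice subset")
    dz, dy, dx = stack.voxel_size_um
    heights = _height_map(sub, dz, threshold_method) + z0 * dz
    heights = np.where(np.isnan(heights), z0 * dz, heights)
    return triangulated_area(heights, dy, dx)
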