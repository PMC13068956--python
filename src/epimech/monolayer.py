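"""2D and cross-sectional quantifications of epithelial monolayers.

Covers nuclei density, proliferation fraction, cell height, shape factor,
stress-fibre fraction, microvilli length, junctional/cytoplasmic and
nuclear/cytoplasmic intensity ratios, thresholded junctional intensity and
extrusion-event counting on time-lapse movies.

All physical outputs are in µm / µm² / cells·mm⁻²; intensity ratios are
dimensionless. Label maps use 0 for background and positive integers per
cell; pixel sizes are carried on the containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, registration, segmentation

__all__ = [
    "IntensityImage",
    "CellLabelMap",
    "CrossSectionMask",
    "resolve_threshold",
    "count_nuclei_density",
    "proliferation_fraction",
    "measure_cell_height",
    "shape_index",
    "shape_factor",
    "slim_rois",
    "stress_fibre_fraction",
    "microvilli_length",
    "junctional_cytoplasmic_ratio",
    "nuclear_cytoplasmic_ratio",
    "thresholded_junctional_mean",
    "count_extrusions",
]


@dataclass
class IntensityImage:
    """Single-channel fluorescence image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def area_mm2(self) -> float:
        return self.pixels.size * self.pixel_size_um ** 2 / 1e6


@dataclass
class CellLabelMap:
    """Instance segmentation: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def n_cells(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


@dataclass
class CrossSectionMask:
    """Binary x–z mask of a monolayer cross-section (rows = z, columns = x)."""

    mask: np.ndarray
    lateral_px_um: float
    axial_px_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.mask.ndim != 2:
            raise ValueError("cross-section mask must be 2D")
        if self.lateral_px_um <= 0 or self.axial_px_um <= 0:
            raise ValueError("pixel sizes must be positive")


def resolve_threshold(pixels: np.ndarray, method) -> float:
    """Turn a threshold spec into a value: a number is used as-is, 'otsu'
    applies Otsu's method, 'sigma:K' uses mean + K·std."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        return float(filters.threshold_otsu(pixels))
    if isinstance(method, str) and method.startswith("sigma"):
        k = float(method.split(":", 1)[1]) if ":" in method else 6.0
        return float(pixels.mean() + k * pixels.std())
    raise ValueError(f"unknown threshold method: {method!r}")


def count_nuclei_density(nuclei: IntensityImage,
                         gaussian_sigma: float = 2.0,
                         threshold_method="otsu",
                         min_size_px: int = 20,
                         min_separation_px: int = 5,
                         ) -> tuple[float, int, np.ndarray]:
    """Count nuclei and report the density in cells/mm².

    Pipeline: Gaussian smoothing → thresholding → watershed splitting of
    touching nuclei (distance-transform markers) → size filter → count.
    Returns (density, count, nucleus label image). An empty field returns
    density 0 with a warning.
    """
    smoothed = ndi.gaussian_filter(nuclei.pixels, gaussian_sigma)
    if np.allclose(smoothed, smoothed.flat[0]):
        warnings.warn("blank nuclei image: density 0", stacklevel=2)
        return 0.0, 0, np.zeros(nuclei.pixels.shape, int)
    thr = resolve_threshold(smoothed, threshold_method)
    mask = smoothed > thr
    if not mask.any():
        warnings.warn("no supra-threshold nuclei: density 0", stacklevel=2)
        return 0.0, 0, np.zeros(nuclei.pixels.shape, int)
    distance = ndi.distance_transform_edt(mask)
    coords = feature.peak_local_max(
        distance, min_distance=min_separation_px, labels=mask,
        exclude_border=False)
    markers = np.zeros(mask.shape, int)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)
    ids, sizes = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[sizes >= min_size_px]
    labels = np.where(np.isin(labels, keep), labels, 0)
    count = int(keep.size)
    density = count / nuclei.area_mm2
    return float(density), count, labels


def proliferation_fraction(positive, nuclei_count: int,
                           min_size_px: int = 4) -> float:
    """Percentage of marker-positive cells among all nuclei.

    ``positive`` is either an integer count or a binary mask whose connected
    components (≥ ``min_size_px``) are counted as positive cells.
    """
    if nuclei_count <= 0:
        raise ValueError("nuclei count must be positive")
    if np.isscalar(positive):
        n_pos = int(positive)
    else:
        mask = np.asarray(positive, bool)
        lab, _ = ndi.label(mask)
        _, sizes = np.unique(lab[lab > 0], return_counts=True)
        n_pos = int(np.sum(sizes >= min_size_px))
    return 100.0 * n_pos / nuclei_count


def measure_cell_height(section: CrossSectionMask,
                        n_positions: int = 10) -> tuple[np.ndarray, float]:
    """Cell height at ``n_positions`` lateral positions of a cross-section.

    At each sampled foreground column the height is the full vertical extent
    (max z − min z + 1 pixels) times the axial pixel size. Columns are taken
    uniformly across the foreground span. Returns (per-position heights, mean).
    """
    cols = np.nonzero(section.mask.any(axis=0))[0]
    if cols.size == 0:
        raise ValueError("cross-section has no foreground")
    n = min(n_positions, cols.size)
    picks = cols[np.unique(np.linspace(0, cols.size - 1, n).round().astype(int))]
    heights = []
    for c in picks:
        rows = np.nonzero(section.mask[:, c])[0]
        heights.append((rows.max() - rows.min() + 1) * section.axial_px_um)
    heights = np.asarray(heights, float)
    return heights, float(heights.mean())


def shape_index(perimeter: float, area: float) -> float:
    """Dimensionless shape factor q = P/√A (≥ 2√π, the circle's value)."""
    if area <= 0:
        raise ValueError("area must be positive")
    return perimeter / np.sqrt(area)


def _contour_perimeter_area(mask: np.ndarray, px: float,
                            smooth_window: int = 5) -> tuple[float, float]:
    """Sub-pixel polygon perimeter and shoelace area of the largest 0.5-level
    contour of a binary mask (padded so the contour closes).

    The closed contour is smoothed with a short circular moving average
    before measuring: the raw marching-squares staircase overestimates the
    length of curved boundaries by several percent, while smoothing leaves
    straight edges untouched up to a slight corner rounding.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)[:-1]  # drop the duplicated closing point
    if len(contour) > 2 * smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        contour = np.column_stack([
            np.convolve(np.concatenate([c[-smooth_window:], c,
                                        c[:smooth_window]]), kernel,
                        mode="same")[smooth_window:-smooth_window]
            for c in (contour[:, 0], contour[:, 1])])
    contour = np.vstack([contour, contour[:1]])  # re-close
    diffs = np.diff(contour, axis=0)
    perimeter = float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1]))) * px
    y, x = contour[:, 0], contour[:, 1]
    area = 0.5 * float(np.abs(np.dot(y, np.roll(x, -1)) - np.dot(x, np.roll(y, -1))))
    return perimeter, area * px ** 2


def shape_factor(cells: CellLabelMap) -> pd.DataFrame:
    """Per-cell area, perimeter and shape factor q = P/√A.

    The perimeter is the length of the sub-pixel boundary polygon (marching
    squares at level 0.5) and the area the polygon's shoelace area, which
    avoids the overestimation of pixel-edge counting. Cells touching the
    image border are excluded as truncated.
    """
    labels = cells.labels
    border = np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]]))
    rows = []
    for region in measure.regionprops(labels):
        if region.label in border:
            continue
        sl = region.slice
        mask = labels[sl] == region.label
        perimeter, area = _contour_perimeter_area(mask, cells.pixel_size_um)
        rows.append({
            "cell_id": int(region.label),
            "area_um2": area,
            "perimeter_um": perimeter,
            "shape_factor": shape_index(perimeter, area),
        })
    return pd.DataFrame(rows, columns=["cell_id", "area_um2", "perimeter_um",
                                       "shape_factor"])


def stress_fibre_fraction(flags, cells: CellLabelMap) -> dict:
    """Fraction of cells flagged (by manual point annotation) as bearing
    transcellular stress fibres.

    ``flags`` is either an integer count or an (N, 2) array of (x_um, y_um)
    points; points landing on background are bookkept separately and do not
    enter the percentage. Returns a dict with percent, counts and the number
    of background flags.
    """
    n_cells = cells.n_cells
    if n_cells == 0:
        raise ValueError("label map contains no cells")
    n_background = 0
    if np.isscalar(flags):
        n_flagged = int(flags)
    else:
        pts = np.asarray(flags, float).reshape(-1, 2)
        px = cells.pixel_size_um
        cols = np.clip((pts[:, 0] / px).astype(int), 0, cells.labels.shape[1] - 1)
        rows = np.clip((pts[:, 1] / px).astype(int), 0, cells.labels.shape[0] - 1)
        hit = cells.labels[rows, cols]
        n_background = int(np.sum(hit == 0))
        n_flagged = int(np.sum(hit > 0))
    if n_flagged > n_cells:
        raise ValueError("more flagged cells than cells in the field")
    return {
        "percent": 100.0 * n_flagged / n_cells,
        "n_flagged": n_flagged,
        "n_cells": n_cells,
        "n_background_flags": n_background,
    }


def microvilli_length(cross_section: IntensityImage,
                      gaussian_sigma: float = 1.0,
                      threshold_method="otsu",
                      min_size_px: int = 20) -> np.ndarray:
    """Approximate microvilli length from an apical-band cross-section.

    The image is Gaussian blurred and thresholded; each connected band region
    is fitted with an ellipse (second image moments) and the minor-axis
    length in µm is reported — the thickness of the apical band, used as a
    proxy for microvilli length.
    """
    blurred = ndi.gaussian_filter(cross_section.pixels, gaussian_sigma)
    thr = resolve_threshold(blurred, threshold_method)
    mask = blurred > thr
    mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1)
    if not mask.any():
        raise ValueError("thresholded mask is empty")
    labels, _ = ndi.label(mask)
    lengths = [r.axis_minor_length * cross_section.pixel_size_um
               for r in measure.regionprops(labels)]
    return np.asarray(lengths, float)


def slim_rois(labels: np.ndarray, shrink_px: int = 3,
              warn_empty: bool = False) -> np.ndarray:
    """Union of all cell ROIs after per-cell binary erosion by a disk of
    ``shrink_px``. Its complement is the junctional band along and between
    cell boundaries."""
    selem = morphology.disk(shrink_px)
    out = np.zeros(labels.shape, bool)
    for region in measure.regionprops(labels):
        sl = region.slice
        eroded = ndi.binary_erosion(labels[sl] == region.label,
                                    structure=selem)
        if warn_empty and not eroded.any():
            warnings.warn(f"cell {region.label} vanished after {shrink_px} px "
                          "erosion; excluded", stacklevel=3)
            continue
        out[sl] |= eroded
    return out


def junctional_cytoplasmic_ratio(image: IntensityImage, cells: CellLabelMap,
                                 shrink_px: int = 3) -> dict:
    """Junctional-to-cytoplasmic mean intensity ratio of one image.

    Cell ROIs are slimmed down by ``shrink_px`` (binary erosion); the
    inverted slimmed mask — the band along and between junctions — is the
    junctional region. The ratio of the junctional mean to the cytoplasmic
    mean (over all slimmed ROIs) is returned together with both means. Cells
    annihilated by the erosion are excluded with a warning.
    """
    if image.pixels.shape != cells.labels.shape:
        raise ValueError("image and label map are not congruent")
    cyto = slim_rois(cells.labels, shrink_px, warn_empty=True)
    if not cyto.any():
        raise ValueError("no cytoplasmic region left after erosion")
    junction = ~cyto
    j_mean = float(image.pixels[junction].mean())
    c_mean = float(image.pixels[cyto].mean())
    return {"ratio": j_mean / c_mean, "junctional_mean": j_mean,
            "cytoplasmic_mean": c_mean}


def nuclear_cytoplasmic_ratio(image: IntensityImage, nuclei: CellLabelMap,
                              cytoplasm_threshold_method="otsu") -> dict:
    """Nuclear-to-cytoplasmic mean grey value ratio.

    The nuclear mean is taken over all nucleus labels. Nuclear pixels are
    then zeroed and the remaining image thresholded; the cytoplasmic mean is
    the mean of the supra-threshold, non-zero region.
    """
    if image.pixels.shape != nuclei.labels.shape:
        raise ValueError("image and nuclei labels are not congruent")
    nuc_mask = nuclei.labels > 0
    if not nuc_mask.any():
        raise ValueError("no nuclei in the label map")
    nuclear_mean = float(image.pixels[nuc_mask].mean())
    rest = image.pixels.copy()
    rest[nuc_mask] = 0.0
    nonzero = rest[rest > 0]
    if nonzero.size == 0:
        raise ValueError("empty cytoplasmic region")
    if np.allclose(nonzero, nonzero[0]):
        cyto_mask = rest > 0
    else:
        thr = resolve_threshold(nonzero, cytoplasm_threshold_method)
        cyto_mask = rest > thr
    if not cyto_mask.any():
        raise ValueError("empty cytoplasmic region after thresholding")
    cyto_mean = float(rest[cyto_mask].mean())
    return {"ratio": nuclear_mean / cyto_mean, "nuclear_mean": nuclear_mean,
            "cytoplasmic_mean": cyto_mean}


def thresholded_junctional_mean(image: IntensityImage,
                                threshold_method="otsu") -> float:
    """Mean grey value within the supra-threshold (junctional) region only."""
    thr = resolve_threshold(image.pixels, threshold_method)
    sel = image.pixels > thr
    if not sel.any():
        raise ValueError("thresholded region is empty")
    return float(image.pixels[sel].mean())


def count_extrusions(movie: np.ndarray, n_cells: int,
                     pixel_size_um: float = 1.0,
                     gaussian_sigma: float = 2.0,
                     threshold_method: str | float = "sigma:10",
                     min_size_px: int = 4,
                     align: bool = True) -> tuple[int, float]:
    """Count extrusion events (very bright transient spots) in a time-lapse.

    Frames are aligned to the first frame by integer-pixel translation
    (phase cross-correlation), Gaussian smoothed, overlaid in a maximum
    intensity projection over time, thresholded and the size-filtered
    components counted. Returns (count, percent of ``n_cells``).

    The default threshold is mean + 10·std of the projection, which stays
    above the projected background texture when no event occurred.
    """
    movie = np.asarray(movie, float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be a (t, y, x) stack with ≥2 frames")
    smoothed = np.stack([ndi.gaussian_filter(f, gaussian_sigma) for f in movie])
    if align:
        ref = smoothed[0]
        aligned = [movie[0]]
        for raw, frame in zip(movie[1:], smoothed[1:]):
            # plain (unnormalised) cross-correlation: phase normalisation is
            # unreliable on smooth low-contrast fluorescence backgrounds
            shift, _, _ = registration.phase_cross_correlation(
                ref, frame, upsample_factor=1, normalization=None)
            aligned.append(np.roll(raw, shift.astype(int), axis=(0, 1)))
        smoothed = np.stack([ndi.gaussian_filter(f, gaussian_sigma)
                             for f in aligned])
    projection = smoothed.max(axis=0)
    thr = resolve_threshold(projection, threshold_method)
    mask = projection > thr
    mask = morphology.remove_small_objects(mask, max_size=min_size_px - 1)
    _, count = ndi.label(mask)
    if n_cells <= 0:
        raise ValueError("total cell count must be positive")
    return int(count), 100.0 * count / n_cells
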