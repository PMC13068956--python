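"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its parameters and a seed: the same
call is bit-identical across runs. Every generator returns ``(data, truth)``
where ``truth`` is a JSON-serialisable dict of the ground-truth parameters
(true modulus, true shift, true class per particle, true counts, ...) so the
analysis operations can be validated without any instrument data.

The defaults emulate the study conditions of a density-reduced retinal
pigment epithelium experiment: a 20 µm spherical indenter of 0.025 N/m
stiffness driven 6 µm into the tissue; Stokes/anti-Stokes Brillouin doublets
near 6.3 GHz; 80 µm depth scans at 2 µm steps over a hydrogel–monolayer–
medium sandwich; 50 × 50 µm shift maps at 1.5 µm lateral step; Voronoi
monolayer fields around 3000 cells/mm²; POS particle stacks partitioned by
a ~9 µm apical surface; and 15 h extrusion movies with ~2% bright events.

Noise is additive Gaussian with standard deviation ``noise_level`` times the
signal amplitude (the z-profile generator takes an absolute ``noise_ghz``
instead, since depth-scan noise is naturally quoted in GHz).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import expit

from .brillouin import BrillouinSpectrum, ShiftMap, ZProfile, lorentzian
from .indentation import ForceIndentationCurve, hertz_force
from .monolayer import CellLabelMap, IntensityImage, slim_rois
from .pos import Stack3D

__all__ = [
    "gen_hertz_curve",
    "gen_brillouin_spectrum",
    "gen_z_profile",
    "gen_shift_map",
    "gen_monolayer_images",
    "gen_pos_stack",
    "gen_extrusion_movie",
]

_UM = 1e-6


# ---------------------------------------------------------------------------
# nanoindentation

def gen_hertz_curve(E_eff_Pa: float,
                    radius_um: float = 10.0,
                    stiffness_N_per_m: float = 0.025,
                    z_c_um: float = 1.0,
                    max_displacement_um: float = 6.0,
                    n_samples: int = 241,
                    noise_level: float = 0.0,
                    seed: int = 0) -> tuple[ForceIndentationCurve, dict]:
    """Hertzian loading curve with a hidden contact point.

    Before contact (z < z_c) the force is exactly zero; after contact the
    force solves the displacement-control coupling of the Hertz law with the
    cantilever compliance,

        F = (4/3)·E_eff·√R·δ^{3/2},   δ = (z − z_c) − F/k.

    Gaussian noise of ``noise_level`` times the maximum force is added.
    """
    if E_eff_Pa <= 0 or radius_um <= 0 or stiffness_N_per_m <= 0:
        raise ValueError("modulus, radius and stiffness must be positive")
    if not 0 <= z_c_um < max_displacement_um:
        raise ValueError("contact point must lie within the displacement range")
    if noise_level < 0:
        raise ValueError("noise level must be non-negative")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, max_displacement_um, n_samples)
    compliance_um_per_N = 1.0 / stiffness_N_per_m / _UM

    force = np.zeros_like(z)
    for i, zi in enumerate(z):
        d = zi - z_c_um
        if d <= 0:
            continue
        upper = hertz_force(d, E_eff_Pa, radius_um)

        def residual(f: float, d: float = d) -> float:
            return f - hertz_force(d - f * compliance_um_per_N,
                                   E_eff_Pa, radius_um)

        force[i] = brentq(residual, 0.0, float(upper) + 1e-30, xtol=1e-18)

    if noise_level > 0:
        force = force + rng.normal(0.0, noise_level * force.max(), force.shape)
    curve = ForceIndentationCurve(z, force, radius_um, stiffness_N_per_m)
    truth = {
        "E_eff_Pa": E_eff_Pa,
        "z_c_um": z_c_um,
        "radius_um": radius_um,
        "stiffness_N_per_m": stiffness_N_per_m,
        "noise_level": noise_level,
        "seed": seed,
    }
    return curve, truth


# ---------------------------------------------------------------------------
# Brillouin spectra / profiles / maps

def gen_brillouin_spectrum(omega_B_GHz: float,
                           Gamma_GHz: float = 0.5,
                           I0: float = 1.0,
                           freq_range_GHz: float = 8.0,
                           freq_step_GHz: float = 0.01,
                           noise_level: float = 0.0,
                           seed: int = 0) -> tuple[BrillouinSpectrum, dict]:
    """Symmetric Stokes/anti-Stokes Lorentzian doublet with optional noise.

    The damped-oscillator Lorentzian is even in ω, so a single expression
    produces both peaks at ±ω_B with peak height I0/(π·Γ). Noise is Gaussian
    with sd ``noise_level`` × peak height.
    """
    if omega_B_GHz <= 0 or Gamma_GHz <= 0 or I0 <= 0:
        raise ValueError("shift, linewidth and amplitude must be positive")
    if freq_range_GHz <= omega_B_GHz:
        raise ValueError("frequency axis must cover both ±ω_B peaks")
    rng = np.random.default_rng(seed)
    freq = np.arange(-freq_range_GHz, freq_range_GHz + freq_step_GHz / 2,
                     freq_step_GHz)
    inten = lorentzian(freq, I0, Gamma_GHz, omega_B_GHz)
    if noise_level > 0:
        peak = I0 / (np.pi * Gamma_GHz)
        inten = inten + rng.normal(0.0, noise_level * peak, inten.shape)
    spectrum = BrillouinSpectrum(freq, inten)
    truth = {"omega_B_GHz": omega_B_GHz, "Gamma_GHz": Gamma_GHz, "I0": I0,
             "noise_level": noise_level, "seed": seed}
    return spectrum, truth


def gen_z_profile(gel_shift_GHz: float = 6.25,
                  peak_shift_GHz: float = 6.40,
                  medium_shift_GHz: float = 6.10,
                  peak_z_um: float = 20.0,
                  peak_width_um: float = 4.0,
                  transition_width_um: float = 3.0,
                  z_step_um: float = 2.0,
                  z_range_um: float = 80.0,
                  noise_ghz: float = 0.0,
                  with_peak: bool = True,
                  seed: int = 0) -> tuple[ZProfile, dict]:
    """Depth scan: hydrogel plateau → basal-side shift peak → medium plateau.

    The background is a smooth (logistic) gel→medium transition centred past
    the peak position; with ``with_peak`` a Gaussian bump is added whose
    amplitude is solved so the on-grid profile maximum equals
    ``peak_shift_GHz`` exactly at ``peak_z_um``. With ``with_peak=False`` the
    profile is the monotone non-increasing transition alone. ``noise_ghz`` is
    the absolute Gaussian noise sd in GHz.
    """
    if peak_width_um <= 0 or transition_width_um <= 0:
        raise ValueError("widths must be positive")
    if noise_ghz < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, z_range_um + z_step_um / 2, z_step_um)
    z_mid = peak_z_um + 2.0 * peak_width_um

    def background(zz):
        return medium_shift_GHz + (gel_shift_GHz - medium_shift_GHz) * expit(
            (z_mid - zz) / transition_width_um)

    shift = background(z)
    if with_peak:
        amp = peak_shift_GHz - background(peak_z_um)
        if amp <= 0:
            raise ValueError("peak shift must exceed the local background")
        shift = shift + amp * np.exp(-0.5 * ((z - peak_z_um) / peak_width_um) ** 2)
    if noise_ghz > 0:
        shift = shift + rng.normal(0.0, noise_ghz, shift.shape)
    profile = ZProfile(z, shift)
    truth = {
        "gel_shift_GHz": gel_shift_GHz,
        "peak_shift_GHz": peak_shift_GHz if with_peak else None,
        "medium_shift_GHz": medium_shift_GHz,
        "peak_z_um": peak_z_um if with_peak else None,
        "with_peak": with_peak,
        "noise_ghz": noise_ghz,
        "seed": seed,
    }
    return profile, truth


def _voronoi_labels(shape: tuple[int, int], seeds_px: np.ndarray) -> np.ndarray:
    tree = cKDTree(seeds_px)
    yy, xx = np.indices(shape)
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    _, idx = tree.query(pts)
    return (idx + 1).reshape(shape).astype(np.int32)


def gen_shift_map(core_shift_GHz: float = 6.37,
                  interstitium_shift_GHz: float = 6.33,
                  n_cells: int = 9,
                  map_size_um: float = 50.0,
                  step_um: float = 1.5,
                  band_um: float = 3.0,
                  noise_level: float = 0.0,
                  seed: int = 0) -> tuple[ShiftMap, np.ndarray, dict]:
    """Voronoi-compartmentalised Brillouin shift map.

    Cell interiors (eroded Voronoi regions) carry ``core_shift_GHz``; the
    boundary band of roughly ``band_um`` width — and the map border — carry
    ``interstitium_shift_GHz``. Returns (map, ground-truth core mask, truth).
    With ``n_cells=1`` the core is a single region ringed by interstitium.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    if step_um > map_size_um:
        raise ValueError("lateral step exceeds the map size")
    rng = np.random.default_rng(seed)
    n = int(round(map_size_um / step_um))
    seeds = rng.uniform(0, n, size=(n_cells, 2))
    labels = _voronoi_labels((n, n), seeds)
    erode_px = max(1, int(round(band_um / 2.0 / step_um)))
    selem = np.ones((2 * erode_px + 1, 2 * erode_px + 1), bool)
    core = np.zeros((n, n), bool)
    for lab in range(1, n_cells + 1):
        core |= ndi.binary_erosion(labels == lab, structure=selem,
                                   border_value=0)
    grid = np.where(core, core_shift_GHz, interstitium_shift_GHz)
    if noise_level > 0:
        amp = abs(core_shift_GHz - interstitium_shift_GHz)
        grid = grid + rng.normal(0.0, noise_level * amp, grid.shape)
    shift_map = ShiftMap(grid, step_um)
    truth = {
        "core_shift_GHz": core_shift_GHz,
        "interstitium_shift_GHz": interstitium_shift_GHz,
        "n_cells": n_cells,
        "n_core_voxels": int(core.sum()),
        "n_interstitium_voxels": int((~core).sum()),
        "noise_level": noise_level,
        "seed": seed,
    }
    return shift_map, core, truth


# ---------------------------------------------------------------------------
# monolayer fields

_DEFAULT_INTENSITIES = {
    "nuclei": 180.0,
    "junction": 200.0,
    "cytoplasm": 100.0,
    "nf_nuclear": 150.0,
    "nf_cytoplasm": 50.0,
}


def gen_monolayer_images(density_cells_per_mm2: float = 3000.0,
                         field_size_um: float = 316.2278,
                         pixel_size_um: float = 1.0,
                         nucleus_radius_um: float = 3.5,
                         junction_shrink_px: int = 3,
                         intensities: dict | None = None,
                         positive_fraction: float = 0.0,
                         noise_level: float = 0.0,
                         seed: int = 0):
    """Voronoi-tessellated epithelial field with ground-truth segmentation.

    One nucleus per cell is placed on a jittered grid so nuclei never touch;
    cells are the Voronoi regions of the nucleus centres. Channels:

    * ``nuclei`` — nucleus disks on dark background;
    * ``junction`` — junctional band at the junction intensity over a
      cytoplasmic background (their ratio is a ground truth);
    * ``cytoplasm`` — uniform cytoplasmic signal;
    * ``nuclear_factor`` — nuclear vs cytoplasmic intensity (for
      nuclear/cytoplasmic ratio recovery);
    * ``positive`` — binary mask of marker-positive nuclei
      (``positive_fraction`` of cells, rounded).

    Returns (channels dict of IntensityImage / mask, cell label map,
    nucleus label map, truth).
    """
    inten = dict(_DEFAULT_INTENSITIES)
    if intensities:
        inten.update(intensities)
    area_mm2 = field_size_um ** 2 / 1e6
    n_cells = int(round(density_cells_per_mm2 * area_mm2))
    if n_cells < 1:
        raise ValueError("density × area must give at least one cell")
    rng = np.random.default_rng(seed)

    g = int(np.ceil(np.sqrt(n_cells)))
    cell_pitch = field_size_um / g
    jitter_max = cell_pitch / 2.0 - nucleus_radius_um - 1.0
    if jitter_max < 0:
        raise ValueError("requested density packs nuclei beyond the "
                         "non-overlap limit for this nucleus radius")
    slots = rng.permutation(g * g)[:n_cells]
    gy, gx = np.divmod(slots, g)
    centers_um = np.column_stack([
        (gy + 0.5) * cell_pitch + rng.uniform(-jitter_max, jitter_max, n_cells),
        (gx + 0.5) * cell_pitch + rng.uniform(-jitter_max, jitter_max, n_cells),
    ])

    npx = int(round(field_size_um / pixel_size_um))
    centers_px = centers_um / pixel_size_um
    labels = _voronoi_labels((npx, npx), centers_px)

    yy, xx = np.indices((npx, npx))
    nuclei_labels = np.zeros((npx, npx), np.int32)
    r_px = nucleus_radius_um / pixel_size_um
    for k, (cy, cx) in enumerate(centers_px, start=1):
        y0, y1 = int(max(cy - r_px - 1, 0)), int(min(cy + r_px + 2, npx))
        x0, x1 = int(max(cx - r_px - 1, 0)), int(min(cx + r_px + 2, npx))
        patch = ((yy[y0:y1, x0:x1] - cy) ** 2 +
                 (xx[y0:y1, x0:x1] - cx) ** 2) <= r_px ** 2
        nuclei_labels[y0:y1, x0:x1][patch] = k
    nuclei_mask = nuclei_labels > 0

    # the junctional band is the complement of the slimmed cell ROIs, the
    # same construction the ratio measurement uses, so the drawn band and
    # the measured junctional region coincide pixel for pixel
    band = ~slim_rois(labels, junction_shrink_px)

    n_positive = int(round(positive_fraction * n_cells))
    positive_ids = rng.choice(np.arange(1, n_cells + 1), size=n_positive,
                              replace=False) if n_positive else np.array([], int)
    positive_mask = np.isin(nuclei_labels, positive_ids)

    def channel(img: np.ndarray, name: str) -> IntensityImage:
        if noise_level > 0:
            img = img + rng.normal(0.0, noise_level * img.max(), img.shape)
        return IntensityImage(np.clip(img, 0.0, None), pixel_size_um, name)

    channels = {
        "nuclei": channel(np.where(nuclei_mask, inten["nuclei"], 0.0), "nuclei"),
        "junction": channel(np.where(band, inten["junction"],
                                     inten["cytoplasm"]), "junction"),
        "cytoplasm": channel(np.full((npx, npx), inten["cytoplasm"]),
                             "cytoplasm"),
        "nuclear_factor": channel(np.where(nuclei_mask, inten["nf_nuclear"],
                                           inten["nf_cytoplasm"]),
                                  "nuclear_factor"),
        "positive": positive_mask,
    }
    truth = {
        "n_cells": n_cells,
        "density_cells_per_mm2": n_cells / area_mm2,
        "field_area_mm2": area_mm2,
        "n_positive": n_positive,
        "positive_fraction_percent": 100.0 * n_positive / n_cells,
        "junctional_cytoplasmic_ratio": inten["junction"] / inten["cytoplasm"],
        "nuclear_cytoplasmic_ratio": inten["nf_nuclear"] / inten["nf_cytoplasm"],
        "intensities": inten,
        "noise_level": noise_level,
        "seed": seed,
    }
    return (channels,
            CellLabelMap(labels, pixel_size_um),
            CellLabelMap(nuclei_labels, pixel_size_um),
            truth)


# ---------------------------------------------------------------------------
# POS stacks

def gen_pos_stack(n_internalised: int = 30,
                  n_bound: int = 20,
                  particle_volume_range_um3: tuple[float, float] = (0.3, 1.0),
                  monolayer_height_um: float = 9.1,
                  xy_extent_um: float = 24.0,
                  z_extent_um: float = 16.0,
                  voxel_size_um: tuple[float, float, float] = (0.1, 0.25, 0.25),
                  centroid_margin_um: float = 0.5,
                  noise_level: float = 0.0,
                  seed: int = 0) -> tuple[Stack3D, dict]:
    """3D stack with an apical actin slab and POS particles above/below it.

    The actin channel holds a 1 µm slab whose top face sits at
    ``monolayer_height_um`` (snapped to the voxel grid), so the recovered
    apical cut-off equals that height. Ellipsoidal particles are rasterised
    into the POS channel with centroids at least ``centroid_margin_um`` below
    (internalised) or above (bound) the cut-off and non-touching placements.
    Truth carries the achieved cut-off and each particle's rasterised
    centroid, voxel volume and class.
    """
    if n_internalised < 0 or n_bound < 0:
        raise ValueError("particle counts must be non-negative")
    if n_internalised == 0 and n_bound == 0:
        warnings.warn("no particles requested in either class", stacklevel=2)
    dz, dy, dx = voxel_size_um
    nz = int(round(z_extent_um / dz))
    ny = nx = int(round(xy_extent_um / dy))
    rng = np.random.default_rng(seed)

    iz_top = int(round(monolayer_height_um / dz)) - 1
    cutoff_um = (iz_top + 1) * dz
    slab_lo = max(int(round((monolayer_height_um - 1.0) / dz)), 0)
    actin = np.zeros((nz, ny, nx), np.float32)
    actin[slab_lo:iz_top + 1] = 200.0

    pos = np.zeros((nz, ny, nx), np.float32)
    vmin, vmax = particle_volume_range_um3
    placed: list[tuple[float, float, float, float]] = []  # z, y, x (µm), radius
    particles = []

    def place(cls: str):
        for _ in range(2000):
            vol = rng.uniform(vmin, vmax)
            r = (3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0)
            ax = r * rng.uniform(0.85, 1.15, size=3)  # semi-axes (z, y, x)
            margin = centroid_margin_um + max(dz, dy, dx)
            if cls == "internalised":
                z_lo, z_hi = ax[0] + dz, cutoff_um - margin
            else:
                z_lo, z_hi = cutoff_um + margin, z_extent_um - ax[0] - dz
            if z_hi <= z_lo:
                raise ValueError("stack too shallow for the requested "
                                 "particles and margins")
            cz = rng.uniform(z_lo, z_hi)
            cy = rng.uniform(ax[1] + dy, xy_extent_um - ax[1] - dy)
            cx = rng.uniform(ax[2] + dx, xy_extent_um - ax[2] - dx)
            if all((cz - pz) ** 2 + (cy - py) ** 2 + (cx - px) ** 2 >
                   (r + pr + 3 * max(dy, dx)) ** 2
                   for pz, py, px, pr in placed):
                placed.append((cz, cy, cx, r))
                return cz, cy, cx, ax
        raise RuntimeError("could not place a particle without contact; "
                           "reduce counts or volumes")

    order = ["internalised"] * n_internalised + ["bound"] * n_bound
    for cls in order:
        cz, cy, cx, ax = place(cls)
        z0 = max(int((cz - ax[0]) / dz) - 1, 0)
        z1 = min(int((cz + ax[0]) / dz) + 2, nz)
        y0 = max(int((cy - ax[1]) / dy) - 1, 0)
        y1 = min(int((cy + ax[1]) / dy) + 2, ny)
        x0 = max(int((cx - ax[2]) / dx) - 1, 0)
        x1 = min(int((cx + ax[2]) / dx) + 2, nx)
        zz = (np.arange(z0, z1)[:, None, None] + 0.5) * dz
        yy = (np.arange(y0, y1)[None, :, None] + 0.5) * dy
        xx = (np.arange(x0, x1)[None, None, :] + 0.5) * dx
        inside = (((zz - cz) / ax[0]) ** 2 + ((yy - cy) / ax[1]) ** 2 +
                  ((xx - cx) / ax[2]) ** 2) <= 1.0
        n_vox = int(inside.sum())
        if n_vox == 0:
            continue
        pos[z0:z1, y0:y1, x0:x1][inside] = 150.0
        idx = np.argwhere(inside)
        centroid = idx.mean(axis=0) + np.array([z0, y0, x0]) + 0.5
        particles.append({
            "z_um": float(centroid[0] * dz),
            "y_um": float(centroid[1] * dy),
            "x_um": float(centroid[2] * dx),
            "volume_um3": n_vox * dz * dy * dx,
            "n_voxels": n_vox,
            "class": cls,
        })

    if noise_level > 0:
        actin = actin + rng.normal(0.0, noise_level * 200.0, actin.shape
                                   ).astype(np.float32)
        pos = pos + rng.normal(0.0, noise_level * 150.0, pos.shape
                               ).astype(np.float32)
        actin = np.clip(actin, 0.0, None)
        pos = np.clip(pos, 0.0, None)

    stack = Stack3D({"actin": actin, "pos": pos}, voxel_size_um)
    truth = {
        "cutoff_um": cutoff_um,
        "monolayer_height_um": monolayer_height_um,
        "n_internalised": sum(p["class"] == "internalised" for p in particles),
        "n_bound": sum(p["class"] == "bound" for p in particles),
        "particles": particles,
        "noise_level": noise_level,
        "seed": seed,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# extrusion movies

def gen_extrusion_movie(n_cells: int = 500,
                        extrusion_fraction: float = 0.02,
                        n_frames: int = 60,
                        field_size_um: float = 316.2278,
                        pixel_size_um: float = 1.0,
                        background: float = 100.0,
                        spot_amplitude: float = 1000.0,
                        spot_sigma_px: float = 2.0,
                        noise_level: float = 0.05,
                        texture_level: float = 0.1,
                        drift_px_per_frame: tuple[int, int] = (0, 0),
                        seed: int = 0) -> tuple[np.ndarray, dict]:
    """Time-lapse with bright transient extrusion events over a textured
    monolayer background.

    ``round(n_cells × extrusion_fraction)`` Gaussian spots appear at random
    frames/positions (minimum mutual distance, two-frame duration). The
    background combines a static smooth texture (``texture_level`` of the
    background, the monolayer pattern frame registration locks onto) with
    per-frame photon noise (``noise_level``). Optional integer stage drift is
    applied cumulatively to whole frames so alignment can be exercised.
    Returns ((t, y, x) movie, truth with the event list).
    """
    if not 0 <= extrusion_fraction <= 1:
        raise ValueError("extrusion fraction must lie in [0, 1]")
    if n_frames < 2:
        raise ValueError("a movie needs at least 2 frames")
    rng = np.random.default_rng(seed)
    npx = int(round(field_size_um / pixel_size_um))
    n_events = int(round(n_cells * extrusion_fraction))

    smooth_field = ndi.gaussian_filter(rng.standard_normal((npx, npx)), 3.0)
    smooth_field /= smooth_field.std()
    texture = background * texture_level * smooth_field
    movie = background + texture[None] + background * noise_level * \
        rng.standard_normal((n_frames, npx, npx))
    movie = np.clip(movie, 0.0, None)

    margin = 10
    min_dist = 6 * spot_sigma_px
    events: list[dict] = []
    for _ in range(n_events):
        for _ in range(1000):
            y = rng.uniform(margin, npx - margin)
            x = rng.uniform(margin, npx - margin)
            if all((y - e["y_px"]) ** 2 + (x - e["x_px"]) ** 2 > min_dist ** 2
                   for e in events):
                break
        else:
            raise RuntimeError("could not place extrusion events apart")
        t = int(rng.integers(0, n_frames - 1))
        events.append({"t": t, "y_px": float(y), "x_px": float(x)})
        half = int(4 * spot_sigma_px)
        y0, y1 = int(y) - half, int(y) + half + 1
        x0, x1 = int(x) - half, int(x) + half + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        blob = spot_amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2 * spot_sigma_px ** 2))
        for tf in (t, min(t + 1, n_frames - 1)):
            movie[tf, y0:y1, x0:x1] += blob

    sy, sx = drift_px_per_frame
    if sy or sx:
        for tf in range(n_frames):
            movie[tf] = np.roll(movie[tf], (sy * tf, sx * tf), axis=(0, 1))

    truth = {
        "n_events": n_events,
        "n_cells": n_cells,
        "extrusion_fraction_percent": 100.0 * n_events / n_cells,
        "events": events,
        "noise_level": noise_level,
        "seed": seed,
    }
    return movie, truth
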