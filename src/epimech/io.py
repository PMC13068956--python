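"""Readers and writers for the pipeline's on-disk formats.

Curves, spectra, profiles and maps travel as headered CSV with fixed column
names (``z_um, force_N``; ``freq_GHz, intensity``; ``z_um, shift_GHz``;
``x_um, y_um, shift_GHz``); images and stacks as TIFF with a JSON metadata
sidecar (pixel/voxel sizes, channel order); ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .brillouin import BrillouinSpectrum, ShiftMap, ZProfile
from .indentation import ForceIndentationCurve
from .pos import Stack3D


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_truth(path, truth: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(truth), indent=1))


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text())


# --- force–indentation curves ---------------------------------------------

def save_curve(csv_path, curve: ForceIndentationCurve) -> None:
    """CSV (z_um, force_N) plus a JSON sidecar with the probe metadata."""
    csv_path = Path(csv_path)
    pd.DataFrame({"z_um": curve.z_um, "force_N": curve.force_N}
                 ).to_csv(csv_path, index=False)
    meta = {"R_um": curve.radius_um, "k_N_per_m": curve.stiffness_N_per_m}
    csv_path.with_suffix(".json").write_text(json.dumps(meta))


def load_curve(csv_path) -> ForceIndentationCurve:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ForceIndentationCurve(df["z_um"].to_numpy(),
                                 df["force_N"].to_numpy(),
                                 meta["R_um"], meta["k_N_per_m"])


# --- Brillouin data --------------------------------------------------------

def save_spectrum(path, spectrum: BrillouinSpectrum) -> None:
    pd.DataFrame({"freq_GHz": spectrum.freq_GHz,
                  "intensity": spectrum.intensity}).to_csv(path, index=False)


def load_spectrum(path) -> BrillouinSpectrum:
    df = pd.read_csv(path)
    return BrillouinSpectrum(df["freq_GHz"].to_numpy(),
                             df["intensity"].to_numpy())


def save_profile(path, profile: ZProfile) -> None:
    pd.DataFrame({"z_um": profile.z_um,
                  "shift_GHz": profile.shift_GHz}).to_csv(path, index=False)


def load_profile(path) -> ZProfile:
    df = pd.read_csv(path)
    return ZProfile(df["z_um"].to_numpy(), df["shift_GHz"].to_numpy())


def save_map_csv(path, shift_map: ShiftMap) -> None:
    """Long-format CSV (x_um, y_um, shift_GHz) of a raster map."""
    ny, nx = shift_map.grid_GHz.shape
    yy, xx = np.indices((ny, nx))
    pd.DataFrame({
        "x_um": xx.ravel() * shift_map.step_um,
        "y_um": yy.ravel() * shift_map.step_um,
        "shift_GHz": shift_map.grid_GHz.ravel(),
    }).to_csv(path, index=False)


def load_map_csv(path) -> ShiftMap:
    df = pd.read_csv(path)
    xs = np.unique(df["x_um"])
    ys = np.unique(df["y_um"])
    step = float(xs[1] - xs[0]) if xs.size > 1 else float(ys[1] - ys[0])
    grid = np.full((ys.size, xs.size), np.nan)
    iy = (df["y_um"].to_numpy() / step).round().astype(int)
    ix = (df["x_um"].to_numpy() / step).round().astype(int)
    grid[iy, ix] = df["shift_GHz"].to_numpy()
    return ShiftMap(grid, step)


def save_map_tiff(path, shift_map: ShiftMap) -> None:
    tifffile.imwrite(path, shift_map.grid_GHz.astype(np.float32),
                     metadata={"step_um": shift_map.step_um})


def load_map_tiff(path, step_um: float) -> ShiftMap:
    return ShiftMap(tifffile.imread(path).astype(float), step_um)


# --- stacks and movies -----------------------------------------------------

def save_stack(tiff_path, stack: Stack3D) -> None:
    """Channels stacked along the first axis, (c, z, y, x), with a JSON
    sidecar naming the channel order and voxel sizes."""
    tiff_path = Path(tiff_path)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    tifffile.imwrite(tiff_path, data)
    meta = {"channels": names, "voxel_size_um": list(stack.voxel_size_um)}
    tiff_path.with_suffix(".json").write_text(json.dumps(meta))


def load_stack(tiff_path) -> Stack3D:
    tiff_path = Path(tiff_path)
    data = tifffile.imread(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    channels = {name: data[i] for i, name in enumerate(meta["channels"])}
    return Stack3D(channels, tuple(meta["voxel_size_um"]))


def save_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie, np.float32))


def load_movie(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)
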