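"""Brillouin microscopy analysis: spectral fitting, z-profile features and
region statistics on 2D shift maps.

A Brillouin spectrum carries a Stokes / anti-Stokes doublet symmetric about
the laser line. Each peak is fitted with the damped-oscillator Lorentzian

    I(ω) = (I0/π) · Γ ω_B² / ((ω² − ω_B²)² + Γ² ω_B²),

whose maximum sits at ω = ±ω_B with height I0/(π·Γ). The voxel shift is the
arithmetic mean of the two sides' fitted |ω_B| (likewise Γ).

Depth scans through a monolayer on a hydrogel show a gel plateau, a shift
peak at the basal cell side, and a decay to the medium plateau; the profile
analyser returns either the refined peak (value, position) or, when no peak
exists, the plateau value before the shift drops off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, signal

__all__ = [
    "BrillouinSpectrum",
    "LorentzianPeakFit",
    "VoxelShift",
    "ZProfile",
    "ProfileFeature",
    "ShiftMap",
    "RegionStats",
    "Scaled8Bit",
    "lorentzian",
    "fit_lorentzian",
    "fit_doublet",
    "average_sides",
    "analyze_z_profile",
    "scale_map_to_8bit",
    "region_stats",
]


def lorentzian(omega: np.ndarray, i0: float, gamma: float,
               omega_b: float) -> np.ndarray:
    """Brillouin peak model; symmetric in ω, so one expression covers both
    the Stokes (ω<0) and anti-Stokes (ω>0) windows."""
    om2 = np.asarray(omega, float) ** 2
    return (i0 / np.pi) * gamma * omega_b ** 2 / (
        (om2 - omega_b ** 2) ** 2 + gamma ** 2 * omega_b ** 2)


@dataclass
class BrillouinSpectrum:
    """Frequency axis (GHz, signed, strictly increasing) and intensities."""

    freq_GHz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.freq_GHz = np.asarray(self.freq_GHz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.freq_GHz.shape != self.intensity.shape:
            raise ValueError("frequency and intensity arrays differ in length")
        if np.any(np.diff(self.freq_GHz) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if not (np.any(self.freq_GHz < 0) and np.any(self.freq_GHz > 0)):
            raise ValueError("axis must cover both Stokes (ω<0) and "
                             "anti-Stokes (ω>0) windows")

    def window(self, side: Literal["stokes", "anti-stokes"]) -> "tuple[np.ndarray, np.ndarray]":
        sel = self.freq_GHz < 0 if side == "stokes" else self.freq_GHz > 0
        return self.freq_GHz[sel], self.intensity[sel]


@dataclass
class LorentzianPeakFit:
    omega_B_GHz: float          # magnitude of the fitted shift
    Gamma_GHz: float
    I0: float
    side: Literal["stokes", "anti-stokes"]
    rss: float
    valid: bool = True


@dataclass
class VoxelShift:
    """Stokes/anti-Stokes average for one voxel."""

    omega_B_GHz: float
    Gamma_GHz: float
    single_sided: bool = False


@dataclass
class ZProfile:
    z_um: np.ndarray
    shift_GHz: np.ndarray

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, float)
        self.shift_GHz = np.asarray(self.shift_GHz, float)
        if self.z_um.shape != self.shift_GHz.shape:
            raise ValueError("z and shift arrays differ in length")
        if np.any(np.diff(self.z_um) <= 0):
            raise ValueError("z axis must be strictly increasing")


@dataclass
class ProfileFeature:
    kind: Literal["peak", "plateau", "indeterminate"]
    value_GHz: float
    z_position_um: float | None = None


@dataclass
class ShiftMap:
    """2D raster of Brillouin shifts (GHz); NaN marks missing voxels."""

    grid_GHz: np.ndarray
    step_um: float

    def __post_init__(self) -> None:
        self.grid_GHz = np.asarray(self.grid_GHz, float)
        if self.grid_GHz.ndim != 2:
            raise ValueError("shift map must be 2D")
        if self.step_um <= 0:
            raise ValueError("lateral step must be positive")


@dataclass
class RegionStats:
    region: Literal["core", "interstitium", "whole"]
    mean_GHz: float
    sd_GHz: float
    n_voxels: int


@dataclass
class Scaled8Bit:
    """8-bit rendering of a shift map plus the inverse-mapping parameters."""

    image: np.ndarray           # uint8
    valid: np.ndarray           # bool mask of finite voxels
    vmin_GHz: float
    vmax_GHz: float

    def inverse(self) -> np.ndarray:
        """Map bytes back to GHz (to within half a quantisation step)."""
        out = self.vmin_GHz + self.image.astype(float) / 255.0 * (
            self.vmax_GHz - self.vmin_GHz)
        out[~self.valid] = np.nan
        return out


def _initial_guess(freq: np.ndarray, inten: np.ndarray) -> tuple[float, float, float]:
    i = int(np.argmax(inten))
    omega_b0 = abs(float(freq[i]))
    peak = float(inten[i])
    # half-width from the samples above half maximum
    above = np.nonzero(inten >= peak / 2.0)[0]
    if above.size >= 2:
        gamma0 = max(float(abs(freq[above[-1]] - freq[above[0]])), 1e-3)
    else:
        gamma0 = 0.5
    i0 = peak * np.pi * gamma0
    return i0, gamma0, omega_b0


def fit_lorentzian(freq_GHz: np.ndarray, intensity: np.ndarray,
                   initial_guess: tuple[float, float, float] | None = None,
                   ) -> LorentzianPeakFit:
    """Nonlinear least-squares Lorentzian fit on one spectral window.

    Parameters are (I0, Γ, ω_B), all constrained positive. The window must
    contain a single peak and at least 7 samples. A failed optimisation
    returns a fit flagged ``valid=False`` (the voxel is then excluded).
    """
    freq = np.asarray(freq_GHz, float)
    inten = np.asarray(intensity, float)
    if freq.size < 7:
        raise ValueError("spectral window needs at least 7 samples")
    side: Literal["stokes", "anti-stokes"] = (
        "stokes" if np.median(freq) < 0 else "anti-stokes")
    p0 = initial_guess if initial_guess is not None else _initial_guess(freq, inten)
    try:
        popt, _ = optimize.curve_fit(
            lorentzian, freq, inten, p0=p0,
            bounds=([0.0, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return LorentzianPeakFit(np.nan, np.nan, np.nan, side, np.inf,
                                 valid=False)
    resid = inten - lorentzian(freq, *popt)
    return LorentzianPeakFit(
        omega_B_GHz=abs(float(popt[2])),
        Gamma_GHz=float(popt[1]),
        I0=float(popt[0]),
        side=side,
        rss=float(resid @ resid),
    )


def fit_doublet(spectrum: BrillouinSpectrum,
                ) -> tuple[LorentzianPeakFit, LorentzianPeakFit]:
    """Fit the Stokes and anti-Stokes windows of a full spectrum."""
    stokes = fit_lorentzian(*spectrum.window("stokes"))
    anti = fit_lorentzian(*spectrum.window("anti-stokes"))
    return stokes, anti


def average_sides(stokes: LorentzianPeakFit,
                  antistokes: LorentzianPeakFit) -> VoxelShift:
    """Combine the two sides into a voxel value by arithmetic averaging.

    If one side failed to fit, the valid side is used alone and the voxel is
    flagged ``single_sided``; if both failed, a ValueError is raised.
    """
    fits = [f for f in (stokes, antistokes) if f.valid]
    if not fits:
        raise ValueError("both spectral sides failed to fit")
    return VoxelShift(
        omega_B_GHz=float(np.mean([f.omega_B_GHz for f in fits])),
        Gamma_GHz=float(np.mean([f.Gamma_GHz for f in fits])),
        single_sided=len(fits) == 1,
    )


def _gauss_offset(z, c, a, mu, sigma):
    return c + a * np.exp(-0.5 * ((z - mu) / sigma) ** 2)


def analyze_z_profile(profile: ZProfile,
                      sg_window: int = 5,
                      sg_order: int = 2,
                      min_peak_width: int = 3,
                      min_peak_prominence: float = 0.02,
                      plateau_drop_threshold: float = 0.005,
                      drop_ma_window: int = 3) -> ProfileFeature:
    """Extract the basal peak or, failing that, the plateau of a depth scan.

    The profile is Savitzky–Golay smoothed; candidate peaks must exceed a
    minimum width (samples) and prominence (GHz). The winning peak is refined
    by a Gaussian-plus-offset fit bounded by the derivative's local maximum
    before and local minimum after the candidate. Without a peak, the onset
    of the gel→medium drop is located as the first point where a centred
    moving average of the derivative falls below −``plateau_drop_threshold``
    (GHz/µm); the plateau value is the mean of the smoothed shifts before the
    onset. Profiles with neither feature are flagged indeterminate.
    """
    z, y = profile.z_um, profile.shift_GHz
    if z.size < sg_window:
        raise ValueError("profile shorter than the smoothing window")
    smooth = signal.savgol_filter(y, sg_window, sg_order)
    deriv = np.gradient(smooth, z)

    peaks, props = signal.find_peaks(
        smooth, width=min_peak_width, prominence=min_peak_prominence)
    if peaks.size:
        p = int(peaks[np.argmax(smooth[peaks])])
        # bound the refinement window by the derivative extrema flanking the peak
        lo = 0
        for i in range(p - 1, 0, -1):
            if deriv[i] >= deriv[i - 1] and deriv[i] >= deriv[i + 1]:
                lo = i
                break
        hi = z.size - 1
        for i in range(p + 1, z.size - 1):
            if deriv[i] <= deriv[i - 1] and deriv[i] <= deriv[i + 1]:
                hi = i
                break
        lo = max(lo - 1, 0)
        hi = min(hi + 1, z.size - 1)
        zi, yi = z[lo:hi + 1], smooth[lo:hi + 1]
        try:
            if zi.size < 5:
                raise RuntimeError("window too short for refinement")
            p0 = (float(yi.min()), float(smooth[p] - yi.min()),
                  float(z[p]), max(float(z[hi] - z[lo]) / 4.0, 1e-3))
            popt, _ = optimize.curve_fit(_gauss_offset, zi, yi, p0=p0,
                                         maxfev=5000)
            c, a, mu, sigma = popt
            if a <= 0 or not (zi[0] <= mu <= zi[-1]):
                raise RuntimeError("refinement left the window")
            return ProfileFeature("peak", float(c + a), float(mu))
        except RuntimeError:
            return ProfileFeature("peak", float(smooth[p]), float(z[p]))

    kernel = np.ones(drop_ma_window) / drop_ma_window
    ma_deriv = np.convolve(deriv, kernel, mode="same")
    below = np.nonzero(ma_deriv < -plateau_drop_threshold)[0]
    if below.size == 0 or below[0] == 0:
        return ProfileFeature("indeterminate", np.nan)
    onset = int(below[0])
    return ProfileFeature("plateau", float(np.mean(smooth[:onset])))


def scale_map_to_8bit(shift_map: ShiftMap) -> Scaled8Bit:
    """Linearly rescale a shift map to 8-bit grey values (min→0, max→255,
    rounding half-up); missing voxels stay masked."""
    grid = shift_map.grid_GHz
    valid = np.isfinite(grid)
    vals = grid[valid]
    if vals.size < 2 or np.isclose(vals.min(), vals.max()):
        raise ValueError("map has no dynamic range to scale")
    vmin, vmax = float(vals.min()), float(vals.max())
    scaled = (grid - vmin) / (vmax - vmin) * 255.0
    image = np.zeros(grid.shape, dtype=np.uint8)
    # epsilon guards exact halves against binary float representation error
    image[valid] = np.floor(scaled[valid] + 0.5 + 1e-9).astype(np.uint8)
    return Scaled8Bit(image=image, valid=valid, vmin_GHz=vmin, vmax_GHz=vmax)


def region_stats(shift_map: ShiftMap, core_mask: np.ndarray) -> list[RegionStats]:
    """Mean/SD/count over the core, the interstitium (its complement) and
    the whole map. Missing voxels are excluded everywhere; an empty region is
    reported with n=0 and NaN statistics."""
    grid = shift_map.grid_GHz
    core_mask = np.asarray(core_mask, bool)
    if core_mask.shape != grid.shape:
        raise ValueError("core mask not congruent with the map grid")
    finite = np.isfinite(grid)
    out: list[RegionStats] = []
    for name, sel in (("core", core_mask & finite),
                      ("interstitium", ~core_mask & finite),
                      ("whole", finite)):
        vals = grid[sel]
        if vals.size == 0:
            out.append(RegionStats(name, np.nan, np.nan, 0))
        else:
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out.append(RegionStats(name, float(vals.mean()), sd, int(vals.size)))
    return out
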