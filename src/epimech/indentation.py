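"""Force–indentation curve analysis for spherical-probe nanoindentation.

Implements contact-point detection, the spherical Hertz fit with cantilever
compliance correction, R²-based quality filtering, matrix-scan aggregation,
and storage/loss moduli from small-amplitude oscillatory indentation.

Conventions
-----------
* Displacements are piezo positions in µm; forces in N; moduli in Pa.
* ``E_eff`` is the effective Young's modulus E/(1−ν²) of Hertzian contact:
  no Poisson ratio is assumed or reported separately.
* Indentation depth is compliance-corrected, δ = (z − z_c) − F/k, so that
  the probe deflection F/k does not count as sample deformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "ForceIndentationCurve",
    "HertzFitResult",
    "OscillationSweep",
    "ViscoelasticModuli",
    "MonolayerSummary",
    "NoContactError",
    "MalformedCurveError",
    "InsufficientDataError",
    "hertz_force",
    "indentation_depth",
    "detect_contact_point",
    "grid_search_contact_point",
    "fit_hertz",
    "filter_by_r2",
    "compute_dma_moduli",
    "aggregate_matrix_scan",
    "probing_depth_percent",
]

#: metres per micrometre
_UM = 1e-6


class NoContactError(ValueError):
    """The curve contains no detectable probe–sample contact."""


class MalformedCurveError(ValueError):
    """The loading segment is not usable (non-monotone, too short, ...)."""


class InsufficientDataError(ValueError):
    """Too few samples in the requested fit range."""


@dataclass
class ForceIndentationCurve:
    """One indentation cycle recorded in displacement control.

    Parameters
    ----------
    z_um:
        Piezo displacement (µm), strictly increasing over the loading segment.
    force_N:
        Cantilever force (N), same length as ``z_um``.
    radius_um:
        Spherical probe radius (µm).
    stiffness_N_per_m:
        Cantilever spring constant (N/m).
    segments:
        Optional per-sample labels (``load``/``hold``/``oscillate``/``unload``).
        When absent the whole curve is treated as the loading segment.
    """

    z_um: np.ndarray
    force_N: np.ndarray
    radius_um: float
    stiffness_N_per_m: float
    segments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.z_um.shape != self.force_N.shape:
            raise MalformedCurveError("z and force arrays differ in length")
        if self.z_um.size < 10:
            raise MalformedCurveError("curve needs at least 10 samples")
        if self.radius_um <= 0:
            raise ValueError("probe radius must be positive")
        if self.stiffness_N_per_m <= 0:
            raise ValueError("cantilever stiffness must be positive")

    def loading(self) -> "ForceIndentationCurve":
        """Return the loading segment (the full curve if unlabelled)."""
        if self.segments is None:
            return self
        sel = np.asarray(self.segments) == "load"
        return ForceIndentationCurve(
            self.z_um[sel], self.force_N[sel], self.radius_um,
            self.stiffness_N_per_m,
        )


@dataclass
class HertzFitResult:
    """Outcome of a Hertz fit on a single indentation."""

    z_c_um: float
    E_eff_Pa: float
    r_squared: float
    accepted: bool
    fit_depth_um: float
    n_samples: int = 0


@dataclass
class OscillationSweep:
    """Small-amplitude oscillation data around an operating indentation.

    Arrays are parallel over frequency. Amplitudes are the measured
    indentation and force oscillation amplitudes; ``phase_rad`` is the force
    lag behind indentation (0 for purely elastic response).
    """

    frequency_Hz: np.ndarray
    delta_amp_um: np.ndarray
    force_amp_N: np.ndarray
    phase_rad: np.ndarray
    delta_op_um: float

    def __post_init__(self) -> None:
        self.frequency_Hz = np.atleast_1d(np.asarray(self.frequency_Hz, float))
        self.delta_amp_um = np.atleast_1d(np.asarray(self.delta_amp_um, float))
        self.force_amp_N = np.atleast_1d(np.asarray(self.force_amp_N, float))
        self.phase_rad = np.atleast_1d(np.asarray(self.phase_rad, float))
        if np.any(self.delta_amp_um <= 0):
            raise ValueError("indentation amplitudes must be positive")
        if self.delta_op_um <= 0:
            raise ValueError("operating indentation must be positive")
        if np.any(self.delta_amp_um >= self.delta_op_um):
            raise ValueError("oscillation amplitude must be below the "
                             "operating indentation")


@dataclass
class ViscoelasticModuli:
    frequency_Hz: float
    storage_Pa: float
    loss_Pa: float


@dataclass
class MonolayerSummary:
    """Per-monolayer aggregate of accepted Hertz fits."""

    mean_E_eff_Pa: float
    scan_means_Pa: list[float] = field(default_factory=list)
    n_accepted_per_scan: list[int] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.scan_means_Pa)


def hertz_force(delta_um: np.ndarray, E_eff_Pa: float, radius_um: float) -> np.ndarray:
    """Hertz force F = (4/3)·E_eff·√R·δ^{3/2} for a spherical probe (N).

    ``delta_um`` is the true indentation depth in µm; negative depths give
    zero force.
    """
    delta_m = np.clip(np.asarray(delta_um, float), 0.0, None) * _UM
    return (4.0 / 3.0) * E_eff_Pa * np.sqrt(radius_um * _UM) * delta_m ** 1.5


def indentation_depth(curve: ForceIndentationCurve, z_c_um: float) -> np.ndarray:
    """Compliance-corrected indentation depth δ = (z − z_c) − F/k (µm)."""
    deflection_um = curve.force_N / curve.stiffness_N_per_m / _UM
    return (curve.z_um - z_c_um) - deflection_um


def _hertz_prefactor(curve: ForceIndentationCurve, z_c_um: float):
    """Profiled linear least squares: given z_c, the model F = a·δ^{3/2} is
    linear in a. Returns (a_hat, residual SSE, design vector x)."""
    delta = np.clip(indentation_depth(curve, z_c_um), 0.0, None)
    x = (delta * _UM) ** 1.5
    denom = float(x @ x)
    if denom == 0.0:
        a = 0.0
    else:
        a = float(x @ curve.force_N) / denom
        a = max(a, 0.0)
    resid = curve.force_N - a * x
    return a, float(resid @ resid), x


def _e_from_prefactor(a: float, radius_um: float) -> float:
    return a / ((4.0 / 3.0) * np.sqrt(radius_um * _UM))


def _low_load_segment(curve: ForceIndentationCurve,
                      load_fraction: float) -> ForceIndentationCurve:
    load = curve.loading()
    if np.any(np.diff(load.z_um) <= 0):
        raise MalformedCurveError("loading displacement not strictly increasing")
    f_max = float(np.max(load.force_N))
    if f_max <= 0:
        raise NoContactError("no positive force recorded: probe never touched "
                             "the sample")
    # keep everything up to the first sample exceeding the load fraction,
    # i.e. the baseline plus the low-force part of the contact region
    above = np.nonzero(load.force_N > load_fraction * f_max)[0]
    stop = int(above[0]) + 1 if above.size else load.z_um.size
    stop = max(stop, 10)
    return ForceIndentationCurve(
        load.z_um[:stop], load.force_N[:stop], load.radius_um,
        load.stiffness_N_per_m,
    )


def grid_search_contact_point(curve: ForceIndentationCurve,
                              load_fraction: float = 0.30) -> float:
    """Exhaustive contact-point search over the sample grid.

    Evaluates the profiled Hertz residual at every sample position of the
    low-load segment and returns the minimiser. Serves as a brute-force
    reference for :func:`detect_contact_point`.
    """
    seg = _low_load_segment(curve, load_fraction)
    sses = [_hertz_prefactor(seg, zc)[1] for zc in seg.z_um]
    return float(seg.z_um[int(np.argmin(sses))])


def detect_contact_point(curve: ForceIndentationCurve,
                         load_fraction: float = 0.30) -> float:
    """Detect the contact point by a joint (z_c, E_eff) Hertz fit.

    The fit is restricted to samples with force at most ``load_fraction`` of
    the maximum load. E_eff is profiled out in closed form, leaving a 1-D
    search over z_c: a coarse pass over the sample grid followed by a bounded
    refinement between the neighbouring grid points.

    Raises
    ------
    NoContactError
        If the force never rises above zero.
    MalformedCurveError
        If the loading displacement is not strictly increasing.
    """
    if not 0 < load_fraction <= 1:
        raise ValueError("load_fraction must lie in (0, 1]")
    seg = _low_load_segment(curve, load_fraction)

    sses = np.array([_hertz_prefactor(seg, zc)[1] for zc in seg.z_um])
    i = int(np.argmin(sses))
    lo = seg.z_um[max(i - 1, 0)]
    hi = seg.z_um[min(i + 1, seg.z_um.size - 1)]
    if hi <= lo:
        return float(seg.z_um[i])
    res = optimize.minimize_scalar(
        lambda zc: _hertz_prefactor(seg, zc)[1],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def fit_hertz(curve: ForceIndentationCurve, z_c_um: float,
              max_depth_um: float = 2.5,
              r2_threshold: float = 0.95) -> HertzFitResult:
    """Least-squares Hertz fit between the contact point and ``max_depth_um``.

    The model F = (4/3)·E_eff·√R·δ^{3/2} with δ = (z − z_c) − F/k is fitted on
    samples whose corrected depth lies in (0, max_depth_um]. R² is computed
    against the mean-force null on the fitted segment only; ``accepted`` is
    set iff R² exceeds ``r2_threshold``.
    """
    load = curve.loading()
    delta = indentation_depth(load, z_c_um)
    sel = (delta > 0) & (delta <= max_depth_um)
    if int(sel.sum()) < 5:
        raise InsufficientDataError(
            f"only {int(sel.sum())} samples with depth in (0, {max_depth_um}] µm")
    f_sel = load.force_N[sel]
    d_sel = np.clip(delta[sel], 0.0, None)
    x = (d_sel * _UM) ** 1.5
    a = float(x @ f_sel) / float(x @ x)
    a = max(a, 0.0)
    fitted = a * x
    ss_res = float(np.sum((f_sel - fitted) ** 2))
    ss_tot = float(np.sum((f_sel - f_sel.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    e_eff = _e_from_prefactor(a, load.radius_um)
    return HertzFitResult(
        z_c_um=float(z_c_um),
        E_eff_Pa=e_eff,
        r_squared=r2,
        accepted=r2 > r2_threshold,
        fit_depth_um=float(d_sel.max()),
        n_samples=int(sel.sum()),
    )


def filter_by_r2(results: Sequence[HertzFitResult],
                 threshold: float = 0.95) -> list[HertzFitResult]:
    """Keep fits with R² strictly above ``threshold``, preserving order."""
    return [r for r in results if r.r_squared > threshold]


def compute_dma_moduli(sweep: OscillationSweep,
                       radius_um: float) -> list[ViscoelasticModuli]:
    """Storage and loss moduli from an oscillation sweep.

    Linearised Hertzian contact around the operating indentation δ_op gives
    the contact stiffness S = 2·E·√(R·δ_op), so the complex modulus is

        E* = (F_amp/δ_amp)·e^{iφ} / (2·√(R·δ_op)),

    with E′ = Re(E*) (storage) and E″ = Im(E*) (loss).
    """
    if radius_um <= 0:
        raise ValueError("probe radius must be positive")
    ratio = sweep.force_amp_N / (sweep.delta_amp_um * _UM)  # N/m
    denom = 2.0 * np.sqrt(radius_um * _UM * sweep.delta_op_um * _UM)
    e_star = ratio * np.exp(1j * sweep.phase_rad) / denom
    return [
        ViscoelasticModuli(float(f), float(es.real), float(es.imag))
        for f, es in zip(sweep.frequency_Hz, e_star)
    ]


def aggregate_matrix_scan(
        scans: Sequence[Sequence[HertzFitResult]]) -> MonolayerSummary:
    """Aggregate accepted fits: mean within each matrix scan, then mean of
    scan means. Scans with no accepted fit are dropped with a warning."""
    scan_means: list[float] = []
    counts: list[int] = []
    for idx, scan in enumerate(scans):
        acc = [r.E_eff_Pa for r in scan if r.accepted]
        if not acc:
            warnings.warn(f"matrix scan {idx} has no accepted indentation",
                          stacklevel=2)
            continue
        scan_means.append(float(np.mean(acc)))
        counts.append(len(acc))
    if not scan_means:
        raise ValueError("no accepted indentations in any scan")
    return MonolayerSummary(
        mean_E_eff_Pa=float(np.mean(scan_means)),
        scan_means_Pa=scan_means,
        n_accepted_per_scan=counts,
    )


def probing_depth_percent(depth_um: float, cell_height_um: float) -> float:
    """Indented depth as a percentage of the cell height."""
    if cell_height_um <= 0:
        raise ValueError("cell height must be positive")
    return 100.0 * depth_um / cell_height_um
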