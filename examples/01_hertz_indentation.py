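"""Fit a spherical-probe indentation curve and aggregate a matrix scan.

Generates noise-free and noisy Hertzian loading curves (20 µm probe,
0.025 N/m cantilever), detects the contact point, fits the Hertz model up to
2.5 µm depth, filters by R² > 0.95 and averages a 3 × 16 matrix scan.
"""

from epimech import indentation as ind
from epimech import synthetic as syn

# one clean curve at a 694 Pa effective Young's modulus
curve, truth = syn.gen_hertz_curve(E_eff_Pa=694.0, z_c_um=1.0, seed=0)
z_c = ind.detect_contact_point(curve, load_fraction=0.30)
fit = ind.fit_hertz(curve, z_c, max_depth_um=2.5)
print(f"contact point: {z_c:.3f} um (true {truth['z_c_um']:.3f})")
print(f"E_eff: {fit.E_eff_Pa:.1f} Pa (true {truth['E_eff_Pa']:.0f}), "
      f"R^2 = {fit.r_squared:.4f}, accepted = {fit.accepted}")

# a monolayer: three matrix scans of 16 noisy indentations each
scans = []
for s in range(3):
    fits = []
    for i in range(16):
        c, _ = syn.gen_hertz_curve(694.0, noise_level=0.02, seed=16 * s + i)
        fits.append(ind.fit_hertz(c, ind.detect_contact_point(c)))
    scans.append(ind.filter_by_r2(fits, threshold=0.95))
summary = ind.aggregate_matrix_scan(scans)
print(f"monolayer mean E_eff over {summary.n_scans} scans: "
      f"{summary.mean_E_eff_Pa:.1f} Pa (scan means "
      f"{[round(m, 1) for m in summary.scan_means_Pa]})")
# the scan-mean average should sit within ~2% of the 694 Pa ground truth

# storage and loss moduli from an oscillation sweep at 1/2/4/10 Hz
sweep = ind.OscillationSweep([1, 2, 4, 10], [0.1] * 4,
                             [7.6e-10] * 4, [0.24] * 4, delta_op_um=2.5)
for m in ind.compute_dma_moduli(sweep, radius_um=10.0):
    print(f"{m.frequency_Hz:>4.0f} Hz: E' = {m.storage_Pa:6.1f} Pa, "
          f"E'' = {m.loss_Pa:5.1f} Pa")
# E' is the elastic (in-phase) and E'' the viscous (out-of-phase) response
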