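"""Monolayer morphometrics: density, shape factor, ratios, extrusions.

Builds a 300-cell Voronoi field with ground truth and runs the 2D image
quantifications on it, then counts extrusion events in a time-lapse.
"""

from epimech import monolayer as ml
from epimech import synthetic as syn

channels, cells, nuclei, truth = syn.gen_monolayer_images(
    density_cells_per_mm2=3000.0, seed=0)

density, count, _ = ml.count_nuclei_density(channels["nuclei"])
print(f"nuclei: {count} counted (truth {truth['n_cells']}), "
      f"density {density:.0f} cells/mm^2")

table = ml.shape_factor(cells)
print(f"shape factor q = P/sqrt(A): median {table['shape_factor'].median():.3f} "
      f"over {len(table)} interior cells (circle = 3.545)")

jc = ml.junctional_cytoplasmic_ratio(channels["junction"], cells)
nc = ml.nuclear_cytoplasmic_ratio(channels["nuclear_factor"], nuclei)
print(f"junctional/cytoplasmic ratio: {jc['ratio']:.3f} "
      f"(truth {truth['junctional_cytoplasmic_ratio']})")
print(f"nuclear/cytoplasmic ratio: {nc['ratio']:.3f} "
      f"(truth {truth['nuclear_cytoplasmic_ratio']})")

movie, mtruth = syn.gen_extrusion_movie(n_cells=500, extrusion_fraction=0.02,
                                        seed=1)
n_events, percent = ml.count_extrusions(movie, n_cells=500)
print(f"extrusions: {n_events} events = {percent:.1f}% of cells "
      f"(truth {mtruth['n_events']})")
# each number above is recovered from images alone; the truths come from
# the generator and would be unknown for real data
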