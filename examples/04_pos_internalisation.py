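"""Classify photoreceptor fragments as internalised vs bound in a 3D stack.

The apical actin surface defines a cut-off height; fragments with centroids
below it were taken up by the cells, the rest sit bound on the surface.
"""

from epimech import pos
from epimech import synthetic as syn

stack, truth = syn.gen_pos_stack(n_internalised=30, n_bound=20,
                                 monolayer_height_um=9.1, seed=0)

surface = pos.build_apical_surface(stack)
print(f"apical cut-off height: {surface.cutoff_um:.2f} um "
      f"(truth {truth['cutoff_um']:.2f})")

particles = pos.segment_particles(stack, min_voxels=4)
classified = pos.classify_particles(particles, surface)
summary = pos.summarize_internalisation(classified, cell_count=50)
print(f"internalised: {summary.n_internalised} (truth "
      f"{truth['n_internalised']}), bound: {summary.n_bound} "
      f"(truth {truth['n_bound']})")
print(f"mean internalised volume: {summary.mean_internalised_volume_um3:.3f} "
      f"um^3; per cell: {summary.internalised_per_cell:.2f}")

area = pos.apical_actin_area(stack, (0, stack.shape[0]))
footprint = (stack.shape[1] - 1) * (stack.shape[2] - 1) * \
    stack.voxel_size_um[1] * stack.voxel_size_um[2]
print(f"apical actin area: {area:.0f} um^2 (flat footprint {footprint:.0f})")
# a flat surface gives exactly the footprint; roughness only increases it
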