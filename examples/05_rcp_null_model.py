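"""Radial density profile of a layered spheroid vs the RCP null model.

A two-layer point phantom (outer region twice as dense as the core, boundary
at NDS 0.5) is profiled against a 10-replicate random-cell-position (RCP)
ensemble inside the same alpha shape: uniformly placed non-overlapping
spheres matched in number.  A real structure shows up as a deviation of the
profile from the flat RCP curve.
"""

import numpy as np

import spheroidkit as sk
from spheroidkit.phantoms import sample_ball_points

pts = sample_ball_points(600, 63.0, min_dist=8.0, layering=(0.5, 2.0), seed=12)
shape = sk.build_alpha_shape(pts, alpha=90.0)

g = sk.build_pcg(pts, threshold=18.0)
deg = np.array([g.graph.degree[i] for i in range(len(pts))], float)
_, nds = sk.depth_from_surface(pts, shape)
real = sk.radial_profile(deg, nds, n_bins=10)

spec = sk.RcpSpec(n_cells=len(pts), sphere_radius=4.0, n_reps=10, seed=5)
rcp, _ = sk.rcp_profile_ensemble(shape, spec, edge_distance_threshold=18.0, n_bins=10)

print("NDS bin centre | real density | RCP density (+- SE)")
for c, m_r, m_n, se in zip(real.bin_centers, real.mean, rcp.mean, rcp.se):
    print(f"     {c:4.2f}      |    {m_r:5.1f}     |  {m_n:5.1f} +- {se:.2f}")
# The real profile drops past NDS 0.5 (the sparser core); the RCP curve
# stays flat once deeper than one graph threshold from the surface.
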