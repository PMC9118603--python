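"""Build the cross-classified domain lattice and district adjacency.

The estimation domains are the full cross of 64 districts (nested in 8
divisions) with residence (rural/urban), five child age groups and sex
— 1280 domains.  District adjacency feeds the intrinsic-CAR precision
matrix used by the spatial random effect.
"""

import numpy as np

import mlsae

lattice = mlsae.example_lattice(n_districts=64, n_divisions=8)
print(f"domains: {lattice.n_domains}  (64 districts x 2 x 5 x 2)")
print(lattice.frame.head(4).to_string(index=False))

cells = mlsae.margin_map(lattice, ("district",))
print(f"\ndistrict margin: {cells.nunique()} cells of "
      f"{int(cells.value_counts().iloc[0])} domains each")

graph = mlsae.grid_adjacency(lattice.districts)
Q = mlsae.car_precision(graph, order=lattice.districts)
print(f"\nICAR precision: {Q.shape[0]}x{Q.shape[1]}, "
      f"row sums all zero: {np.allclose(Q.sum(axis=1), 0)}, "
      f"rank: {np.linalg.matrix_rank(Q)} (n-1: one sum-to-zero constraint)")
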