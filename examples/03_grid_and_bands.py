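"""Equal-area gridding and latitudinal banding.

Every sequence is assigned to a 200-km cell of a Behrmann (cylindrical
equal-area) world grid; per-cell genetic diversity is later summarized in
10-degree latitude bands.
"""

import pandas as pd

from macrodiv import diversity, grid

x, y = grid.project(180.0, 0.0)
print(f"antimeridian on the equator projects to x = {x/1e6:.2f} thousand km")

cell = grid.cell_of(5.2, -12.7)
lon, lat = grid.cell_centroid_lonlat(*cell)
print(f"point (5.2E, 12.7S) -> cell {grid.cell_id(*cell)} "
      f"(centroid lon {lon:.2f}, lat {lat:.2f})")
band = grid.band_of(-12.7)
print(f"latitude -12.7 falls in band [{band.lower}, {band.upper})")

cells = pd.DataFrame({
    "cell_id": ["a", "b", "c"],
    "centroid_lat": [-15.0, -12.0, 31.0],
    "gd": [0.012, 0.020, 0.004],
})
print(diversity.band_aggregate(cells).to_string(index=False))
# mean_gd per band, with ci = sd/sqrt(n_cells) across cells (NaN for a
# single-cell band).
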