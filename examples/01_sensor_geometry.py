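"""Sensor geometry: ground sampling distance and plot pixel windows.

Computes the ground footprint of one pixel for the two camera setups used
in a typical low-altitude survey, then maps a 0.72 m x 1.8 m field plot
onto DSM pixels and takes the central cell of its 3x3 partition.
"""

import numpy as np

import canopygp as cg

# A compact camera (6.2 mm sensor, 4608 px wide, 4.3 mm lens) flown at 40 m
compact = cg.SensorSpec(6.2, 4.7, 4608, 3456, 4.3)
gsd40 = cg.ground_sampling_distance(compact, 40.0)
print(f"compact camera @ 40 m : {gsd40 * 1000:.1f} mm/px (~{round(gsd40 * 1000)} mm)")

# An APS-C camera (23.5 mm sensor, 6000 px wide, 20 mm lens) flown at 50 m
apsc = cg.SensorSpec(23.5, 15.6, 6000, 4000, 20.0)
gsd50 = cg.ground_sampling_distance(apsc, 50.0)
print(f"APS-C camera  @ 50 m : {gsd50 * 1000:.1f} mm/px (~{round(gsd50 * 1000)} mm)")

# Map one plot onto a 13 mm/px raster: the window is the plot's pixel
# footprint, the central block is the only part analysed for height
raster = cg.Raster(np.zeros((300, 100)), resolution=0.013, origin=(0.0, 3.9))
window = cg.plot_window((0.0, 3.9, 0.72, 1.8), raster)
block = cg.central_block(window)
print(f"0.72 m x 1.8 m plot  : {window.n_cols} x {window.n_rows} px")
print(f"central 3x3 block    : {block.n_cols} x {block.n_rows} px")
# The central block keeps the statistic away from plot margins, which are
# contaminated by neighbouring plants.
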