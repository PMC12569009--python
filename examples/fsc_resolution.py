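"""Fourier-shell-correlation resolution of two half-data reconstructions.

Splits a synthetic microbubble track set 50/50, renders two density
volumes, and reads the resolution where the FSC curve crosses the half-bit
information threshold.
"""

import numpy as np

from lensulm.grids import VolumeGrid
from lensulm.phantoms import advect_microbubbles, make_vessel_tree
from lensulm.quantify import fourier_shell_correlation
from lensulm.ulm import Localization, MicrobubbleTrack, tracks_to_maps

rng = np.random.default_rng(7)
tree = make_vessel_tree(5, 0.6, 3.0, seed=7, root_position=np.array([0.0, 0.0, 10.0]))
pop = advect_microbubbles(tree, 8.0, np.arange(250) * 3.2e-3, seed=8)

jitter = 0.1  # mm of localization noise
tracks = []
for bid in np.unique(pop.ids):
    m = pop.ids == bid
    pos = pop.positions[m] + rng.normal(0, jitter, (m.sum(), 3))
    if len(pos) < 2:
        continue
    locs = [Localization(tuple(p), f, 1.0, 0.9) for f, p in enumerate(pos)]
    vel = np.diff(pos, axis=0) * 312.5
    tracks.append(MicrobubbleTrack(locs, vel, int(bid)))

rng.shuffle(tracks)
half = len(tracks) // 2
grid = VolumeGrid((-15, -15, 8), (0.12, 0.12, 0.12), (250, 250, 250))
vol_a = tracks_to_maps(tracks[:half], grid).density
vol_b = tracks_to_maps(tracks[half:], grid).density

res = fourier_shell_correlation(vol_a, vol_b)
print(f"tracks: {len(tracks)} split into {half} + {len(tracks) - half}")
if res.resolution_mm is not None:
    print(f"FSC half-bit resolution: {res.resolution_mm*1000:.0f} um")
else:
    print("FSC never crossed the half-bit curve (resolution beyond Nyquist)")
print("more tracks -> denser maps -> finer FSC resolution, saturating at the")
print("localization jitter scale")
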