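"""Single-fiber sensitivity profile by Monte Carlo photon transport.

Launches photon packets from a 5.1-um fiber core into tissue with 490-nm
optical properties and prints how the excitation sensitivity falls off along
the fiber axis, the energy-conservation tally, and the tissue volume that
receives at least 2.5 mW/mm^2 for three coupled-power levels.
"""

import numpy as np

from fibermix import bundle, optics

grid = optics.VoxelGrid(voxel_size=0.005, dims=(100, 100, 100))  # 0.5-mm cube
launch = optics.LaunchSpec()
profile = optics.simulate_fluence(300_000, launch, optics.TISSUE_490, grid,
                                  seed=1, wavelength="490nm")

book = profile.bookkeeping
balance = (book["launched"] + book["roulette_gain"]
           - book["deposited"] - book["escaped"] - book["roulette_killed"])
print(f"launched {book['launched']:.0f} packets; "
      f"absorbed {book['deposited']:.0f}, escaped {book['escaped']:.0f}, "
      f"conservation residual {abs(balance) / book['launched']:.1e} (relative)")

z, fz = profile.on_axis()
zf, ff = z[z > 0], fz[z > 0]   # ahead of the tip
print("\non-axis sensitivity (fraction of the near-tip value) vs depth:")
for depth in (0.0025, 0.025, 0.05, 0.1, 0.2):
    iz = np.argmin(np.abs(zf - depth))
    print(f"  z = {zf[iz] * 1000:5.1f} um   {ff[iz] / ff[0]:7.4f}")

print("\nvolume receiving >= 2.5 mW/mm^2 (the usable excitation zone):")
for power in (1.25, 2.5, 5.0):
    intensity = bundle.scale_fluence(profile, power)
    vol = bundle.iso_contour_volume(intensity, grid.voxel_size, 2.5)
    print(f"  {power:4.2f} uW coupled -> {vol * 1e6:8.0f} x 10^-6 mm^3")
print("\nHigher coupled power extends the excitation zone; the profile is a")
print("narrow forward cone set by the fiber's numerical aperture.")
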