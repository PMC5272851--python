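"""The partial-volume mechanism separating the two SBR quantifiers.

Blur the ground-truth phantom at increasing resolution FWHM and quantify:
the BRASS-style concentration estimate collapses while the Southampton
(specific uptake size index) estimate, which captures displaced counts in
a generous VOI and converts them via an assumed striatal volume, barely
moves.  True SBR is 9 throughout.
"""

import numpy as np
from scipy import ndimage

import spectsbr as s

spec = s.PhantomSpec(filling_ratio=10.0).desk_scale()
vol = s.build_phantom(spec)
to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

print("blur FWHM   BRASS   Southampton")
for fwhm in (0.0, 4.0, 8.0, 12.0, 16.0):
    data = (
        ndimage.gaussian_filter(vol.activity, fwhm * to_sigma / spec.voxel_size_mm)
        if fwhm else vol.activity
    )
    blurred = s.ReconVolume(data, spec.voxel_size_mm, {"recon": "truth", "camera": "-"})
    by = {}
    for rec in s.quantify_volume(blurred, spec):
        by.setdefault(rec.method, []).append(rec.sbr)
    print(
        f"{fwhm:7.0f} mm   {np.mean(by['brass']):5.2f}   {np.mean(by['southampton']):5.2f}"
    )

print("\n-> the widening gap is the partial-volume effect; it is the largest")
print("   single driver of differences between SBR normal databases.")
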