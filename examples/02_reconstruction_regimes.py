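"""Reconstruct one phantom scan under three regimes and quantify both ways.

Shows the two dominant effects on the measured SBR: the losses removed by
attenuation and scatter corrections (IRNC -> IRAC -> ACSC), and the
partial-volume gap between the tight-VOI (BRASS-style) and large-VOI
(Southampton) quantifiers.  The true SBR here is 9.
"""

import spectsbr as s

spec = s.PhantomSpec(filling_ratio=10.0).desk_scale()
vol = s.build_phantom(spec)
cam = s.CameraModel(name="camB", psf_fwhm_mm=12.0)
scan = s.simulate_scan(vol, cam, seed=7)
scan.meta["study_type"] = "phantom"

for method in ("IRNC", "IRAC", "ACSC"):
    recon = s.reconstruct_study(scan, method)
    for rec in s.quantify_volume(recon, spec):
        print(f"{method} {rec.method:11s} {rec.side}  SBR = {rec.sbr:.2f}")

print(
    "\n-> corrections recover the Southampton value toward the truth of 9;\n"
    "   the BRASS-style value stays low: that residual is the partial-volume\n"
    "   effect of tight anatomical VOIs, later absorbed by phantom calibration."
)
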