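"""Camera-specific phantom calibration and its round-trip accuracy.

Scan the phantom at filling ratios 10:1 ... 1:1 on two cameras with
different resolution, reconstruct with ACSC, fit the recovery line
measured = slope x true + intercept per camera and quantifier, and apply
it back to the measurements.
"""

import numpy as np

import spectsbr as s

spec = s.PhantomSpec(filling_ratio=10.0).desk_scale()
cameras = [
    s.CameraModel(name="sharp", psf_fwhm_mm=8.0, seed=1),
    s.CameraModel(name="blurry", psf_fwhm_mm=16.0, seed=2),
]

records = []
for cam in cameras:
    for _, scan in s.generate_phantom_series(cam, (10, 8, 5, 4, 1), seed=cam.seed,
                                             geometry=spec):
        recon = s.reconstruct_study(scan, "ACSC")
        records.extend(s.quantify_volume(recon, spec))

factors = s.fit_calibration_table(records)
for (camera, method, recon), f in sorted(factors.items()):
    print(f"{camera:6s} {method:11s} {recon}: slope {f.slope:.3f} "
          f"intercept {f.intercept:+.3f} (r^2 {f.r_squared:.3f})")

errors = []
for rec in records:
    f = factors[(rec.camera, rec.method, rec.recon)]
    calibrated = s.apply_calibration(rec, f)
    if rec.true_sbr >= 2.5:
        errors.append(abs(calibrated.sbr - rec.true_sbr) / rec.true_sbr)
print(f"\nround-trip mean |error| over clinical-range fillings: "
      f"{100 * np.mean(errors):.1f}%")
print("-> slopes below 1 quantify the losses each camera/method pair suffers;")
print("   the blurry camera's BRASS slope is smallest (strongest partial volume).")
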