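"""A small end-to-end normal-database experiment.

One call simulates phantom series and a healthy-control cohort on two
cameras, reconstructs with and without corrections, quantifies both ways,
applies phantom calibration and reports the database statistics.  The key
output is the residual post-calibration ACSC-IRNC difference: phantom
factors cannot remove the extra-brain septal penetration present only in
human scans.
"""

import spectsbr as s

cfg = s.ExperimentConfig(
    cameras=[
        s.CameraModel(name="camA", psf_fwhm_mm=9.0, seed=1),
        s.CameraModel(name="camB", psf_fwhm_mm=14.0, seed=2),
    ],
    phantom_ratios=(10.0, 8.0, 5.0, 4.0, 1.0),
    n_subjects=6,
    recon_methods=("IRNC", "ACSC"),
    seed=3,
)
report = s.run_experiment(cfg)

print("Age-corrected summary (reference age 65):")
print(report.summary.to_string(index=False))

print("\nPairwise comparisons (% difference, paired t with Bonferroni):")
cols = ["comparison", "method", "pct_difference", "p_value", "significant"]
print(report.comparisons[cols].to_string(index=False))

print("\nScatter-window report (phantom vs human, per camera):")
print(report.scatter_report.to_string(index=False))

print(
    "\n-> ACSC-IRNC stays positive after calibration and the upper-window\n"
    "   extra-brain contribution is positive on every camera: the phantom\n"
    "   provides only a first-order, camera-level correction."
)
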