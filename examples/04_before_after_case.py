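"""Full before/after stenting analysis: velocity retention and expansion.

A paired phantom shares one vessel path; after "stenting" the lumen is
wider (proximal x1.185, middle x1.2) and the bolus slower (x0.647).  The
pipeline recovers both effects: the velocity retention ratio
(after/before, %) and the per-site diameter expansion (%).
"""

from ticvelo import AnalysisConfig, PhantomConfig, generate_paired_case, run_case

config_before = PhantomConfig(shape=(96, 1024), bolus_velocity=309.4, seed=5)
(seq_before, truth_before), (seq_after, truth_after) = generate_paired_case(
    config_before,
    expansion_factor=(1.185, 1.2),  # proximal, middle radius multipliers
    velocity_factor=0.647,
)

report = run_case(
    seq_before,
    seq_after,
    config=AnalysisConfig(roi_strategy="arc_fraction", roi_fractions=(0.05, 0.95)),
    case_id="demo",
    vessel="helical",
)

print(f"velocity before: {report.velocity_before_mean:.1f} ± "
      f"{report.velocity_before_sd:.1f} mm/s (truth {truth_before.bolus_velocity})")
print(f"velocity after:  {report.velocity_after_mean:.1f} ± "
      f"{report.velocity_after_sd:.1f} mm/s (truth {truth_after.bolus_velocity:.1f})")
print(f"retention:       {report.retention_pct}% (truth 64.7%)")
for site in ("proximal", "middle"):
    d = report.diameters_mm[site]
    print(f"expansion {site:8s} {d['before']:.2f} -> {d['after']:.2f} mm "
          f"= {report.expansion_pct[site]}%")
# Retention differs from truth only through frame quantization of the
# two integer peak shifts; diameters through the FWHM pixel resolution.
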