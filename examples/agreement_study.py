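"""A two-tool agreement study on a synthetic cohort.

Simulates 186 participants whose Nova shares are observed by two tools
with within-tool noise implying a per-coordinate ICC of about 0.72, then
runs the full agreement analysis: paired means with 95% CIs, ICC(3,1)
with bands, and quintile cross-classification with PABAK.
"""

from novarecall import CohortSpec, agreement_report, simulate_paired_shares

spec = CohortSpec(n_participants=186, seed=42)
print(f"implied ALR-scale ICC: {spec.implied_icc():.3f}")

frame = simulate_paired_shares(spec, tools=("self_report", "reference"))
report = agreement_report(frame, "self_report", "reference")
print(report.render_text())
# Both tools see the same latent diets, so their means agree and the
# paired tests are non-significant.  Share-scale ICCs land a little below
# the ALR-scale 0.72 (the simplex transform compresses extreme shares),
# and PABAK around 0.2-0.3 means same-fifth ranking agreement well above
# the chance level of 20%.
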