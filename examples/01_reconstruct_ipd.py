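"""Rebuild patient-level data from a digitized Kaplan-Meier curve.

Simulates one chemotherapy study, emulates its plot digitization (0.5-month
click grid, numbers at risk every 3 months), inverts the curve back into
pseudo-IPD with the Guyot algorithm, and compares medians.
"""

import numpy as np

import ros1ce as r

spec = r.StudySpec(
    "chemo_demo", "chemotherapy", n=60, true_family="log_logistic",
    median=7.8, shape=1.5, admin_cutoff_months=24.0, seed=11,
)
records = r.simulate_ipd_study(spec)
curve = r.emulate_digitization(records, grid=0.5, jitter=0.005, risk_every=3.0,
                               rng=np.random.default_rng(1))
reconstructed = r.reconstruct_ipd(curve)

km_true = r.km_estimate(records)
km_recon = r.km_estimate(reconstructed)
grid = np.linspace(0, float(km_true.times.max()), 300)
sup = np.max(np.abs(km_true.evaluate(grid) - km_recon.evaluate(grid)))

print(f"study n = {len(records)}, reconstructed n = {len(reconstructed)}")
print(f"true KM median      = {km_true.median:.2f} months")
print(f"reconstructed median = {km_recon.median:.2f} months")
print(f"sup-norm distance between KM curves = {sup:.3f}")
# The reconstruction recovers the published curve's survival experience from
# plot coordinates alone; the sup-norm gap reflects only click-grid coarseness.
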