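"""Evaluate both treatment strategies through the Markov cohort model.

Uses the selected survival fit from the benchmark suite and the published
cost/utility inputs; prints discounted per-state costs, LYs, QALYs and the
incremental cost-effectiveness ratios.
"""

import ros1ce as r

suite = r.generate_benchmark_suite(seed=1)
fits = r.fit_all_families(suite.true_ipd, shared_treatment=True, seed=1)
best, _ = r.select_distribution(fits)

cfg = r.ModelConfig()
pfs = r.PFSInputs.from_fit(best)
res_c, res_h, icer = r.evaluate_incremental(cfg, pfs)

for res in (res_c, res_h):
    print(f"\n{res.arm} strategy")
    for key, v in res.cost.items():
        print(f"  cost {key:16s} ${v:>10,.0f}")
    print(f"  total cost          ${res.total_cost:>10,.0f}")
    print(f"  total LYs  {res.total_ly:6.3f}   total QALYs {res.total_qaly:6.3f}")

print(f"\nincremental cost  ${icer.delta_cost:,.0f}")
print(f"incremental LYs   {icer.delta_ly:.3f}   QALYs {icer.delta_qaly:.3f}")
print(f"ICER  ${icer.icer_ly:,.0f}/LY   ${icer.icer_qaly:,.0f}/QALY")
# The ICER is the extra spend per (quality-adjusted) life-year gained by
# first-line crizotinib over pemetrexed-platinum chemotherapy.
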