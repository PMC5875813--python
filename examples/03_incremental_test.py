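"""Incremental-test utilities: protocol, maximality, thresholds, cuff.

Shows the graded-protocol stage powers, evaluates the maximal-effort
criteria for one test, detects a ventilatory threshold in a synthetic
ramp, and prescribes a blood-flow-restriction cuff pressure.
"""

import numpy as np

from ergo import incremental_test as it

print("protocol (first 13 min):")
for st in it.build_protocol(13):
    print(f"  minute {st.minute_index:2d}: {st.power:.0f} W")

report = it.maximality_criteria(plateau=False, rer_max=1.15, hr_max=185, age=24, rpe_max=16)
print(f"\nmaximality: {report.n_met}/4 criteria met -> maximal = {report.is_maximal}")
print("  (RER 1.15 > 1.1 and HR 185 > 90% of 220-24 = 176.4 both hold)")

# synthetic ramp whose V̇E/V̇O2 turns upward at 24 mL/kg/min
vo2 = np.linspace(15, 33, 20)
ve_over_vo2 = 26.0 - 0.1 * vo2 + 0.8 * np.maximum(vo2 - 24.0, 0.0)
rng = np.random.default_rng(1)
est = it.detect_breakpoint(vo2, ve_over_vo2 + rng.normal(0, 0.1, vo2.size), "VT")
print(f"\nVT detected: {est.found}, breakpoint at {est.breakpoint_vo2:.1f} mL/kg/min")
print(f"as %V̇O2max (V̇O2max 33.4): {it.fraction_of_vo2max(est.breakpoint_vo2, 33.4)} %")

rx = it.occlusion_target(aop=136.0, fraction=0.80)
print(f"\ncuff prescription: 80% of AOP {rx.aop:.0f} mmHg -> {rx.target} mmHg")
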