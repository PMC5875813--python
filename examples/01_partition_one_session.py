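"""Partition one simulated cycling session into its three energy systems.

Builds a zero-noise 30-min constant-load session for one synthetic
subject, runs the full partition and prints the aerobic, anaerobic
alactic and anaerobic lactic O2 volumes plus total energy expenditure.
"""

from ergo import synthetic_data as sd
from ergo.energetics import partition_session

subject = sd.make_population(1, seed=3)[0]
effects = sd.ConditionEffects(
    noise_vo2=0.0, noise_la=0.0, noise_hr=0.0, noise_ve=0.0,
    session_sd_vo2=0.0, session_sd_a1=0.0, session_sd_tau1=0.0,
    session_sd_hr=0.0, session_sd_ve=0.0, session_sd_la=0.0,
)
series, truth = sd.simulate_breath_series(
    subject, effects, "LIE", seed=5, return_truth=True
)
profile = sd.simulate_lactate_profile(
    subject, effects, "LIE", seed=6, session_la_rise=truth.net_lactate_mmol
)

report = partition_session(series, profile, subject.body_mass, seed=1)
p = report.partition

print(f"subject: {subject.subject_id}, mass {subject.body_mass:.1f} kg, "
      f"power {subject.power_w:.0f} W")
print(f"resting baseline V̇O2 : {report.baseline_l_min:.3f} L/min")
print(f"aerobic              : {p.aerobic_l:8.3f} L O2  (exercise V̇O2 above rest)")
print(f"anaerobic alactic    : {p.alactic_l:8.3f} L O2  (fast EPOC, A1·τ1)")
print(f"anaerobic lactic     : {p.lactic_l:8.3f} L O2  (3 mL/kg per mmol/L net lactate)")
print(f"total                : {p.total_l:8.3f} L O2 = {p.total_kj:.1f} kJ")
print("\nThe aerobic system dominates low-intensity cycling; the anaerobic")
print("systems together contribute only a few percent of the session's energy.")
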