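"""Generate a full synthetic constant-routine cohort (mechanistic backend).

18 subjects x 2 constant routines x 20 two-hourly occasions x
{estimation, production} x {10 s, 40 s} x 3 trials, with hourly melatonin
profiles carrying a known DLMO per subject-epoch.
"""

from circatiming import simulate_mechanistic

trials, melatonin, truth = simulate_mechanistic(seed=1)

print(f"trial rows:     {len(trials)}  (18*2*20*4*3 = 8640)")
print(f"melatonin rows: {len(melatonin)} (39 hourly samples per subject-epoch)")
print(f"parameter redraws during subject sampling: {truth.redraws}")
print("\nfirst trials:")
print(trials.head(6).to_string(index=False))
s01 = truth.subjects["S01"]
print(f"\ntrue DLMO of S01: CR1 {s01.dlmo_cr1:.2f} h, CR2 {s01.dlmo_cr2:.2f} h "
      "(hours since CR start)")
print("Responses are generated by the pacemaker-accumulator model with "
      "subject-specific\nmodulation parameters and multiplicative trial noise.")
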