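"""Build a 30-trial event-related schedule and inspect its timing.

Each trial shows a cross (relax; the 5.5-8.5 s inter-stimulus interval),
a prepare circle (1-3 s) and a go circle (scheduled at its 5 s maximum;
at acquisition time it ends when the moving leg's force drops).  Durations
sit on a 0.5 s grid with truncated-Poisson weights, which jitters stimulus
timing for event-related fMRI modelling.
"""

import apakit as ak
from apakit.paradigm import schedule_summary

schedule = ak.build_schedule(ak.ParadigmConfig(n_trials=30, seed=42))
print(schedule_summary(schedule))
print()
print(schedule.events.frame.head(6).to_string(index=False))
print()
print("Each row is one stimulus event: onset/duration in seconds from run")
print("start.  30 cross/prepare/go triplets make one run; short durations")
print("are the most probable (Poisson weighting), the grid keeps them")
print("aligned to 0.5 s steps.")

# Half a cohort sees the open circle as the prepare cue, half the closed one
mapping = ak.counterbalance([f"sub-{i:02d}" for i in range(10)], seed=42)
n_open = sum(v == "open_is_prepare" for v in mapping.values())
print(f"\nCue counterbalancing over 10 subjects: {n_open} open-is-prepare, "
      f"{10 - n_open} closed-is-prepare")
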