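"""Generate a synthetic two-option tracking dataset and round-trip it.

The generator emulates a screen-based categorization task: 60 subjects,
19 trials each (10 typical / 9 atypical), a start button at the bottom
center and response boxes at (+-665, 974) px, sampled every 10 ms.
"""

import reachtrace as rt

ds, truth = rt.generate(rt.SynthSpec(seed=7))
arr = ds.get(rt.RAW)
print(f"trials: {ds.n_trials}, samples per trial: "
      f"{arr.valid_length.min()}..{arr.valid_length.max()}")
print("condition counts:", ds.trial_table["Condition"].value_counts().to_dict())
print("true type counts:", truth["true_type"].value_counts().to_dict())

# long-format export/import is lossless, so CSV files are a safe interchange
table = rt.export_long(ds)
back = rt.import_long(table, ["trial_id"])
print("round trip preserved all trials:", back.n_trials == ds.n_trials)

# The sample counts span the short-to-long trial range of 100-Hz recordings;
# the type mixture differs between conditions, which every later example
# exploits as ground truth.
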