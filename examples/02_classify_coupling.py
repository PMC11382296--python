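"""Classify minutes into coupling and intensity classes.

Builds a handful of aligned minutes by hand and shows the coupling ratio
R = SR/HR, the deviation bands (CLC <= 1% < weak CLC <= 10% < no CLC)
and the cadence-based intensity classes (60/100/130 steps/min cuts).
"""

import pandas as pd

from clckit import classify, occurrence

minutes = pd.DataFrame({
    "timestamp": pd.date_range("2023-01-02 10:00", periods=6, freq="min"),
    "sr": [100.0, 99.0, 90.0, 88.0, 130.0, 160.0],
    "hr": [100.0, 100.0, 100.0, 100.0, 100.0, 158.0],
})

instances = classify(minutes)
print(instances[["sr", "hr", "ratio", "deviation",
                 "coupling_class", "intensity_class"]].to_string(index=False))
print()
print(occurrence(instances).to_string(index=False))

# 99 vs 100 deviates by exactly 1% and still counts as coupled; 90 vs 100
# (10%) is the outer edge of weak coupling; 88 vs 100 is uncoupled.  The
# occurrence table gives the share of minutes per class, i.e. the
# percentage of observational time spent in each coupling state.
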