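# clckit — cardiac-locomotor coupling from wearable recordings

Cardiac-locomotor coupling (CLC) is the 1:1 frequency locking of the
heartbeat and the step cycle: when step rate (SR, steps/min) equals
heart rate (HR, beats/min), each stride can be timed against the cardiac
cycle, which has documented hemodynamic benefits. `clckit` measures how
often this locking occurs in free-living wrist-device recordings — the
kind of intraday Fitbit-style data physiologists and epidemiologists
download as per-minute step counts and 5-second heart-rate samples —
and asks whether the observed amount of coupling exceeds chance.

## The analysis

For every minute carrying both signals (HR averaged over its twelve 5-s
samples, minutes below 60 steps/min discarded as rest), the coupling
ratio is

```
R = SR [steps/min] / HR [beats/min]
```

and the minute is classified by the relative deviation `|SR − HR| / HR`:

* **CLC** — deviation ≤ 1%
* **weak CLC** — 1% < deviation ≤ 10% (reachable with a small cadence change)
* **no CLC** — deviation > 10%

Minutes are also stratified by cadence intensity (light [60, 100),
moderate [100, 130), vigorous ≥ 130 steps/min) and segmented into
activity bouts (consecutive observations less than one hour apart).
Because HR and SR are physiologically correlated, apparent coupling can
arise by chance: per subject, the package builds the distribution of
`R_sim` under random pairing of the recorded HR and SR values — all
N × N combinations, computed exactly in O(B·N log N) by sorting and
binary search rather than by sampling — and compares it with the
observed distribution (band probabilities, IQR, skewness, two-sample
Kolmogorov-Smirnov). Subjects are grouped by
`D = occurrence(moderate) − occurrence(vigorous)` at ±1.5 percentage
points, and contrasts use Wilcoxon signed-rank with effect size
`r = |Z|/√N` and Kruskal-Wallis with `η² = H/(N−1)`.

A seeded synthetic-cohort generator emulates the device (daytime
activity bouts, 5-s HR samples tracking cadence, integer step counts
with −3% undercount, HR noise with 11% mean absolute percentage error)
and injects a known fraction of entrained minutes, so the whole pipeline
can be validated against ground truth without any real deposit.

## Worked example

Simulate one subject for two weeks with 5% of active minutes entrained,
run the pipeline, and compare observed coupling with the random-pairing
null (`examples/03_null_model.py`):

```
$ python examples/03_null_model.py
active minutes:          1479
injected entrainment:    6.22% of active minutes
observed  P(dev <= 10%): 0.511   P(dev <= 1%): 0.0203
null      P(dev <= 10%): 0.224   P(dev <= 1%): 0.0179
observed IQR 0.060 vs null IQR 0.406; skewness 0.26 vs 0.82
KS statistic 0.354, p = 3.17e-166
```

The observed ratio distribution is far tighter than random pairing of
the same values (IQR 0.06 vs 0.41) and holds more than twice the mass
within 10% of R = 1 (0.51 vs 0.22): heart rate and cadence move together
minute by minute, and the injected entrainment adds a spike at R = 1.
The KS test overwhelmingly rejects the chance-pairing null. The other
scripts in `examples/` walk through simulation + ingest, minute
classification, the cohort report and the effect-size wrappers.

A thin CLI covers the same pipeline from a shell:

```
clc simulate --n-subjects 4 --days 14 --seed 1 --out-dir cohort/
clc report --manifest cohort/manifest.json --out-dir results/
clc analyze --hr heart_rate.json --steps steps.json --dialect fitbit-json
```

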