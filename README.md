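# actirhythm

Nonparametric rest-activity rhythm (RAR) analysis for week-long wrist
actigraphy, aimed at studies of circadian disruption in hospitalised
populations (e.g. poststroke rehabilitation inpatients versus matched
inpatient controls). The package covers the full chain:

1. **Preprocessing** — raw tri-axial acceleration (g-units, e.g. 30 Hz) to
   1-minute *acti-counts*: per-axis gravity removal (10-s moving mean),
   Euclidean-norm combination, 0.5–3 Hz zero-phase Butterworth band-pass,
   thresholded rectification, 2-s integration, per-minute averaging.
2. **RAR metrics** — the five standard nonparametric circadian indicators
   from a ≥7-day epoch series. With `X_i` (i = 1..N) the hourly-averaged
   counts, `X̄_h` the 24-point daily template and `X̄` the grand mean:

   ```
   IS = (N Σ_h (X̄_h − X̄)²) / (p Σ_i (X_i − X̄)²),         p = 24
   IV = (N Σ_{i=2..N} (X_i − X_{i−1})²) / ((N−1) Σ_i (X_i − X̄)²)
   RA = (M10 − L5) / (M10 + L5)
   ```

   where M10 / L5 are the means over the most active 10 and least active 5
   consecutive hours of each day (600/300-minute moving-window search at
   1-minute resolution), averaged across days into composites.
3. **Cohort statistics** — Shapiro–Wilk screening (annotation only),
   Mann–Whitney U group contrasts with median (IQR) reporting, chi-square /
   Fisher exact for categorical tables, and Spearman correlations between
   the indicators and clinical scores (Barthel Index, 4AT delirium screen).
4. **Synthetic cohorts** — a calibrated simulator (rectified-cosine diurnal
   envelope, day-to-day phase/amplitude jitter, Markov rest–activity
   fragmentation, score links) so the entire pipeline is testable
   end-to-end without any real recordings.

## Worked example

```python
from actirhythm import RhythmParams, generate_epoch_series, composite_rar

params = RhythmParams(mesor=4.3, amplitude=70.0)   # stroke-like inpatient
series = generate_epoch_series(params, seed=7)      # 7 days x 1440 minutes
m = composite_rar(series)
print(f"IS={m.IS:.2f}  IV={m.IV:.2f}  M10={m.M10:.2f}  L5={m.L5:.2f}  RA={m.RA:.2f}")
d = m.per_day[0]
print(f"day 0: M10={d.m10:.2f} @ {d.m10_onset_clock}, L5={d.l5:.2f} @ {d.l5_onset_clock}")
```

prints

```
IS=0.75  IV=0.59  M10=33.15  L5=4.14  RA=0.78
day 0: M10=37.82 @ 08:41, L5=4.21 @ 00:46
```

IS = 0.75 says three quarters of the hourly variance is explained by the
average 24-h profile (a fairly regular week); IV = 0.59 is modest
hour-to-hour fragmentation; the composite most-active-10-h level is 33.2
activity units/min against a least-active-5-h floor of 4.1, giving a
day–night contrast RA = 0.78. The per-day detail locates each day's
windows in clock time — here the most active 10 h start at 08:41 and the
nocturnal trough at 00:46.

The same analysis runs from the shell on CSV artifacts:

```sh
actirhythm run --out demo --seed 1          # simulate -> metrics -> compare
actirhythm metrics --in demo/epochs --min-days 7
actirhythm compare --metrics demo --cohort demo/cohort.csv --alpha 0.05
```

`demo/report.txt` contains the group-contrast block (median (IQR) per
group with Mann–Whitney p per indicator), the Spearman correlation block
for both clinical scores, and the normality annotations. With the shipped
default cohort (25 per group) the stroke-like group shows elevated L5 and
depressed RA while M10, IS and IV do not separate — the contrast
structure the simulator is calibrated to produce.

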