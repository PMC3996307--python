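# Methods

## Signal model

A simulated tracing is

```
x(t) = Σ_n [ B(t − nT) + s(n)·b(t − nT) ] + w(t) + ε(t)
```

where `B` is a fixed 0.7 s beat sampled at 500 Hz, `T = RR = 0.7 s`
(constant — no heart-rate variability), `b` is a unit-peak raised-cosine
bump of width 160 ms centred on the T apex, `s(n) = ±A(n)/2` carries the
alternans with strictly alternating sign, `w` is an optional sinusoidal
baseline (default 0.1 mV at 0.30 / 0.71 / 1.50 Hz) and `ε` optional white
noise (off by default — the study conditions add only baseline wander).
Because consecutive beats receive `+A/2` and `−A/2`, the maximum absolute
sample difference between consecutive T waves equals `A(n)` exactly, so the
configured amplitude *is* the ground truth without calibration.

The beat is parametric (a sum of compactly supported raised-cosine
deflections: P 60 µV, Q −80 µV, R 1000 µV at 0.15 s, S −120 µV, monophasic
T 500 µV at 0.35 s, width 0.24 s). Compact support makes the pre-P, PQ, ST
and TP segments *exactly* isoelectric, which the baseline stage exploits.
With RR = 0.7 s the alternans fundamental is 1/(2·0.7) ≈ 0.71 Hz, so the
0.71 Hz wander condition deliberately collides with it.

**Ground truth A(n).** `SimTruth.a_n` is the predefined amplitude sequence
(the gold standard used for RMSE). `SimTruth.a_n_measured` is the same
quantity re-measured from the clean injected waves as the consecutive-beat
maximum difference; the two coincide for stationary patterns but differ at
a phase reversal, where the consecutive difference physically vanishes for
one beat pair while the pattern amplitude does not. Scoring against the
predefined sequence is what makes a perfect phase-reversal analysis score
RMSE = 0.

Study amplitude patterns: stationary 10/50/100 µV; sinusoidal
`A(n) = 25·(1 + sin(2πn/128))` µV (the sinusoidal peak is a parameter; the
0–50 µV default is consistent with the 10–100 µV range used elsewhere);
cascaded step 50→20 µV with a 24-beat raised-cosine transition placed at
beats 52–76 (centred in the record; the exact placement is not critical and
is exposed as a parameter); phase reversal = stationary 10 µV with the
parity flipping after beats 40 and 80 (1-based).

## Pipeline choices

**Baseline suppression.** Cubic-spline interpolation through isoelectric
knots, subtracted from the signal. Default knots sit at 7 isoelectric
offsets per beat (−130, −36, +50, +74, +326, +400, +500 ms from the
fiducial): pre-P, PQ, ST, the two edges of the T-wave support, and two TP
points. Knot offsets are configurable and must be isoelectric for the
morphology at hand. The limiting factor is the non-isoelectric T region
(~0.25 s here): spline interpolation across a gap of width `h` leaves a
residual of order `h⁴/384·max|w⁗|`, i.e. ~0.05 µV for 0.30 Hz wander but
~8 µV at 1.50 Hz — no isoelectric-knot spline can track a wander whose
period (0.67 s) is comparable to the gap it must bridge. Interpolation is
exact at the knots, so a second pass changes nothing.

**Fiducials.** Simulated tracings carry exact R-peak fiducials, used by
default in the study runs (detector choice is orthogonal to the method).
The built-in detector band-passes at 8–25 Hz (zero-phase), thresholds at
50 % of the global peak with a 0.25 s refractory period, and refines to the
raw R apex within ±30 ms; on simulator output it lands within ±10 ms of
truth.

**Segmentation and alignment.** Windows are 300 ms from
`40 + 1.3·√RR_ms` ms after the fiducial (74.4 ms at RR = 700 ms), rounded
to the nearest sample; windows overrunning the record are dropped and
logged. Alignment searches integer shifts within ±30 ms for the maximum
dot product with the median template, recomputing the template until shifts
stabilize (cap 5 passes); ties prefer the smallest |shift|, negative before
positive.

**Detection.** Episodes are maximal runs with strictly alternating ACI
differences, each exceeding `alternation_min`, of length ≥ 7 beats; a
non-zero breaking difference may seed the following run, and episodes are
kept disjoint (an overlapping start is trimmed by one beat). The published
magnitude threshold 0.12 is tied to the T-wave energy of the waveforms the
correlation method was calibrated on: the ACI deflection of an alternans of
amplitude A scales as `A·⟨b,T_m⟩/⟨T_m,T_m⟩` ≈ A/(0.75·T_apex), so on the
500 µV default template a 10 µV alternans moves the ACI by only ~0.013.
The defaults honor the published constants; the simulation-study
configuration (`PipelineConfig.simulation_study()`) keeps the structural
strict-alternation criterion and sets `alternation_min = 0`, which detects
every injected amplitude while still reporting zero episodes on clean or
wander-only tracings (their ACI drift is slow, never alternating at period
2 for 7 beats). This preserves episode splitting at phase reversals, which
whole-tracing quantification (`quantify_all`) would break.

**Correction.** Per column of each parity matrix: 7-beat epochs (a final
remainder < 4 beats is merged into the previous epoch — 2-point epochs fit
exactly and would disable outlier detection); OLS line in the beat index
(the first-degree polynomial is taken in the beat index — regressing a
value on itself has no least-squares content); replace the worst point with
the column mean while `max θ ≥ 3·θ̄` and `max θ ≥ 2 µV`, with the column
mean re-evaluated each pass (a frozen mean need not converge: a gross
outlier inflates the very mean meant to replace it), capped at 25 passes
(cap hits are reported, not fatal). The 2 µV condition is an absolute
floor in signal units. Two structural properties worth knowing: the rule
is deliberately neutral on smooth variation (max/mean deviation ratios of
detrended smooth segments stay below 3, so alternans-only data is never
touched), and an outlier at an epoch *endpoint* can evade the ratio test
because the fitted slope absorbs part of it.

**Local TWA window.** `TWA(k)` takes the maximum over the full 300 ms
window by default; `[t_onset_idx, t_offset_idx]` is configurable.

**Reporting.** Global TWA, per-episode values and RMSE are rounded to
0.1 µV at output only; internal arithmetic is unrounded. RMSE runs over
all 128 beats with 0 for undetected beats; the unpaired trailing beat of an
odd-length episode carries its last pair's value.

## What the simulations do and do not show

The generator produces exactly repeating beats, constant RR, sinusoidal
wander and known fiducials. Passing these conditions demonstrates the
estimator's correctness (exact amplitude recovery, zero false positives,
phase-reversal handling) but not robustness to morphology variability,
RR variability, electrode noise, or non-sinusoidal drift of real Holter
data. Under these conditions, with ground-truth fiducials and the
simulation-study configuration:

- clean and 0.30 Hz-wander tracings give exact results — global TWA equal
  to the injected amplitude, RMSE 0.0 µV for stationary and phase-reversal
  patterns, ≤ 0.5 µV for the time-varying patterns (the residual there is
  the half-beat lag between a pair's shared estimate and a per-beat truth);
- 0.71 Hz wander (the alternans frequency) is largely removed by the dense
  isoelectric knots (residual RMSE ≈ 0.7–0.8 µV, spurious TWA on
  alternans-free tracings ≈ 0.6 µV) — beat-aliased wander at exactly
  period 2 is indistinguishable from TWA in principle, and only survives
  here to the extent the spline misses it;
- 1.50 Hz wander hits the spline floor described above: amplitude estimates
  stay accurate to ~0.1 µV, but per-beat RMSE flattens at ≈ 2.1–2.3 µV.
  This is a physical limit of isoelectric-knot spline baseline removal, not
  a tunable: removing it would require either a narrower T wave or a
  different (model-based) baseline estimator.

Problem sizes throughout are the study conditions themselves (128 beats,
350 samples/beat); every run completes in well under a second.
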