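# alternans

Time-domain detection and quantification of **T-wave alternans (TWA)** in
single-lead ECG, together with an artificial-TWA ECG simulator that provides
the ground truth needed to validate any TWA detector.

TWA is a beat-to-beat (2:1) fluctuation of T-wave amplitude or morphology in
the surface ECG and a recognized marker of cardiac electrical instability.
Amplitudes of clinical interest are tiny — tens of µV riding on millivolt
waveforms contaminated by baseline wander — so both the detector and a
controlled way of testing it matter.

## Method

The analyzer is a hybrid time-domain pipeline:

1. **Preprocessing.** Baseline wander is estimated by a cubic spline through
   isoelectric knots of every beat and subtracted. T waves are segmented as
   300 ms windows starting `b_i = 40 + 1.3·√RR` ms after each QRS fiducial
   (RR in ms), then aligned to the per-sample **median T wave** `T_m` by
   maximizing cross-correlation over integer shifts within ±30 ms
   (recursively, until the shifts stabilize).
2. **Detection.** Each aligned wave gets an *alternans correlation index*

   `ACI_i = Σ_j T_i(j)·T_m(j) / Σ_j T_m(j)²`

   An alternans episode is a maximal run of ≥ 7 beats whose successive ACI
   differences strictly alternate in sign (each exceeding a configurable
   magnitude threshold; published value 0.12 = 2 × Th_ACI).
3. **Quantification.** Episode beats are split by parity into odd (A) and
   even (B) T-wave matrices. Each column is cut into 7-beat epochs; a
   least-squares line in the beat index is fitted per epoch and any point
   with deviation `θ ≥ 3·θ̄` (and ≥ 2 µV) is replaced by the column mean,
   iterating until the rule is satisfied. Local TWA of pair *k* is
   `TWA(k) = max_i |T̄A_k(i) − T̄B_k(i)|`; the segment TWA is the mean over
   pairs and the global TWA the mean over episodes.
4. **Validation.** On simulated tracings the per-beat estimates are scored
   against the true alternans sequence `A(n)` with
   `RMSE = √(Σ_n (TWA(n) − A(n))²/N)`, reported at 0.1 µV resolution;
   beats outside any detected episode count as 0, so missed detection is
   penalized.

The simulator repeats a parametric 0.7 s beat (500 Hz) 128 times with
constant RR and injects alternans as a ±A(n)/2 raised-cosine bump in a
160 ms window centred on the T apex, following stationary (10/50/100 µV),
sinusoidal, smoothed-step (50→20 µV), or phase-reversal amplitude patterns,
optionally plus a 0.1 mV baseline sinusoid (0.30 / 0.71 / 1.50 Hz) and
white noise.

## Worked example

```sh
alternans simulate --case S_TWA50 --baseline bw030 --out s50.csv
alternans evaluate s50.csv --sidecar s50.csv.json --alternation-min 0
```

prints (config echo elided):

```json
{
 "global_twa_uv": 50.0,
 "rmse_uv": 0.0,
 "n_beats": 128
}
```

i.e. a 50 µV stationary alternans under 0.30 Hz baseline wander is recovered
exactly: the spline removes the wander, all 128 beats form one detected
episode, every beat pair's local TWA is 50 µV and the per-beat error against
the known A(n) is zero at the 0.1 µV reporting resolution. The same is
available from Python:

```python
from alternans import run_case
run_case("S_TWA50", "bw030")
# {'case': 'S_TWA50', 'baseline': 'bw030', 'TWA_HAM': 50.0, 'RMSE_HAM': 0.0,
#  'n_episodes': 1, 'detected': True}
```

`alternans report` runs the whole case × baseline grid and tabulates global
TWA and RMSE per row (comparator columns print `n/a` unless a plug-in
comparator is registered via `alternans.register_comparator`).

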