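# openqct

Entropy-based complexity monitoring of beat-to-beat cardiovascular
hemodynamics, built for head-up tilt testing (HUTT).

## The problem

During a tilt test a subject is monitored beat by beat (impedance
cardiography + continuous blood pressure) while posture and
pharmacological provocations stress the circulation.  Single markers —
heart rate, mean blood pressure — react late in vasovagal (pre)syncope.
The idea implemented here is to watch the *whole* hemodynamic state
vector at once and quantify, per sliding window, how much structured
information the system carries: a bounded scalar **complexity** that
spikes on coherent transients (tilt, nitroglycerine, posture
restoration) and rises when the dependency structure of the circulation
destabilizes before collapse.

## The statistic

For a window of M beats and N variables
{HR, SBP, DBP, MBP, LVET, PEP, SV, CO, HI, TAC, SVR}:

1. Every pair's scatter plot is discretized on a b × b mesh,
   b = ⌊√M⌋ (M = 100 → 10 × 10), using equal-frequency **rank bins**;
   pixel densities m/M give Shannon entropies H = −Σ pᵢ log₂ pᵢ.
2. A pair is **structured** when its mutual information exceeds a seeded
   permutation-surrogate threshold (level α, default 0.05) — the
   "generalized correlation" test, invariant to monotone rescaling and
   outliers.
3. The window's complexity is the spectral norm of the Hadamard product
   of structure and entropy matrices,

       C = ‖S ∘ E‖₂   [bits],

   bounded by **C_min** (same topology, perfect dependence) and
   **C_critical** (same topology, maximal disorder).  Per-variable
   **complexity profiles** (leave-one-out percentages) and the
   **complexity map** (graph of structured pairs) localize what drives C.

Derived hemodynamics follow the impedance-cardiography conventions
(SV = VEPT·dZmax·LVET/Z0 with Sramek's VEPT, CO = SV·HR, HI = dZmax·TRC,
TAC = SV/PP, SVR = 80·(MBP−CVP)/CO).  See `docs/methods.md` for the full
model, estimator calibration, and the bundled synthetic HUTT generator
(phases, VASIS type-1 mixed collapse, MBP gap injection).

## Worked example

Simulate a positive tilt test with an early-warning prodrome, analyze
it, and profile the moment of syncope:

```bash
openqct simulate --preset type1_mixed_with_warning --seed 1 --out run.csv
openqct analyze run.csv --step 4 --seed 1 --out-prefix run
openqct profile run.csv --at-time 950 --seed 1 --out run.profile.json
```

`simulate` writes 1267 beats (1015 s: 5 min supine, tilt, passive
standing, progressive collapse, restoration) and the ground truth
`run.truth.json` with `"syncope": 955.0`.  `analyze` writes
`run.trend.csv` (columns `window_end_time, C, C_min, C_critical,
n_beats_used, profile_*`) and `run.events.json`.  In Python, the
early-warning reading of the same record is:

```python
import openqct as q

scn = q.get_scenario("type1_mixed_with_warning", seed=1)
records, truth = q.simulate_hutt(scn)
data, mask, times = q.assemble_state_matrix(records, scn.subject)
names = q.StateVectorConfig().variables
trend = q.sliding_trend(data, mask, times, window=100, step=4,
                        variable_names=names, seed=1)
alert = q.detect_surge(trend, baseline_span=150.0,
                       start_time=truth.events["tilt"] + 150.0)
drops = {e.kind: e for e in q.reference_events(data, times, names)}
print(round(alert.time), round(drops["mbp_drop"].time), truth.events["syncope"])
```

prints `654 850 955.0`: the complexity surge fires at t ≈ 654 s,
~196 s before the MBP criterion (850 s) and ~301 s before syncope
(955 s) — heart-rate depression follows later still, the mixed-type
sequence.  On the negative-protocol preset the same pipeline shows the
tilt spike (post-tilt C peaks at >2× the supine median within 2 min)
followed by return to baseline.

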