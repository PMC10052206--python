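# Methods

`openqct` computes a bounded, entropy-based complexity statistic for
multivariate beat-to-beat cardiovascular recordings and tracks it through
a head-up tilt test (HUTT).  This note records the model, the estimator
choices, the synthetic-data design and the known limitations — the things
a maintainer or reviewer would want stated rather than reverse-engineered
from code.

## 1. The complexity statistic

A recording window is an M x N array: M heartbeats, N state-vector
variables (default N = 11: HR, SBP, DBP, MBP, LVET, PEP, SV, CO, HI, TAC,
SVR).  Two matrices are estimated per window:

- **S** (structure): N x N symmetric 0/1 adjacency; S_ij = 1 when
  variables i and j show *generalized correlation* (below).  S_ii = 1.
- **E** (entropy, bits): E_ii is the marginal Shannon entropy of variable
  i; E_ij the joint entropy of the pair (i, j).

The scalar complexity is the spectral norm (operator 2-norm, the largest
singular value) of the Hadamard product,

    C = || S o E ||_2 ,

in bits.  For the symmetric nonnegative matrices produced here this
equals the largest eigenvalue.  Unstructured pairs are zeroed by S, so C
aggregates the disorder carried by the *detected* dependency topology:
it grows both when more pairs are coupled and when coupled pairs carry
more joint disorder.

### Pairwise dependence: rank-pixelated scatter images

The dependence of a pair is judged from the pixelated image of its
scatter plot.  With M pairwise-complete samples the mesh has
b = floor(sqrt(M)) pixels per side (M = 100 -> 10 x 10); each pixel's
density is m/M.  Axes are partitioned into *equal-frequency rank bins*
(a copula grid) rather than equal-width value bins: the image is then
invariant under strictly monotone rescaling of either variable, immune to
outliers, and the marginal entropies are pinned at ~log2(b), so all
dependence information sits in the joint entropy.  Ties in rank are
broken by stable input order.

The structured/chaotic verdict is a permutation-surrogate test on the
mutual information MI = H_i + H_j − H_ij of the pixel image: the pairing
is destroyed by n_surrogates (default 200) seeded row permutations and
the pair is declared structured when the observed MI strictly exceeds the
k-th largest surrogate MI with k = floor(alpha (n+1)) (default alpha =
0.05, k = 10).  This order-statistic threshold gives an exact
finite-sample level of floor(alpha(n+1))/(n+1) <= alpha under
exchangeability; the suite verifies the realized false-positive rate
against the exact binomial interval.  Surrogate seeds derive from
(global seed, window index, canonical pair index), so runs are exactly
reproducible and the test is symmetric in its arguments bit for bit.

MI estimated from a b x b histogram carries an O((b−1)²/2M ln 2) positive
bias; the permutation null carries the same bias, so the verdict is
unaffected — the bias cancels in the comparison rather than in the value.

### Bounds

C is bounded by the entropy extremes achievable on the *current*
topology S:

- **C_min** — every connected pair perfectly dependent: joint entropy at
  its information-theoretic floor.  Dynamics dominated by structure.
- **C_critical** — every connected pair independent: joint entropy at
  the independence ceiling.  Dynamics dominated by disorder.

Two constructions are provided.  The textbook form (argument `b`) sets
connected entries of E_min to log2(b) and of E_max to 2·log2(b) (diagonal
log2(b)) — exact for a full window whose M is divisible by b.  The
default, data-driven form uses each pair's *measured* marginals:
E_min_ij = max(h_i, h_j) and E_max_ij = h_i + h_j, which bracket the
joint entropy exactly (H(X,Y) >= max H, <= H(X)+H(Y)) even when the gap
policy gives different pairs different sample counts or M is not
b-divisible.  Since all three matrices are entrywise ordered, symmetric
and nonnegative, Perron–Frobenius monotonicity of the spectral radius
guarantees C_min <= C <= C_critical on every window, which the suite
asserts end to end.  The two constructions coincide on gap-free,
b-divisible windows.

### Profiles and maps

The per-variable *complexity profile* is a leave-one-out attribution:
the raw contribution of variable k is max(0, C − C_without_k), normalized
to percentages.  A variable whose removal does not lower C contributes
0%; if no removal lowers C the attribution is uniform.  Squared leading-
eigenvector loadings are available as an alternative
(`profile_method="eigenvector"`) for sensitivity analysis.  The
*complexity map* is the graph of structured pairs, edge-weighted by joint
entropy, exportable as JSON or GraphML.

### Scale

With rank binning, C is at most ~N·2·log2(b) bits (tens of bits for
N = 11, b = 10).  Published clinical complexity traces from proprietary
software print hundreds to thousands of bits; the absolute scale of such
software is not reproducible from its public description (it involves an
undisclosed normalization), so this package's supported outputs are
trends, ratios, bounds and profiles — not absolute magnitudes.

## 2. Hemodynamic derivations

ICG primitives per beat: baseline thoracic impedance Z0 (ohm), maximum
impedance-change rate dZmax (ohm/s), LVET (s), R-to-C interval TRC (s).
Derived parameters:

    VEPT = (0.17 h_cm)^3 / 4.25 mL      (Sramek; optional multiplicative
                                         correction for the Bernstein
                                         weight/sex adjustment, default 1)
    SV  = VEPT dZmax LVET / Z0    [mL]
    CO  = SV · HR / 1000          [L/min]
    HI  = dZmax · TRC             (product form; the textbook Heather
                                   index dZmax/TRC is available via
                                   heather_index_form="quotient")
    TAC = SV / (SBP − DBP)        [mL/mmHg]
    SVR = 80 (MBP − CVP) / CO     [dyn·s·cm⁻⁵]

CVP is not measured by ICG and defaults to a constant 6 mmHg
(configurable).  The device convention this package targets defines HI as
a product, which conflicts with the conventional quotient; both forms are
exposed and the product is the default for fidelity.  Pulse pressure
(SBP − DBP) may replace SBP/DBP in the state vector to avoid a purely
redundant triple; it is not added on top of them by default.  Input rows
must be pre-aligned per beat; no resampling is performed.  Missingness is
closed under derivation: a derived cell is masked iff an input is masked.

## 3. Sliding-window trend and events

Windows are beat-counted (default 100 beats; 50 and 125 supported for
the lag/noise tradeoff), right-aligned and causal: the value stamped at
time t uses only beats up to t.  Step defaults to 1 beat; analyses in the
test suite use steps of 4–10 beats (a point every 3–8 s), which samples
every phase densely while keeping the suite fast — results are stepwise
subsamples of the step-1 trend, not approximations.

**Gap policy.**  Every pair is evaluated on its pairwise-complete rows.
A pair (or variable) left with fewer than `min_valid_fraction` (default
0.5) of the window is forced unstructured (isolated) for that window and
logged; a window is never aborted by gaps.

**Surge detector.**  Alert at the first run of >= s (default 5)
consecutive trend points above median + k·MAD (default k = 6) of a
baseline span.  For tilt tests the detector should be started after tilt
stabilization (`start_time` ≈ tilt + 150 s with a ~150 s standing
baseline); run from t = 0 it will — correctly — flag the tilt transient
itself.  **Reference events.**  mbp_drop / hr_drop fire at the first
>= 5-beat run below baseline median − d (defaults d_mbp = 20 mmHg,
d_hr = 15 bpm; the magnitude that counts as "relevant" is a tunable
choice, not an established constant).  Lead time is reference minus alert
time, positive when complexity led.

## 4. The synthetic HUTT generator

No public beat-to-beat tilt recordings exist for this protocol, so the
package bundles a generator that emulates the *statistical shape* of such
recordings.  Three physiological latents — venous return v, sympathetic
tone s, vagal tone g — plus a net vascular-tone factor r follow piecewise
phase targets (supine 5 min -> abrupt tilt -> passive standing ->
optional NTG provocation -> optional VASIS type-1 mixed collapse ->
supine restoration) with first-order autoregressive log-noise
(per-beat phi = 0.6).  Observables are algebraic maps of the latents (HR = 65·s^0.9/g^1.1 bpm,
SV = 85·v mL, MBP = CO·R/80 + CVP with R = R0·r², PP = 45·sqrt(v) mmHg,
SBP/DBP = MBP ± 2PP/3, PP/3), and the ICG primitives are back-solved
(dZmax = SV·Z0/(VEPT·LVET)) so that re-deriving SV/CO/TAC/SVR through
the hemodynamics module reproduces the latent values exactly.  HR and
MBP are soft-clipped to the 40–110 bpm / 52–135 mmHg envelopes reported
for tilt-table recordings.  Beat times advance by 60/HR s.

Noise scales (stationary log-SD: v 0.04, s 0.015, g 0.015, r 0.07, plus
small independent channel noises) were chosen to give physiologically
plausible rest variability (HR ~±2%, MBP ~±10 mmHg) and a decisive
resting dependency skeleton: the flow channels (SV–CO–HI–TAC) and the
pressure channels (SBP–DBP–MBP–SVR) form strongly coupled blocks, while
cross-block correlations stay weak at rest.

Mixed-type collapse: vascular tone and venous return fall with an
accelerating (quadratic) profile from collapse onset — a progressive MBP
decline — while the vagal surge (HR depression) starts only after a
configurable delay (60–90 s), and syncope is placed at collapse end, so
the ground truth always orders MBP decline < HR depression < syncope.
The early-warning preset adds a *prodrome*: a growing Mayer-band
oscillation of tone and venous return (log-amplitudes 0.07/0.05) starting
120 s before collapse onset.  This couples the pressure and flow blocks
— densifying the dependency structure and raising C — long before any
sustained MBP fall, emulating presyncopal hemodynamic instability.
Which channel pairs actually decouple or couple first in real presyncope
is unknown; driving the vascular-tone channels first is an assumption of
this generator, not a physiological claim.

Gaps are injected by a two-state (Gilbert) dropout process with
geometric burst lengths (mean 5 beats) at a target long-run masked
fraction, on the MBP channel by default.

**What the generator does not emulate:** respiratory sinus arrhythmia
and respiration-coupled stroke-volume modulation, resting Mayer-wave
oscillations outside the prodrome, ectopy and artifacts,
baroreflex feedback loops (latents are driven, not closed-loop),
measurement quantization, and inter-subject variability beyond
anthropometry.  Tests passing on these data therefore demonstrate the
pipeline's statistical behavior under a controlled dependency/phase
structure — not clinical validity on real recordings.

## 5. Numerical and design choices

- "Spectral matrix norm" is read as the operator 2-norm; for the
  symmetric matrices here it is computed as max |eigenvalue| via a
  symmetric eigendecomposition, and cross-checked in the suite against
  characteristic-polynomial root finding.
- Degenerate (constant) variables get zero marginal entropy and are
  isolated in S rather than raising an error mid-pipeline.
- The surge detector's MAD can be zero on pathological flat trends; the
  alert then requires a strict exceedance of the median, which a flat
  trend never produces.
- The trend-analysis problem sizes used in the test suite (records of
  ~700–3300 beats, steps 4–10) were chosen as the smallest that exercise
  every protocol phase with dense sampling.
- The window-size variability study (window 50 vs 125) is run on the
  flow-coupled subsystem (SV, CO, HI, TAC), where every pair is
  decisively dependent and trend variance purely reflects estimation
  noise, which shrinks with window length.  On weakly coupled channel
  sets an opposing effect can appear: the mesh rule b = floor(sqrt(M))
  gives wider windows a larger bits scale and more test power exactly in
  the borderline-dependence region, so structured-verdict flicker there
  carries more variance, not less.  Both behaviors are real properties
  of the estimator; the decisive-subsystem design isolates the
  classical tradeoff the window sizes are meant to illustrate.
- An optional linear display-scaling factor exists for plotting only; it
  never enters any computation or test.

## 6. Limitations

- The generalized-correlation algorithm of the originating clinical
  software is proprietary; the rank-pixelation + permutation-MI design
  here is an open, calibrated reconstruction of its published
  description, and its absolute complexity values are not comparable.
- Complexity reacts to any coherent hemodynamic transient (tilt, NTG,
  posture restoration), so specificity for presyncope requires
  re-baselining after each provocation, as the surge detector's
  `start_time` supports.
- Beat alignment across ICG and continuous-BP channels is assumed done
  upstream; misalignment would masquerade as decorrelation.
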