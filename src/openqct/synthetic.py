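"""Synthetic beat-to-beat head-up tilt test (HUTT) recordings.

No public beat-to-beat tilt-table dataset accompanies the method this
package implements, so every pipeline stage is exercised against a
generator that emulates the study protocol: 5 min supine stabilization,
abrupt tilt to 60-70 degrees, a passive standing phase, an optional
sublingual-nitrate (NTG) provocation, an optional VASIS type-1 (mixed)
vasovagal collapse — mean blood pressure falling progressively *before*
heart-rate depression — and supine restoration.

The model is deliberately minimal: three physiological latents (venous
return, sympathetic tone, vagal tone) plus a net vascular-tone factor
follow piecewise phase targets with first-order autoregressive log-noise,
and every observable is mapped algebraically from them:

    HR  = baseline_hr * sympathetic^0.9 / vagal^1.1        (bpm)
    SV  = sv_base * venous_return                          (mL)
    R   = r_base * vascular_tone^2                         (dyn*s*cm^-5)
    MBP = (SV * HR / 1000) * R / 80 + CVP                  (mmHg)
    PP  = pp_base * (SV / sv_base)^0.5 * noise             (mmHg)

ICG primitives are back-solved from the stroke-volume state
(dZmax = SV * Z0 / (VEPT * LVET)), so re-deriving SV/CO/TAC/SVR from the
emitted primitives through the hemodynamics module reproduces the latent
values exactly — the generated data satisfy the derivation algebra by
construction.  HR and MBP are soft-clipped to the physiological envelopes
seen in tilt-table recordings (40-110 bpm, 52-135 mmHg).

Beat times advance by 60/HR seconds; there is no respiratory or ectopic
modulation.  The generator is a test harness emulating the *statistical
shape* of tilt-table data (phase structure, dependency structure, noise,
gaps), not a validated cardiovascular model.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .hemodynamics import SubjectAnthropometry, compute_vept

PHASE_KINDS = ("supine_rest", "tilt_transition", "passive", "ntg", "collapse", "supine_restore")

#: Latent targets at the quiet supine operating point.
_SUPINE = {"v": 1.0, "sym": 1.0, "vag": 1.0, "tone": 1.0}
#: Passive upright standing: pooled blood, sympathetic activation.
_PASSIVE = {"v": 0.72, "sym": 1.28, "vag": 0.92, "tone": 1.15}
#: NTG plateau: venodilation and reflex tachycardia.
_NTG = {"v": 0.66, "sym": 1.40, "vag": 0.90, "tone": 0.85}

#: Stationary log-noise SD per latent (AR(1) around the phase target).
DEFAULT_NOISE_SD = {"v": 0.04, "sym": 0.015, "vag": 0.015, "tone": 0.07,
                    "pp": 0.010, "z0": 0.01, "lvet": 0.012, "trc": 0.01,
                    "pep": 0.03}

HR_ENVELOPE = (40.0, 110.0)   # bpm
MBP_ENVELOPE = (52.0, 135.0)  # mmHg


@dataclass(frozen=True)
class Phase:
    kind: str
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ConfigurationError(f"unknown phase kind {self.kind!r}")
        if not self.duration > 0:
            raise ConfigurationError("phase duration must be positive")


@dataclass
class HuttScenario:
    """Phase schedule plus physiological parameters for one simulated test."""

    subject: SubjectAnthropometry = field(
        default_factory=lambda: SubjectAnthropometry(weight=80.0, height=180.0, sex="male"))
    baseline_hr: float = 65.0    # bpm
    baseline_mbp: float = 90.0   # mmHg
    sv_base: float = 85.0        # mL
    pp_base: float = 45.0        # mmHg
    cvp: float = 6.0             # mmHg
    z0_base: float = 25.0        # ohm
    phases: tuple[Phase, ...] = (Phase("supine_rest", 300.0),)
    syncope: str = "none"        # none | vasis_type1_mixed
    hr_depression_delay: float = 60.0   # s after MBP decline onset (mixed type)
    collapse_mbp_fraction: float = 0.45  # fractional tone loss at syncope
    # Prodrome: growing low-frequency (Mayer-wave-like) oscillation of
    # vascular tone and venous return in the last `prodrome_duration`
    # seconds before collapse onset, persisting until syncope.  It couples
    # the pressure and flow channels without a sustained MBP fall — the
    # subclinical instability that precedes the hemodynamic collapse.
    prodrome_duration: float = 0.0      # s before collapse onset; 0 = none
    prodrome_amp_tone: float = 0.07     # log-amplitude on vascular tone
    prodrome_amp_v: float = 0.05        # log-amplitude on venous return
    prodrome_period: float = 40.0       # s
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    ar_coefficient: float = 0.6
    gap_rate_mbp: float = 0.0
    gap_burst_length: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.phases = tuple(p if isinstance(p, Phase) else Phase(*p) for p in self.phases)
        if not self.phases or self.phases[0].kind != "supine_rest":
            raise ConfigurationError("schedule must start with supine_rest")
        has_collapse = any(p.kind == "collapse" for p in self.phases)
        if has_collapse and self.syncope == "none":
            raise ConfigurationError("collapse phase requires syncope != 'none'")
        if self.syncope not in ("none", "vasis_type1_mixed"):
            raise ConfigurationError(f"unknown syncope type {self.syncope!r}")
        if not 0.0 <= self.gap_rate_mbp < 1.0:
            raise ConfigurationError("gap_rate_mbp must be in [0, 1)")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ConfigurationError("ar_coefficient must be in [0, 1)")
        missing = set(DEFAULT_NOISE_SD) - set(self.noise_sd)
        extra = set(self.noise_sd) - set(DEFAULT_NOISE_SD)
        if missing or extra:
            raise ConfigurationError(
                f"noise_sd channels mismatch: missing {sorted(missing)}, "
                f"unknown {sorted(extra)}")
        # canonical key order: the noise draw sequence (hence the simulated
        # record) must not depend on how the dict was built or deserialized
        self.noise_sd = {k: float(self.noise_sd[k]) for k in DEFAULT_NOISE_SD}

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))


@dataclass
class GeneratorTruth:
    """Ground-truth event times and latent trajectories of a simulation."""

    events: dict  # kind -> time (s): tilt, ntg, supine_restore, syncope,
                  # mbp_decline_onset, hr_depression_onset (where applicable)
    latents: pd.DataFrame  # t, venous_return, sympathetic, vagal, vascular_tone


def _phase_targets(scn: HuttScenario) -> list[tuple[Phase, dict, dict]]:
    """Per phase: (phase, start targets, end targets) for linear blending."""
    segments = []
    prev_end = dict(_SUPINE)
    for ph in scn.phases:
        if ph.kind == "supine_rest":
            start = end = dict(_SUPINE)
        elif ph.kind == "tilt_transition":
            start, end = dict(prev_end), dict(_PASSIVE)
        elif ph.kind == "passive":
            start = end = dict(_PASSIVE)
        elif ph.kind == "ntg":
            start, end = dict(prev_end), dict(_NTG)
        elif ph.kind == "collapse":
            start = dict(prev_end)
            end = {"v": start["v"] * 0.65,
                   "sym": start["sym"] * 0.75,
                   "vag": 2.6,
                   "tone": start["tone"] * (1.0 - scn.collapse_mbp_fraction)}
        elif ph.kind == "supine_restore":
            start, end = dict(prev_end), dict(_SUPINE)
        segments.append((ph, start, end))
        prev_end = end
    return segments


def _targets_at(ph: Phase, f: float, start: dict, end: dict, scn: HuttScenario) -> dict:
    """Deterministic latent targets at fraction f of a phase."""
    if ph.kind in ("supine_rest", "passive"):
        return dict(start)
    if ph.kind in ("tilt_transition", "supine_restore"):
        return {k: start[k] + (end[k] - start[k]) * f for k in start}
    if ph.kind == "ntg":
        # fast onset (first third), plateau, partial recovery in last third
        if f < 1 / 3:
            g = f * 3
            return {k: start[k] + (end[k] - start[k]) * g for k in start}
        if f < 2 / 3:
            return dict(end)
        g = (f - 2 / 3) * 3
        rec = {k: end[k] + (_PASSIVE[k] - end[k]) * 0.7 * g for k in end}
        return rec
    if ph.kind == "collapse":
        # accelerating (quadratic) loss of vascular tone and venous return:
        # MBP declines progressively from phase onset ...
        out = {"v": start["v"] + (end["v"] - start["v"]) * f ** 2,
               "tone": start["tone"] + (end["tone"] - start["tone"]) * f ** 2,
               "sym": start["sym"] + (end["sym"] - start["sym"]) * max(0.0, f - 0.7) / 0.3}
        # ... while the vagal surge (HR depression) starts only after a delay.
        fd = min(0.95, scn.hr_depression_delay / ph.duration)
        g = max(0.0, (f - fd) / (1.0 - fd))
        out["vag"] = start["vag"] + (end["vag"] - start["vag"]) * g ** 2
        return out
    raise ConfigurationError(f"unknown phase kind {ph.kind!r}")


def simulate_hutt(scenario: HuttScenario) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Simulate one HUTT recording.

    Returns a beat table with the primitive columns (t, hr, sbp, dbp, mbp,
    lvet, pep, z0, dzmax, trc; NaN = gap) and the ground truth (event
    times, latent trajectories).  Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    segments = _phase_targets(scenario)
    bounds = np.cumsum([0.0] + [p.duration for p, _, _ in segments])
    vept = compute_vept(scenario.subject)
    r_base = 80.0 * (scenario.baseline_mbp - scenario.cvp) / (
        scenario.sv_base * scenario.baseline_hr / 1000.0)

    phi = scenario.ar_coefficient
    innov = np.sqrt(1.0 - phi ** 2)
    sd = scenario.noise_sd
    ar = {k: rng.normal(0.0, sd[k]) for k in sd}  # stationary start

    # prodrome window [collapse onset - duration, syncope)
    t_pro0 = t_syn = None
    if scenario.prodrome_duration > 0:
        for (ph, _, _), t0, t1 in zip(segments, bounds[:-1], bounds[1:]):
            if ph.kind == "collapse":
                t_pro0, t_syn = t0 - scenario.prodrome_duration, t1
                break

    rows, lat_rows = [], []
    events: dict[str, float] = {}
    t = 0.0
    total = scenario.total_duration
    while t < total:
        seg_idx = min(np.searchsorted(bounds, t, side="right") - 1, len(segments) - 1)
        ph, start, end = segments[seg_idx]
        f = (t - bounds[seg_idx]) / ph.duration
        tgt = _targets_at(ph, f, start, end, scenario)

        for k in ar:
            ar[k] = phi * ar[k] + innov * rng.normal(0.0, sd[k])
        v = tgt["v"] * np.exp(ar["v"])
        sym = tgt["sym"] * np.exp(ar["sym"])
        vag = tgt["vag"] * np.exp(ar["vag"])
        tone = tgt["tone"] * np.exp(ar["tone"])
        if t_pro0 is not None and t_pro0 <= t < t_syn:
            ramp = min(1.0, (t - t_pro0) / 60.0)
            osc = ramp * np.sin(2.0 * np.pi * (t - t_pro0) / scenario.prodrome_period)
            v *= np.exp(scenario.prodrome_amp_v * osc)
            tone *= np.exp(scenario.prodrome_amp_tone * osc)

        hr = float(np.clip(scenario.baseline_hr * sym ** 0.9 / vag ** 1.1, *HR_ENVELOPE))
        sv = scenario.sv_base * v
        co = sv * hr / 1000.0
        r = r_base * tone ** 2
        mbp = float(np.clip(co * r / 80.0 + scenario.cvp, *MBP_ENVELOPE))
        pp = scenario.pp_base * np.sqrt(v) * np.exp(ar["pp"])
        sbp = mbp + 2.0 * pp / 3.0
        dbp = mbp - pp / 3.0

        z0 = scenario.z0_base * np.exp(ar["z0"])
        lvet = float(np.clip((0.40 - 0.0012 * (hr - 60.0)) * np.exp(ar["lvet"]), 0.15, 0.50))
        trc = 0.15 * np.exp(ar["trc"])
        pep = float(np.clip((0.09 + 0.0004 * (hr - 60.0)) * np.exp(ar["pep"]),
                            0.05, 0.15))
        dzmax = sv * z0 / (vept * lvet)

        rows.append((t, hr, sbp, dbp, mbp, lvet, pep, z0, dzmax, trc))
        lat_rows.append((t, v, sym, vag, tone))
        t += 60.0 / hr

    records = pd.DataFrame(rows, columns=["t", "hr", "sbp", "dbp", "mbp",
                                          "lvet", "pep", "z0", "dzmax", "trc"])
    latents = pd.DataFrame(lat_rows, columns=["t", "venous_return", "sympathetic",
                                              "vagal", "vascular_tone"])

    for (ph, _, _), t0, t1 in zip(segments, bounds[:-1], bounds[1:]):
        if ph.kind == "tilt_transition" and "tilt" not in events:
            events["tilt"] = float(t0)
        elif ph.kind == "ntg" and "ntg" not in events:
            events["ntg"] = float(t0)
        elif ph.kind == "supine_restore" and "supine_restore" not in events:
            events["supine_restore"] = float(t0)
        elif ph.kind == "collapse" and "syncope" not in events:
            if scenario.prodrome_duration > 0:
                events["prodrome_onset"] = float(t0 - scenario.prodrome_duration)
            events["mbp_decline_onset"] = float(t0)
            events["hr_depression_onset"] = float(t0 + scenario.hr_depression_delay)
            events["syncope"] = float(t1)
    truth = GeneratorTruth(events=events, latents=latents)

    if scenario.gap_rate_mbp > 0:
        records = inject_gaps(records, "mbp", scenario.gap_rate_mbp,
                              scenario.gap_burst_length,
                              seed=np.random.SeedSequence(
                                  entropy=scenario.seed & 0x7FFFFFFF, spawn_key=(9,)))
    return records, truth


def inject_gaps(records: pd.DataFrame, channel: str, rate: float,
                burst_length: float = 5.0, seed=0) -> pd.DataFrame:
    """Mask a channel's cells in geometric bursts at a target overall rate.

    A two-state (Gilbert) dropout process: from the good state the channel
    enters a gap with probability rate / (burst_length * (1 - rate)) per
    beat, and leaves it with probability 1 / burst_length, so gaps have
    geometric length (mean ``burst_length``) and the long-run masked
    fraction equals ``rate``.  Returns a copy; only ``channel`` is touched.
    """
    if channel not in records.columns:
        raise ConfigurationError(f"unknown channel {channel!r}")
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError("rate must be in [0, 1)")
    out = records.copy()
    if rate == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    p_enter = rate / (burst_length * (1.0 - rate))
    p_exit = 1.0 / burst_length
    u = rng.random(len(out))
    masked = np.zeros(len(out), dtype=bool)
    state = u[0] < rate  # stationary start
    masked[0] = state
    for k in range(1, len(out)):
        state = (u[k] >= p_exit) if state else (u[k] < p_enter)
        masked[k] = state
    out.loc[masked, channel] = np.nan
    return out


def scenario_presets() -> dict[str, HuttScenario]:
    """Named scenarios spanning the tilt-table outcomes of interest.

    - ``supine_baseline``: stationary quiet rest (robustness / variance
      studies).
    - ``negative_with_ntg``: full negative protocol — supine, tilt,
      passive, NTG provocation, supine restoration; no syncope.
    - ``type1_mixed_early``: VASIS type-1 (mixed) collapse during the
      passive phase, brisk decline.
    - ``type1_mixed_with_warning``: the same collapse preceded by a long,
      initially subclinical decline, so the dependency structure degrades
      well before the blood-pressure criterion is met — the early-warning
      case.
    """
    return {
        "supine_baseline": HuttScenario(
            phases=(Phase("supine_rest", 700.0),)),
        "negative_with_ntg": HuttScenario(
            phases=(Phase("supine_rest", 300.0), Phase("tilt_transition", 15.0),
                    Phase("passive", 900.0), Phase("ntg", 900.0),
                    Phase("supine_restore", 120.0))),
        "type1_mixed_early": HuttScenario(
            phases=(Phase("supine_rest", 300.0), Phase("tilt_transition", 15.0),
                    Phase("passive", 500.0), Phase("collapse", 150.0),
                    Phase("supine_restore", 60.0)),
            syncope="vasis_type1_mixed"),
        "type1_mixed_with_warning": HuttScenario(
            phases=(Phase("supine_rest", 300.0), Phase("tilt_transition", 15.0),
                    Phase("passive", 400.0), Phase("collapse", 240.0),
                    Phase("supine_restore", 60.0)),
            syncope="vasis_type1_mixed",
            hr_depression_delay=90.0,
            prodrome_duration=120.0),
    }


def get_scenario(name: str, seed: int | None = None) -> HuttScenario:
    """Fetch a preset by name, optionally reseeded."""
    presets = scenario_presets()
    if name not in presets:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(presets)}")
    scn = presets[name]
    return replace(scn, seed=seed) if seed is not None else scn


def scenario_to_dict(scn: HuttScenario) -> dict:
    """Plain-dict form of a scenario (YAML/JSON serializable)."""
    d = asdict(scn)
    d["subject"] = {"weight": scn.subject.weight, "height": scn.subject.height,
                    "sex": scn.subject.sex}
    d["phases"] = [[p.kind, p.duration] for p in scn.phases]
    return d


def scenario_from_dict(d: dict) -> HuttScenario:
    d = dict(d)
    if "subject" in d:
        d["subject"] = SubjectAnthropometry(**d["subject"])
    if "phases" in d:
        d["phases"] = tuple(Phase(kind, float(dur)) for kind, dur in d["phases"])
    known = {f.name for f in fields(HuttScenario)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    return HuttScenario(**d)


def save_scenario(scn: HuttScenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=True)


def load_scenario(path) -> HuttScenario:
    """Read a scenario from a YAML file written by :func:`save_scenario`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigurationError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(payload)
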