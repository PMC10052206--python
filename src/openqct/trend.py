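"""Sliding-window complexity trends, gap handling and event timing.

The monitor slides a causal window of W beats (default 100, the window
size best suited to tilt-table monitoring; 50 and 125 trade lag against
noise) along the beat-indexed state matrix, rebuilding the dependency
matrices and the complexity triple {C_min, C, C_critical} on every window
position.  Each trend point is stamped with the *end* time of its window,
so a value at time t uses only beats observed up to t — the online,
early-warning reading of the trend.

Gaps (masked cells, typically in the continuous-BP channel) are handled
per pair: every variable pair is evaluated on its pairwise-complete rows,
and a pair left with fewer than ``min_valid_fraction`` of the window is
forced unstructured for that window.  A window is never aborted by gaps.

Event machinery quantifies the tilt-table phenomenology: a sustained
median + k*MAD exceedance detector for complexity surges (the presyncopal
rise), sustained-drop detectors for the reference MBP and HR events, and
signed lead times in seconds between them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .complexity import ComplexityState, evaluate_window
from .dependency import build_matrices
from .exceptions import InsufficientBaselineError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
SUPPORTED_WINDOWS = (50, 100, 125)  # sizes discussed for tilt-table use


@dataclass
class TrendPoint:
    window_end_time: float
    window_index: int
    state: ComplexityState
    n_beats_used: int


@dataclass
class EventAnnotation:
    kind: str  # tilt | ntg | supine_restore | syncope | presyncope_alert | mbp_drop | hr_drop
    time: float
    detail: str = ""


def sliding_trend(
    data: np.ndarray,
    mask: np.ndarray | None,
    times: np.ndarray,
    window: int = DEFAULT_WINDOW,
    step: int = 1,
    variable_names: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    n_surrogates: int = 200,
    min_valid_fraction: float = 0.5,
    seed: int = 0,
    profile_method: str = "leave_one_out",
) -> list[TrendPoint]:
    """Beat-indexed complexity trend over causal sliding windows.

    Produces floor((M - window)/step) + 1 points; point w covers beats
    [w*step, w*step + window) and is stamped with the last beat's time.
    Raises :class:`InsufficientDataError` when M < window.
    """
    data = np.asarray(data, dtype=float)
    times = np.asarray(times, dtype=float)
    m = data.shape[0]
    if step < 1:
        raise InvalidInputError("step must be >= 1")
    if m < window:
        raise InsufficientDataError(f"record has {m} beats, window needs {window}")
    if mask is None:
        mask = np.isnan(data)
    points: list[TrendPoint] = []
    for w, start in enumerate(range(0, m - window + 1, step)):
        stop = start + window
        rows = slice(start, stop)
        mp = build_matrices(
            data[rows], mask[rows], variable_names=variable_names,
            alpha=alpha, n_surrogates=n_surrogates,
            min_valid_fraction=min_valid_fraction,
            seed=seed, window_index=w,
        )
        if mp.dropped:
            logger.info("window %d: variables isolated by gap policy: %s", w, mp.dropped)
        state = evaluate_window(mp, window_index=w,
                                window_end_time=float(times[stop - 1]),
                                profile_method=profile_method)
        points.append(TrendPoint(window_end_time=float(times[stop - 1]),
                                 window_index=w, state=state,
                                 n_beats_used=int((~mask[rows]).all(axis=1).sum())))
    return points


def trend_arrays(trend: list[TrendPoint]) -> dict[str, np.ndarray]:
    """Column view of a trend: times, C, C_min, C_critical."""
    return {
        "time": np.array([p.window_end_time for p in trend]),
        "C": np.array([p.state.C for p in trend]),
        "C_min": np.array([p.state.C_min for p in trend]),
        "C_critical": np.array([p.state.C_critical for p in trend]),
    }


def _sustained_crossing(flags: np.ndarray, s: int) -> int | None:
    """Index of the first flag that starts a run of >= s consecutive Trues."""
    if s < 1:
        raise InvalidInputError("sustain count must be >= 1")
    run = 0
    for k, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= s:
            return k - s + 1
    return None


def detect_surge(
    trend: list[TrendPoint],
    baseline_span: float,
    k: float = 6.0,
    s: int = 5,
    start_time: float | None = None,
) -> EventAnnotation | None:
    """First sustained complexity surge above the baseline band.

    The baseline band is median(C) + k * MAD(C) over the trend points in
    the first ``baseline_span`` seconds (after ``start_time``, when
    given); an alert is raised at the first time C exceeds the band for
    >= s consecutive points.  Deterministic; returns None for a flat
    trend.  For tilt-table monitoring pass ``start_time`` past the tilt
    stabilization so the detector re-baselines on the standing phase and
    is not triggered by the tilt transient itself.
    """
    cols = trend_arrays(trend)
    t, c = cols["time"], cols["C"]
    if start_time is not None:
        keep = t >= start_time
        t, c = t[keep], c[keep]
        if t.size == 0:
            raise InsufficientBaselineError("no trend points after start_time")
    base = c[t <= t[0] + baseline_span]
    if base.size < 10:
        raise InsufficientBaselineError(
            f"baseline span covers {base.size} trend points, need >= 10")
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    threshold = med + k * mad
    idx = _sustained_crossing(c > threshold, s)
    if idx is None:
        return None
    return EventAnnotation(kind="presyncope_alert", time=float(t[idx]),
                           detail=f"C={c[idx]:.2f} bits > {threshold:.2f} "
                                  f"(median {med:.2f} + {k}*MAD {mad:.2f})")


def _sustained_drop(times: np.ndarray, values: np.ndarray, baseline_span: float,
                    delta: float, s: int, kind: str) -> EventAnnotation | None:
    valid = ~np.isnan(values)
    t, v = times[valid], values[valid]
    base = v[t <= t[0] + baseline_span]
    if base.size < 10:
        raise InsufficientBaselineError(
            f"baseline span covers {base.size} valid beats of {kind}, need >= 10")
    floor = float(np.median(base)) - delta
    idx = _sustained_crossing(v < floor, s)
    if idx is None:
        return None
    return EventAnnotation(kind=kind, time=float(t[idx]),
                           detail=f"value {v[idx]:.1f} below baseline median - {delta:g}")


def reference_events(
    data: np.ndarray,
    times: np.ndarray,
    variable_names: tuple[str, ...],
    baseline_span: float = 300.0,
    d_mbp: float = 20.0,
    d_hr: float = 15.0,
    sustain: int = 5,
) -> list[EventAnnotation]:
    """Reference hemodynamic events: sustained MBP and HR drops.

    ``mbp_drop`` fires at the first beat where MBP stays below its
    baseline median - d_mbp (mmHg) for >= ``sustain`` beats; ``hr_drop``
    analogously with d_hr (bpm).  In a mixed-type vasovagal collapse the
    MBP drop precedes the HR drop.
    """
    names = list(variable_names)
    events: list[EventAnnotation] = []
    for var, delta, kind in (("mbp", d_mbp, "mbp_drop"), ("hr", d_hr, "hr_drop")):
        if var not in names:
            continue
        ev = _sustained_drop(np.asarray(times, dtype=float),
                             np.asarray(data[:, names.index(var)], dtype=float),
                             baseline_span, delta, sustain, kind)
        if ev is not None:
            events.append(ev)
    return events


def lead_time(alert: EventAnnotation | None, reference: EventAnnotation | None) -> float:
    """Seconds by which the alert precedes the reference event.

    Positive = complexity led; negative = complexity lagged.  Raises if
    either annotation is missing.
    """
    if alert is None or reference is None:
        raise InvalidInputError("lead time undefined: missing annotation")
    return reference.time - alert.time
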