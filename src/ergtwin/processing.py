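"""Turn raw ERG sweeps into the standard response parameters.

Pipeline per subject: baseline estimation from the 20 ms preceding the
flash, artifact rejection, sweep averaging within eye, a-/b-wave and
flicker measurement per eye, parameter-level averaging across eyes, and
rod isolation by pointwise subtraction of blue-background (cone-driven)
responses from dark (rod+cone) responses to identical flashes.

Measurement conventions (ISCEV style): the a-wave is reported as the
positive baseline-to-trough excursion with the trough searched in
3–30 ms; the b-wave is trough-to-peak with the peak searched in 10–80 ms;
the 30-Hz flicker amplitude is the mean peak-to-trough excursion over
complete steady-state cycles.  Ties at plateau extrema break to the
earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ergtwin.forward_model import FLICKER_PERIOD_MS, Trace
from ergtwin.protocols import XENON_STRENGTHS, _strength_tag

__all__ = [
    "ArtifactCriteria",
    "A_WINDOW",
    "B_WINDOW",
    "estimate_baseline",
    "reject_artifacts",
    "average_traces",
    "measure_a_wave",
    "measure_b_wave",
    "measure_flicker_amplitude",
    "isolate_rod_response",
    "extract_features",
    "TABLE1_PARAMETERS",
    "CONE_PARAMETERS",
    "ROD_PARAMETERS",
]

#: Default search windows (ms after flash onset).
A_WINDOW = (3.0, 30.0)
B_WINDOW = (10.0, 80.0)

#: The eight standard-protocol parameters (dim-flash a-wave not reported).
TABLE1_PARAMETERS = (
    "DA 0.01 b",
    "DA 3 a", "DA 3 b",
    "DA 10 a", "DA 10 b",
    "LA 30Hz peak",
    "LA 3 a", "LA 3 b",
)
CONE_PARAMETERS = tuple(f"cone {_strength_tag(s)} a" for s in XENON_STRENGTHS)
ROD_PARAMETERS = tuple(f"rod {_strength_tag(s)} a" for s in XENON_STRENGTHS)


@dataclass(frozen=True)
class ArtifactCriteria:
    """Explicit artifact-rejection rule.

    A sweep is rejected if any sample exceeds ``abs_cap`` µV in magnitude,
    or (with at least three sweeps) if its RMS deviation from the pointwise
    median sweep exceeds ``k`` times the scaled median of the per-sweep RMS
    deviations.  If every sweep fails, the single least deviant sweep is
    kept and flagged.
    """

    abs_cap: float = 1000.0
    k: float = 5.0


def estimate_baseline(trace: Trace) -> float:
    """Mean voltage over the 20 ms window preceding flash onset, [-20, 0)."""
    if trace.pre_stimulus_ms < 20.0 - 1e-9:
        raise ValueError("trace must include >= 20 ms of pre-stimulus data")
    mask = (trace.times >= -20.0) & (trace.times < 0.0)
    return float(trace.volts[mask].mean())


def reject_artifacts(
    sweeps: Sequence[Trace],
    criteria: ArtifactCriteria = ArtifactCriteria(),
) -> Tuple[List[Trace], Dict]:
    """Drop artifacted sweeps; never drop everything.

    Returns the kept sweeps and a log dict with per-sweep decisions.
    """
    sweeps = list(sweeps)
    if not sweeps:
        raise ValueError("need at least one sweep")
    volts = np.stack([s.volts for s in sweeps])
    over_cap = np.abs(volts).max(axis=1) > criteria.abs_cap

    if len(sweeps) >= 3:
        median = np.median(volts, axis=0)
        rms_dev = np.sqrt(((volts - median) ** 2).mean(axis=1))
        spread = 1.4826 * np.median(rms_dev)
        over_dev = rms_dev > criteria.k * max(spread, 1e-12)
    else:
        rms_dev = np.abs(volts).max(axis=1)
        over_dev = np.zeros(len(sweeps), dtype=bool)

    rejected = over_cap | over_dev
    log = {
        "n_input": len(sweeps),
        "rejected": [
            {"index": i, "over_cap": bool(over_cap[i]), "over_dev": bool(over_dev[i])}
            for i in range(len(sweeps))
            if rejected[i]
        ],
        "all_failed": False,
    }
    if rejected.all():
        best = int(np.argmin(rms_dev))
        log["all_failed"] = True
        log["kept_best"] = best
        return [sweeps[best]], log
    kept = [s for s, r in zip(sweeps, rejected) if not r]
    log["n_kept"] = len(kept)
    return kept, log


def average_traces(traces: Sequence[Trace], **meta) -> Trace:
    """Pointwise mean of sweeps sharing one time grid."""
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].times
    for tr in traces[1:]:
        if tr.times.shape != t0.shape or not np.allclose(tr.times, t0, rtol=0, atol=1e-9):
            raise ValueError("traces must share an identical time grid")
    mean = np.mean(np.stack([tr.volts for tr in traces]), axis=0)
    m = dict(traces[0].meta)
    m.update(n_averaged=len(traces), **meta)
    return Trace(t0.copy(), mean, m)


def _check_window(trace: Trace, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be ordered (lo < hi)")
    if lo < trace.times[0] or hi > trace.times[-1]:
        raise ValueError("window extends outside the trace span")
    mask = trace.window(lo, hi)
    if not mask.any():
        raise ValueError("window contains no samples")
    return mask


def measure_a_wave(
    trace: Trace,
    baseline: Optional[float] = None,
    window: Tuple[float, float] = A_WINDOW,
) -> Tuple[float, float]:
    """A-wave amplitude (baseline-to-trough, reported positive, floored at
    0) and trough time; earliest sample wins ties."""
    if baseline is None:
        baseline = estimate_baseline(trace)
    mask = _check_window(trace, window)
    v = trace.volts[mask]
    t = trace.times[mask]
    i = int(np.argmin(v))  # argmin returns the first minimum: earliest tie
    return max(baseline - float(v[i]), 0.0), float(t[i])


def measure_b_wave(
    trace: Trace,
    baseline: Optional[float] = None,
    a_window: Optional[Tuple[float, float]] = A_WINDOW,
    b_window: Tuple[float, float] = B_WINDOW,
) -> Tuple[float, float]:
    """B-wave amplitude (a-trough-to-peak) and peak time.

    With ``a_window=None`` (dim flashes with no discernible a-wave) the
    reference is the baseline rather than the trough.
    """
    if baseline is None:
        baseline = estimate_baseline(trace)
    if a_window is not None:
        amask = _check_window(trace, a_window)
        trough = float(trace.volts[amask].min())
        trough = min(trough, baseline)
    else:
        trough = baseline
    bmask = _check_window(trace, b_window)
    v = trace.volts[bmask]
    t = trace.times[bmask]
    i = int(np.argmax(v))
    return max(float(v[i]) - trough, 0.0), float(t[i])


def measure_flicker_amplitude(
    trace: Trace, period_ms: float = FLICKER_PERIOD_MS
) -> float:
    """Mean peak-to-trough amplitude over complete post-onset cycles,
    discarding the first cycle."""
    start = period_ms  # discard first cycle
    n_cycles = int(np.floor((trace.times[-1] - start) / period_ms))
    if n_cycles < 2:
        raise ValueError("need at least two complete cycles after the first")
    amps = []
    for c in range(n_cycles):
        mask = trace.window(start + c * period_ms, start + (c + 1) * period_ms)
        v = trace.volts[mask]
        amps.append(v.max() - v.min())
    return float(np.mean(amps))


def gradient_change_prominence(
    trace: Trace,
    window: Tuple[float, float] = (20.0, 30.0),
    smooth_ms: float = 2.5,
) -> float:
    """Prominence (µV/ms) of a gradient change on the rising b-wave limb.

    Detects an interior local minimum of the (lightly smoothed) first
    derivative inside ``window`` — the waveform-shape signature of a
    shifting ON/OFF balance, seen as an inflection around 25 ms in the
    light-adapted flash response.  Returns 0 when the slope has no
    interior dip.  Prominence is the smaller of the rises flanking the
    deepest dip.
    """
    d1 = np.gradient(trace.volts, trace.times)
    half = max(int(round(smooth_ms / trace.dt / 2)), 1)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    d1s = np.convolve(d1, kernel, mode="same")
    mask = trace.window(*window)
    seg = d1s[mask]
    best = 0.0
    for i in range(1, len(seg) - 1):
        if seg[i] < seg[i - 1] and seg[i] <= seg[i + 1]:
            left = seg[:i + 1].max() - seg[i]
            right = seg[i:].max() - seg[i]
            best = max(best, min(left, right))
    return float(best)


def isolate_rod_response(dark_trace: Trace, blue_background_trace: Trace) -> Trace:
    """Pointwise dark − blue: removes the cone-driven components, leaving
    the estimated dark-adapted rod-driven response.

    Only defined for identical flashes: flash strengths recorded in the
    trace metadata (key ``flash_strength``) must agree.
    """
    fs_d = dark_trace.meta.get("flash_strength")
    fs_b = blue_background_trace.meta.get("flash_strength")
    if fs_d is not None and fs_b is not None and not np.isclose(fs_d, fs_b):
        raise ValueError(
            f"flash strengths differ ({fs_d} vs {fs_b}); "
            "rod isolation requires identical flashes"
        )
    if dark_trace.times.shape != blue_background_trace.times.shape or not np.allclose(
        dark_trace.times, blue_background_trace.times, rtol=0, atol=1e-9
    ):
        raise ValueError("traces must share an identical time grid")
    meta = {
        "component": "rod_isolated",
        "flash_strength": fs_d,
        "parents": [dark_trace.meta.get("stimulus"), blue_background_trace.meta.get("stimulus")],
    }
    for key in ("subject_id", "eye"):
        if key in dark_trace.meta:
            meta[key] = dark_trace.meta[key]
    return Trace(dark_trace.times.copy(), dark_trace.volts - blue_background_trace.volts, meta)


# ---------------------------------------------------------------------------
# session-level feature extraction
# ---------------------------------------------------------------------------

def _eye_average_trace(
    sweeps: Sequence[Trace], criteria: ArtifactCriteria
) -> Tuple[Trace, Dict]:
    kept, log = reject_artifacts(sweeps, criteria)
    return average_traces(kept), log


def extract_features(
    sweeps: Iterable[Trace],
    criteria: ArtifactCriteria = ArtifactCriteria(),
) -> Tuple[Dict[str, float], List[Dict]]:
    """Measure all protocol parameters from a subject's sweeps.

    ``sweeps`` carry metadata keys ``stimulus`` (protocol label), ``eye``
    (``"R"``/``"L"``), ``flash_strength``, ``background`` and ``mode``.
    Sweeps are averaged within eye after artifact rejection, features are
    measured per eye, and the per-eye feature values are averaged.  The
    rod-isolated features come from subtracting each eye's blue-background
    average from its dark average at the same xenon strength.

    Returns the feature dict (parameter name -> µV) and the rejection log.
    """
    by_key: Dict[Tuple[str, str], List[Trace]] = {}
    for sw in sweeps:
        key = (sw.meta["stimulus"], sw.meta.get("eye", "R"))
        by_key.setdefault(key, []).append(sw)

    eye_avg: Dict[Tuple[str, str], Trace] = {}
    logs: List[Dict] = []
    for (label, eye), group in sorted(by_key.items()):
        avg, log = _eye_average_trace(group, criteria)
        log.update(stimulus=label, eye=eye)
        logs.append(log)
        eye_avg[(label, eye)] = avg

    eyes_present = sorted({k[1] for k in eye_avg})
    labels = sorted({k[0] for k in eye_avg})

    def per_eye(label: str, fn) -> Optional[float]:
        vals = []
        for eye in eyes_present:
            tr = eye_avg.get((label, eye))
            if tr is not None:
                vals.append(fn(tr))
        return float(np.mean(vals)) if vals else None

    features: Dict[str, float] = {}

    def put(name: str, value: Optional[float]) -> None:
        if value is not None:
            features[name] = value

    for label in labels:
        any_trace = next(eye_avg[k] for k in eye_avg if k[0] == label)
        mode = any_trace.meta.get("mode", "single_flash")
        if mode == "flicker_30hz":
            put(f"{label} peak", per_eye(label, measure_flicker_amplitude))
            continue
        if label == "DA 0.01":
            # dim-flash a-wave not reported; b-wave referenced to baseline
            put(f"{label} b", per_eye(
                label, lambda tr: measure_b_wave(tr, a_window=None)[0]))
            continue
        if label.startswith(("DA", "LA")):
            put(f"{label} a", per_eye(label, lambda tr: measure_a_wave(tr)[0]))
            put(f"{label} b", per_eye(label, lambda tr: measure_b_wave(tr)[0]))

    # cone-driven a-waves (blue background) and rod-isolated a-waves
    for strength in XENON_STRENGTHS:
        tag = _strength_tag(strength)
        dark_label, blue_label = f"X{tag}-dark", f"X{tag}-blue"
        put(f"cone {tag} a", per_eye(blue_label, lambda tr: measure_a_wave(tr)[0]))
        rod_vals = []
        for eye in eyes_present:
            d = eye_avg.get((dark_label, eye))
            b = eye_avg.get((blue_label, eye))
            if d is not None and b is not None:
                rod = isolate_rod_response(d, b)
                rod_vals.append(measure_a_wave(rod)[0])
        if rod_vals:
            features[f"rod {tag} a"] = float(np.mean(rod_vals))

    return features, logs


def features_to_frame(rows: Dict[str, Dict[str, float]]) -> pd.DataFrame:
    """Stack per-subject feature dicts into a wide table (rows = subjects)."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
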