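"""Deterministic cellular-component generative model of full-field ERG traces.

The corneal ERG is modelled as an additive superposition of stylized
cellular components:

* rod and cone photoreceptor PIII — a saturating-exponential negative
  deflection (the a-wave generator),
* rod- and cone-driven ON-bipolar PII — a positive gamma-shaped kernel
  (the b-wave generator),
* a cone-driven OFF-bipolar kernel — biphasic (early negative lobe adding
  to the cone a-wave trough, later positive lobe adding to the b-wave
  region),
* oscillatory potentials — a damped sinusoid riding the rising b-wave,
  gated on the ON-bipolar gain (amacrine activity is driven by the ON
  pathway, so selective ON loss silences the oscillations too).

Backgrounds modify the component mix: a blue rod-saturating background
suppresses the rod pathway (completely in the idealized default), and the
standard white photopic background additionally scales the cone pathway by
a light-adaptation factor.  Lesion switches emulate recordings from eyes
with central retinal artery occlusion (CRAO: all postreceptoral components
lost, photoreceptors intact) and complete congenital stationary night
blindness (cCSNB: ON-bipolar signals selectively lost).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

__all__ = [
    "StimulusSpec",
    "CellularGains",
    "Trace",
    "ERGResponse",
    "LesionType",
    "LESION_TYPES",
    "make_time_grid",
    "photoreceptor_piii",
    "gamma_kernel",
    "bipolar_kernel",
    "off_bipolar_kernel",
    "oscillatory_potentials",
    "apply_lesion",
    "synthesize_flash_response",
    "synthesize_flicker_response",
    "flicker_steady_state_amplitude",
    "add_noise",
]

# Closed enumeration of lesion switches.
LESION_TYPES = ("none", "crao", "ccsnb")
LesionType = str

FLICKER_PERIOD_MS = 1000.0 / 30.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """A single full-field stimulus.

    Parameters
    ----------
    label : str
        Protocol name, e.g. ``"DA 3"`` or ``"X67-blue"``.
    flash_strength : float
        Flash energy in photopic cd·m⁻²·s (must be positive).
    background_kind : str
        One of ``"dark"``, ``"blue_rod_saturating"``, ``"white_photopic"``.
    background_scotopic_luminance, background_photopic_luminance : float
        Steady background luminances (scotopic / photopic cd·m⁻²).
    mode : str
        ``"single_flash"`` or ``"flicker_30hz"``.
    """

    label: str
    flash_strength: float
    background_kind: str = "dark"
    background_scotopic_luminance: float = 0.0
    background_photopic_luminance: float = 0.0
    mode: str = "single_flash"

    def __post_init__(self) -> None:
        if self.flash_strength <= 0:
            raise ValueError("flash_strength must be positive")
        if self.background_kind not in ("dark", "blue_rod_saturating", "white_photopic"):
            raise ValueError(f"unknown background_kind {self.background_kind!r}")
        if self.mode not in ("single_flash", "flicker_30hz"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.background_kind == "dark" and (
            self.background_scotopic_luminance != 0.0
            or self.background_photopic_luminance != 0.0
        ):
            raise ValueError("dark background must have zero luminance")

    @classmethod
    def blue_background(cls, label: str, flash_strength: float) -> "StimulusSpec":
        """Flash on the standard dim blue rod-saturating background
        (30 scotopic and 1 photopic cd·m⁻²)."""
        return cls(
            label=label,
            flash_strength=flash_strength,
            background_kind="blue_rod_saturating",
            background_scotopic_luminance=30.0,
            background_photopic_luminance=1.0,
        )

    @classmethod
    def white_background(
        cls, label: str, flash_strength: float, mode: str = "single_flash"
    ) -> "StimulusSpec":
        """Flash (or 30-Hz flicker) on the standard white photopic background
        (30 photopic cd·m⁻²)."""
        return cls(
            label=label,
            flash_strength=flash_strength,
            background_kind="white_photopic",
            background_scotopic_luminance=0.0,
            background_photopic_luminance=30.0,
            mode=mode,
        )


@dataclass(frozen=True)
class CellularGains:
    """Per-subject amplitudes, sensitivities and kernel shapes of the
    cellular ERG components.

    All gains are in µV, delays/peak times in ms, sensitivities in
    (photopic cd·m⁻²·s)⁻¹·ms⁻², half-saturation constants in photopic
    cd·m⁻²·s.
    """

    # photoreceptor PIII
    rod_pr_max: float = 130.4
    cone_pr_max: float = 30.8
    rod_sensitivity: float = 0.003833
    cone_sensitivity: float = 0.000866
    rod_delay: float = 2.5
    cone_delay: float = 1.5
    # bipolar pathway gains
    on_bipolar_gain: float = 118.9
    off_bipolar_gain: float = 29.64
    op_gain: float = 6.0
    # ON (PII) kernel shapes
    rod_pii_weight: float = 2.223        # rod PII amplitude relative to on_bipolar_gain
    rod_pii_onset: float = 30.0          # rod b-wave silent through the a-wave window
    rod_pii_peak: float = 55.0
    rod_pii_shape: float = 3.0
    cone_on_onset: float = 13.73
    cone_on_peak: float = 29.4
    cone_on_shape: float = 3.0
    # OFF kernel (difference of gammas): a plateau-like sustained negative
    # lobe (hyperpolarization, low shape exponent) and a sharper, later
    # positive lobe
    off_neg_onset: float = 2.0
    off_neg_peak: float = 32.0
    off_neg_shape: float = 0.5
    off_pos_onset: float = 23.55
    off_pos_peak: float = 28.94
    off_pos_shape: float = 4.0
    off_pos_weight: float = 1.5          # positive-lobe amplitude relative to off_bipolar_gain
    # pathway drive half-saturations / tuning
    rod_pii_i50: float = 0.001254
    cone_on_i50: float = 1.311           # cone ON-pathway half-saturation
    off_neg_i50: float = 0.7374          # OFF negative-lobe half-saturation
    off_pos_i_peak: float = 3.0          # flash strength of maximal OFF positive-lobe drive
    # oscillatory potentials
    op_frequency: float = 120.0          # Hz
    op_damping: float = 0.18             # 1/ms
    op_onset: float = 13.0
    # light adaptation of the cone pathway on the white photopic background
    cone_adaptation: float = 0.9546

    def __post_init__(self) -> None:
        for name in (
            "rod_pr_max", "cone_pr_max", "on_bipolar_gain", "off_bipolar_gain",
            "op_gain", "rod_pii_weight", "off_pos_weight",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rod_sensitivity", "cone_sensitivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rod_delay", "cone_delay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rod_pii_peak", "cone_on_peak", "off_neg_peak", "off_pos_peak"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kw) -> "CellularGains":
        return dataclasses.replace(self, **kw)


@dataclass
class Trace:
    """Uniformly sampled voltage-vs-time sweep (µV vs ms), time zero at
    flash onset."""

    times: np.ndarray
    volts: np.ndarray
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volts = np.asarray(self.volts, dtype=float)
        if self.times.shape != self.volts.shape:
            raise ValueError("times and volts must have identical shape")
        if self.times.size < 2:
            raise ValueError("trace needs at least two samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("time grid must be strictly uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def sample_rate_khz(self) -> float:
        return 1.0 / self.dt

    @property
    def pre_stimulus_ms(self) -> float:
        return float(-self.times[0])

    def copy(self, volts: Optional[np.ndarray] = None, **meta) -> "Trace":
        m = dict(self.meta)
        m.update(meta)
        return Trace(self.times.copy(),
                     self.volts.copy() if volts is None else np.asarray(volts, float),
                     m)

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask for samples with t0 <= t <= t1."""
        return (self.times >= t0) & (self.times <= t1)


@dataclass
class ERGResponse:
    """A synthesized response: the summed trace plus labelled component
    sub-traces whose voltages add exactly to the summed trace."""

    trace: Trace
    components: Dict[str, Trace]


def make_time_grid(pre_ms: float = 20.0, post_ms: float = 250.0, dt_ms: float = 0.5) -> np.ndarray:
    """Uniform sample grid spanning [-pre_ms, post_ms]; flash onset at 0."""
    if pre_ms < 20.0:
        raise ValueError("pre-stimulus span must be >= 20 ms (baseline window)")
    n = int(round((pre_ms + post_ms) / dt_ms))
    return -pre_ms + dt_ms * np.arange(n + 1)


# ---------------------------------------------------------------------------
# component primitives
# ---------------------------------------------------------------------------

def photoreceptor_piii(
    t: np.ndarray,
    flash_strength: float,
    sensitivity: float,
    max_amp: float,
    delay: float,
) -> np.ndarray:
    """Saturating photoreceptor (PIII) response.

    ``-max_amp * (1 - exp(-flash_strength * sensitivity * (t - delay)^2))``
    for ``t > delay`` and 0 before; a negative-going deflection whose
    magnitude grows monotonically with time and flash strength.
    """
    if flash_strength < 0:
        raise ValueError("flash_strength must be >= 0")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    if max_amp < 0:
        raise ValueError("max_amp must be >= 0")
    t = np.asarray(t, dtype=float)
    tau = t - delay
    out = np.zeros_like(t)
    late = tau > 0
    out[late] = -max_amp * (
        1.0 - np.exp(-flash_strength * sensitivity * tau[late] ** 2)
    )
    return out


def gamma_kernel(
    t: np.ndarray, peak_time: float, shape_exponent: float, onset: float = 0.0
) -> np.ndarray:
    """Unit-peak gamma kernel ``(x)^n exp(n(1-x))`` with ``x = (t-onset)/(peak-onset)``.

    Exactly zero for ``t <= onset`` and exactly 1 at ``t == peak_time``.
    """
    if peak_time <= onset:
        raise ValueError("peak_time must exceed onset")
    t = np.asarray(t, dtype=float)
    tau = t - onset
    tp = peak_time - onset
    out = np.zeros_like(t)
    late = tau > 0
    x = tau[late] / tp
    out[late] = x ** shape_exponent * np.exp(shape_exponent * (1.0 - x))
    return out


def bipolar_kernel(
    t: np.ndarray,
    gain: float,
    peak_time: float,
    shape_exponent: float,
    polarity: int = 1,
    onset: float = 0.0,
) -> np.ndarray:
    """Monophasic bipolar-cell kernel: ``polarity * gain`` at ``peak_time``.

    The depolarizing ON (PII) kernel uses ``polarity=+1``; the lobes of the
    biphasic OFF kernel are built from two calls with opposite polarity (see
    :func:`off_bipolar_kernel`).
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if peak_time <= 0:
        raise ValueError("peak_time must be > 0")
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    return polarity * gain * gamma_kernel(t, peak_time, shape_exponent, onset)


def off_bipolar_kernel(
    t: np.ndarray,
    neg_amp: float,
    pos_amp: float,
    neg_peak: float,
    pos_peak: float,
    neg_shape: float,
    pos_shape: float,
    neg_onset: float = 0.0,
    pos_onset: float = 0.0,
) -> np.ndarray:
    """Biphasic OFF-bipolar kernel: difference of two gamma kernels.

    The negative lobe (low shape exponent: fast onset, sustained plateau)
    deepens the cone a-wave trough; the sharper, later positive lobe
    contributes to the b-wave region and produces the ~25 ms gradient
    change in the light-adapted flash response.  The negative extremum
    reached inside the measurement span precedes the positive one.
    """
    if neg_onset >= pos_onset:
        raise ValueError("negative lobe must start before the positive lobe")
    return bipolar_kernel(t, neg_amp, neg_peak, neg_shape, -1, neg_onset) + \
        bipolar_kernel(t, pos_amp, pos_peak, pos_shape, +1, pos_onset)


def oscillatory_potentials(
    t: np.ndarray,
    gain: float,
    frequency: float = 120.0,
    damping: float = 0.09,
    onset: float = 13.0,
) -> np.ndarray:
    """Damped sinusoid (amacrine-cell oscillatory potentials); zero before onset."""
    if gain < 0:
        raise ValueError("gain must be >= 0")
    if damping < 0:
        raise ValueError("damping must be >= 0")
    t = np.asarray(t, dtype=float)
    tau = t - onset
    out = np.zeros_like(t)
    late = tau > 0
    out[late] = (
        gain
        * np.exp(-damping * tau[late])
        * np.sin(2.0 * np.pi * frequency * tau[late] / 1000.0)
    )
    return out


def apply_lesion(gains: CellularGains, lesion: LesionType) -> CellularGains:
    """Zero the component gains lost under a lesion.

    ``crao`` removes every postreceptoral component (photoreceptors are
    supplied by the choroid and survive); ``ccsnb`` selectively removes the
    ON-bipolar signal; ``none`` is the identity.
    """
    if lesion == "none":
        return gains
    if lesion == "crao":
        return gains.replace(on_bipolar_gain=0.0, off_bipolar_gain=0.0, op_gain=0.0)
    if lesion == "ccsnb":
        return gains.replace(on_bipolar_gain=0.0)
    raise ValueError(f"unknown lesion {lesion!r}; expected one of {LESION_TYPES}")


# ---------------------------------------------------------------------------
# drive nonlinearities (flash strength -> component amplitude scaling)
# ---------------------------------------------------------------------------

def _naka_rushton(i: float, i50: float) -> float:
    return i / (i + i50)


def _bell_drive(i: float, i_peak: float) -> float:
    """Unit-max drive (i/i_peak)·exp(1-i/i_peak): rises to 1 at ``i_peak``
    then falls.  Models the disappearance of the OFF positive lobe from
    bright-flash cone b-waves while it remains prominent at the standard
    photopic flash strength."""
    x = i / i_peak
    return x * np.exp(1.0 - x)


def _pathway_scales(stimulus: StimulusSpec, rod_suppression: float,
                    cone_desensitization: float, gains: CellularGains):
    """(rod_scale, cone_scale) applied multiplicatively to pathway gains."""
    if not (0.0 <= rod_suppression <= 1.0):
        raise ValueError("rod_suppression must be in [0, 1]")
    if not (0.0 < cone_desensitization <= 1.0):
        raise ValueError("cone_desensitization must be in (0, 1]")
    if stimulus.background_kind == "dark":
        return 1.0, 1.0
    if stimulus.background_kind == "blue_rod_saturating":
        return 1.0 - rod_suppression, cone_desensitization
    # white photopic background: rods saturated, cones light-adapted
    return 1.0 - rod_suppression, gains.cone_adaptation


def _flash_components(
    t: np.ndarray,
    stimulus: StimulusSpec,
    gains: CellularGains,
    rod_scale: float,
    cone_scale: float,
) -> Dict[str, np.ndarray]:
    """Component voltage arrays for a single flash on grid ``t``."""
    g = gains
    i = stimulus.flash_strength

    rod_pr = photoreceptor_piii(
        t, i, g.rod_sensitivity, g.rod_pr_max * rod_scale, g.rod_delay
    )
    cone_pr = photoreceptor_piii(
        t, i, g.cone_sensitivity, g.cone_pr_max * cone_scale, g.cone_delay
    )

    rod_on_amp = (
        g.on_bipolar_gain * g.rod_pii_weight * rod_scale * _naka_rushton(i, g.rod_pii_i50)
    )
    rod_on = bipolar_kernel(
        t, rod_on_amp, g.rod_pii_peak, g.rod_pii_shape, 1, g.rod_pii_onset
    )

    cone_on_drive = _naka_rushton(i, g.cone_on_i50)
    cone_on = bipolar_kernel(
        t, g.on_bipolar_gain * cone_scale * cone_on_drive,
        g.cone_on_peak, g.cone_on_shape, 1, g.cone_on_onset,
    )

    off = off_bipolar_kernel(
        t,
        neg_amp=g.off_bipolar_gain * cone_scale * _naka_rushton(i, g.off_neg_i50),
        pos_amp=g.off_bipolar_gain * g.off_pos_weight * cone_scale
        * _bell_drive(i, g.off_pos_i_peak),
        neg_peak=g.off_neg_peak,
        pos_peak=g.off_pos_peak,
        neg_shape=g.off_neg_shape,
        pos_shape=g.off_pos_shape,
        neg_onset=g.off_neg_onset,
        pos_onset=g.off_pos_onset,
    )

    # Oscillatory potentials are gated on the ON-bipolar gain: amacrine
    # cells are driven through the ON pathway, so selective ON loss (cCSNB)
    # silences them along with the PII.  The drive is cone-ON based, so rod
    # suppression by a background leaves the oscillations untouched.
    on_gate = min(g.on_bipolar_gain / CellularGains.on_bipolar_gain, 1.0)
    op_amp = g.op_gain * on_gate * cone_scale * cone_on_drive
    op = oscillatory_potentials(t, op_amp, g.op_frequency, g.op_damping, g.op_onset)

    return {
        "rod_pr": rod_pr,
        "cone_pr": cone_pr,
        "rod_on_bipolar": rod_on,
        "cone_on_bipolar": cone_on,
        "cone_off_bipolar": off,
        "oscillatory": op,
    }


# Components that belong to the rod pathway (zeroed by rod-saturating
# backgrounds in idealized mode).
ROD_PATHWAY = ("rod_pr", "rod_on_bipolar")
COMPONENT_ORDER = (
    "rod_pr", "cone_pr", "rod_on_bipolar", "cone_on_bipolar",
    "cone_off_bipolar", "oscillatory",
)


def synthesize_flash_response(
    stimulus: StimulusSpec,
    gains: CellularGains,
    lesion: LesionType = "none",
    *,
    rod_suppression: float = 1.0,
    cone_desensitization: float = 1.0,
    grid: Optional[np.ndarray] = None,
) -> ERGResponse:
    """Noiseless single-flash response: component sum plus labelled sub-traces.

    ``rod_suppression`` is the fraction of the rod pathway silenced by a
    background (1.0 = complete, the idealized default; lower values model
    incomplete rod saturation).  ``cone_desensitization`` scales cone gains
    on the blue background (1.0 = cones unaffected, the idealized default).
    """
    if stimulus.mode != "single_flash":
        raise ValueError("use synthesize_flicker_response for flicker stimuli")
    t = make_time_grid() if grid is None else np.asarray(grid, dtype=float)
    g = apply_lesion(gains, lesion)
    rod_scale, cone_scale = _pathway_scales(
        stimulus, rod_suppression, cone_desensitization, g
    )
    comps = _flash_components(t, stimulus, g, rod_scale, cone_scale)
    total = np.zeros_like(t)
    for name in COMPONENT_ORDER:
        total = total + comps[name]
    meta = {"stimulus": stimulus.label, "lesion": lesion, "component": "sum"}
    return ERGResponse(
        trace=Trace(t, total, meta),
        components={
            name: Trace(t, comps[name], {**meta, "component": name})
            for name in COMPONENT_ORDER
        },
    )


def _flicker_voltage(
    times: np.ndarray,
    stimulus: StimulusSpec,
    gains: CellularGains,
    rod_scale: float,
    cone_scale: float,
) -> np.ndarray:
    """Steady-state 30-Hz voltage: the periodic superposition of single-flash
    responses, evaluated as a function of ``t mod period``.

    The photoreceptor PIII plateau is treated as recovering after one
    flicker period (the photoreceptors sit at a steady adaptation level
    under rapid flicker, so their plateau telescopes to a DC term), which
    makes the superposition convergent and leaves the flicker modulation
    dominated by the transient postreceptoral components — the known
    physiology of the 30-Hz flicker response.
    """
    period = FLICKER_PERIOD_MS
    g = gains
    i = stimulus.flash_strength
    tau = np.mod(times, period)
    # wrap depth: enough that even the slow OFF-lobe tail is < 1e-9 uV
    n_wrap = 60
    v = np.zeros_like(tau)
    for k in range(n_wrap):
        t_k = tau + k * period
        comps = _flash_components(t_k, stimulus, g, rod_scale, cone_scale)
        for name in COMPONENT_ORDER:
            v = v + comps[name]
        # one-period PIII recovery (release of the previous plateau)
        v = v - photoreceptor_piii(
            t_k - period, i, g.rod_sensitivity, g.rod_pr_max * rod_scale, g.rod_delay
        )
        v = v - photoreceptor_piii(
            t_k - period, i, g.cone_sensitivity, g.cone_pr_max * cone_scale, g.cone_delay
        )
    return v


def synthesize_flicker_response(
    stimulus: StimulusSpec,
    gains: CellularGains,
    lesion: LesionType = "none",
    *,
    rod_suppression: float = 1.0,
    cone_desensitization: float = 1.0,
    grid: Optional[np.ndarray] = None,
) -> Trace:
    """Periodic steady-state 30-Hz flicker response (cone-driven: the white
    background saturates the rod pathway)."""
    if stimulus.mode != "flicker_30hz":
        raise ValueError("use synthesize_flash_response for single flashes")
    t = make_time_grid() if grid is None else np.asarray(grid, dtype=float)
    g = apply_lesion(gains, lesion)
    rod_scale, cone_scale = _pathway_scales(
        stimulus, rod_suppression, cone_desensitization, g
    )
    v = _flicker_voltage(t, stimulus, g, rod_scale, cone_scale)
    return Trace(t, v, {"stimulus": stimulus.label, "lesion": lesion, "component": "sum"})


def flicker_steady_state_amplitude(
    stimulus: StimulusSpec,
    gains: CellularGains,
    lesion: LesionType = "none",
    *,
    rod_suppression: float = 1.0,
    cone_desensitization: float = 1.0,
    dt_ms: float = 0.01,
) -> float:
    """Peak-to-trough amplitude of one steady-state flicker cycle, from a
    dense evaluation (the generator-side reference for round-trip tests)."""
    g = apply_lesion(gains, lesion)
    rod_scale, cone_scale = _pathway_scales(
        stimulus, rod_suppression, cone_desensitization, g
    )
    tt = np.arange(0.0, FLICKER_PERIOD_MS, dt_ms)
    v = _flicker_voltage(tt, stimulus, g, rod_scale, cone_scale)
    return float(v.max() - v.min())


def add_noise(
    trace: Trace,
    noise_sd: float,
    drift_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Trace:
    """White Gaussian sample noise plus an optional slow baseline drift
    (one sinusoidal period across the sweep with random amplitude/phase).
    Reproducible under a fixed seed or generator."""
    if noise_sd < 0 or drift_sd < 0:
        raise ValueError("noise_sd and drift_sd must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    v = trace.volts.copy()
    if drift_sd > 0:
        span = trace.times[-1] - trace.times[0]
        amp = rng.normal(0.0, drift_sd)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        v = v + amp * np.sin(2.0 * np.pi * (trace.times - trace.times[0]) / span + phase)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return trace.copy(volts=v)
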