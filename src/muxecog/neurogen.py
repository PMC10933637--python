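"""Synthetic ground truth for grid-organized cortical field potentials.

Generates what an epidural micro-electrode grid sees under anesthesia:

* a 1/f-shaped stochastic background shared partially across channels,
* band-limited oscillatory events — delta (1-4 Hz) waves covering most of the
  grid, spindles (10-16 Hz) and ripples (100-150 Hz) spatially confined to a
  few electrodes — with optional delta/spindle/ripple coupling,
* somatosensory evoked potentials (SSEPs) time-locked to stimulation triggers
  with a localized Gaussian spatial footprint, and
* per-electrode DC offsets (open-circuit electrode potentials, hundreds of mV).

Everything is driven by a seeded generator and bookkept: every injected event
is returned in a ground-truth table so detectors can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GridGeometry, TraceSet

__all__ = [
    "BandEventSpec",
    "NeuralFieldConfig",
    "StimProtocol",
    "generate_field",
    "generate_ssep_trials",
    "draw_edos",
    "ssep_template",
]

#: span of a burst in units of its Gaussian-envelope sigma.  The nominal event
#: duration is the interval where the envelope exceeds ~20% of its peak
#: (+-1.8 sigma), which is what an envelope-threshold detector measures for
#: events 4-6x above background.
_ENVELOPE_SPAN = 3.6


@dataclass(frozen=True)
class BandEventSpec:
    """One oscillatory event class (delta / spindle / ripple).

    Durations are drawn log-normally around ``duration_median_ms`` with
    log-sigma ``duration_spread``; center frequencies normally around
    ``center_freq_hz`` (sd ``freq_sd_hz``).  ``spatial_sd_um=None`` means the
    event covers the whole grid ("global").
    """

    rate_per_s: float
    amplitude_uv: float
    center_freq_hz: float
    freq_sd_hz: float = 0.0
    duration_median_ms: float = 100.0
    duration_spread: float = 0.3
    duration_bounds_ms: tuple[float, float] = (30.0, 350.0)
    spatial_center: tuple[int, int] | None = None  # (row, col); None -> grid center
    spatial_sd_um: float | None = None  # None -> global
    min_gap_ms: float = 250.0  # refractory spacing between event onsets

    def __post_init__(self) -> None:
        if self.rate_per_s < 0 or self.amplitude_uv < 0:
            raise ValueError("rate and amplitude must be >= 0")
        if self.spatial_sd_um is not None and self.spatial_sd_um <= 0:
            raise ValueError("spatial_sd_um must be > 0 or None (global)")
        lo, hi = self.duration_bounds_ms
        if not 0 < lo < hi:
            raise ValueError("duration bounds must satisfy 0 < lo < hi")


def _default_bands() -> dict[str, BandEventSpec]:
    # Delta waves are near-global; spindle/ripple activity confined to a
    # ~2 x 1.5 mm^2 patch (4x3 electrodes at 500 um pitch -> Gaussian sd
    # ~500 um).  Ripple statistics follow the physiology: median duration
    # 96 ms with log-sd 0.5 (SD ~58 ms), peak frequency 134 +- 9 Hz, rate
    # 0.75 events/s.
    return {
        "delta": BandEventSpec(
            rate_per_s=0.5,
            amplitude_uv=200.0,
            center_freq_hz=2.0,
            freq_sd_hz=0.5,
            duration_median_ms=900.0,
            duration_spread=0.2,
            duration_bounds_ms=(500.0, 2000.0),
            spatial_sd_um=None,
            min_gap_ms=400.0,
        ),
        "spindle": BandEventSpec(
            rate_per_s=0.3,
            amplitude_uv=60.0,
            center_freq_hz=13.0,
            freq_sd_hz=1.0,
            duration_median_ms=500.0,
            duration_spread=0.2,
            duration_bounds_ms=(300.0, 1200.0),
            spatial_sd_um=700.0,
            min_gap_ms=400.0,
        ),
        "ripple": BandEventSpec(
            rate_per_s=0.75,
            amplitude_uv=80.0,
            center_freq_hz=134.0,
            freq_sd_hz=9.0,
            duration_median_ms=96.0,
            duration_spread=0.5,
            duration_bounds_ms=(30.0, 350.0),
            spatial_sd_um=500.0,
            min_gap_ms=250.0,
        ),
    }


@dataclass(frozen=True)
class NeuralFieldConfig:
    """Generative model of spontaneous cortical activity on the grid.

    Background: white Gaussian noise shaped to a 1/f^beta *amplitude*
    spectrum (power falls as f^(-2 beta)) and scaled to ``background_rms_uv``,
    mixed from a grid-common and a per-channel independent component
    (``background_common_frac``).  Events per band per :class:`BandEventSpec`.
    """

    duration_s: float
    fs_hz: float = 16000.0
    background_rms_uv: float = 150.0
    background_exponent: float = 1.0  # beta of the 1/f^beta amplitude spectrum
    background_common_frac: float = 0.5
    bands: dict[str, BandEventSpec] = field(default_factory=_default_bands)
    coupling: bool = True  # snap ripples to delta rising phase, spindles nearby
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_hz <= 0:
            raise ValueError("duration and sampling rate must be > 0")
        if self.background_rms_uv < 0:
            raise ValueError("background RMS must be >= 0")
        if not 0.0 <= self.background_common_frac <= 1.0:
            raise ValueError("background_common_frac must be in [0, 1]")


@dataclass(frozen=True)
class StimProtocol:
    """Peripheral stimulation protocol and the SSEP it evokes.

    The template is a first positive lobe (Gaussian, ``peak_amplitude_uv`` at
    ``peak_latency_ms`` post-trigger, width ``peak_width_ms`` FWHM) followed by
    an optional broader opposite-polarity lobe.  The response is focal: a
    Gaussian spatial footprint around ``contra_center`` and a weaker, delayed
    mirror response in the ipsilateral hemisphere.
    """

    pulse_amplitude_ua: float = 200.0
    pulse_width_ms: float = 2.0
    rate_hz: float = 1.0
    n_trials: int = 100
    peak_amplitude_uv: float = 580.0
    peak_latency_ms: float = 20.0
    peak_width_ms: float = 10.0
    second_lobe_scale: float = -0.4  # relative to first peak; 0 disables
    second_lobe_delay_ms: float = 25.0
    second_lobe_width_ms: float = 30.0
    contra_center: tuple[int, int] = (4, 4)
    spatial_sd_um: float = 500.0
    ipsi_center: tuple[int, int] | None = None  # None -> no ipsilateral lobe
    ipsi_scale: float = 0.15
    ipsi_extra_latency_ms: float = 10.0
    amplitude_jitter_cv: float = 0.10
    latency_jitter_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.peak_latency_ms <= 0:
            raise ValueError("latency must be > 0")
        if self.rate_hz <= 0:
            raise ValueError("stimulation rate must be > 0")
        for name in ("peak_amplitude_uv", "pulse_amplitude_ua"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def template_support_s(self) -> float:
        """Duration after the trigger over which the template is nonzero."""
        end = self.peak_latency_ms + 3 * self.peak_width_ms
        if self.second_lobe_scale != 0.0:
            end = max(
                end,
                self.peak_latency_ms
                + self.second_lobe_delay_ms
                + 3 * self.second_lobe_width_ms,
            )
        return (end + self.ipsi_extra_latency_ms) / 1e3


# --------------------------------------------------------------------------
# background


def _one_over_f(rng: np.random.Generator, n: int, fs: float, beta: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^beta amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-beta)
    shaping[0] = 0.0  # no DC in the background (electrode DC handled separately)
    shaped = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _background(
    rng: np.random.Generator, geom: GridGeometry, n: int, cfg: NeuralFieldConfig
) -> np.ndarray:
    if cfg.background_rms_uv == 0:
        return np.zeros((geom.n_channels, n))
    common = _one_over_f(rng, n, cfg.fs_hz, cfg.background_exponent)
    a = np.sqrt(cfg.background_common_frac)
    b = np.sqrt(1.0 - cfg.background_common_frac)
    out = np.empty((geom.n_channels, n))
    for ch in range(geom.n_channels):
        own = _one_over_f(rng, n, cfg.fs_hz, cfg.background_exponent)
        out[ch] = cfg.background_rms_uv * (a * common + b * own)
    return out


# --------------------------------------------------------------------------
# event placement


def _place_events(
    rng: np.random.Generator,
    n_events: int,
    durations_s: np.ndarray,
    total_s: float,
    min_gap_s: float,
) -> np.ndarray:
    """Hard-core placement: n event centers, no two bursts closer than the gap.

    Draws Poisson-count events elsewhere; here the count is given and centers
    are uniform conditional on pairwise spacing >= half-durations + gap.
    Returns center times (s), sorted.  Raises if the events cannot fit.
    """
    if n_events == 0:
        return np.empty(0)
    order = rng.permutation(n_events)  # random assignment of durations to slots
    d = durations_s[order]
    # spacing consumed between consecutive centers
    spacing = 0.5 * (d[:-1] + d[1:]) + min_gap_s if n_events > 1 else np.empty(0)
    edge = 0.5 * d[0] + 0.5 * d[-1]  # keep bursts inside the recording
    slack = total_s - float(np.sum(spacing)) - edge
    if slack <= 0:
        raise ValueError(
            f"duration {total_s} s too short for {n_events} events with the "
            "requested durations and minimum gap"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n_events))
    centers = 0.5 * d[0] + u + np.concatenate([[0.0], np.cumsum(spacing)])
    # undo the duration permutation so centers[i] pairs with durations_s[i]
    out = np.empty(n_events)
    out[order] = centers
    return out


def _burst(
    t: np.ndarray, center_s: float, duration_s: float, freq_hz: float, phase: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid; envelope sigma = duration / _ENVELOPE_SPAN."""
    sigma = duration_s / _ENVELOPE_SPAN
    env = np.exp(-0.5 * ((t - center_s) / sigma) ** 2)
    return env * np.sin(2 * np.pi * freq_hz * (t - center_s) + phase)


def _spatial_weights(
    geom: GridGeometry, spec: BandEventSpec
) -> tuple[np.ndarray, int]:
    if spec.spatial_center is None:
        row, col = geom.rows // 2, geom.cols // 2
    else:
        row, col = spec.spatial_center
    center_ch = geom.channel_index(row, col)
    if spec.spatial_sd_um is None:
        return np.ones(geom.n_channels), center_ch
    d = geom.distances_um(row, col)
    return np.exp(-0.5 * (d / spec.spatial_sd_um) ** 2), center_ch


def _delta_rising_times(events: pd.DataFrame) -> np.ndarray:
    """Trough-to-crest transition times of placed delta waves.

    For a sine burst sin(2 pi f (t - c)), troughs occur at phase 3pi/2 and the
    following crest at 5pi/2; the midpoint (rising zero-crossing) of every
    cycle inside the burst core (+-1 sigma-span/2) is a candidate.
    """
    times: list[float] = []
    for _, ev in events.iterrows():
        period = 1.0 / ev.center_freq_hz
        half = 0.5 * (ev.end_s - ev.start_s)
        k = np.arange(-int(half / period), int(half / period) + 1)
        times.extend(ev.start_s + half + k * period)  # rising crossings at phase 0
    return np.asarray(sorted(times))


def generate_field(
    geom: GridGeometry, cfg: NeuralFieldConfig
) -> tuple[TraceSet, pd.DataFrame]:
    """Synthesize spontaneous activity; returns traces plus ground-truth events.

    The event table has columns ``event_id, kind, channel, start_s, end_s,
    center_freq_hz, amplitude_uv`` where ``channel`` is the spatial-center
    electrode and start/end delimit the nominal burst duration (envelope above
    ~20% of peak).  Bitwise-reproducible for a given (config, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    data_uv = _background(rng, geom, n, cfg)

    records: list[dict] = []
    placed: dict[str, pd.DataFrame] = {}
    event_id = 0
    for kind in ("delta", "spindle", "ripple"):  # delta first: coupling anchor
        if kind not in cfg.bands:
            continue
        spec = cfg.bands[kind]
        if spec.rate_per_s == 0 or spec.amplitude_uv == 0:
            continue
        n_events = rng.poisson(spec.rate_per_s * cfg.duration_s)
        if n_events == 0:
            placed[kind] = pd.DataFrame()
            continue
        lo, hi = spec.duration_bounds_ms
        durations_ms = np.clip(
            np.exp(
                rng.normal(
                    np.log(spec.duration_median_ms), spec.duration_spread, n_events
                )
            ),
            lo,
            hi,
        )
        durations_s = durations_ms / 1e3
        centers = _place_events(
            rng, n_events, durations_s, cfg.duration_s, spec.min_gap_ms / 1e3
        )
        freqs = spec.center_freq_hz + spec.freq_sd_hz * rng.standard_normal(n_events)
        freqs = np.clip(freqs, 0.1, cfg.fs_hz / 2.5)
        phases = rng.uniform(0, 2 * np.pi, n_events)
        if cfg.coupling and kind == "delta":
            # zero phase puts rising zero-crossings at center + k/f, which is
            # what the ripple-coupling snap below assumes
            phases = np.zeros(n_events)

        if cfg.coupling and kind == "ripple" and "delta" in placed and len(placed["delta"]):
            # snap each ripple center toward the nearest delta trough->crest
            # transition, limited to +-80 ms so hard-core spacing survives
            rising = _delta_rising_times(placed["delta"])
            if rising.size:
                idx = np.searchsorted(rising, centers)
                idx = np.clip(idx, 1, rising.size - 1)
                nearest = np.where(
                    np.abs(rising[idx] - centers) < np.abs(rising[idx - 1] - centers),
                    rising[idx],
                    rising[idx - 1],
                )
                shift = np.clip(nearest - centers, -0.08, 0.08)
                centers = np.clip(
                    centers + shift, durations_s / 2, cfg.duration_s - durations_s / 2
                )

        weights, center_ch = _spatial_weights(geom, spec)
        for i in range(n_events):
            half = durations_s[i] / 2
            # render only the +-3 sigma support for speed
            sigma = durations_s[i] / _ENVELOPE_SPAN
            i0 = max(0, int((centers[i] - 3 * sigma) * cfg.fs_hz))
            i1 = min(n, int((centers[i] + 3 * sigma) * cfg.fs_hz) + 1)
            if i1 <= i0:
                continue
            wave = spec.amplitude_uv * _burst(
                t[i0:i1], centers[i], durations_s[i], freqs[i], phases[i]
            )
            data_uv[:, i0:i1] += weights[:, None] * wave[None, :]
            records.append(
                dict(
                    event_id=event_id,
                    kind=kind,
                    channel=center_ch,
                    start_s=centers[i] - half,
                    end_s=centers[i] + half,
                    center_freq_hz=freqs[i],
                    amplitude_uv=spec.amplitude_uv,
                )
            )
            event_id += 1
        placed[kind] = pd.DataFrame([r for r in records if r["kind"] == kind])

    events = pd.DataFrame(
        records,
        columns=[
            "event_id",
            "kind",
            "channel",
            "start_s",
            "end_s",
            "center_freq_hz",
            "amplitude_uv",
        ],
    )
    traces = TraceSet(
        data=data_uv * 1e-6,
        fs=cfg.fs_hz,
        geometry=geom,
        annotations={"events": events},
    )
    traces.log(f"generate_field(seed={cfg.seed}, duration={cfg.duration_s}s)")
    return traces, events


# --------------------------------------------------------------------------
# evoked potentials


def ssep_template(protocol: StimProtocol, fs: float) -> np.ndarray:
    """Single-trial evoked-response template sampled at ``fs`` from t=0 (trigger).

    Units: uV at the spatial focus (weight 1).
    """
    n = int(np.ceil(protocol.template_support_s * fs)) + 1
    t_ms = np.arange(n) / fs * 1e3
    sd1 = protocol.peak_width_ms / 2.355  # FWHM -> sigma
    out = protocol.peak_amplitude_uv * np.exp(
        -0.5 * ((t_ms - protocol.peak_latency_ms) / sd1) ** 2
    )
    if protocol.second_lobe_scale != 0.0:
        sd2 = protocol.second_lobe_width_ms / 2.355
        c2 = protocol.peak_latency_ms + protocol.second_lobe_delay_ms
        out += (
            protocol.second_lobe_scale
            * protocol.peak_amplitude_uv
            * np.exp(-0.5 * ((t_ms - c2) / sd2) ** 2)
        )
        # the opposite-polarity lobe bites into the first peak; rescale so the
        # template's measured first-peak amplitude equals the configured value
        peak = float(np.max(np.abs(out)))
        if peak > 0:
            out *= abs(protocol.peak_amplitude_uv) / peak
    return out


def generate_ssep_trials(
    geom: GridGeometry,
    field_cfg: NeuralFieldConfig,
    protocol: StimProtocol,
) -> tuple[TraceSet, np.ndarray]:
    """Stimulation session: ongoing background + per-trial evoked responses.

    Triggers are spaced exactly ``1/rate_hz`` starting 0.5 s into the
    recording; each trial adds the spatially weighted template with per-trial
    amplitude (lognormal, CV ``amplitude_jitter_cv``) and latency (Gaussian,
    ``latency_jitter_ms``) jitter.  Returns the traces and trigger times (s).
    """
    spacing = 1.0 / protocol.rate_hz
    if spacing <= protocol.template_support_s:
        raise ValueError(
            f"trial spacing {spacing:.3f}s does not exceed the template support "
            f"{protocol.template_support_s:.3f}s: templates would overlap"
        )
    t_start = 0.5
    needed = t_start + protocol.n_trials * spacing + 0.5
    cfg = field_cfg
    if cfg.duration_s < needed:
        cfg = replace(cfg, duration_s=needed)
    traces, _ = generate_field(geom, cfg)
    fs = cfg.fs_hz
    triggers = t_start + spacing * np.arange(protocol.n_trials)

    rng = np.random.default_rng(np.random.SeedSequence([protocol.seed, 0x55E9]))
    cv = protocol.amplitude_jitter_cv
    if cv > 0:
        log_sd = np.sqrt(np.log1p(cv**2))
        amps = np.exp(rng.normal(-0.5 * log_sd**2, log_sd, protocol.n_trials))
    else:
        amps = np.ones(protocol.n_trials)
    lats = rng.normal(0.0, protocol.latency_jitter_ms, protocol.n_trials) / 1e3

    template = ssep_template(protocol, fs)
    m = template.size
    row, col = protocol.contra_center
    w_contra = np.exp(
        -0.5 * (geom.distances_um(row, col) / protocol.spatial_sd_um) ** 2
    )
    w_ipsi = None
    ipsi_shift = 0
    if protocol.ipsi_center is not None:
        ir, ic = protocol.ipsi_center
        w_ipsi = protocol.ipsi_scale * np.exp(
            -0.5 * (geom.distances_um(ir, ic) / protocol.spatial_sd_um) ** 2
        )
        ipsi_shift = int(round(protocol.ipsi_extra_latency_ms / 1e3 * fs))

    data_uv = traces.data * 1e6
    n = data_uv.shape[1]
    for k, trig in enumerate(triggers):
        i0 = int(round((trig + lats[k]) * fs))
        i1 = min(i0 + m, n)
        if i1 <= i0:
            continue
        seg = amps[k] * template[: i1 - i0]
        data_uv[:, i0:i1] += w_contra[:, None] * seg[None, :]
        if w_ipsi is not None and i0 + ipsi_shift < n:
            j1 = min(i0 + ipsi_shift + m, n)
            data_uv[:, i0 + ipsi_shift : j1] += (
                w_ipsi[:, None] * (amps[k] * template[: j1 - i0 - ipsi_shift])[None, :]
            )

    out = TraceSet(
        data=data_uv * 1e-6,
        fs=fs,
        geometry=geom,
        annotations={"triggers": triggers.tolist()},
    )
    out.log(
        f"generate_ssep_trials(seed={protocol.seed}, n={protocol.n_trials}, "
        f"rate={protocol.rate_hz} Hz)"
    )
    return out, triggers


def draw_edos(
    n_channels: int,
    mean_v: float = 0.397,
    sd_v: float = 0.115,
    seed: int = 0,
) -> np.ndarray:
    """Per-electrode DC offsets (open-circuit potentials), volts.

    Gaussian with the characteristic statistics of gold microelectrodes in
    saline: mean ~397 mV, SD ~115 mV.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xED0]))
    return rng.normal(mean_v, sd_v, n_channels)
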