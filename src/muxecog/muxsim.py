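"""Behavioral simulator of the time-division-multiplexed acquisition chain.

A select-line scan connects the N electrodes of a data line one at a time to
a shared readout "super-channel" running at N times the per-electrode rate
``f_ch``.  What the readout sees is a step-like waveform dominated by the
(divider-attenuated) electrode DC offsets, with the neural signal riding on
top.  The converter integrates over each slot (windowed integration), which
acts as a boxcar anti-aliasing filter with equivalent noise bandwidth
``N * f_ch / 2``; noise above that corner is rejected, noise between the
signal band and the corner folds into the band on demultiplexing — for white
noise an N-fold in-band power increase.  A mixed-signal feedback loop cancels
the modulated offsets (within a limited peak-to-peak range) and occasionally
steps, leaving DC glitches in the demultiplexed traces.

The chain is modeled stage by stage: schedule -> compose (with single-pole
settling) -> windowed integration -> noise injection -> offset compensation
-> demultiplex.  ``simulate_tdm`` runs the whole chain using an exact
slot-level solution of the settling + integration stages; the oversampled
``compose_superchannel`` / ``windowed_integrate`` pair exposes the same
stages as inspectable streams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .impedance import BOLTZMANN, RandlesTFTParams, dc_resistance, model_impedance
from .io import GridGeometry, TraceSet

__all__ = [
    "ElectrodePixel",
    "MuxConfig",
    "ReadoutConfig",
    "make_pixels",
    "mux_schedule",
    "noise_bandwidth",
    "required_superchannels",
    "edo_attenuation",
    "compose_superchannel",
    "windowed_integrate",
    "compensate_edo",
    "demultiplex",
    "simulate_tdm",
    "simulate_addressing",
]

#: default pixel circuit: 300-um Au electrode with a 300/3 a-IGZO switch TFT
DEFAULT_CIRCUIT = RandlesTFTParams(
    r_s=8.0e3, q=2.0e-8, alpha=0.9, r_ct=5.0e8, r_tft=16.3e3, c_par=0.0
)


@dataclass(frozen=True)
class ElectrodePixel:
    """One recording site: DC offset, equivalent circuit, grid position."""

    row: int
    col: int
    edo_v: float = 0.0
    circuit: RandlesTFTParams = DEFAULT_CIRCUIT
    defective: bool = False


def make_pixels(
    geom: GridGeometry,
    edos_v=None,
    circuit: RandlesTFTParams = DEFAULT_CIRCUIT,
) -> list[ElectrodePixel]:
    """Row-major pixel list for a grid; ``edos_v`` is per-channel or scalar."""
    if edos_v is None:
        edos_v = np.zeros(geom.n_channels)
    edos_v = np.broadcast_to(np.asarray(edos_v, dtype=float), (geom.n_channels,))
    return [
        ElectrodePixel(row=i // geom.cols, col=i % geom.cols, edo_v=float(edos_v[i]),
                       circuit=circuit)
        for i in range(geom.n_channels)
    ]


@dataclass(frozen=True)
class MuxConfig:
    """Multiplexing schedule: ratio N, per-electrode rate, select levels."""

    n: int  # multiplexing ratio (electrodes per super-channel)
    f_ch: float = 1000.0  # per-electrode sampling rate, Hz
    v_sel_on: float = 5.0
    v_sel_off: float = -2.0
    slot_order: tuple[int, ...] | None = None  # default ascending rows
    mode: str = "tdm"  # "tdm" | "addressing"
    oversample: int = 16  # stream samples per slot in compose_superchannel

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("multiplexing ratio n must be >= 1")
        if self.f_ch <= 0:
            raise ValueError("f_ch must be > 0")
        if self.mode not in ("tdm", "addressing"):
            raise ValueError("mode must be 'tdm' or 'addressing'")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        order = self.slot_order
        if order is not None and sorted(order) != list(range(self.n)):
            raise ValueError("slot_order must be a permutation of range(n)")

    @property
    def superchannel_rate(self) -> float:
        """Samples per second on the shared line: N * f_ch."""
        return self.n * self.f_ch

    @property
    def slot_duration(self) -> float:
        return 1.0 / self.superchannel_rate

    @property
    def duty(self) -> float:
        return 1.0 / self.n

    @property
    def order(self) -> np.ndarray:
        return np.asarray(
            self.slot_order if self.slot_order is not None else range(self.n)
        )


@dataclass(frozen=True)
class ReadoutConfig:
    """Behavioral readout model: noise figures, input divider, EDO loop.

    ``roic_inband_noise_uv`` is the input-referred in-band (1-500 Hz) RMS noise
    of one demultiplexed channel contributed by the readout; alternatively a
    flat ``noise_density_v_rthz`` can be given and is band-limited by the
    windowed integration to N*f_ch/2.  ``c_line_f`` is the shared-line
    capacitance of the single-pole settling model (0 = instant settling).
    """

    roic_inband_noise_uv: float = 1.55
    noise_density_v_rthz: float | None = None
    z_in_dc_ohm: float = 5.0e6  # readout DC input impedance
    edo_compensation_range_vpp: float = 0.160
    compensation_step_v: float = 1.0e-3  # DAC LSB
    glitch_rate_per_s: float = 0.0  # loop-update events per super-channel per s
    glitch_amplitude_v: float = 1.0e-3
    include_electrode_noise: bool = True
    temperature_k: float = 298.0
    c_line_f: float = 50.0e-12
    signal_band: tuple[float, float] = (1.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roic_inband_noise_uv < 0 or self.glitch_rate_per_s < 0:
            raise ValueError("noise terms must be >= 0")
        if self.noise_density_v_rthz is not None and self.noise_density_v_rthz < 0:
            raise ValueError("noise density must be >= 0")
        if self.edo_compensation_range_vpp <= 0:
            raise ValueError("compensation range must be > 0")
        if self.z_in_dc_ohm <= 0:
            raise ValueError("input impedance must be > 0")
        if self.c_line_f < 0:
            raise ValueError("line capacitance must be >= 0")


def mux_schedule(mux: MuxConfig, duration_s: float | None = None) -> pd.DataFrame:
    """Slot timing table: start, duration and electrode (row) per slot.

    One frame (every electrode visited once) by default, or as many frames as
    fit in ``duration_s``.
    """
    n_frames = 1 if duration_s is None else int(round(duration_s * mux.f_ch))
    order = mux.order
    slots = np.arange(n_frames * mux.n)
    return pd.DataFrame(
        {
            "slot": slots,
            "start_s": slots * mux.slot_duration,
            "duration_s": mux.slot_duration,
            "electrode": order[slots % mux.n],
        }
    )


def noise_bandwidth(mux: MuxConfig) -> float:
    """Equivalent noise bandwidth of the windowed integration: N * f_ch / 2 (Hz)."""
    return mux.n * mux.f_ch / 2.0


def required_superchannels(n_electrodes: int, n: int) -> int:
    """Readout super-channels needed to serve an array at ratio N:1."""
    if n_electrodes < 1 or n < 1:
        raise ValueError("electrode count and ratio must be >= 1")
    return math.ceil(n_electrodes / n)


def edo_attenuation(z_dc_electrode: float, z_in: float) -> float:
    """DC divider between electrode impedance and readout input impedance.

    The electrode open-circuit potential appears at the readout input scaled
    by ``z_in / (z_in + z_dc)``; a ~500 Mohm electrode against a ~5 Mohm
    input attenuates a ~400 mV offset about 100-fold.
    """
    if z_dc_electrode <= 0 or z_in <= 0:
        raise ValueError("impedances must be > 0")
    return z_in / (z_in + z_dc_electrode)


# --------------------------------------------------------------------------
# chain stages


def _pixel_grid(pixels: list[ElectrodePixel], geom: GridGeometry) -> list[ElectrodePixel]:
    if len(pixels) != geom.n_channels:
        raise ValueError(f"{len(pixels)} pixels for {geom.n_channels} channels")
    out = [None] * geom.n_channels
    for p in pixels:
        out[geom.channel_index(p.row, p.col)] = p
    if any(p is None for p in out):
        raise ValueError("pixel list does not cover the grid")
    return out


def _attenuated_edos(pixels, geom: GridGeometry, ro: ReadoutConfig) -> np.ndarray:
    """(rows, cols) attenuated DC offsets seen by the readout (V)."""
    att = np.empty(geom.n_channels)
    for i, p in enumerate(pixels):
        factor = edo_attenuation(dc_resistance(p.circuit), ro.z_in_dc_ohm)
        att[i] = p.edo_v * factor
    return att.reshape(geom.rows, geom.cols)


def _check_field(field: TraceSet, mux: MuxConfig) -> int:
    if field.geometry.rows != mux.n:
        raise ValueError(
            f"grid has {field.geometry.rows} select rows but mux ratio is {mux.n}"
        )
    ratio = field.fs / mux.superchannel_rate
    m = int(round(ratio))
    if m < 1 or abs(ratio - m) > 1e-9:
        raise ValueError(
            f"field rate {field.fs} Hz must be an integer multiple of the "
            f"super-channel rate {mux.superchannel_rate} Hz"
        )
    return m


def _settling_tau(pixels, geom: GridGeometry, ro: ReadoutConfig) -> np.ndarray:
    """Per-channel single-pole time constant (R_s + R_tft) * C_line, (rows, cols)."""
    tau = np.empty(geom.n_channels)
    for i, p in enumerate(pixels):
        tau[i] = (p.circuit.r_s + p.circuit.r_tft) * ro.c_line_f
    return tau.reshape(geom.rows, geom.cols)


def compose_superchannel(
    field: TraceSet,
    pixels: list[ElectrodePixel],
    mux: MuxConfig,
    ro: ReadoutConfig,
) -> tuple[np.ndarray, float]:
    """Oversampled super-channel streams: the step-like multiplexed waveform.

    Each data line (grid column) is scanned across its N select rows; the
    stream carries the attenuated DC offset plus neural signal of the active
    electrode, settling exponentially from the previous slot's line voltage
    with time constant ``(R_s + R_tft) * C_line``.  Returns
    ``(streams, stream_rate)`` with ``streams`` shaped
    (n_superchannels, oversample * N * f_ch * duration).
    """
    _check_field(field, mux)
    geom = field.geometry
    pixels = _pixel_grid(pixels, geom)
    att_edo = _attenuated_edos(pixels, geom, ro)
    tau = _settling_tau(pixels, geom, ro)
    order = mux.order

    f_sim = mux.oversample * mux.superchannel_rate
    n_slots = int(field.duration * mux.superchannel_rate)
    n_sim = n_slots * mux.oversample
    t_sim = np.arange(n_sim) / f_sim
    slot_of = (np.arange(n_sim) // mux.oversample) % mux.n
    rows = order[slot_of]  # active select row per sim sample
    idx_field = np.minimum((t_sim * field.fs).astype(int), field.n_samples - 1)

    grid = field.as_grid()  # (rows, cols, samples), V
    streams = np.empty((geom.cols, n_sim))
    for j in range(geom.cols):
        target = grid[rows, j, idx_field] + att_edo[rows, j]
        if ro.c_line_f == 0:
            streams[j] = target
            continue
        tau_smp = tau[rows, j]
        if np.ptp(tau_smp) < 1e-18:  # uniform time constant: one-pole IIR
            a = math.exp(-1.0 / (f_sim * tau_smp[0])) if tau_smp[0] > 0 else 0.0
            zi = sps.lfiltic([1 - a], [1, -a], [target[0]])
            streams[j], _ = sps.lfilter([1 - a], [1, -a], target, zi=zi)
        else:
            a = np.exp(-1.0 / (f_sim * np.maximum(tau_smp, 1e-18)))
            v = target[0]
            out = np.empty(n_sim)
            for i in range(n_sim):  # heterogeneous pixels: explicit scan
                v = target[i] + (v - target[i]) * a[i]
                out[i] = v
            streams[j] = out
    if np.max(tau) > mux.slot_duration / 3:
        warnings.warn(
            "settling time constant exceeds a third of the slot duration: "
            "crosstalk-dominated regime",
            UserWarning,
        )
    return streams, f_sim


def windowed_integrate(stream: np.ndarray, samples_per_slot: int) -> np.ndarray:
    """Boxcar average over each acquisition slot: one output sample per slot.

    Behavioral model of the incremental delta-sigma conversion; the boxcar
    transfer |sinc(f / slot_rate)| attenuates input power above the noise
    bandwidth and nulls exact slot-rate multiples.
    """
    stream = np.atleast_2d(np.asarray(stream))
    if samples_per_slot < 1:
        raise ValueError("samples_per_slot must be >= 1")
    if stream.shape[-1] % samples_per_slot:
        raise ValueError(
            f"stream length {stream.shape[-1]} is not an integer number of "
            f"{samples_per_slot}-sample slots"
        )
    out = stream.reshape(stream.shape[0], -1, samples_per_slot).mean(axis=2)
    return out


def compensate_edo(
    slots: np.ndarray,
    mux: MuxConfig,
    ro: ReadoutConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Mixed-signal offset cancellation, quantized to the DAC step.

    Per slot position the loop estimates the DC level (mean of the first
    ~128 ms), quantizes it to the DAC LSB and subtracts it.  Offsets farther
    than half the compensation range from the super-channel median cannot be
    cancelled and are flagged saturated.  Loop updates occur at the
    configured glitch rate and leave logged DC step discontinuities.

    Returns ``(corrected slots, glitch log, saturation flags (nsc, N))``.
    """
    slots = np.atleast_2d(np.asarray(slots, dtype=float)).copy()
    nsc, n_slots = slots.shape
    if n_slots % mux.n:
        raise ValueError("slot stream length must be a multiple of N")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([ro.seed, 0xC0]))
    n_frames = n_slots // mux.n
    frames = slots.reshape(nsc, n_frames, mux.n)
    est_frames = min(n_frames, max(1, int(round(0.128 * mux.f_ch))))
    est = frames[:, :est_frames, :].mean(axis=1)  # (nsc, N)
    step = ro.compensation_step_v
    est_q = np.round(est / step) * step
    center = np.median(est_q, axis=1, keepdims=True)
    half = ro.edo_compensation_range_vpp / 2.0
    saturated = np.abs(est_q - center) > half
    comp = np.clip(est_q, center - half, center + half)
    frames = frames - comp[:, None, :]

    glitches: list[dict] = []
    duration = n_frames / mux.f_ch
    for sc in range(nsc):
        n_g = rng.poisson(ro.glitch_rate_per_s * duration)
        for _ in range(n_g):
            k = int(rng.integers(mux.n))
            f0 = int(rng.integers(n_frames))
            amp = float(rng.choice([-1.0, 1.0]) * ro.glitch_amplitude_v)
            frames[sc, f0:, k] += amp
            glitches.append(
                dict(
                    superchannel=sc,
                    slot_position=k,
                    electrode=int(mux.order[k]),
                    t_s=f0 / mux.f_ch,
                    amplitude_v=amp,
                )
            )
    log = pd.DataFrame(
        glitches,
        columns=["superchannel", "slot_position", "electrode", "t_s", "amplitude_v"],
    )
    return frames.reshape(nsc, n_slots), log, saturated


def demultiplex(
    slots: np.ndarray,
    mux: MuxConfig,
    geometry: GridGeometry,
    annotations: dict | None = None,
) -> TraceSet:
    """De-interleave slot samples into per-electrode traces at f_ch.

    Channel (row r, col j) receives the slot-position samples of row r on
    super-channel j; per-channel timestamp skew (slot centers) is recorded in
    the annotations.
    """
    slots = np.atleast_2d(np.asarray(slots))
    nsc, n_slots = slots.shape
    if nsc != geometry.cols or geometry.rows != mux.n:
        raise ValueError("slot array shape inconsistent with geometry/mux")
    if n_slots % mux.n:
        raise ValueError(f"slot count {n_slots} is not a multiple of N={mux.n}")
    n_frames = n_slots // mux.n
    frames = slots.reshape(nsc, n_frames, mux.n)
    data = np.empty((geometry.n_channels, n_frames))
    offsets = np.empty(geometry.n_channels)
    order = mux.order
    for k in range(mux.n):
        row = int(order[k])
        for j in range(nsc):
            ch = geometry.channel_index(row, j)
            data[ch] = frames[j, :, k]
            offsets[ch] = (k + 0.5) * mux.slot_duration
    ann = dict(annotations or {})
    ann["slot_offsets_s"] = offsets.tolist()
    out = TraceSet(data=data, fs=mux.f_ch, geometry=geometry, t0=0.0, annotations=ann)
    out.log(f"demultiplex(N={mux.n}, f_ch={mux.f_ch})")
    return out


def _slot_level_chain(
    field: TraceSet,
    pixels: list[ElectrodePixel],
    mux: MuxConfig,
    ro: ReadoutConfig,
) -> np.ndarray:
    """Exact slot-level solution of compose + settling + windowed integration.

    Within slot s the line relaxes toward the active electrode's level u_s
    with time constant tau; the integrated output over the slot is
    ``u_s + (v_{s-1} - u_s) * (tau/T)(1 - exp(-T/tau))`` and the slot-end
    voltage ``u_s + (v_{s-1} - u_s) * exp(-T/tau)``.  This reproduces the
    continuous-time settling behavior without oversampling the stream.
    """
    m = _check_field(field, mux)
    geom = field.geometry
    att_edo = _attenuated_edos(pixels, geom, ro)
    tau = _settling_tau(pixels, geom, ro)
    order = mux.order

    n_slots = int(field.duration * mux.superchannel_rate)
    grid = field.as_grid()[:, :, : n_slots * m]
    # boxcar mean of the source over each slot window, all channels
    slot_mean = grid.reshape(geom.rows, geom.cols, n_slots, m).mean(axis=3)
    rows = order[np.arange(n_slots) % mux.n]
    # active-electrode level per slot: (cols, n_slots)
    u = slot_mean[rows, :, np.arange(n_slots)].T + att_edo[rows].T

    if ro.c_line_f == 0 or np.max(tau) == 0:
        return u
    T = mux.slot_duration
    tau_s = np.maximum(tau[rows], 1e-18).T  # (cols, n_slots)
    e = np.exp(-T / tau_s)
    g = (tau_s / T) * (1.0 - e)
    if np.max(tau) > T / 3:
        warnings.warn(
            "settling time constant exceeds a third of the slot duration: "
            "crosstalk-dominated regime",
            UserWarning,
        )
    if np.ptp(tau) < 1e-18:  # uniform tau: slot-end recursion is a one-pole IIR
        a = e[0, 0]
        # initial condition: line settled at the first level before slot 0
        v, _ = sps.lfilter([1 - a], [1, -a], u, axis=1, zi=u[:, :1] * a)
        v_prev = np.concatenate([u[:, :1], v[:, :-1]], axis=1)
        out = u + (v_prev - u) * g
    else:
        out = np.empty_like(u)
        v_prev = u[:, 0].copy()
        for s in range(u.shape[1]):
            out[:, s] = u[:, s] + (v_prev - u[:, s]) * g[:, s]
            v_prev = u[:, s] + (v_prev - u[:, s]) * e[:, s]
    return out


def _slot_noise_sigma(mux: MuxConfig, ro: ReadoutConfig) -> float:
    """Per-slot readout noise SD (V) after windowed integration.

    With a flat density d the integrated noise power is d^2 * NBW with
    NBW = N*f_ch/2.  Without an explicit density, the SD is set so the
    demultiplexed in-band (1-500 Hz) RMS equals ``roic_inband_noise_uv``:
    demuxed samples are white over [0, f_ch/2], of which the signal band
    holds a fraction (hi-lo)/(f_ch/2).
    """
    if ro.noise_density_v_rthz is not None:
        return ro.noise_density_v_rthz * math.sqrt(noise_bandwidth(mux))
    lo, hi = ro.signal_band
    frac = (hi - lo) / (mux.f_ch / 2.0)
    return ro.roic_inband_noise_uv * 1e-6 / math.sqrt(frac)


def simulate_tdm(
    field: TraceSet,
    pixels: list[ElectrodePixel],
    mux: MuxConfig,
    ro: ReadoutConfig,
) -> tuple[TraceSet, np.ndarray, dict]:
    """Full acquisition chain, field in, demultiplexed traces out.

    compose (+ settling) -> windowed integration -> noise injection
    (flat readout noise over the N*f_ch/2 noise bandwidth, plus per-electrode
    Johnson noise of Re Z at 1 kHz) -> EDO compensation -> demultiplex.
    Reproducible for a given ``ro.seed``.  Returns
    ``(demuxed TraceSet, slot streams, logs)``.
    """
    geom = field.geometry
    pixels = _pixel_grid(pixels, geom)
    slots = _slot_level_chain(field, pixels, mux, ro)
    rng = np.random.default_rng(np.random.SeedSequence([ro.seed, 0x7D9]))

    sigma_ro = _slot_noise_sigma(mux, ro)
    if sigma_ro > 0:
        slots = slots + rng.normal(0.0, sigma_ro, slots.shape)
    if ro.include_electrode_noise:
        nbw = noise_bandwidth(mux)
        order = mux.order
        n_slots = slots.shape[1]
        rows = order[np.arange(n_slots) % mux.n]
        re_z = np.empty(geom.n_channels)
        for i, p in enumerate(pixels):
            re_z[i] = float(model_impedance(p.circuit, [1000.0]).z.real[0])
        sig = np.sqrt(4.0 * BOLTZMANN * ro.temperature_k * re_z * nbw)
        sig = sig.reshape(geom.rows, geom.cols)
        slots = slots + rng.normal(0.0, 1.0, slots.shape) * sig[rows].T

    slots, glitch_log, saturated = compensate_edo(slots, mux, ro, rng)
    logs = {
        "glitches": glitch_log,
        "saturated": saturated,
        "schedule": mux_schedule(mux),
    }
    traces = demultiplex(slots, mux, geom, annotations={"mode": "tdm"})
    traces.log(f"simulate_tdm(seed={ro.seed})")
    return traces, slots, logs


def simulate_addressing(
    field: TraceSet,
    pixels: list[ElectrodePixel],
    mux: MuxConfig,
    select_row: int,
    ro: ReadoutConfig | None = None,
    off_leakage: float = 0.0,
    analog_band: tuple[float, float] = (1.0, 500.0),
) -> TraceSet:
    """Channel-selection mode: one select row recorded continuously at f_ch.

    No folding penalty — the selected electrodes are sampled continuously.
    Unselected rows couple in only through the OFF-state leakage of their
    switches (amplitude fraction ``off_leakage``, default negligible).  A
    first-order analog Butterworth band-pass precedes sampling.
    """
    geom = field.geometry
    if not 0 <= select_row < geom.rows:
        raise ValueError(f"select_row {select_row} outside 0..{geom.rows - 1}")
    ratio = field.fs / mux.f_ch
    dec = int(round(ratio))
    if dec < 1 or abs(ratio - dec) > 1e-9:
        raise ValueError("field rate must be an integer multiple of f_ch")
    grid = field.as_grid()
    sig = grid[select_row].astype(float).copy()
    if off_leakage != 0.0:
        others = np.delete(np.arange(geom.rows), select_row)
        sig = sig + off_leakage * grid[others].sum(axis=0)
    sos = sps.butter(1, analog_band, btype="bandpass", fs=field.fs, output="sos")
    sig = sps.sosfilt(sos, sig, axis=1)
    sig = sig[:, ::dec]
    out_geom = GridGeometry(
        rows=1,
        cols=geom.cols,
        pitch_um=geom.pitch_um,
        electrode_diameter_um=geom.electrode_diameter_um,
    )
    out = TraceSet(
        data=sig,
        fs=mux.f_ch,
        geometry=out_geom,
        annotations={"mode": "addressing", "select_row": select_row},
    )
    out.log(f"simulate_addressing(row={select_row})")
    return out
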