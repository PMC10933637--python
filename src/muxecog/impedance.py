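"""Electrical model of an actively switched recording pixel.

A recording pixel is a metal microelectrode in electrolyte placed in series
with a thin-film-transistor (TFT) selection switch.  The electrode-electrolyte
interface is described by a Randles equivalent circuit whose double layer is a
constant-phase element (CPE), extended with the switch ON resistance ``R_tft``
in series and a parasitic capacitance ``C_par`` across the electrode branch:

    Z(w) = R_tft + [ (R_s + Z_cpe || R_ct)  ||  1/(j w C_par) ]
    Z_cpe(w) = 1 / (Q (j w)^alpha),   w = 2 pi f

This module provides the forward model, a Levenberg-Marquardt spectrum fit
with modulus weighting, ON-resistance extraction from TFT transfer curves,
linear-region width scaling, and Johnson-Nyquist noise budgeting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "RandlesTFTParams",
    "ImpedanceSpectrum",
    "TransferCurve",
    "NoiseBudget",
    "ImpedanceFit",
    "model_impedance",
    "fit_impedance",
    "extract_r_on",
    "extract_v_on",
    "scale_r_on",
    "johnson_noise_rms",
    "quadrature_add",
    "quadrature_subtract",
]

BOLTZMANN = 1.380649e-23  # J/K
DEFAULT_TEMPERATURE = 298.0  # K


@dataclass(frozen=True)
class RandlesTFTParams:
    """Circuit elements of the pixel impedance model.

    Parameters
    ----------
    r_s : float
        Solution plus track series resistance (ohm).
    q : float
        CPE magnitude (S s^alpha).
    alpha : float
        CPE exponent in (0, 1]; 1 is an ideal capacitor.
    r_ct : float
        Charge-transfer (faradaic) resistance (ohm).
    r_tft : float
        ON resistance of the selection TFT (ohm); 0 means no TFT.
    c_par : float
        Parasitic capacitance across the electrode branch (F).
    """

    r_s: float
    q: float
    alpha: float
    r_ct: float
    r_tft: float = 0.0
    c_par: float = 0.0

    def __post_init__(self) -> None:
        if self.r_s <= 0 or self.r_ct <= 0:
            raise ValueError("resistances r_s and r_ct must be > 0")
        if self.r_tft < 0:
            raise ValueError("r_tft must be >= 0 (0 = no TFT)")
        if self.q <= 0:
            raise ValueError("CPE magnitude q must be > 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("CPE exponent alpha must be in (0, 1]")
        if self.c_par < 0:
            raise ValueError("c_par must be >= 0")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance sampled on a strictly increasing frequency grid."""

    freq: np.ndarray  # Hz
    z: np.ndarray  # complex ohm

    def __post_init__(self) -> None:
        freq = np.asarray(self.freq, dtype=float)
        z = np.asarray(self.z, dtype=complex)
        if freq.shape != z.shape or freq.ndim != 1 or freq.size < 1:
            raise ValueError("freq and z must be 1-D and of equal length")
        if np.any(freq <= 0):
            raise ValueError("frequencies must be > 0")
        if np.any(np.diff(freq) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(np.abs(z) <= 0):
            raise ValueError("|Z| must be > 0 everywhere")
        object.__setattr__(self, "freq", freq)
        object.__setattr__(self, "z", z)

    @property
    def magnitude(self) -> np.ndarray:
        """|Z| in ohm."""
        return np.abs(self.z)

    @property
    def phase_deg(self) -> np.ndarray:
        """Impedance phase in degrees."""
        return np.degrees(np.angle(self.z))

    @property
    def n_decades(self) -> float:
        return float(np.log10(self.freq[-1] / self.freq[0]))


@dataclass(frozen=True)
class TransferCurve:
    """TFT transfer characteristic I_DS(V_GS) at fixed drain bias V_DS."""

    v_gs: np.ndarray  # V, increasing
    i_ds: np.ndarray  # A
    v_ds: float  # V
    w_um: float  # channel width, um
    l_um: float  # channel length, um

    def __post_init__(self) -> None:
        v = np.asarray(self.v_gs, dtype=float)
        i = np.asarray(self.i_ds, dtype=float)
        if v.shape != i.shape or v.ndim != 1 or v.size < 2:
            raise ValueError("v_gs and i_ds must be 1-D, equal length >= 2")
        if np.any(np.diff(v) <= 0):
            raise ValueError("v_gs must be strictly increasing")
        if self.v_ds <= 0:
            raise ValueError("v_ds must be > 0")
        if self.w_um <= 0 or self.l_um <= 0:
            raise ValueError("channel dimensions must be > 0")
        object.__setattr__(self, "v_gs", v)
        object.__setattr__(self, "i_ds", i)


@dataclass
class NoiseBudget:
    """Named RMS noise components over a common band, at one temperature."""

    temperature: float = DEFAULT_TEMPERATURE  # K
    band: tuple[float, float] = (1.0, 500.0)  # Hz
    components: list[tuple[str, float]] = field(default_factory=list)  # (label, uVrms)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band must satisfy lo < hi")
        if any(v < 0 for _, v in self.components):
            raise ValueError("noise components must be >= 0")

    def add(self, label: str, v_rms_uv: float) -> None:
        if v_rms_uv < 0:
            raise ValueError("noise components must be >= 0")
        self.components.append((label, float(v_rms_uv)))

    @property
    def total_uv(self) -> float:
        """Quadrature sum of all components (uVrms)."""
        vals = [v for _, v in self.components]
        return float(np.sqrt(np.sum(np.square(vals)))) if vals else 0.0


def model_impedance(params: RandlesTFTParams, freq) -> ImpedanceSpectrum:
    """Complex impedance of the Randles+TFT circuit at the given frequencies.

    Topology: C_par in parallel with the electrode branch
    [R_s in series with (CPE || R_ct)], all in series with R_tft.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be > 0")
    w = 2.0 * np.pi * f
    z_cpe = 1.0 / (params.q * (1j * w) ** params.alpha)
    z_elec = params.r_s + (z_cpe * params.r_ct) / (z_cpe + params.r_ct)
    if params.c_par > 0:
        y = 1.0 / z_elec + 1j * w * params.c_par
        z_elec = 1.0 / y
    return ImpedanceSpectrum(freq=f, z=z_elec + params.r_tft)


@dataclass(frozen=True)
class ImpedanceFit:
    """Result of a spectrum fit: parameter estimates and fit quality."""

    params: RandlesTFTParams
    relative_residual: float  # rms of modulus-weighted complex residuals
    n_points: int
    converged: bool
    message: str = ""

    def summary(self) -> str:
        p = self.params
        lines = [
            "Randles+TFT impedance fit",
            f"  points: {self.n_points}   converged: {self.converged}",
            f"  relative residual (rms): {self.relative_residual:.3e}",
            f"  R_s    = {p.r_s:.4g} ohm",
            f"  Q      = {p.q:.4g} S s^alpha",
            f"  alpha  = {p.alpha:.4f}",
            f"  R_ct   = {p.r_ct:.4g} ohm",
            f"  R_tft  = {p.r_tft:.4g} ohm (held fixed)",
            f"  C_par  = {p.c_par:.4g} F",
        ]
        return "\n".join(lines)


def _initial_guess(spec: ImpedanceSpectrum, r_tft: float) -> RandlesTFTParams:
    """Heuristic start: plateaus give the resistances, mid-band slope the CPE."""
    mag = spec.magnitude
    f = spec.freq
    r_hf = max(mag[-1] - r_tft, 1e-3)  # high-frequency plateau ~ R_s (+R_tft)
    r_lf = max(mag[0], r_hf * 1.01)  # low-frequency plateau ~ R_s + R_ct
    # CPE slope: d log|Z| / d log f ~ -alpha in the capacitive mid-band
    logm, logf = np.log10(mag), np.log10(f)
    slopes = np.diff(logm) / np.diff(logf)
    alpha0 = float(np.clip(-np.min(slopes), 0.3, 1.0))
    # pick the mid-band point and solve |Z_cpe| = 1/(Q w^alpha) ~ |Z| there
    k = int(np.argmin(np.abs(logm - 0.5 * (logm[0] + logm[-1]))))
    w_mid = 2.0 * np.pi * f[k]
    q0 = 1.0 / (mag[k] * w_mid**alpha0)
    return RandlesTFTParams(
        r_s=r_hf, q=q0, alpha=alpha0, r_ct=r_lf - r_hf, r_tft=r_tft, c_par=0.0
    )


def fit_impedance(
    spec: ImpedanceSpectrum,
    init: RandlesTFTParams | None = None,
    fit_c_par: bool = False,
) -> ImpedanceFit:
    """Fit the Randles+TFT model to a measured spectrum.

    Levenberg-Marquardt on modulus-weighted complex residuals
    ``(Z_model - Z) / |Z|`` so that every frequency decade contributes
    comparably even though |Z| spans several orders of magnitude.  Positive
    parameters are fitted in log space; ``r_tft`` is held fixed at the value
    supplied in ``init`` (0 if no ``init``): the switch resistance is measured
    independently from transfer curves, and in a blind fit it is completely
    degenerate with ``r_s``.

    Raises on degenerate (near-constant) spectra; flags non-convergence in the
    returned :class:`ImpedanceFit` rather than failing silently.
    """
    if spec.n_decades < 2.0:
        raise ValueError("spectrum must span at least 2 decades of frequency")
    mag = spec.magnitude
    if np.ptp(mag) < 1e-9 * np.max(mag):
        raise ValueError("degenerate spectrum: |Z| is constant")
    r_tft = init.r_tft if init is not None else 0.0
    p0 = init if init is not None else _initial_guess(spec, r_tft)

    use_cpar = fit_c_par or (init is not None and init.c_par > 0)

    def pack(p: RandlesTFTParams) -> np.ndarray:
        # positive parameters in log space; alpha through a logistic map onto
        # (0, 1) so the Levenberg-Marquardt step stays unconstrained
        a = np.clip(p.alpha, 1e-6, 1.0 - 1e-9)
        x = [np.log(p.r_s), np.log(p.q), np.log(a / (1.0 - a)), np.log(p.r_ct)]
        if use_cpar:
            x.append(np.log(max(p.c_par, 1e-15)))
        return np.asarray(x)

    def unpack(x: np.ndarray) -> RandlesTFTParams:
        return RandlesTFTParams(
            r_s=float(np.exp(x[0])),
            q=float(np.exp(x[1])),
            alpha=float(np.clip(special.expit(x[2]), 1e-6, 1.0)),
            r_ct=float(np.exp(x[3])),
            r_tft=r_tft,
            c_par=float(np.exp(x[4])) if use_cpar else 0.0,
        )

    weights = 1.0 / mag

    def residuals(x: np.ndarray) -> np.ndarray:
        zm = model_impedance(unpack(x), spec.freq).z
        r = (zm - spec.z) * weights
        return np.concatenate([r.real, r.imag])

    sol = optimize.least_squares(residuals, pack(p0), method="lm", xtol=1e-14, ftol=1e-14)
    rel = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success)
    if not converged:
        warnings.warn(f"impedance fit did not converge: {sol.message}", RuntimeWarning)
    return ImpedanceFit(
        params=unpack(sol.x),
        relative_residual=rel,
        n_points=spec.freq.size,
        converged=converged,
        message=str(sol.message),
    )


def extract_r_on(curve: TransferCurve, v_gs_op: float = 5.0) -> float:
    """ON resistance R_ON = V_DS / I_DS at the operating gate bias (ohm).

    Valid in the linear (ohmic) region, i.e. for small drain bias
    (v_ds <= 0.1 V); I_DS is linearly interpolated between grid points.
    """
    if curve.v_ds > 0.1:
        warnings.warn(
            f"v_ds={curve.v_ds} V is outside the linear region (<= 0.1 V); "
            "R_ON extraction assumes ohmic operation",
            UserWarning,
        )
    if not curve.v_gs[0] <= v_gs_op <= curve.v_gs[-1]:
        raise ValueError(
            f"v_gs_op={v_gs_op} outside curve range "
            f"[{curve.v_gs[0]}, {curve.v_gs[-1]}]"
        )
    i_op = float(np.interp(v_gs_op, curve.v_gs, curve.i_ds))
    if i_op <= 0:
        raise ValueError(f"I_DS <= 0 at V_GS={v_gs_op} V; transistor not ON")
    return curve.v_ds / i_op


def extract_v_on(curve: TransferCurve, i_crit_per_square: float = 1e-9) -> float:
    """Turn-on voltage: first V_GS where I_DS exceeds 1 nA * (W/L).

    The criterion current scales with the aspect ratio so that geometrically
    scaled devices report comparable turn-on voltages.  Reported for device
    characterization only; nothing downstream consumes it.
    """
    i_crit = i_crit_per_square * curve.w_um / curve.l_um
    above = curve.i_ds > i_crit
    if not above.any():
        raise ValueError("device never exceeds the turn-on current criterion")
    k = int(np.argmax(above))
    if k == 0:
        return float(curve.v_gs[0])
    # linear interpolation of the crossing between grid points
    v0, v1 = curve.v_gs[k - 1], curve.v_gs[k]
    i0, i1 = curve.i_ds[k - 1], curve.i_ds[k]
    return float(v0 + (i_crit - i0) * (v1 - v0) / (i1 - i0))


def scale_r_on(r_on: float, w_from_um: float, w_to_um: float) -> float:
    """Linear-region ON-resistance scaling with channel width (equal length).

    R_ON is inversely proportional to W, so halving the width doubles the
    resistance: returns ``r_on * w_from / w_to``.
    """
    if w_from_um <= 0 or w_to_um <= 0:
        raise ValueError("channel widths must be > 0")
    return r_on * w_from_um / w_to_um


def johnson_noise_rms(
    r_ohm: float,
    band: tuple[float, float] = (1.0, 500.0),
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Johnson-Nyquist thermal noise of a resistance, in uVrms.

    sqrt(4 k_B T R (hi - lo)) converted to microvolts.
    """
    if r_ohm < 0:
        raise ValueError("resistance must be >= 0")
    lo, hi = band
    if not lo < hi:
        raise ValueError("band must satisfy lo < hi")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return 1e6 * float(np.sqrt(4.0 * BOLTZMANN * temperature * r_ohm * (hi - lo)))


def quadrature_add(a: float, b: float) -> float:
    """RMS sum of independent noise sources: sqrt(a^2 + b^2)."""
    if a < 0 or b < 0:
        raise ValueError("noise magnitudes must be >= 0")
    return float(np.hypot(a, b))


def quadrature_subtract(total: float, component: float) -> float:
    """Remove a known independent component from a total RMS noise.

    sqrt(total^2 - component^2); errors if the component exceeds the total
    (negative power).
    """
    if component < 0:
        raise ValueError("component must be >= 0")
    if component > total:
        raise ValueError(
            f"component ({component}) exceeds total ({total}): negative power"
        )
    return float(np.sqrt(total**2 - component**2))


def dc_resistance(params: RandlesTFTParams) -> float:
    """Zero-frequency limit of |Z|: R_s + R_ct + R_tft."""
    return params.r_s + params.r_ct + params.r_tft
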