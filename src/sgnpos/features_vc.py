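"""Voltage-clamp feature extraction: steady-state conductance curves and
outward-current inactivation kinetics.

The steady-state current near the end of a 400 ms voltage step is converted to
an approximate whole-cell K conductance by dividing by the potassium driving
force (V - E_K), after subtracting a leak line estimated from the
hyperpolarized limb where voltage-gated channels are closed.  The conductance
curve is then fit with a Boltzmann function, yielding g_max, V_1/2 and the
conductance at -30 mV; the +70 mV sweep yields the inactivation time constant
tau_inact from a single-exponential fit to the decaying outward current.

Neurons whose curves do not saturate within the command range, or whose decay
is poorly fit by a single exponential, are flagged as excluded rather than
dropped, so downstream analyses can apply list-wise deletion explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import E_K_DEFAULT, Sweep, boltzmann

__all__ = [
    "ConductanceCurve",
    "InactivationFit",
    "steady_state_current",
    "conductance_curve",
    "fit_boltzmann",
    "fit_tau_inact",
    "extract_vc_features",
]

#: window for the steady-state current, ms after step onset
SS_WINDOW = (380.0, 400.0)
#: command voltages closer than this to E_K are dropped (singularity guard)
EK_EXCLUSION_BAND = 5.0
#: saturation rule: fitted ceiling must be within this factor of the largest
#: measured conductance, and V_1/2 + 2k must fall inside the command range
GMAX_SATURATION_FACTOR = 1.25
#: single-exponential fits below this R^2 mark the neuron's tau as excluded
TAU_FIT_R2_MIN = 0.8


@dataclass
class ConductanceCurve:
    command_v: np.ndarray
    g_ss: np.ndarray
    boltzmann: dict | None = None      # {"g_max", "v_half", "slope_k"}
    saturated: bool | None = None
    g_minus30: float | None = None
    negative_floored: bool = False
    leak_fit: tuple | None = None      # (slope nS, intercept pA)

    def __post_init__(self):
        self.command_v = np.asarray(self.command_v, dtype=float)
        self.g_ss = np.asarray(self.g_ss, dtype=float)
        if self.command_v.shape != self.g_ss.shape:
            raise ValueError("command_v and g_ss must have equal length")
        if np.any(self.g_ss < 0):
            raise ValueError("g_ss must be non-negative after leak handling")


@dataclass
class InactivationFit:
    tau_inact: float
    baseline: float
    amplitude: float
    fit_r2: float
    excluded: bool

    def __post_init__(self):
        if not self.excluded and self.tau_inact <= 0:
            raise ValueError("tau_inact must be positive when not excluded")


def steady_state_current(sweep: Sweep, window: tuple = SS_WINDOW) -> float:
    """Mean current over the final window of the step (default 380-400 ms)."""
    if sweep.protocol.step_ms < window[1]:
        raise ValueError(
            f"step of {sweep.protocol.step_ms} ms is shorter than the "
            f"steady-state window end {window[1]} ms")
    t = sweep.time - sweep.protocol.pre_ms
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError("no samples inside the steady-state window")
    return float(sweep.signal[mask].mean())


def _estimate_leak(volts: np.ndarray, currents: np.ndarray) -> tuple:
    """Leak line (slope, intercept) from the hyperpolarized limb, -120..-90 mV,
    where voltage-gated K channels are essentially closed."""
    mask = (volts >= -120.0) & (volts <= -90.0)
    if mask.sum() < 2:
        raise ValueError("need >= 2 command voltages in [-120, -90] mV "
                         "to estimate leak")
    slope, intercept = np.polyfit(volts[mask], currents[mask], 1)
    return float(slope), float(intercept)


def conductance_curve(family: list, e_k: float = E_K_DEFAULT,
                      exclusion_band: float = EK_EXCLUSION_BAND,
                      leak_subtract: bool = True,
                      window: tuple = SS_WINDOW) -> ConductanceCurve:
    """Steady-state conductance g(V) = I_ss(V) / (V - E_K) per command voltage.

    Voltages within ``exclusion_band`` of E_K are dropped (driving-force
    singularity); negative quotients are floored at zero with a flag.
    """
    volts = np.array([sw.stimulus_level for sw in family])
    i_ss = np.array([steady_state_current(sw, window) for sw in family])
    order = np.argsort(volts)
    volts, i_ss = volts[order], i_ss[order]

    leak = None
    if leak_subtract:
        leak = _estimate_leak(volts, i_ss)
        i_ss = i_ss - (leak[0] * volts + leak[1])

    keep = np.abs(volts - e_k) > exclusion_band
    if not keep.any():
        raise ValueError("every command voltage lies inside the E_K "
                         "exclusion band")
    volts, i_ss = volts[keep], i_ss[keep]
    g = i_ss / (volts - e_k)
    floored = bool(np.any(g < 0))
    g = np.maximum(g, 0.0)
    return ConductanceCurve(command_v=volts, g_ss=g,
                            negative_floored=floored, leak_fit=leak)


def fit_boltzmann(curve: ConductanceCurve, min_points: int = 6) -> ConductanceCurve:
    """Least-squares Boltzmann fit g(V) = g_max / (1 + exp(-(V - V_1/2)/k)).

    Returns a copy of the curve carrying the fit, the saturation flag and the
    fit-evaluated conductance at -30 mV.  A curve whose fitted ceiling lies
    well above the largest measured value, or whose half-activation plus two
    slope factors exceeds the command range, did not saturate and is flagged
    for downstream exclusion.
    """
    v, g = curve.command_v, curve.g_ss
    if v.size < min_points:
        raise ValueError(f"need >= {min_points} usable points, got {v.size}")
    g_top = float(g.max())
    if g_top <= 1e-6:
        raise ValueError("flat conductance curve (g_max ~ 0); nothing to fit")

    half = 0.5 * g_top
    above = v[g >= half]
    p0 = (g_top, float(above[0]) if above.size else 0.0, 10.0)
    try:
        popt, _ = curve_fit(
            lambda x, gm, vh, k: gm * boltzmann(x, vh, k), v, g, p0=p0,
            bounds=([1e-9, -150.0, 0.5], [20.0 * g_top, 200.0, 100.0]),
            maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"Boltzmann fit did not converge: {exc}") from exc
    g_max, v_half, k = (float(x) for x in popt)

    saturated = (v_half + 2.0 * k <= float(v.max())
                 and g_max <= GMAX_SATURATION_FACTOR * g_top)
    out = dataclasses.replace(
        curve,
        boltzmann={"g_max": g_max, "v_half": v_half, "slope_k": k},
        saturated=bool(saturated),
        g_minus30=float(g_max * boltzmann(-30.0, v_half, k)),
    )
    return out


def fit_tau_inact(sweep: Sweep, r2_min: float = TAU_FIT_R2_MIN,
                  blank_ms: float = 5.0) -> InactivationFit:
    """Single-exponential fit to the decaying outward current at +70 mV.

    Fits A*exp(-(t - t_peak)/tau) + C from the outward-current peak to the end
    of the step; the first ``blank_ms`` after onset are skipped to avoid the
    fast inward transient.  ``excluded`` is set when the fit is poor
    (R^2 < ``r2_min``) or tau exceeds the step duration.
    """
    t = sweep.time - sweep.protocol.pre_ms
    mask = (t >= blank_ms) & (t <= sweep.protocol.step_ms)
    ts, ys = t[mask], sweep.signal[mask]
    if ts.size < 10:
        raise ValueError("step window too short for an inactivation fit")
    i_peak = int(np.argmax(ys))
    if i_peak >= ys.size - 5:
        raise ValueError("no identifiable outward-current peak "
                         "(monotonically rising trace)")
    tv = ts[i_peak:] - ts[i_peak]
    yv = ys[i_peak:]

    amp0 = max(float(yv[0] - yv[-1]), 1e-6)
    p0 = (amp0, float(yv[-1]), max(tv[-1] / 3.0, 1.0))
    try:
        popt, _ = curve_fit(
            lambda x, a, c, tau: a * np.exp(-x / tau) + c, tv, yv, p0=p0,
            bounds=([0.0, -np.inf, 0.1], [np.inf, np.inf, 1e5]), maxfev=10000)
    except RuntimeError as exc:
        raise ValueError(f"inactivation fit did not converge: {exc}") from exc
    amp, base, tau = (float(x) for x in popt)
    resid = yv - (amp * np.exp(-tv / tau) + base)
    sst = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    excluded = bool(r2 < r2_min or tau > sweep.protocol.step_ms)
    return InactivationFit(tau_inact=tau, baseline=base, amplitude=amp,
                           fit_r2=r2, excluded=excluded)


def extract_vc_features(family: list, e_k: float = E_K_DEFAULT, **curve_kw) -> dict:
    """Per-neuron voltage-clamp feature row.

    Returns g_max, g_minus30, v_half (None when the curve failed saturation)
    and tau_inact (None when the exponential fit was excluded), plus the
    exclusion flags themselves so nothing is dropped silently.
    """
    curve = fit_boltzmann(conductance_curve(family, e_k=e_k, **curve_kw))
    vc_excluded = not curve.saturated
    row = {
        "g_max": None if vc_excluded else curve.boltzmann["g_max"],
        "g_minus30": None if vc_excluded else curve.g_minus30,
        "v_half": None if vc_excluded else curve.boltzmann["v_half"],
        "vc_excluded": vc_excluded,
        "tau_inact": None,
        "tau_excluded": True,
    }
    plus70 = [sw for sw in family if sw.stimulus_level >= 69.0]
    if plus70:
        try:
            fit = fit_tau_inact(plus70[-1])
        except ValueError:
            fit = None
        if fit is not None:
            row["tau_excluded"] = fit.excluded
            row["tau_inact"] = None if fit.excluded else fit.tau_inact
    return row
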