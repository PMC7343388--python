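"""Synthetic spiral-ganglion-neuron (SGN) populations and patch-clamp recordings.

Generates conductance-based model neurons whose potassium-conductance magnitude
varies with synaptic contact position (normalized basal position, NBP) and
post-natal age, then simulates the two standard stimulus protocols:

* current clamp -- 1000 ms current steps from rest (firing patterns, thresholds,
  latencies);
* voltage clamp -- 400 ms voltage steps from a -60 mV hold, -120 to +70 mV
  (steady-state conductance curves, inactivation kinetics).

Every neuron carries its generating parameters as ground truth so that feature
extraction and model fitting can be tested as recovery problems.

Units are internally consistent throughout: mV, ms, nS, pA, pF
(pA = nS * mV; pF * mV / ms = pA).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate as _integrate
from scipy import stats as _stats

from .morphometry import Contact, ContactGeometry

__all__ = [
    "StimulusProtocol",
    "Sweep",
    "NeuronParams",
    "NeuronRecording",
    "SimulationConfig",
    "SimulationError",
    "default_cc_protocol",
    "default_vc_protocol",
    "boltzmann",
    "inactivation_gate",
    "sample_population",
    "simulate_voltage_clamp",
    "simulate_current_clamp",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

E_K_DEFAULT = -85.0   # Nernst for 165 mM internal / 5.8 mM bath K+ at room temp
E_NA_DEFAULT = 60.0


class SimulationError(RuntimeError):
    """Raised when the integrator produces non-finite or runaway voltages."""


# ---------------------------------------------------------------------------
# protocols and sweeps


@dataclass(frozen=True)
class StimulusProtocol:
    """One stimulus family: a pre/step/post epoch structure with a ladder of
    step amplitudes (pA in current clamp, mV in voltage clamp)."""

    mode: str
    pre_ms: float
    step_ms: float
    post_ms: float
    amplitudes: tuple
    holding_level: float
    sample_rate: float  # kHz

    def __post_init__(self):
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.size == 0 or np.any(np.diff(amps) <= 0):
            raise ValueError("amplitudes must be non-empty and strictly increasing")
        object.__setattr__(self, "amplitudes", tuple(amps))
        if min(self.pre_ms, self.post_ms) < 0 or self.step_ms <= 0 or self.sample_rate <= 0:
            raise ValueError("invalid protocol timing")

    @property
    def total_ms(self) -> float:
        return self.pre_ms + self.step_ms + self.post_ms

    def time_axis(self) -> np.ndarray:
        dt = 1.0 / self.sample_rate
        n = int(round(self.total_ms / dt))
        return np.arange(n) * dt


def default_cc_protocol(sample_rate: float = 10.0) -> StimulusProtocol:
    """1000 ms current steps; a ladder fine at low amplitudes where most
    thresholds fall, coarser above."""
    amps = tuple(np.r_[np.arange(10.0, 201.0, 10.0), np.arange(220.0, 501.0, 20.0)])
    return StimulusProtocol(
        mode="current_clamp", pre_ms=100.0, step_ms=1000.0, post_ms=100.0,
        amplitudes=amps, holding_level=0.0, sample_rate=sample_rate,
    )


def default_vc_protocol(sample_rate: float = 10.0) -> StimulusProtocol:
    """400 ms voltage steps, -120 to +70 mV in 10 mV increments, from -60 mV."""
    return StimulusProtocol(
        mode="voltage_clamp", pre_ms=20.0, step_ms=400.0, post_ms=20.0,
        amplitudes=tuple(np.arange(-120.0, 71.0, 10.0)),
        holding_level=-60.0, sample_rate=sample_rate,
    )


@dataclass
class Sweep:
    """A single stimulus-locked trace (mV in current clamp, pA in voltage clamp)."""

    time: np.ndarray
    signal: np.ndarray
    stimulus_level: float
    protocol: StimulusProtocol

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size >= 2:
            d = np.diff(self.time)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


# ---------------------------------------------------------------------------
# neuron parameters


@dataclass
class NeuronParams:
    """Generating parameters for one model neuron.

    ``g_ss_true`` is the steady-state (400 ms) conductance ceiling that the
    spatial/age gradient lines describe; ``g_max_true`` is the Boltzmann
    ceiling before inactivation, ``g_max_true = g_ss_true / h(400 ms)``.
    """

    nbp_true: float
    age: int
    g_max_true: float
    v_half_true: float
    slope_k_true: float
    tau_inact_true: float
    g_leak: float
    e_k: float
    e_leak: float
    e_na: float
    g_na: float
    v_rest_target: float
    c_m: float
    fiber_type: str = "type_I"
    g_ss_true: float = 0.0
    inact_floor: float = 0.7

    def __post_init__(self):
        if self.g_max_true <= 0 or self.tau_inact_true <= 0 or self.c_m <= 0:
            raise ValueError("g_max_true, tau_inact_true and c_m must be positive")
        if self.slope_k_true <= 0:
            raise ValueError("slope_k_true must be positive")
        if not -1.0 <= self.nbp_true <= 1.0:
            raise ValueError("nbp_true outside [-1, 1]")
        if self.fiber_type not in ("type_I", "type_II"):
            raise ValueError(f"unknown fiber_type {self.fiber_type!r}")


@dataclass
class NeuronRecording:
    neuron_id: str
    params: NeuronParams | None
    cc_family: list
    vc_family: list
    contact: ContactGeometry | None = None


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic population.

    Defaults encode the empirical structure the generator emulates: NBP
    distributed as a truncated normal with mean 0.11 and SD 0.23; face-binned
    steady-state conductance growing along g = 4.93*age + 10 (modiolar) and
    g = 2.29*age + 10 (pillar); latency inversely proportional to conductance
    (reference constant K = 420); a depolarized-rest subgroup whose sodium
    channels are inactivated, producing graded (non-spiking) responses; and
    lognormal parameter dispersion tuned so per-feature coefficients of
    variation stay flat across age.
    """

    n_neurons: int = 100
    age_range: tuple = (1, 16)
    seed: int = 0

    # contact-position distribution
    nbp_mean: float = 0.11
    nbp_sd: float = 0.23
    nbp_bounds: tuple = (-0.6, 0.6)

    # face-binned steady-state conductance vs age (nS per day, nS)
    gmax_slope_modiolar: float = 4.93
    gmax_intercept_modiolar: float = 10.0
    gmax_slope_pillar: float = 2.29
    gmax_intercept_pillar: float = 10.0
    latency_constant: float = 420.0
    # width (NBP units) of the logistic position response interpolating
    # between the pillar- and modiolar-face conductance lines
    nbp_gradient_width: float = 0.10

    # per-parameter lognormal dispersion (coefficient of variation).  The
    # position gradient steepens with age, so the structural (position-driven)
    # share of the conductance variance grows; the multiplicative noise is
    # tuned per age so the TOTAL conductance CV stays flat across age bins,
    # at gmax_cv_total.  gmax_cv_floor bounds the noise from below.
    gmax_cv_total: float = 0.42
    gmax_cv_floor: float = 0.10
    #: canonical age bins over which the dispersion is held flat
    cv_reference_bins: tuple = ((1, 5), (6, 9), (10, 16))
    tau_cv: float = 0.20
    gleak_cv: float = 0.10

    # trace-level additive noise
    trace_noise_cc_mv: float = 0.2
    trace_noise_vc_pa: float = 5.0

    # resting-potential mixture controlling the graded (non-spiking) fraction
    graded_fraction: float = 0.4
    v_rest_spiking: float = -56.9
    v_rest_graded: float = -51.8
    v_rest_sd: float = 1.0

    type_ii_fraction: float = 0.0

    # voltage-clamp K-conductance shape
    v_half_mean: float = -28.0
    v_half_sd: float = 4.0
    slope_k_mean: float = 10.0
    slope_k_sd: float = 1.0
    tau_inact_base: float = 220.0
    tau_inact_nbp_slope: float = 180.0
    inact_floor: float = 0.7

    # passive / sodium machinery; the leak scales with the K ceiling (overall
    # channel-density scaling), which keeps current thresholds and latencies
    # close to proportional / reciprocal in conductance
    c_m: float = 55.0
    gleak_base: float = 0.0
    gleak_per_gss: float = 0.06
    gna_factor: float = 60.0
    e_k: float = E_K_DEFAULT
    e_na: float = E_NA_DEFAULT

    # sodium gating (activation m, inactivation h); the h midpoint sits
    # between the spiking (-56.9 mV) and graded (-51.8 mV) resting-potential
    # modes so that a depolarized rest silences spiking
    na_m_half: float = -28.0
    na_m_k: float = 4.0
    na_m_tau: float = 0.1
    na_h_half: float = -57.0
    na_h_k: float = 1.2
    na_h_tau: float = 150.0

    # K activation lag (gives the early depolarization peak in graded cells)
    k_act_tau: float = 1.5

    # integrator
    dt_ms: float = 0.02
    sample_rate: float = 10.0

    def __post_init__(self):
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        lo, hi = self.nbp_bounds
        if not lo < hi:
            raise ValueError("nbp_bounds must be ordered")
        if not lo <= self.nbp_mean <= hi:
            raise ValueError("nbp_bounds exclude nbp_mean")
        for name in ("nbp_sd", "gmax_cv_total", "tau_cv", "gleak_cv",
                     "trace_noise_cc_mv", "trace_noise_vc_pa", "v_rest_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.graded_fraction <= 1:
            raise ValueError("graded_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(d["age_range"])
        d["nbp_bounds"] = list(d["nbp_bounds"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("age_range", "nbp_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# gating functions


def boltzmann(v, v_half, k):
    """Steady-state activation 1 / (1 + exp(-(v - v_half)/k))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / k))


def inactivation_gate(t, tau, floor):
    """K inactivation h(t): exponential decay from 1 toward ``floor``."""
    return floor + (1.0 - floor) * np.exp(-np.asarray(t, dtype=float) / tau)


def _m_inf(v, cfg):
    return boltzmann(v, cfg.na_m_half, cfg.na_m_k)


def _h_inf(v, cfg):
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - cfg.na_h_half) / cfg.na_h_k))


# ---------------------------------------------------------------------------
# population sampling


def _position_response(cfg: SimulationConfig):
    """Normalized position response mapping NBP to the pillar->modiolar
    conductance interpolation weight.

    The two printed face lines are group-level fits (NBP < 0 vs >= 0), so the
    raw logistic response sigma((nbp - mid)/width) is affinely renormalized so
    that its conditional mean is exactly 0 on the pillar face and 1 on the
    modiolar face; the face-binned regression of a generated population is
    then centered on the configured lines by construction.  The response
    flattens toward the observed position extremes, keeping within-face
    dispersion realistic.

    Returns ``frac(nbp)`` plus the overall SD of the response under the
    configured NBP distribution (used to budget the noise CV).
    """
    if cfg.nbp_sd == 0:
        mid, width = 0.1, cfg.nbp_gradient_width

        def frac_degenerate(x):
            return 1.0 / (1.0 + np.exp(-(np.asarray(x, float) - mid) / width))

        return frac_degenerate, 0.0

    lo, hi = cfg.nbp_bounds
    a, b = (lo - cfg.nbp_mean) / cfg.nbp_sd, (hi - cfg.nbp_mean) / cfg.nbp_sd
    dist = _stats.truncnorm(a, b, loc=cfg.nbp_mean, scale=cfg.nbp_sd)
    width = cfg.nbp_gradient_width
    mid = 0.0  # the face boundary

    def sig(x):
        return 1.0 / (1.0 + np.exp(-(np.asarray(x, float) - mid) / width))

    def cond_mean(x0, x1, fallback):
        mass = dist.cdf(x1) - dist.cdf(x0)
        if mass < 1e-6:
            return fallback
        num, _ = _integrate.quad(lambda x: sig(x) * dist.pdf(x), x0, x1)
        return num / mass

    sbar_p = cond_mean(lo, 0.0, 0.0)
    sbar_m = cond_mean(0.0, hi, 1.0)
    if sbar_m - sbar_p < 1e-9:
        sbar_p, sbar_m = 0.0, 1.0

    def frac(x):
        return (sig(x) - sbar_p) / (sbar_m - sbar_p)

    mean_f, _ = _integrate.quad(lambda x: frac(x) * dist.pdf(x), lo, hi)
    m2, _ = _integrate.quad(lambda x: frac(x) ** 2 * dist.pdf(x), lo, hi)
    sd_frac = float(np.sqrt(max(m2 - mean_f**2, 0.0)))
    return frac, sd_frac


def _lognormal(rng, cv, size):
    """Unit-mean lognormal multiplier with the given coefficient of variation
    (scalar or per-element array)."""
    cv = np.asarray(cv, dtype=float)
    if np.all(cv == 0):
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, 1.0, size=size) * sigma - 0.5 * sigma**2)


def _solve_e_leak(v_rest, g_leak, g_max, v_half, k, g_na, cfg):
    """Leak reversal that places the resting potential exactly at target.

    At rest the K inactivation gate is ~1 and activation sits at its steady
    state, so the residual K and Na window currents are cancelled through the
    leak battery.
    """
    i_k = g_max * boltzmann(v_rest, v_half, k) * (v_rest - cfg.e_k)
    i_na = g_na * _m_inf(v_rest, cfg) * _h_inf(v_rest, cfg) * (v_rest - cfg.e_na)
    return v_rest + (i_k + i_na) / g_leak


def sample_population(config: SimulationConfig) -> list:
    """Draw a population of ``NeuronParams`` under the configured gradients.

    NBP comes from a truncated normal; each neuron's steady-state conductance
    is obtained by linear interpolation in NBP between the pillar- and
    modiolar-face age lines (anchored at the face-conditional mean positions)
    and multiplied by unit-mean lognormal noise.  Resting potentials are drawn
    from a two-component mixture so a configurable fraction of neurons sit
    depolarized enough to inactivate their sodium channels (graded phenotype).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons

    if cfg.nbp_sd == 0:
        nbp = np.full(n, cfg.nbp_mean)
    else:
        lo, hi = cfg.nbp_bounds
        a, b = (lo - cfg.nbp_mean) / cfg.nbp_sd, (hi - cfg.nbp_mean) / cfg.nbp_sd
        nbp = _stats.truncnorm.rvs(a, b, loc=cfg.nbp_mean, scale=cfg.nbp_sd,
                                   size=n, random_state=rng)

    lo_age, hi_age = cfg.age_range
    ages = rng.integers(lo_age, hi_age + 1, size=n)

    frac_fn, sd_frac = _position_response(cfg)
    g_pillar = cfg.gmax_slope_pillar * ages + cfg.gmax_intercept_pillar
    g_modiolar = cfg.gmax_slope_modiolar * ages + cfg.gmax_intercept_modiolar
    frac = frac_fn(nbp)
    g_line = g_pillar + (g_modiolar - g_pillar) * frac
    # age-compensated multiplicative dispersion: the position-driven
    # (structural) variance grows with age as the face lines diverge, and the
    # canonical age bins mix ages; the noise CV is budgeted per bin so the
    # TOTAL bin-level conductance CV stays flat at gmax_cv_total
    mean_g = 0.5 * (g_pillar + g_modiolar)
    struct_cv = np.abs(g_modiolar - g_pillar) * sd_frac / np.maximum(mean_g, 1e-9)
    agemix_cv = np.zeros(n)
    for lo_b, hi_b in cfg.cv_reference_bins:
        in_bin = (ages >= lo_b) & (ages <= hi_b)
        if not np.any(in_bin):
            continue
        bin_ages = np.arange(max(lo_b, lo_age), min(hi_b, hi_age) + 1)
        mid_slope = 0.5 * (cfg.gmax_slope_modiolar + cfg.gmax_slope_pillar)
        bin_mean = 0.5 * (cfg.gmax_intercept_modiolar + cfg.gmax_intercept_pillar) \
            + mid_slope * bin_ages.mean()
        agemix_cv[in_bin] = mid_slope * bin_ages.std() / max(bin_mean, 1e-9)
    noise_cv = np.sqrt(np.maximum(
        cfg.gmax_cv_total**2 - struct_cv**2 - agemix_cv**2,
        cfg.gmax_cv_floor**2))
    g_ss = np.maximum(g_line * _lognormal(rng, noise_cv, n), 1.0)

    tau = np.maximum(
        (cfg.tau_inact_base + cfg.tau_inact_nbp_slope * nbp) * _lognormal(rng, cfg.tau_cv, n),
        50.0,
    )
    h400 = inactivation_gate(400.0, tau, cfg.inact_floor)
    g_max = g_ss / h400

    v_half = rng.normal(cfg.v_half_mean, cfg.v_half_sd, size=n)
    slope_k = np.clip(rng.normal(cfg.slope_k_mean, cfg.slope_k_sd, size=n), 2.0, None)

    graded = rng.random(n) < cfg.graded_fraction
    v_rest = np.where(
        graded,
        rng.normal(cfg.v_rest_graded, cfg.v_rest_sd, size=n),
        rng.normal(cfg.v_rest_spiking, cfg.v_rest_sd, size=n),
    )

    g_leak = (cfg.gleak_base + cfg.gleak_per_gss * g_ss) * _lognormal(rng, cfg.gleak_cv, n)
    g_na = cfg.gna_factor * g_leak
    type_ii = rng.random(n) < cfg.type_ii_fraction

    population = []
    for i in range(n):
        e_leak = _solve_e_leak(v_rest[i], g_leak[i], g_max[i], v_half[i],
                               slope_k[i], g_na[i], cfg)
        population.append(NeuronParams(
            nbp_true=float(np.clip(nbp[i], -1.0, 1.0)),
            age=int(ages[i]),
            g_max_true=float(g_max[i]),
            v_half_true=float(v_half[i]),
            slope_k_true=float(slope_k[i]),
            tau_inact_true=float(tau[i]),
            g_leak=float(g_leak[i]),
            e_k=cfg.e_k,
            e_leak=float(e_leak),
            e_na=cfg.e_na,
            g_na=float(g_na[i]),
            v_rest_target=float(v_rest[i]),
            c_m=cfg.c_m,
            fiber_type="type_II" if type_ii[i] else "type_I",
            g_ss_true=float(g_ss[i]),
            inact_floor=cfg.inact_floor,
        ))
    return population


# ---------------------------------------------------------------------------
# voltage clamp (closed form: the command voltage fixes every gate trajectory)


def simulate_voltage_clamp(params: NeuronParams, protocol: StimulusProtocol,
                           seed=None, noise_sd_pa: float = 0.0,
                           na_transient: bool = True,
                           cfg: SimulationConfig | None = None) -> list:
    """Current responses to a family of voltage steps.

    During the step at command voltage V the clamped current is

        I(t) = g_max * B(V) * h(t) * (V - E_K) + g_leak * (V - E_leak) [+ Na]

    with B the Boltzmann activation at (v_half_true, slope_k_true) and h the
    inactivation gate decaying from 1 toward ``inact_floor`` with time constant
    tau_inact_true.  The optional fast Na transient decays within ~1 ms and is
    long gone by the steady-state measurement window.
    """
    if protocol.mode != "voltage_clamp":
        raise ValueError("protocol mode must be voltage_clamp")
    cfg = cfg or SimulationConfig()
    p = params
    rng = np.random.default_rng(seed)
    t = protocol.time_axis()
    on = protocol.pre_ms
    off = protocol.pre_ms + protocol.step_ms
    in_step = (t >= on) & (t < off)
    vh = protocol.holding_level

    i_hold = (p.g_leak * (vh - p.e_leak)
              + p.g_max_true * boltzmann(vh, p.v_half_true, p.slope_k_true) * (vh - p.e_k))

    sweeps = []
    h_na_hold = _h_inf(vh, cfg)
    for v in protocol.amplitudes:
        sig = np.full_like(t, i_hold)
        ts = t[in_step] - on
        h = inactivation_gate(ts, p.tau_inact_true, p.inact_floor)
        i_k = p.g_max_true * boltzmann(v, p.v_half_true, p.slope_k_true) * h * (v - p.e_k)
        i_leak = p.g_leak * (v - p.e_leak)
        i_step = i_k + i_leak
        if na_transient and p.g_na > 0:
            i_step = i_step + (p.g_na * _m_inf(v, cfg) * h_na_hold
                               * np.exp(-ts / 1.0) * (v - p.e_na))
        sig[in_step] = i_step
        if noise_sd_pa > 0:
            sig = sig + rng.normal(0.0, noise_sd_pa, size=sig.shape)
        sweeps.append(Sweep(time=t, signal=sig, stimulus_level=float(v),
                            protocol=protocol))
    return sweeps


# ---------------------------------------------------------------------------
# current clamp (single-compartment ODE, fixed-step Heun integration)


def _cc_derivatives(V, m, h, nk, w, i_inj, P, cfg):
    i_ion = (P["g_leak"] * (V - P["e_leak"])
             + P["g_max"] * nk * w * (V - P["e_k"])
             + P["g_na"] * m * h * (V - P["e_na"]))
    dV = (i_inj - i_ion) / P["c_m"]
    dm = (_m_inf(V, cfg) - m) / cfg.na_m_tau
    dh = (_h_inf(V, cfg) - h) / cfg.na_h_tau
    b = boltzmann(V, P["v_half"], P["slope_k"])
    dnk = (b - nk) / cfg.k_act_tau
    # K inactivation develops only where the conductance activates, so the
    # resting state carries no inactivation; at strong depolarization (B -> 1)
    # w relaxes from 1 to the floor with tau_inact, matching the clamped case
    dw = ((1.0 - (1.0 - P["floor"]) * b) - w) / P["tau_inact"]
    return dV, dm, dh, dnk, dw


def _integrate_cc(P: dict, amplitudes: np.ndarray, protocol: StimulusProtocol,
                  cfg: SimulationConfig, prehold_mv=None,
                  passive: bool = False) -> np.ndarray:
    """Vectorized Heun integration of the membrane equation.

    ``P`` maps parameter names to arrays of shape (N, 1); the state is carried
    as (N, A) arrays for A step amplitudes, and the voltage is recorded at the
    protocol sample rate.  Returns an (N, A, T) voltage array.
    """
    dt = cfg.dt_ms
    t_out = protocol.time_axis()
    record_every = max(int(round((1.0 / protocol.sample_rate) / dt)), 1)
    n_steps = (len(t_out) - 1) * record_every + 1
    on = protocol.pre_ms
    off = protocol.pre_ms + protocol.step_ms

    n_cells = P["g_leak"].shape[0]
    n_amps = len(amplitudes)
    amps = np.broadcast_to(np.asarray(amplitudes, dtype=float), (n_cells, n_amps))

    if prehold_mv is None:
        # a passive cell rests at the leak battery; otherwise the leak was
        # solved so the full model rests at the target potential
        v0 = P["e_leak"] if passive else P["v_rest"]
        V = np.broadcast_to(v0, (n_cells, n_amps)).copy()
        i_bias = np.zeros((n_cells, n_amps))
    else:
        V = np.full((n_cells, n_amps), float(prehold_mv))
        # constant bias holding the cell at the pre-hold level
        i_bias = (P["g_leak"] * (V - P["e_leak"])
                  + P["g_max"] * boltzmann(V, P["v_half"], P["slope_k"]) * (V - P["e_k"])
                  + P["g_na"] * _m_inf(V, cfg) * _h_inf(V, cfg) * (V - P["e_na"]))
    m = _m_inf(V, cfg).copy()
    h = _h_inf(V, cfg).copy()
    nk = boltzmann(V, P["v_half"], P["slope_k"]).copy()
    w = 1.0 - (1.0 - P["floor"]) * nk
    if passive:
        m = np.zeros_like(V)
        h = np.zeros_like(V)
        nk = np.zeros_like(V)

    out = np.empty((n_cells, n_amps, len(t_out)))
    out[:, :, 0] = V
    rec = 1
    for step in range(1, n_steps):
        t_prev = (step - 1) * dt
        t_mid = step * dt
        i1 = i_bias + np.where((on <= t_prev) & (t_prev < off), amps, 0.0)
        i2 = i_bias + np.where((on <= t_mid) & (t_mid < off), amps, 0.0)
        d1 = _cc_derivatives(V, m, h, nk, w, i1, P, cfg)
        Vp = V + dt * d1[0]
        mp = m + dt * d1[1]
        hp = h + dt * d1[2]
        nkp = nk + dt * d1[3]
        wp = w + dt * d1[4]
        d2 = _cc_derivatives(Vp, mp, hp, nkp, wp, i2, P, cfg)
        V = V + 0.5 * dt * (d1[0] + d2[0])
        m = np.clip(m + 0.5 * dt * (d1[1] + d2[1]), 0.0, 1.0)
        h = np.clip(h + 0.5 * dt * (d1[2] + d2[2]), 0.0, 1.0)
        nk = np.clip(nk + 0.5 * dt * (d1[3] + d2[3]), 0.0, 1.0)
        w = np.clip(w + 0.5 * dt * (d1[4] + d2[4]), 0.0, 1.0)
        if step % record_every == 0:
            out[:, :, rec] = V
            rec += 1

    if not np.all(np.isfinite(out)) or np.any(np.abs(out) > 500.0):
        raise SimulationError("current-clamp integration unstable (non-finite "
                              "or runaway voltage); reduce dt_ms")
    return out


def _params_to_arrays(population: list) -> dict:
    def col(name):
        return np.array([getattr(p, name) for p in population])[:, None]
    return {
        "g_leak": col("g_leak"), "e_leak": col("e_leak"), "e_k": col("e_k"),
        "e_na": col("e_na"), "g_na": col("g_na"), "g_max": col("g_max_true"),
        "v_half": col("v_half_true"), "slope_k": col("slope_k_true"),
        "tau_inact": col("tau_inact_true"), "floor": col("inact_floor"),
        "c_m": col("c_m"), "v_rest": col("v_rest_target"),
    }


def simulate_current_clamp(params: NeuronParams, protocol: StimulusProtocol,
                           seed=None, noise_sd_mv: float = 0.0,
                           prehold_mv=None, passive: bool = False,
                           cfg: SimulationConfig | None = None) -> list:
    """Voltage responses to a family of current steps.

    Integrates C dV/dt = -I_leak - I_K - I_Na + I_inj with transient sodium
    (fast activation m, slower inactivation h), lagged K activation and slow
    K inactivation.  Neurons resting depolarized enough to inactivate sodium
    produce graded depolarizations; ``prehold_mv=-80`` holds the membrane
    hyperpolarized before the step, restoring spiking in those neurons.
    ``passive=True`` zeroes every voltage-gated conductance (RC limit).
    """
    if protocol.mode != "current_clamp":
        raise ValueError("protocol mode must be current_clamp")
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    P = _params_to_arrays([params])
    if passive:
        P = dict(P)
        P["g_max"] = np.zeros_like(P["g_max"])
        P["g_na"] = np.zeros_like(P["g_na"])
    V = _integrate_cc(P, np.asarray(protocol.amplitudes), protocol, cfg,
                      prehold_mv=prehold_mv, passive=passive)[0]
    t = protocol.time_axis()
    sweeps = []
    for j, amp in enumerate(protocol.amplitudes):
        sig = V[j]
        if noise_sd_mv > 0:
            sig = sig + rng.normal(0.0, noise_sd_mv, size=sig.shape)
        sweeps.append(Sweep(time=t, signal=sig, stimulus_level=float(amp),
                            protocol=protocol))
    return sweeps


# ---------------------------------------------------------------------------
# full dataset


def _contact_geometry(nbp: float, rng) -> ContactGeometry:
    length = float(np.clip(rng.normal(20.0, 2.0), 12.0, None))
    face = "modiolar" if nbp >= 0 else "pillar"
    contacts = [Contact(c=abs(nbp) * length, face=face)]
    # occasional secondary, strictly less extreme, so the max-|c/L| rule
    # still recovers the generating position
    if rng.random() < 0.3 and abs(nbp) > 0.02:
        c2 = rng.uniform(0.0, 0.95 * abs(nbp)) * length
        face2 = "modiolar" if rng.random() < 0.5 else "pillar"
        contacts.append(Contact(c=float(c2), face=face2))
    return ContactGeometry(contacts=contacts, hair_cell_length=length)


def generate_dataset(config: SimulationConfig,
                     cc_protocol: StimulusProtocol | None = None,
                     vc_protocol: StimulusProtocol | None = None) -> list:
    """Sample a population and simulate both recording families per neuron.

    Current-clamp integration is batched across the whole population for
    speed; results are identical to per-neuron calls with the same seeds.
    """
    cfg = config
    cc_protocol = cc_protocol or default_cc_protocol(cfg.sample_rate)
    vc_protocol = vc_protocol or default_vc_protocol(cfg.sample_rate)
    population = sample_population(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD5]))
    noise_seeds = rng.integers(0, 2**31 - 1, size=(len(population), 2))

    P = _params_to_arrays(population)
    V_all = _integrate_cc(P, np.asarray(cc_protocol.amplitudes), cc_protocol, cfg)
    t_cc = cc_protocol.time_axis()

    recordings = []
    for i, params in enumerate(population):
        cc_rng = np.random.default_rng(int(noise_seeds[i, 0]))
        cc_family = []
        for j, amp in enumerate(cc_protocol.amplitudes):
            sig = V_all[i, j]
            if cfg.trace_noise_cc_mv > 0:
                sig = sig + cc_rng.normal(0.0, cfg.trace_noise_cc_mv, size=sig.shape)
            cc_family.append(Sweep(time=t_cc, signal=sig,
                                   stimulus_level=float(amp), protocol=cc_protocol))
        vc_family = simulate_voltage_clamp(
            params, vc_protocol, seed=int(noise_seeds[i, 1]),
            noise_sd_pa=cfg.trace_noise_vc_pa, cfg=cfg)
        geom_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 0xC0, i]))
        recordings.append(NeuronRecording(
            neuron_id=f"sgn{i:04d}",
            params=params,
            cc_family=cc_family,
            vc_family=vc_family,
            contact=_contact_geometry(params.nbp_true, geom_rng),
        ))
    return recordings


# ---------------------------------------------------------------------------
# serialization: one directory per dataset, CSV sweeps + JSON manifest

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _protocol_to_dict(p: StimulusProtocol) -> dict:
    return {"mode": p.mode, "pre_ms": p.pre_ms, "step_ms": p.step_ms,
            "post_ms": p.post_ms, "amplitudes": list(p.amplitudes),
            "holding_level": p.holding_level, "sample_rate": p.sample_rate}


def _family_frame(family: list) -> pd.DataFrame:
    df = pd.DataFrame({"time": family[0].time})
    for sw in family:
        df[_FLOAT_FMT % sw.stimulus_level] = sw.signal
    return df


def _family_from_frame(df: pd.DataFrame, protocol: StimulusProtocol) -> list:
    t = df["time"].to_numpy()
    return [Sweep(time=t, signal=df[c].to_numpy(), stimulus_level=float(c),
                  protocol=protocol) for c in df.columns[1:]]


def save_dataset(recordings: list, path, config: SimulationConfig | None = None):
    """Write a dataset directory: manifest.json, ground_truth.csv,
    contacts.csv and per-neuron sweep CSVs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "neuron_ids": [r.neuron_id for r in recordings],
        "cc_protocol": _protocol_to_dict(recordings[0].cc_family[0].protocol),
        "vc_protocol": _protocol_to_dict(recordings[0].vc_family[0].protocol),
        "config": config.to_dict() if config is not None else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    truth_rows, contact_rows = [], []
    for r in recordings:
        _family_frame(r.cc_family).to_csv(path / f"{r.neuron_id}_cc.csv",
                                          index=False, float_format=_FLOAT_FMT)
        _family_frame(r.vc_family).to_csv(path / f"{r.neuron_id}_vc.csv",
                                          index=False, float_format=_FLOAT_FMT)
        if r.params is not None:
            row = dataclasses.asdict(r.params)
            row["neuron_id"] = r.neuron_id
            truth_rows.append(row)
        if r.contact is not None:
            for ct in r.contact.contacts:
                contact_rows.append({"neuron_id": r.neuron_id, "c": ct.c,
                                     "face": ct.face,
                                     "hair_cell_length": r.contact.hair_cell_length})
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(path / "ground_truth.csv", index=False,
                                        float_format=_FLOAT_FMT)
    if contact_rows:
        pd.DataFrame(contact_rows).to_csv(path / "contacts.csv", index=False,
                                          float_format=_FLOAT_FMT)


def load_dataset(path) -> list:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    cc_proto = StimulusProtocol(**manifest["cc_protocol"])
    vc_proto = StimulusProtocol(**manifest["vc_protocol"])

    truth = {}
    gt_path = path / "ground_truth.csv"
    if gt_path.exists():
        for row in pd.read_csv(gt_path, float_precision="round_trip").to_dict("records"):
            nid = row.pop("neuron_id")
            row["age"] = int(row["age"])
            truth[nid] = NeuronParams(**row)
    contacts = {}
    ct_path = path / "contacts.csv"
    if ct_path.exists():
        for nid, grp in pd.read_csv(ct_path, float_precision="round_trip").groupby("neuron_id"):
            contacts[nid] = ContactGeometry(
                contacts=[Contact(c=r.c, face=r.face) for r in grp.itertuples()],
                hair_cell_length=float(grp["hair_cell_length"].iloc[0]),
            )

    recordings = []
    for nid in manifest["neuron_ids"]:
        cc = _family_from_frame(pd.read_csv(path / f"{nid}_cc.csv", float_precision="round_trip"), cc_proto)
        vc = _family_from_frame(pd.read_csv(path / f"{nid}_vc.csv", float_precision="round_trip"), vc_proto)
        recordings.append(NeuronRecording(
            neuron_id=nid, params=truth.get(nid), cc_family=cc, vc_family=vc,
            contact=contacts.get(nid)))
    return recordings
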