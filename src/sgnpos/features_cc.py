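"""Current-clamp feature extraction.

Operates on a family of current-step sweeps from one neuron and extracts the
standard excitability features: resting potential, spike detection with an
operational voltage threshold (dV/dt criterion), current threshold, first-spike
latency, after-hyperpolarization time constant, graded-response latency and a
qualitative firing-pattern class (rapid / intermediate / slow accommodation,
or graded for non-spiking cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .simulate import Sweep

__all__ = [
    "SpikeEvent",
    "CurrentClampFeatures",
    "GradedLatency",
    "detect_spikes",
    "resting_potential",
    "current_threshold",
    "first_spike_latency",
    "ahp_tau",
    "response_latency_graded",
    "classify_firing_pattern",
    "extract_cc_features",
]

#: dV/dt crossing (mV/ms) that operationalizes the voltage threshold, and the
#: minimum rise above the crossing for an event to count as a spike (mV).
DVDT_THRESHOLD = 10.0
MIN_SPIKE_HEIGHT = 20.0

#: spikes inside the final fraction of the step mark slow accommodation
SLOW_TAIL_FRACTION = 0.2


@dataclass
class SpikeEvent:
    peak_time: float       # ms from step onset
    peak_v: float
    threshold_v: float
    threshold_time: float  # ms from step onset

    def __post_init__(self):
        if self.threshold_time > self.peak_time:
            raise ValueError("threshold_time must not exceed peak_time")
        if self.peak_v <= self.threshold_v:
            raise ValueError("peak_v must exceed threshold_v")


@dataclass
class GradedLatency:
    latency_ms: float
    boundary: bool          # a peak landed on the step-window boundary
    per_sweep: list


@dataclass
class CurrentClampFeatures:
    spiking: bool
    firing_pattern: str
    resting_potential: float
    response_latency: float | None
    i_threshold: float | None = None
    v_threshold: float | None = None
    first_spike_latency: float | None = None
    ahp_tau: float | None = None
    relative_threshold: float | None = None
    ap_height: float | None = None
    graded_boundary: bool = False


def _check_uniform(sweep: Sweep) -> float:
    d = np.diff(sweep.time)
    if d.size == 0 or not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise ValueError("sweep requires uniform sampling")
    return float(d[0])


def detect_spikes(sweep: Sweep, dvdt_threshold: float = DVDT_THRESHOLD,
                  min_height: float = MIN_SPIKE_HEIGHT) -> list:
    """Find action potentials by an upward dV/dt criterion crossing.

    An event is recorded where dV/dt crosses ``dvdt_threshold`` upward and the
    subsequent voltage peak exceeds the crossing voltage by at least
    ``min_height``; the voltage at the crossing is the operational voltage
    threshold.  Times are reported relative to step onset.
    """
    dt = _check_uniform(sweep)
    v = sweep.signal
    t0 = sweep.protocol.pre_ms
    dvdt = np.diff(v) / dt
    up = np.flatnonzero((dvdt[1:] >= dvdt_threshold) & (dvdt[:-1] < dvdt_threshold)) + 1

    events = []
    peak_window = max(int(round(2.0 / dt)), 2)
    last_peak_idx = -1
    for idx in up:
        if idx <= last_peak_idx:
            continue
        seg = v[idx: idx + peak_window]
        rel_peak = int(np.argmax(seg))
        peak_idx = idx + rel_peak
        if v[peak_idx] - v[idx] < min_height:
            continue
        events.append(SpikeEvent(
            peak_time=float(sweep.time[peak_idx] - t0),
            peak_v=float(v[peak_idx]),
            threshold_v=float(v[idx]),
            threshold_time=float(sweep.time[idx] - t0),
        ))
        last_peak_idx = peak_idx
    return events


def _step_spikes(sweep: Sweep, **kw) -> list:
    step_ms = sweep.protocol.step_ms
    return [e for e in detect_spikes(sweep, **kw)
            if 0.0 <= e.threshold_time <= step_ms]


def resting_potential(family: list) -> float:
    """Mean voltage over the pre-step baseline, averaged across sweeps."""
    means = []
    for sw in family:
        mask = sw.time < sw.protocol.pre_ms
        if mask.any():
            means.append(float(sw.signal[mask].mean()))
    if not means:
        raise ValueError("no baseline samples before the step in any sweep")
    return float(np.mean(means))


def current_threshold(family: list, **detect_kw) -> float | None:
    """Smallest step amplitude whose sweep contains at least one spike,
    or None when no sweep spikes (graded neuron)."""
    if not family:
        raise ValueError("empty sweep family")
    for sw in sorted(family, key=lambda s: s.stimulus_level):
        if _step_spikes(sw, **detect_kw):
            return float(sw.stimulus_level)
    return None


def _threshold_sweep(family: list, **detect_kw) -> Sweep:
    for sw in sorted(family, key=lambda s: s.stimulus_level):
        if _step_spikes(sw, **detect_kw):
            return sw
    raise ValueError("neuron does not spike; first-spike latency undefined")


def first_spike_latency(family: list, **detect_kw) -> float:
    """Peak time of the first spike in the threshold-level sweep, from step
    onset (the threshold-level sweep is the smallest spiking amplitude)."""
    sw = _threshold_sweep(family, **detect_kw)
    spikes = _step_spikes(sw, **detect_kw)
    return min(e.peak_time for e in spikes)


def ahp_tau(sweep: Sweep, spike: SpikeEvent, next_spike: SpikeEvent | None = None,
            max_window_ms: float = 100.0) -> float:
    """Time constant of the single-exponential recovery from the
    after-hyperpolarization minimum following ``spike``.

    The fit window runs from the AHP minimum to the post-AHP plateau,
    truncated at the following spike's threshold time when one exists and
    capped at ``max_window_ms`` so slower processes (K-current inactivation)
    do not contaminate the recovery fit.
    """
    dt = _check_uniform(sweep)
    t0 = sweep.protocol.pre_ms
    t = sweep.time - t0
    start = int(np.searchsorted(t, spike.peak_time))
    if next_spike is not None:
        stop = int(np.searchsorted(t, next_spike.threshold_time))
    else:
        stop = int(np.searchsorted(t, sweep.protocol.step_ms))
    stop = min(stop, start + int(round(max_window_ms / dt)))
    seg_v = sweep.signal[start:stop]
    if seg_v.size < 5:
        raise ValueError("no usable window after the spike")
    i_min = int(np.argmin(seg_v))
    if i_min >= seg_v.size - 3:
        raise ValueError("no after-hyperpolarization minimum before window end")
    tv = t[start + i_min: stop] - t[start + i_min]
    vv = sweep.signal[start + i_min: stop]

    def model(x, plateau, amp, tau):
        return plateau - amp * np.exp(-x / tau)

    p0 = (float(vv[-1]), float(max(vv[-1] - vv[0], 0.5)), max(tv[-1] / 5.0, dt))
    try:
        popt, _ = curve_fit(model, tv, vv, p0=p0,
                            bounds=([-150.0, 0.0, dt / 10.0], [50.0, 200.0, 10 * tv[-1]]),
                            maxfev=5000)
    except RuntimeError as exc:
        raise ValueError(f"AHP exponential fit did not converge: {exc}") from exc
    return float(popt[2])


def response_latency_graded(family: list, boundary_fraction: float = 0.02) -> GradedLatency:
    """Mean time-to-peak of the depolarization across depolarizing sweeps.

    A peak in the final ``boundary_fraction`` of the step window is flagged:
    a monotone (pure-RC-like) rise has no interior peak and its time-to-peak
    is not meaningful.
    """
    depol = [sw for sw in family if sw.stimulus_level > 0]
    if len(depol) < 2:
        raise ValueError("need at least two depolarizing sweeps")
    per_sweep, boundary = [], False
    for sw in depol:
        t = sw.time - sw.protocol.pre_ms
        mask = (t >= 0) & (t <= sw.protocol.step_ms)
        seg_t = t[mask]
        idx = int(np.argmax(sw.signal[mask]))
        if seg_t[idx] >= (1.0 - boundary_fraction) * sw.protocol.step_ms:
            boundary = True
        per_sweep.append(float(seg_t[idx]))
    return GradedLatency(latency_ms=float(np.mean(per_sweep)),
                         boundary=boundary, per_sweep=per_sweep)


def classify_firing_pattern(family: list, **detect_kw) -> str:
    """Qualitative accommodation class from the whole sweep family.

    graded: no spikes anywhere; rapid: every suprathreshold sweep fires
    exactly one spike; slow: the maximal sweep still fires within the final
    20% of the step; intermediate: everything else.
    """
    counts = {}
    for sw in sorted(family, key=lambda s: s.stimulus_level):
        counts[sw.stimulus_level] = _step_spikes(sw, **detect_kw)
    spiking_sweeps = {a: ev for a, ev in counts.items() if ev}
    if not spiking_sweeps:
        return "graded"
    if all(len(ev) == 1 for ev in spiking_sweeps.values()):
        return "rapid"
    max_amp = max(counts)
    step_ms = family[0].protocol.step_ms
    tail = (1.0 - SLOW_TAIL_FRACTION) * step_ms
    if counts[max_amp] and any(e.peak_time >= tail for e in counts[max_amp]):
        return "slow"
    return "intermediate"


def extract_cc_features(family: list, **detect_kw) -> CurrentClampFeatures:
    """Full current-clamp feature set for one neuron's sweep family."""
    v_rest = resting_potential(family)
    pattern = classify_firing_pattern(family, **detect_kw)

    if pattern == "graded":
        graded = response_latency_graded(family)
        return CurrentClampFeatures(
            spiking=False, firing_pattern=pattern, resting_potential=v_rest,
            response_latency=graded.latency_ms, graded_boundary=graded.boundary)

    i_thr = current_threshold(family, **detect_kw)
    thr_sweep = _threshold_sweep(family, **detect_kw)
    spikes = _step_spikes(thr_sweep, **detect_kw)
    first = min(spikes, key=lambda e: e.peak_time)
    latency = first.peak_time
    try:
        nxt = sorted(spikes, key=lambda e: e.peak_time)[1] if len(spikes) > 1 else None
        tau = ahp_tau(thr_sweep, first, next_spike=nxt)
    except ValueError:
        tau = None
    return CurrentClampFeatures(
        spiking=True, firing_pattern=pattern, resting_potential=v_rest,
        response_latency=latency, i_threshold=i_thr,
        v_threshold=first.threshold_v, first_spike_latency=latency,
        ahp_tau=tau, relative_threshold=first.threshold_v - v_rest,
        ap_height=first.peak_v - first.threshold_v)
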