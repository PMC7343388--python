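import numpy as np
import pytest

from sgnpos.simulate import (
    NeuronParams,
    SimulationConfig,
    StimulusProtocol,
    _solve_e_leak,
    inactivation_gate,
)


@pytest.fixture(scope="session")
def base_cfg():
    return SimulationConfig()


def make_neuron(cfg, v_rest=-57.0, g_ss=30.0, tau=220.0, v_half=None, slope_k=None,
                nbp=0.0, age=5, g_na=None, g_leak=None):
    """One model neuron with the config's coupling rules, explicit overrides
    allowed for the phenotype knobs."""
    v_half = cfg.v_half_mean if v_half is None else v_half
    slope_k = cfg.slope_k_mean if slope_k is None else slope_k
    h400 = float(inactivation_gate(400.0, tau, cfg.inact_floor))
    g_max = g_ss / h400
    if g_leak is None:
        g_leak = cfg.gleak_base + cfg.gleak_per_gss * g_ss
    if g_na is None:
        g_na = cfg.gna_factor * g_leak
    e_leak = _solve_e_leak(v_rest, g_leak, g_max, v_half, slope_k, g_na, cfg)
    return NeuronParams(
        nbp_true=nbp, age=age, g_max_true=g_max, v_half_true=v_half,
        slope_k_true=slope_k, tau_inact_true=tau, g_leak=g_leak, e_k=cfg.e_k,
        e_leak=e_leak, e_na=cfg.e_na, g_na=g_na, v_rest_target=v_rest,
        c_m=cfg.c_m, g_ss_true=g_ss, inact_floor=cfg.inact_floor,
    )


def cc_protocol(amplitudes, step_ms=1000.0, pre_ms=100.0, post_ms=100.0,
                sample_rate=10.0):
    return StimulusProtocol(mode="current_clamp", pre_ms=pre_ms, step_ms=step_ms,
                            post_ms=post_ms, amplitudes=tuple(amplitudes),
                            holding_level=0.0, sample_rate=sample_rate)


def flat_sweep(level_mv, protocol):
    """A constant-voltage sweep (no excursions)."""
    from sgnpos.simulate import Sweep
    t = protocol.time_axis()
    return Sweep(time=t, signal=np.full_like(t, level_mv),
                 stimulus_level=protocol.amplitudes[0], protocol=protocol)
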