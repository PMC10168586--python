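"""Adaptive point-neuron models with conductance-based exponential synapses.

Three model variants are supported, covering every nucleus in the network:

``aeif``
    Adaptive exponential integrate-and-fire (STN, GPe-TI, GPe-TA)::

        C_m dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_th)/Delta_T)
                    - g_ex (V - E_ex) - g_in (V - E_in) - w + I_e

``aqif``
    Adaptive quadratic integrate-and-fire (D1 and D2 medium spiny neurons)::

        C_m dV/dt = k (V - E_L)(V - V_th)
                    - g_ex (V - E_ex) - g_in (V - E_in) - w + I_e

``aqif2``
    Quadratic variant with a cubic subthreshold adaptation pivot (FSN)::

        tau_w dw/dt = -w + a (V - V_b)^3   if V < V_b,  else  -w

For ``aeif`` and ``aqif`` the adaptation current obeys
``tau_w dw/dt = -w + a (V - E_L)``.  Synaptic conductances decay
exponentially (``tau dg/dt = -g``) and jump by the synaptic weight on
spike arrival.  A spike is detected when V crosses ``V_peak``; V is then
reset to ``V_reset`` and w is incremented by ``b``.

This module provides a scalar (single-neuron) implementation used for
parameter validation, unit tests and as an independent reference for the
vectorised network engine in :mod:`bgbeta.network`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "NeuronParams",
    "NeuronState",
    "derivative",
    "rk4_step",
    "apply_input_spike",
    "ConfigurationError",
    "NumericalDivergenceError",
    "V_FLOOR",
    "EXP_ARG_CAP",
]

#: Hard floor on the membrane potential (mV).  The quadratic/exponential
#: spike mechanisms diverge upward by construction (handled by the V_peak
#: reset); the floor guards against the symmetric downward blow-up of the
#: quadratic term far below rest.
V_FLOOR = -150.0

#: Cap on the argument of the exponential spike current.  Once V is far
#: past threshold the trajectory is certain to reach V_peak within the
#: step; capping only keeps intermediate Runge-Kutta stages finite.
EXP_ARG_CAP = 20.0

_VARIANTS = ("aeif", "aqif", "aqif2")


class ConfigurationError(ValueError):
    """A neuron parameter set is inconsistent with its model variant."""


class NumericalDivergenceError(RuntimeError):
    """The integrated state became non-finite."""


@dataclass(frozen=True)
class NeuronParams:
    """Full parameter record for one population and one model variant.

    Optional fields are variant-specific: ``Delta_T``/``g_L`` for aeif,
    ``k`` for aqif/aqif2 and additionally ``V_b`` for aqif2.
    """

    model_variant: str
    C_m: float          # membrane capacitance, pF
    E_L: float          # leak / quadratic pivot reversal, mV
    E_ex: float         # excitatory reversal, mV
    E_in: float         # inhibitory reversal, mV
    tau_ex: float       # excitatory conductance decay, ms
    tau_in: float       # inhibitory conductance decay, ms
    V_th: float         # threshold, mV
    I_e: float          # constant injected current, pA
    t_ref: float        # refractory period, ms
    V_reset: float      # post-spike reset, mV
    a: float            # subthreshold adaptation, nS (aqif2: nS/mV^2)
    b: float            # spike-triggered adaptation increment, pA
    tau_w: float        # adaptation time constant, ms
    V_peak: float       # spike detection voltage, mV
    Delta_T: Optional[float] = None  # spike slope factor, mV (aeif)
    g_L: Optional[float] = None      # leak conductance, nS (aeif)
    k: Optional[float] = None        # quadratic gain, nS/mV (aqif/aqif2)
    V_b: Optional[float] = None      # adaptation pivot, mV (aqif2)
    nu_ext: float = 0.0              # external Poisson rate, kHz
    dev_ext_weight: float = 0.0      # external-weight jitter half-width, nS

    def __post_init__(self) -> None:
        if self.model_variant not in _VARIANTS:
            raise ConfigurationError(
                f"unknown model variant {self.model_variant!r}"
            )
        for name in ("C_m", "tau_ex", "tau_in", "tau_w"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.V_reset >= self.V_peak:
            raise ConfigurationError("V_reset must lie below V_peak")
        if self.model_variant == "aeif":
            if self.Delta_T is None or self.g_L is None:
                raise ConfigurationError("aeif requires Delta_T and g_L")
            if self.V_th >= self.V_peak:
                raise ConfigurationError("aeif requires V_th < V_peak")
        else:
            if self.k is None:
                raise ConfigurationError(f"{self.model_variant} requires k")
            if self.model_variant == "aqif2" and self.V_b is None:
                raise ConfigurationError("aqif2 requires V_b")

    def with_(self, **kwargs) -> "NeuronParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Per-neuron dynamical variables."""

    V: float                 # membrane potential, mV
    w: float = 0.0           # adaptation current, pA
    g_ex: float = 0.0        # excitatory conductance, nS
    g_in: float = 0.0        # inhibitory conductance, nS
    refractory_until: float = -math.inf  # absolute time, ms
    spike_times: list = field(default_factory=list)


def derivative(
    V: float, w: float, g_ex: float, g_in: float, p: NeuronParams
) -> tuple[float, float, float, float]:
    """Time-derivatives of (V, w, g_ex, g_in) between spike events.

    The delta-function increments (synaptic jumps, spike-triggered b) are
    event handling, not part of the smooth flow, and are therefore absent
    here.
    """
    # The voltage entering the right-hand side is clamped at V_peak: a
    # Runge-Kutta stage past the spike-detection point must still drive
    # the endpoint across V_peak, but its (formally divergent) value may
    # not contaminate the adaptation current or overflow the exponential.
    V = min(V, p.V_peak)
    I_syn = -g_ex * (V - p.E_ex) - g_in * (V - p.E_in)
    if p.model_variant == "aeif":
        arg = min((V - p.V_th) / p.Delta_T, EXP_ARG_CAP)
        I_spk = -p.g_L * (V - p.E_L) + p.g_L * p.Delta_T * math.exp(arg)
    else:
        I_spk = p.k * (V - p.E_L) * (V - p.V_th)
    dV = (I_spk + I_syn - w + p.I_e) / p.C_m
    if p.model_variant == "aqif2":
        if V < p.V_b:
            dw = (-w + p.a * (V - p.V_b) ** 3) / p.tau_w
        else:
            dw = -w / p.tau_w
    else:
        dw = (-w + p.a * (V - p.E_L)) / p.tau_w
    return dV, dw, -g_ex / p.tau_ex, -g_in / p.tau_in


def rk4_step(
    state: NeuronState, p: NeuronParams, h: float, t: float = 0.0
) -> NeuronState:
    """Advance one neuron by one fixed step of classical 4th-order RK.

    A step whose endpoint reaches ``V_peak`` is accepted as-is: the spike
    is timestamped at the end of the step (``t + h``), V is reset and w is
    incremented by ``b`` before the next step.  During the refractory
    window V is clamped at ``V_reset`` while w and the conductances keep
    evolving.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    s = state
    in_ref = t < s.refractory_until

    def f(V, w, ge, gi):
        dV, dw, dge, dgi = derivative(V, w, ge, gi, p)
        return (0.0 if in_ref else dV), dw, dge, dgi

    k1 = f(s.V, s.w, s.g_ex, s.g_in)
    k2 = f(*(y + 0.5 * h * k for y, k in zip((s.V, s.w, s.g_ex, s.g_in), k1)))
    k3 = f(*(y + 0.5 * h * k for y, k in zip((s.V, s.w, s.g_ex, s.g_in), k2)))
    k4 = f(*(y + h * k for y, k in zip((s.V, s.w, s.g_ex, s.g_in), k3)))
    V, w, g_ex, g_in = (
        y + (h / 6.0) * (a + 2 * b_ + 2 * c + d)
        for y, a, b_, c, d in zip((s.V, s.w, s.g_ex, s.g_in), k1, k2, k3, k4)
    )

    out = NeuronState(
        V=V, w=w, g_ex=g_ex, g_in=g_in,
        refractory_until=s.refractory_until,
        spike_times=s.spike_times,
    )
    if not (math.isfinite(V) and math.isfinite(w)):
        raise NumericalDivergenceError(
            f"non-finite state at t={t + h:.3f} ms (V={V}, w={w})"
        )
    if out.V >= p.V_peak:
        out.spike_times.append(t + h)
        out.V = p.V_reset
        out.w = w + p.b
        out.refractory_until = t + h + p.t_ref
    elif out.V < V_FLOOR:
        out.V = V_FLOOR
    return out


def apply_input_spike(
    state: NeuronState, weight: float, sign: str
) -> NeuronState:
    """Instantaneous conductance jump on presynaptic spike arrival.

    ``sign`` is carried by the synapse type (connection table column), so
    the weight itself must be non-negative; excitatory and inhibitory
    inputs superpose linearly on their respective conductances.
    """
    if weight < 0:
        raise ValueError("synaptic weight must be non-negative")
    if sign in ("E", "excitatory"):
        state.g_ex += weight
    elif sign in ("I", "inhibitory"):
        state.g_in += weight
    else:
        raise ValueError(f"unknown synapse sign {sign!r}")
    return state
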