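"""Voltage-dependent gating kinetics for the nine channel gates.

All rate constants live in this one module so alternative channel variants
can be swapped in a single place. Two kinetic families are used:

* ``m, h`` (Na+), ``n`` (delayed-rectifier K+), ``p`` (muscarinic K+) and
  ``q, r`` (high-threshold Ca2+) follow the classical minimal-model cortical
  kinetics with a global spike-threshold shift ``VT``;
* ``mt, ht`` (transient Na+) and ``v`` (Kv3.1) follow the standard
  somatic transient-Na and Kv3.1 channel kinetics used in detailed cortical
  models.

Scalings applied on top of the raw rates:

* every gate's rates are multiplied by the temperature factor
  ``qt = Q10 ** ((T - T_ref) / 10)``;
* the ``m, h, n`` gates are additionally multiplied by the
  rate-to-steady-state scale ``rss`` (steady states are unchanged, time
  constants divide by ``rss``);
* the muscarinic gate ``p`` has its voltage-dependent time constant
  proportional to ``tau_max``.

Units: V in mV, rates in 1/ms, time constants in ms.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GATE_NAMES", "T_REF", "gate_rates", "steady_state_and_tau"]

GATE_NAMES = ("m", "h", "n", "p", "q", "r", "mt", "ht", "v")

#: Reference temperature (deg C) at which the raw rate constants are defined.
T_REF = 36.0


def _efun(z):
    """z / (exp(z) - 1), continuous at z = 0."""
    z = np.asarray(z, dtype=float)
    small = np.abs(z) < 1e-9
    zs = np.where(small, 1.0, z)
    return np.where(small, 1.0 - z / 2.0, zs / np.expm1(zs))


def gate_rates(V, VT=-60.0, tau_max=1000.0):
    """Raw opening/closing kinetics for all nine gates at voltage ``V``.

    Returns a dict mapping gate name to ``(alpha, beta)`` in 1/ms for gates
    defined through rate constants, or ``(x_inf, tau_x)`` for the gates
    (``p``, ``v``) defined through steady state and time constant. No
    temperature or ``rss`` scaling is applied here.
    """
    V = np.asarray(V, dtype=float)
    u = V - VT

    out = {}
    # Na+ activation / inactivation (minimal model, VT-shifted)
    out["m"] = (
        1.28 * _efun((13.0 - u) / 4.0),
        1.4 * _efun((u - 40.0) / 5.0),
    )
    out["h"] = (
        0.128 * np.exp(-(u - 17.0) / 18.0),
        4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0)),
    )
    # delayed-rectifier K+ activation
    out["n"] = (
        0.16 * _efun((15.0 - u) / 5.0),
        0.5 * np.exp(-(u - 10.0) / 40.0),
    )
    # muscarinic K+ gate: (p_inf, tau_p)
    out["p"] = (
        1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0)),
        tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0)),
    )
    # high-threshold Ca2+ activation / inactivation
    out["q"] = (
        0.209 * _efun((-27.0 - V) / 3.8),
        0.94 * np.exp((-75.0 - V) / 17.0),
    )
    out["r"] = (
        0.000457 * np.exp((-13.0 - V) / 50.0),
        0.0065 / (np.exp((-15.0 - V) / 28.0) + 1.0),
    )
    # transient Na+ (6 mV slope, half points -38 / -66 mV)
    out["mt"] = (
        1.092 * _efun(-(V + 38.0) / 6.0),
        0.744 * _efun((V + 38.0) / 6.0),
    )
    out["ht"] = (
        0.09 * _efun((V + 66.0) / 6.0),
        0.09 * _efun(-(V + 66.0) / 6.0),
    )
    # Kv3.1: (v_inf, tau_v)
    out["v"] = (
        1.0 / (1.0 + np.exp(-(V - 18.7) / 9.7)),
        4.0 / (1.0 + np.exp(-(V + 46.56) / 44.14)),
    )
    return out


def steady_state_and_tau(V, VT=-60.0, tau_max=1000.0, rss=1.0, qt=1.0):
    """Steady state and effective time constant of every gate at ``V``.

    Applies the qt temperature scaling to all gates and the ``rss`` scaling
    to the ``m``, ``h`` and ``n`` gates. Both scalings divide the time
    constant and leave the steady state untouched.
    """
    raw = gate_rates(V, VT=VT, tau_max=tau_max)
    out = {}
    for g in GATE_NAMES:
        a, b = raw[g]
        if g in ("p", "v"):
            x_inf, tau = a, b
        else:
            tot = a + b
            x_inf = a / tot
            tau = 1.0 / tot
        scale = qt * rss if g in ("m", "h", "n") else qt
        out[g] = (x_inf, tau / scale)
    return out
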