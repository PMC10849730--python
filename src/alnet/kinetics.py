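"""Voltage-dependent gating kinetics for the antennal-lobe neuron models.

The membrane equations use Hodgkin-Huxley currents I = g * m^M * h^N * (V - E)
whose steady states ``x_inf(V)`` and relaxation times ``tau_x(V)`` follow the
kinetics lineage of prior insect antennal-lobe models: Traub-Miles rate
functions for the fast Na+ and delayed-rectifier K+ currents (with a -50 mV
threshold shift), Huguenard-McCormick kinetics for the transient K+ A-current
and the low-threshold Ca2+ T-current, and McCormick-Pape kinetics for the
hyperpolarization-activated cation current Ih.

Every function is numba-compiled and scalar; the simulation engine calls them
inside its inner loop, and the Python-level API calls them directly (compiled
functions remain plain callables).
"""

import math

from numba import njit

# Traub-Miles voltage threshold shift (mV): positions the Na/K spike threshold
# near -50 mV, appropriate for the resting range set by EL=-70 / EKL=-95.
VSHIFT = -50.0


@njit(cache=True, fastmath=True)
def _vtrap(x, y):
    """x / (exp(x / y) - 1) with the removable singularity at x = 0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (math.exp(x / y) - 1.0)


# ---------------------------------------------------------------------------
# Fast Na+ (activation m, inactivation h), Traub-Miles


@njit(cache=True, fastmath=True)
def na_m(v):
    u = v - VSHIFT
    a = 0.32 * _vtrap(13.0 - u, 4.0)
    b = 0.28 * _vtrap(u - 40.0, 5.0)
    return a / (a + b), 1.0 / (a + b)


@njit(cache=True, fastmath=True)
def na_h(v):
    u = v - VSHIFT
    a = 0.128 * math.exp((17.0 - u) / 18.0)
    b = 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
    return a / (a + b), 1.0 / (a + b)


# ---------------------------------------------------------------------------
# Delayed-rectifier K+ (activation n), Traub-Miles


@njit(cache=True, fastmath=True)
def k_m(v):
    u = v - VSHIFT
    a = 0.032 * _vtrap(15.0 - u, 5.0)
    b = 0.5 * math.exp((10.0 - u) / 40.0)
    return a / (a + b), 1.0 / (a + b)


# ---------------------------------------------------------------------------
# Transient K+ A-current, Huguenard-McCormick


@njit(cache=True, fastmath=True)
def a_m(v):
    inf = 1.0 / (1.0 + math.exp(-(v + 60.0) / 8.5))
    tau = 0.37 + 1.0 / (math.exp((v + 35.8) / 19.7) + math.exp(-(v + 79.7) / 12.7))
    return inf, tau


@njit(cache=True, fastmath=True)
def a_h(v):
    inf = 1.0 / (1.0 + math.exp((v + 78.0) / 6.0))
    if v < -63.0:
        tau = 1.0 / (math.exp((v + 46.0) / 5.0) + math.exp(-(v + 238.0) / 37.5))
    else:
        tau = 19.0
    return inf, tau


# ---------------------------------------------------------------------------
# Low-threshold Ca2+ T-current, Huguenard-McCormick


@njit(cache=True, fastmath=True)
def t_m(v):
    inf = 1.0 / (1.0 + math.exp(-(v + 59.0) / 6.2))
    tau = 0.612 + 1.0 / (math.exp(-(v + 131.6) / 16.7) + math.exp((v + 16.8) / 18.2))
    return inf, tau


@njit(cache=True, fastmath=True)
def t_h(v):
    inf = 1.0 / (1.0 + math.exp((v + 83.0) / 4.0))
    if v < -81.0:
        tau = math.exp((v + 467.0) / 66.6)
    else:
        tau = 28.0 + math.exp(-(v + 22.0) / 10.5)
    return inf, tau


# ---------------------------------------------------------------------------
# Hyperpolarization-activated cation current Ih, McCormick-Pape


@njit(cache=True, fastmath=True)
def h_m(v):
    inf = 1.0 / (1.0 + math.exp((v + 75.0) / 5.5))
    tau = 1.0 / (math.exp(-14.59 - 0.086 * v) + math.exp(-1.87 + 0.0701 * v))
    return inf, tau


#: (activation, inactivation) rate functions per channel name; inactivation is
#: None for channels whose current has no h gate (N = 0).
RATE_FUNCTIONS = {
    "Na": (na_m, na_h),
    "K": (k_m, None),
    "A": (a_m, a_h),
    "T": (t_m, t_h),
    "h": (h_m, None),
}
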