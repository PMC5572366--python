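"""Hyperbolic-type memristor emulator.

The emulator is a voltage-controlled, non-ideal memristor whose memductance
is modulated through a hyperbolic tangent of an inner state variable::

    i = W(v0) * v,      W(v0) = a - b*tanh(v0)
    tau * dv0/dt = -(v0 + v)

`a` sets the memductance offset and `b` the modulation depth, so the
memductance is confined to the open interval (a - b, a + b).  In the
circuit realization the port equation reads
``i = (1/Ra - (g/Rb)*tanh(v0)) * v`` with inner-state time constant
``tau = R*C``; the dimensionless parameters follow from ``a = R/Ra`` and
``b = g*R/Rb``.

Driving the port with a sinusoid ``v = Vm*sin(2*pi*f*t)`` produces the
pinched hysteresis loop that is the defining memristor fingerprint: the
v-i orbit always passes through the origin and its lobe area shrinks as
the drive frequency grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "MemristorParams",
    "CircuitValues",
    "DriveSignal",
    "LoopRecord",
    "memductance",
    "to_dimensionless",
    "circuit_values_for",
    "simulate_loop",
    "lobe_area",
]


@dataclass(frozen=True)
class MemristorParams:
    """Dimensionless memductance parameters.

    Parameters
    ----------
    a : float
        Memductance offset (> 0).
    b : float
        Modulation depth (>= 0).
    tau : float
        Inner-state time constant; seconds for the circuit form, 1 for
        the dimensionless form.
    """

    a: float
    b: float
    tau: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"memductance offset a must be > 0, got {self.a}")
        if self.b < 0:
            raise ValueError(f"modulation depth b must be >= 0, got {self.b}")
        if not self.tau > 0:
            raise ValueError(f"time constant tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class CircuitValues:
    """Component values of the emulator realization circuit.

    Defaults are the reference design: R = 10 kOhm, C = 100 nF,
    Ra = 10 kOhm, Rb = 2 kOhm, multiplier gain g = 0.1, which scale to
    a = 1, b = 0.5, tau = 1 ms.
    """

    R: float = 10e3
    C: float = 100e-9
    Ra: float = 10e3
    Rb: float = 2e3
    g: float = 0.1

    def __post_init__(self) -> None:
        for name in ("R", "C", "Ra", "Rb"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.g < 0:
            raise ValueError("multiplier gain g must be >= 0")


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal voltage drive v(t) = Vm*sin(2*pi*f*t + phase)."""

    Vm: float
    f: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.Vm < 0:
            raise ValueError("amplitude Vm must be >= 0")
        if not self.f > 0:
            raise ValueError("frequency f must be > 0")

    def __call__(self, t):
        return self.Vm * np.sin(2.0 * np.pi * self.f * t + self.phase)


@dataclass
class LoopRecord:
    """Sampled response of the driven emulator.

    ``steady_slice`` indexes the final full drive cycle, taken after the
    automatic transient discard, and is the window used for fingerprint
    measurements (lobe areas, pinch checks).
    """

    t: np.ndarray
    v: np.ndarray
    i: np.ndarray
    v0: np.ndarray
    params: "MemristorParams | CircuitValues"
    drive: DriveSignal
    steady_slice: slice = field(default_factory=lambda: slice(None))

    @property
    def steady_cycle(self) -> "LoopRecord":
        s = self.steady_slice
        return LoopRecord(self.t[s], self.v[s], self.i[s], self.v0[s],
                          self.params, self.drive, slice(None))


def memductance(v0, p: MemristorParams):
    """Memductance W(v0) = a - b*tanh(v0); bounded in (a - b, a + b)."""
    return p.a - p.b * np.tanh(v0)


def to_dimensionless(cv: CircuitValues) -> MemristorParams:
    """Scale circuit component values to dimensionless (a, b) with tau = R*C.

    a = R/Ra, b = g*R/Rb.  For the reference design this gives a = 1,
    b = 0.5.
    """
    return MemristorParams(a=cv.R / cv.Ra, b=cv.g * cv.R / cv.Rb, tau=cv.R * cv.C)


def circuit_values_for(k: float, a: float, b: float, R: float = 10e3,
                       g: float = 0.1) -> tuple[float, float]:
    """Resistances realizing target (k*a, k*b): Ra = R/(k*a), Rb = g*R/(k*b).

    Used when the emulator provides the synaptic weight k*W inside the
    network circuit, so the effective dimensionless parameters are k*a
    and k*b.
    """
    for name, val in (("k", k), ("a", a), ("R", R), ("g", g)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0")
    if not b > 0:
        raise ValueError("b must be > 0 (Rb is undefined at b = 0)")
    return R / (k * a), g * R / (k * b)


def _loop_arrays(p: MemristorParams, drive: DriveSignal, n_cycles: int,
                 samples_per_cycle: int, rtol: float, atol: float):
    """Integrate tau*v0' = -(v0 + v) under the drive and sample uniformly.

    A transient of ceil(5*tau*f) + 1 full cycles is prepended and recorded,
    so the requested ``n_cycles`` are all post-transient; the final full
    cycle is the steady-state window.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2 so a steady-state cycle exists")
    if samples_per_cycle < 16:
        raise ValueError("samples_per_cycle must be >= 16 to avoid aliasing")

    period = 1.0 / drive.f
    n_transient = int(np.ceil(5.0 * p.tau * drive.f)) + 1
    total = n_transient + n_cycles
    t = np.linspace(0.0, total * period, total * samples_per_cycle + 1)

    def rhs(tt, y):
        return [-(y[0] + drive(tt)) / p.tau]

    sol = solve_ivp(rhs, (t[0], t[-1]), [0.0], t_eval=t, method="RK45",
                    rtol=rtol, atol=atol, dense_output=False,
                    max_step=period / 8.0)
    v0 = sol.y[0]
    v = drive(t)
    steady = slice(len(t) - samples_per_cycle - 1, len(t))
    return t, v, v0, steady


def simulate_loop(params: "CircuitValues | MemristorParams", drive: DriveSignal,
                  n_cycles: int = 4, samples_per_cycle: int = 512,
                  rtol: float = 1e-9, atol: float = 1e-12) -> LoopRecord:
    """Simulate the driven emulator and record the sampled v-i orbit.

    Accepts either circuit component values (volts/seconds/amperes) or
    dimensionless parameters (tau defaults to 1).  The inner state starts
    at v0(0) = 0; an automatic transient of ceil(5*tau*f) + 1 cycles is
    simulated before the ``n_cycles`` recorded here, and the final full
    cycle is flagged as the steady-state window.
    """
    if isinstance(params, CircuitValues):
        p = to_dimensionless(params)
        t, v, v0, steady = _loop_arrays(p, drive, n_cycles, samples_per_cycle,
                                        rtol, atol)
        i = (1.0 / params.Ra - (params.g / params.Rb) * np.tanh(v0)) * v
    else:
        p = params
        t, v, v0, steady = _loop_arrays(p, drive, n_cycles, samples_per_cycle,
                                        rtol, atol)
        i = memductance(v0, p) * v
    return LoopRecord(t=t, v=v, i=i, v0=v0, params=params, drive=drive,
                      steady_slice=steady)


def lobe_area(loop: LoopRecord) -> tuple[float, float]:
    """Absolute enclosed area of the two lobes of the steady-state v-i orbit.

    The orbit is split at its v = 0 crossings (where the loop is pinched,
    i = 0 as well); each half-cycle segment is closed through the origin
    and measured with the shoelace formula.  Returns (positive-v lobe,
    negative-v lobe) areas in volt*ampere (dimensionless^2 for the
    dimensionless form).
    """
    cyc = loop.steady_cycle
    v, i = cyc.v, cyc.i
    sign_change = np.nonzero(np.diff(np.signbit(v)))[0]
    if len(sign_change) == 0:
        raise ValueError("steady-state cycle has no v = 0 crossing")

    # crossing times by linear interpolation; i interpolated accordingly
    segments: list[tuple[np.ndarray, np.ndarray]] = []
    bounds = []
    for idx in sign_change:
        frac = -v[idx] / (v[idx + 1] - v[idx])
        bounds.append((idx, frac))
    # build segments between consecutive crossings (plus the wrap-around)
    for (idx0, f0), (idx1, f1) in zip(bounds, bounds[1:]):
        vi0 = i[idx0] + f0 * (i[idx0 + 1] - i[idx0])
        vi1 = i[idx1] + f1 * (i[idx1 + 1] - i[idx1])
        vs = np.concatenate(([0.0], v[idx0 + 1:idx1 + 1], [0.0]))
        is_ = np.concatenate(([vi0], i[idx0 + 1:idx1 + 1], [vi1]))
        segments.append((vs, is_))
    # wrap: last crossing -> end joined with start -> first crossing
    (idxL, fL), (idxF, fF) = bounds[-1], bounds[0]
    viL = i[idxL] + fL * (i[idxL + 1] - i[idxL])
    viF = i[idxF] + fF * (i[idxF + 1] - i[idxF])
    vs = np.concatenate(([0.0], v[idxL + 1:], v[1:idxF + 1], [0.0]))
    is_ = np.concatenate(([viL], i[idxL + 1:], i[1:idxF + 1], [viF]))
    segments.append((vs, is_))

    pos_area = 0.0
    neg_area = 0.0
    for vs, is_ in segments:
        # shoelace on the closed polygon (segment endpoints are the origin)
        area = 0.5 * abs(np.sum(vs * np.roll(is_, -1) - np.roll(vs, -1) * is_))
        if np.mean(vs) >= 0:
            pos_area += area
        else:
            neg_area += area
    return pos_area, neg_area
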