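"""Izhikevich neuron dynamics integrated by forward Euler.

The membrane model is the two-variable quadratic integrate-and-fire
reduction of Izhikevich (2003),

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I / C
    du/dt = a (b v - u)

with the after-spike reset rule: when v >= v_peak, v <- c and u <- u + d.
Voltages are read in mV and time in ms.  The default parameter set
(a=0.02, b=0.25, c=-55, d=0.05) is the phasic-bursting regime: a step of
input current evokes a high-frequency burst, and release from sustained
hyperpolarization evokes a rebound burst.

All state update functions are vectorized: ``v``, ``u`` and ``I`` may be
scalars or arrays of any common shape, so an entire N x N layer (or a
stack of layers) advances in one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IzhikevichParams",
    "SimulationClock",
    "NumericalBlowupError",
    "izhikevich_step",
    "simulate_neuron",
]


class NumericalBlowupError(FloatingPointError):
    """Raised when the Euler update produces non-finite state."""

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(
            f"non-finite membrane state after Euler step {step_index}; "
            "reduce dt or the input current"
        )


@dataclass(frozen=True)
class IzhikevichParams:
    """Constants of the Izhikevich membrane model.

    Parameters
    ----------
    a : recovery time scale (1/ms).  Small values make u slow.
    b : recovery sensitivity to subthreshold voltage.
    c : after-spike voltage reset (mV).
    d : after-spike increment of the recovery variable.
    v_peak : spike cutoff (mV); crossing it registers a spike.
    capacitance : scale factor dividing the input current (kept at 1).
    v0, u0 : initial membrane state.  ``u0=None`` means ``b * v0``,
        the resting equilibrium of the recovery variable.
    """

    a: float = 0.02
    b: float = 0.25
    c: float = -55.0
    d: float = 0.05
    v_peak: float = 30.0
    capacitance: float = 1.0
    v0: float = -64.0
    u0: float | None = None

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if not self.v_peak > self.c:
            raise ValueError("v_peak must exceed the reset voltage c")
        if not self.capacitance > 0:
            raise ValueError("capacitance must be positive")

    @property
    def u_init(self) -> float:
        return self.b * self.v0 if self.u0 is None else self.u0


@dataclass(frozen=True)
class SimulationClock:
    """Euler time grid: ``n_steps`` steps of ``dt`` ms starting at ``t0``."""

    dt: float = 0.20
    n_steps: int = 1500
    t0: float = 0.0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps)

    def step_of(self, t_ms: float) -> int:
        """Index of the Euler step containing time ``t_ms`` (rounded down)."""
        return int(np.floor((t_ms - self.t0) / self.dt + 1e-9))


def izhikevich_step(v, u, I, params: IzhikevichParams, dt: float, *, step_index: int = 0):
    """Advance (v, u) by one forward-Euler step and apply the reset rule.

    Both derivatives are evaluated at the pre-update state (simultaneous
    Euler); the threshold test runs on the updated voltage, and the reset
    is applied before the state is returned, so spiking entries come back
    with ``v == c`` exactly.

    Returns ``(v_new, u_new, spiked)`` where ``spiked`` is a boolean array
    (or scalar) marking threshold crossings at this step.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + np.asarray(I, dtype=float) / params.capacitance
    du = params.a * (params.b * v - u)
    v_new = v + dt * dv
    u_new = u + dt * du
    spiked = v_new >= params.v_peak
    v_new = np.where(spiked, params.c, v_new)
    u_new = np.where(spiked, u_new + params.d, u_new)
    if not (np.all(np.isfinite(v_new)) and np.all(np.isfinite(u_new))):
        raise NumericalBlowupError(step_index)
    if v.ndim == 0:
        return float(v_new), float(u_new), bool(spiked)
    return v_new, u_new, spiked


def simulate_neuron(
    I_trace: np.ndarray,
    params: IzhikevichParams = IzhikevichParams(),
    clock: SimulationClock | None = None,
    *,
    dt: float | None = None,
    v0: float | None = None,
    u0: float | None = None,
) -> np.ndarray:
    """Integrate a single neuron over a pre-computed current trace.

    Parameters
    ----------
    I_trace : input current per Euler step (length defines n_steps unless
        a clock is given, in which case lengths must agree).
    clock : optional time grid; defaults to dt=0.2 ms over the trace.
    v0, u0 : optional overrides of the initial state in ``params``.

    Returns
    -------
    ndarray of spike step indices (multiply by dt for times in ms).
    """
    I_trace = np.asarray(I_trace, dtype=float)
    if clock is None:
        clock = SimulationClock(dt=dt if dt is not None else 0.20, n_steps=len(I_trace))
    if len(I_trace) != clock.n_steps:
        raise ValueError(
            f"I_trace has {len(I_trace)} entries but the clock covers {clock.n_steps} steps"
        )
    v = params.v0 if v0 is None else v0
    u = params.u_init if u0 is None else u0
    spikes = []
    for k in range(clock.n_steps):
        v, u, spiked = izhikevich_step(v, u, I_trace[k], params, clock.dt, step_index=k)
        if spiked:
            spikes.append(k)
    return np.asarray(spikes, dtype=int)
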