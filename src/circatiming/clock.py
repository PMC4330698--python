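"""Pacemaker-accumulator clock model with circadian and homeostatic rate modulation.

The internal-clock (pacemaker-accumulator) account of short-term interval
timing posits a pacemaker emitting pulses that are gated through an
attention-controlled switch into an accumulator and compared against
reference memory.  Two organismic processes modulate the pulse rate:

* a *sleep-homeostatic* drive that builds as a saturating exponential of
  time awake (time constant ``tau_h``, default 18.2 h), and
* a *circadian* oscillation with a near-24-h period.

Attentional lability at the switch leaks pulses, and the loss grows with
stimulus duration, so the behavioural imprint of a given rate change is
duration-specific.  This module is the deterministic core: rate as a
function of time, leakage gain as a function of stimulus duration, and the
mapping from effective rate to expected estimation/production responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PacemakerParams",
    "ClockState",
    "pacemaker_rate",
    "leakage_gain",
    "effective_rate",
    "expected_responses",
    "clock_state",
]


class ParameterError(ValueError):
    """Invalid pacemaker parameters or inputs."""


@dataclass(frozen=True)
class PacemakerParams:
    """Generative parameters of the modulated pacemaker.

    Parameters
    ----------
    r_ref : float
        Reference pulse rate (pulses/s) at which pulse-duration associations
        in reference memory were formed.  Timing is veridical when the
        effective rate equals ``r_ref``.
    h_amp : float
        Dimensionless amplitude of the homeostatic modulation: the rate
        approaches ``r_ref * (1 + h_amp)`` after long sustained wakefulness.
    tau_h : float
        Homeostatic time constant in hours (default 18.2).
    c_amp : float
        Dimensionless amplitude of the circadian modulation.
    c_phase : float
        Circadian acrophase in hours relative to DLMO: the time at which the
        circadian term peaks.
    period : float
        Circadian period in hours (default 24).
    leak_kappa : float
        Leakage growth rate per second of stimulus duration (1/s); the
        switch passes a fraction ``exp(-leak_kappa * d)`` of the rate
        *deviation* for a stimulus of duration ``d``.
    t_wake_offset : float
        Time (hours from DLMO) at which homeostatic buildup starts; for
        earlier times the homeostatic term is clamped at its onset value.
    """

    r_ref: float = 1.0
    h_amp: float = 0.0
    tau_h: float = 18.2
    c_amp: float = 0.0
    c_phase: float = 0.0
    period: float = 24.0
    leak_kappa: float = 0.0
    t_wake_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r_ref > 0 and math.isfinite(self.r_ref)):
            raise ParameterError(f"r_ref must be positive and finite, got {self.r_ref}")
        if not (self.tau_h > 0):
            raise ParameterError(f"tau_h must be positive, got {self.tau_h}")
        if not (self.period > 0):
            raise ParameterError(f"period must be positive, got {self.period}")
        if self.h_amp < 0 or self.c_amp < 0:
            raise ParameterError("h_amp and c_amp must be non-negative")
        if self.h_amp + self.c_amp >= 1.0:
            raise ParameterError(
                "h_amp + c_amp must be < 1 so the rate stays positive "
                f"(got {self.h_amp} + {self.c_amp})"
            )
        if self.leak_kappa < 0:
            raise ParameterError(f"leak_kappa must be >= 0, got {self.leak_kappa}")


@dataclass(frozen=True)
class ClockState:
    """Instantaneous clock state at a time point.

    ``eff_rate_by_duration`` maps stimulus duration (s) to the effective
    pacemaker rate after attentional leakage — the rate at which pulses
    actually reach the accumulator.
    """

    t: float
    rate: float
    eff_rate_by_duration: dict[float, float]


def _homeostatic_term(t, p: PacemakerParams):
    t_pos = np.maximum(np.asarray(t, dtype=float) - p.t_wake_offset, 0.0)
    return 1.0 - np.exp(-t_pos / p.tau_h)


def pacemaker_rate(t, p: PacemakerParams):
    """Instantaneous pacemaker rate (pulses/s) at time ``t`` hours from DLMO.

    rate = r_ref * [1 + h_amp * (1 - exp(-t+/tau_h))
                      + c_amp * cos(2*pi/period * (t - c_phase))]

    where ``t+`` clamps time before homeostatic onset to zero.  Vectorised
    over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ParameterError("t must be finite")
    circ = p.c_amp * np.cos(2.0 * np.pi / p.period * (t - p.c_phase))
    rate = p.r_ref * (1.0 + p.h_amp * _homeostatic_term(t, p) + circ)
    return rate if rate.ndim else float(rate)


def leakage_gain(d, p: PacemakerParams):
    """Fraction of the rate deviation surviving attentional leakage.

    gain = exp(-leak_kappa * d), strictly decreasing in the stimulus
    duration ``d`` (seconds) when ``leak_kappa > 0``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ParameterError("stimulus duration must be positive")
    g = np.exp(-p.leak_kappa * d)
    return g if g.ndim else float(g)


def effective_rate(t, d, p: PacemakerParams):
    """Effective rate at the accumulator for a stimulus of duration ``d``.

    Leakage attenuates the *deviation* of the instantaneous rate from the
    reference rate, so unmodulated timing is veridical at every duration:

    R_eff = r_ref + gain(d) * (rate(t) - r_ref)
    """
    rate = pacemaker_rate(t, p)
    gain = leakage_gain(d, p)
    return p.r_ref + gain * (np.asarray(rate) - p.r_ref) if np.ndim(rate) or np.ndim(gain) \
        else p.r_ref + gain * (rate - p.r_ref)


def expected_responses(t, d, p: PacemakerParams):
    """Expected (estimation, production) responses in seconds.

    A faster effective rate accumulates more pulses during a fixed stimulus,
    inflating estimates; producing a fixed pulse count takes less time, so
    production shrinks reciprocally:

        estimate   = d * R_eff / r_ref
        production = d * r_ref / R_eff

    hence estimate * production = d**2 exactly for every state.
    """
    r_eff = effective_rate(t, d, p)
    if np.any(np.asarray(r_eff) <= 0):
        raise ParameterError("effective rate is non-positive; model degenerate")
    d = np.asarray(d, dtype=float)
    est = d * r_eff / p.r_ref
    prod = d * p.r_ref / r_eff
    if np.ndim(est):
        return est, prod
    return float(est), float(prod)


def clock_state(t: float, p: PacemakerParams, durations=(10.0, 40.0)) -> ClockState:
    """Snapshot of the clock at time ``t`` for a set of stimulus durations."""
    rate = pacemaker_rate(t, p)
    eff = {float(d): float(effective_rate(t, d, p)) for d in durations}
    return ClockState(t=float(t), rate=float(rate), eff_rate_by_duration=eff)
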