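"""Closed-form quantities of the sine-wave vertical ground reaction force model.

During running stance, the vertical ground reaction force is approximated by
``Fz(t) = Fz_max * sin(pi * t / t_c)``, with the peak ``Fz_max`` fixed by
impulse balance over a step: the average vertical force over one contact plus
one flight phase must equal body weight, giving
``Fz_max = m * g * pi * (t_f / t_c + 1) / 2``.

Sensors that threshold force at body weight observe only *effective* timings:
the effective contact time ``t_ce`` (force >= body weight) and effective
flight time ``t_fe`` (force < body weight).  Under the symmetric sine model
the gap between a true and an effective event is the same on both sides of
stance, a single unknown ``t_g`` (time from foot-strike until the force first
reaches body weight), so

    t_c = t_ce + 2 * t_g        t_f = t_fe - 2 * t_g

``t_g`` itself is the root of a transcendental equation (:func:`eq1_residual`)
obtained from ``Fz(t_g) = m * g``; it has no closed form and is solved
numerically in :mod:`stridetime.solver`.

All quantities here are in SI units (seconds, kilograms, newtons).
Millisecond conversion happens only at the I/O layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimingPair",
    "StrideTimings",
    "BodyParams",
    "InfeasibleReconstructionError",
    "peak_force",
    "vertical_force",
    "eq1_residual",
    "boundary_ratio_analytic",
    "reconstruct_from_tg",
    "under_bw_fraction",
    "duty_factor",
]


class InfeasibleReconstructionError(ValueError):
    """Raised when a requested t_g would imply a negative flight time."""


@dataclass(frozen=True)
class TimingPair:
    """One step's effective contact and flight times, in seconds."""

    t_ce: float
    t_fe: float

    def __post_init__(self) -> None:
        if not (self.t_ce > 0):
            raise ValueError(f"t_ce must be positive, got {self.t_ce!r}")
        if not (self.t_fe > 0):
            raise ValueError(f"t_fe must be positive, got {self.t_fe!r}")


@dataclass(frozen=True)
class BodyParams:
    """Body mass (kg) and gravitational acceleration (m/s^2)."""

    mass: float
    g_accel: float = 9.81

    def __post_init__(self) -> None:
        if not (self.mass > 0):
            raise ValueError(f"mass must be positive, got {self.mass!r}")
        if not (self.g_accel > 0):
            raise ValueError(f"g_accel must be positive, got {self.g_accel!r}")

    @property
    def weight(self) -> float:
        """Body weight m*g in newtons."""
        return self.mass * self.g_accel


@dataclass(frozen=True)
class StrideTimings:
    """Full timing set for one step, in seconds.

    Satisfies ``t_c = t_ce + 2 t_g``, ``t_f = t_fe - 2 t_g`` and the
    step-duration conservation ``t_c + t_f = t_ce + t_fe``.
    """

    t_c: float
    t_f: float
    t_ce: float
    t_fe: float
    t_g: float

    def __post_init__(self) -> None:
        if self.t_g < 0:
            raise ValueError(f"t_g must be non-negative, got {self.t_g!r}")
        if self.t_f < 0:
            raise ValueError(f"t_f must be non-negative, got {self.t_f!r}")
        # identities are enforced up to rounding of the constructor arguments
        if not math.isclose(self.t_c, self.t_ce + 2 * self.t_g, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("t_c != t_ce + 2*t_g")
        if not math.isclose(
            self.t_c + self.t_f, self.t_ce + self.t_fe, rel_tol=1e-9, abs_tol=1e-12
        ):
            raise ValueError("step duration not conserved: t_c + t_f != t_ce + t_fe")


def peak_force(body: BodyParams, t_c: float, t_f: float) -> float:
    """Peak vertical force ``Fz_max = m g pi (t_f/t_c + 1) / 2`` in newtons.

    Impulse balance over one step: the sine-shaped stance impulse must carry
    body weight through both contact and flight.  Depends on (t_c, t_f) only
    through their ratio, and is never below ``m g pi / 2`` (the t_f = 0
    limit).
    """
    if not (t_c > 0):
        raise ValueError(f"t_c must be positive, got {t_c!r}")
    if t_f < 0:
        raise ValueError(f"t_f must be non-negative, got {t_f!r}")
    return body.weight * math.pi * (t_f / t_c + 1.0) / 2.0


def vertical_force(t, t_c: float, f_max: float):
    """Sine-model stance force ``Fz(t) = f_max sin(pi t / t_c)`` for t in [0, t_c].

    Accepts a scalar or array ``t``; raises if any value lies outside stance.
    """
    if not (t_c > 0):
        raise ValueError(f"t_c must be positive, got {t_c!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > t_c):
        raise ValueError("t outside the stance interval [0, t_c]")
    out = f_max * np.sin(np.pi * t_arr / t_c)
    return float(out) if np.isscalar(t) else out


def eq1_residual(t_g, pair: TimingPair):
    """Residual whose root in ``t_g`` is the body-weight-crossing time.

    Substituting ``t_c = t_ce + 2 t_g`` and ``t_f = t_fe - 2 t_g`` into
    ``Fz(t_g) = m g`` and dividing by body weight gives

        csc(pi t_g / (t_ce + 2 t_g)) - (pi/2) ((t_fe - 2 t_g)/(t_ce + 2 t_g) + 1)

    The residual diverges to +inf as t_g -> 0+ and depends only on ratios of
    times, so it is invariant under a common rescaling of (t_g, t_ce, t_fe).
    Accepts scalar or array ``t_g``.
    """
    tg = np.asarray(t_g, dtype=float)
    if np.any(tg <= 0):
        raise ValueError("t_g must be positive (residual diverges at 0)")
    t_c = pair.t_ce + 2.0 * tg
    angle = np.pi * tg / t_c
    out = 1.0 / np.sin(angle) - (np.pi / 2.0) * ((pair.t_fe - 2.0 * tg) / t_c + 1.0)
    return float(out) if np.isscalar(t_g) else out


def boundary_ratio_analytic() -> float:
    """Smallest ratio t_fe/t_ce for which the model admits a solution.

    At the existence limit the flight time vanishes (t_f = 0, so
    t_g = t_fe / 2) and the crossing condition reduces to
    ``sin(pi t_fe / (2 (t_ce + t_fe))) = 2 / pi``.  Solving for the ratio
    gives ``2 theta / (pi - 2 theta)`` with ``theta = arcsin(2/pi)``,
    approximately 0.7836.  Below ``t_fe = ratio * t_ce`` no root with
    non-negative flight time exists.
    """
    theta = math.asin(2.0 / math.pi)
    return 2.0 * theta / (math.pi - 2.0 * theta)


def reconstruct_from_tg(pair: TimingPair, t_g: float) -> StrideTimings:
    """Rebuild the full timing set from effective timings and a known t_g.

    ``t_f`` is computed as ``(t_ce + t_fe) - t_c`` so that step-duration
    conservation holds bit-exactly in floating point.
    """
    if t_g < 0:
        raise ValueError(f"t_g must be non-negative, got {t_g!r}")
    if pair.t_fe - 2.0 * t_g < 0:
        raise InfeasibleReconstructionError(
            f"t_g = {t_g!r} implies negative flight time for t_fe = {pair.t_fe!r}"
        )
    t_c = pair.t_ce + 2.0 * t_g
    t_f = (pair.t_ce + pair.t_fe) - t_c
    return StrideTimings(t_c=t_c, t_f=t_f, t_ce=pair.t_ce, t_fe=pair.t_fe, t_g=t_g)


def under_bw_fraction(t_ce: float, t_g: float) -> float:
    """Percentage of contact time spent below body weight: 100 * 2 t_g / (t_ce + 2 t_g)."""
    if not (t_ce > 0):
        raise ValueError(f"t_ce must be positive, got {t_ce!r}")
    if t_g < 0:
        raise ValueError(f"t_g must be non-negative, got {t_g!r}")
    return 100.0 * 2.0 * t_g / (t_ce + 2.0 * t_g)


def duty_factor(t_c: float, t_f: float) -> float:
    """Fraction of the stride spent in contact: t_c / (2 (t_c + t_f)).

    A stride is taken as two symmetric steps (left and right), so the stride
    duration is ``2 (t_c + t_f)``.  Under this convention the duty factor is
    below 0.5 for any positive flight time, the defining property of running,
    and exactly 0.5 at the walking limit t_f = 0.
    """
    if not (t_c > 0):
        raise ValueError(f"t_c must be positive, got {t_c!r}")
    if t_f < 0:
        raise ValueError(f"t_f must be non-negative, got {t_f!r}")
    return t_c / (2.0 * (t_c + t_f))
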