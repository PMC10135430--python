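"""Closed-form relations of the transcriptional pause kinetic scheme.

An elongating RNA polymerase at a pause-prone template position partitions
kinetically between on-pathway nucleotide addition (rate ``kn``) and entry
into an off-pathway paused state (rate ``kp``).  The pause efficiency is the
branching ratio

    E = kp / (kp + kn)

A paused polymerase escapes with intrinsic rate ``k_escape`` (often written
k-p) back to the elongation-competent state, where it again faces the same
branching.  Because it may re-enter the pause, the *apparent* pause duration
observed in an ensemble decay is longer than the intrinsic one:

    T_app = T_intrinsic / (1 - E)       with T_intrinsic = 1 / k_escape

equivalently the apparent escape rate is k_escape * (1 - E).

Optionally a paused ("slow") polymerase may convert to a second, longer-lived
("sluggish") paused state before escaping; this produces biphasic ensemble
decays.  All rates are in s^-1 and times in seconds; unit conversion for
minute-scale gel data happens at the IO boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "KineticScheme",
    "PauseEstimate",
    "pause_efficiency",
    "apparent_pause_duration",
    "apparent_escape_rate",
    "rescue_fraction",
    "predicted_duration_fold_change",
]


@dataclass(frozen=True)
class KineticScheme:
    """On/off-pathway rate constants of the pause competition model.

    Parameters
    ----------
    kn
        On-pathway single-nucleotide addition rate (s^-1).
    kp
        Pause-entry rate at a pause-prone position (s^-1).
    k_escape
        Intrinsic escape rate from the (slow) paused state (s^-1).
    k_slow_to_sluggish
        Optional conversion rate from the slow to the sluggish paused
        state (s^-1).  The sluggish branch is sequential: a slow pause may
        deepen into a sluggish one before escape.
    k_sluggish_escape
        Escape rate from the sluggish state (s^-1); required positive when
        ``k_slow_to_sluggish > 0``.
    p_terminate
        Termination probability at the terminator position, in [0, 1].
    """

    kn: float
    kp: float = 0.0
    k_escape: float = 0.0
    k_slow_to_sluggish: float = 0.0
    k_sluggish_escape: float = 0.0
    p_terminate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kn", "kp", "k_escape", "k_slow_to_sluggish",
                     "k_sluggish_escape"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.p_terminate <= 1.0:
            raise ValueError(f"p_terminate must be in [0, 1], got {self.p_terminate}")
        if self.k_slow_to_sluggish > 0 and self.k_sluggish_escape <= 0:
            raise ValueError(
                "k_sluggish_escape must be > 0 when k_slow_to_sluggish > 0")

    @property
    def efficiency(self) -> float:
        """Pause efficiency E = kp / (kp + kn)."""
        return pause_efficiency(self.kp, self.kn)

    @property
    def intrinsic_duration(self) -> float:
        """Intrinsic pause duration 1 / k_escape (s)."""
        if self.k_escape <= 0:
            raise ValueError("k_escape must be > 0 for a pause duration")
        return 1.0 / self.k_escape

    @property
    def apparent_duration(self) -> float:
        """Apparent pause duration including re-entry, (kp+kn)/(kn*k_escape)."""
        return apparent_pause_duration(self.intrinsic_duration, self.efficiency)


@dataclass
class PauseEstimate:
    """A fitted pause description: efficiency, durations, escape rate.

    ``duration_apparent`` and ``escape_rate_apparent`` are reciprocal;
    ``half_life`` is ln(2) * duration_apparent for a single-exponential
    decay.  ``ci`` optionally maps field names to (lower, upper) bounds.
    """

    efficiency: float
    duration_apparent: float
    escape_rate_apparent: float
    half_life: float
    efficiency_raw: float | None = None
    ci: dict = field(default_factory=dict)
    capped: bool = False

    def __post_init__(self) -> None:
        if self.duration_apparent > 0 and self.escape_rate_apparent > 0:
            prod = self.duration_apparent * self.escape_rate_apparent
            if not math.isclose(prod, 1.0, rel_tol=1e-6):
                raise ValueError(
                    "duration_apparent must equal 1/escape_rate_apparent")


def pause_efficiency(kp: float, kn: float) -> float:
    """Branching-ratio pause efficiency E = kp / (kp + kn).

    ``kp`` is the pause-entry rate and ``kn`` the competing on-pathway
    elongation rate, both >= 0 with at least one positive.
    """
    if kp < 0 or kn < 0:
        raise ValueError("rates must be non-negative")
    if kp + kn <= 0:
        raise ValueError("pause efficiency undefined when kp + kn == 0")
    return kp / (kp + kn)


def apparent_pause_duration(t_intrinsic: float, efficiency: float) -> float:
    """Apparent pause duration with pause re-entry, T / (1 - E).

    After each escape the polymerase re-enters the pause with probability
    ``efficiency``, so the expected total paused time per pausing event is
    the intrinsic duration divided by (1 - E).
    """
    if t_intrinsic <= 0:
        raise ValueError("t_intrinsic must be > 0")
    if not 0.0 <= efficiency < 1.0:
        raise ValueError("efficiency must be in [0, 1) for a finite duration")
    return t_intrinsic / (1.0 - efficiency)


def apparent_escape_rate(k_escape: float, efficiency: float) -> float:
    """Apparent escape rate k_escape * (1 - E), the inverse of T_app."""
    if k_escape <= 0:
        raise ValueError("k_escape must be > 0")
    if not 0.0 <= efficiency < 1.0:
        raise ValueError("efficiency must be in [0, 1)")
    return k_escape * (1.0 - efficiency)


def rescue_fraction(e_minus: float, e_plus: float) -> float:
    """Fraction of pausing events suppressed between two conditions.

    ``(E_minus - E_plus) / E_minus`` where ``e_minus`` is the efficiency
    without and ``e_plus`` with the perturbation (e.g. a coupled ribosome).
    Negative when pausing worsens.
    """
    if not (0.0 < e_minus <= 1.0):
        raise ValueError("e_minus must be in (0, 1]")
    if not 0.0 <= e_plus <= 1.0:
        raise ValueError("e_plus must be in [0, 1]")
    return (e_minus - e_plus) / e_minus


def predicted_duration_fold_change(e_minus: float, e_plus: float) -> float:
    """Predicted T_app(-)/T_app(+) ratio from the re-entry relation.

    With an unchanged intrinsic escape rate, T_app scales as 1/(1-E), so a
    drop in efficiency from ``e_minus`` to ``e_plus`` predicts a duration
    fold change of (1 - e_plus) / (1 - e_minus).
    """
    if not 0.0 <= e_minus < 1.0:
        raise ValueError("e_minus must be in [0, 1)")
    if not 0.0 <= e_plus < 1.0:
        raise ValueError("e_plus must be in [0, 1)")
    return (1.0 - e_plus) / (1.0 - e_minus)
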