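"""Chromatographic gradient model: retention time -> mobile-phase composition.

Retention times vary with instrument, column and method, but the mobile-phase
composition at which a compound elutes is comparable across setups running
the same gradient shape.  This module models a single linear ramp from
``a_start`` %A (aqueous) to ``a_end`` %A over ``ramp_minutes``, optionally
offset by a dead-volume delay ``t_delay``, and converts retention times into
percent-aqueous values that downstream modelling uses in place of raw RT.

The reference program used throughout (20 -> 80 %A over 13 min) has slope
(80 - 20) / 13 = 60/13 ~= 4.615 %A per minute.  The slope is stored as the
exact ratio of the endpoints; rounding to 4.615 happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GradientProgram", "annotate_gradient"]


@dataclass(frozen=True)
class GradientProgram:
    """A single linear-ramp mobile-phase program.

    Parameters
    ----------
    a_start : float
        Percent aqueous solvent (%A) at the start of the ramp.
    a_end : float
        %A at the end of the ramp.
    ramp_minutes : float
        Duration of the linear ramp, minutes. Must be positive.
    t_delay : float
        System dead-volume delay in minutes: the programmed gradient reaches
        the column this much later than programmed. Default 0.
    """

    a_start: float = 20.0
    a_end: float = 80.0
    ramp_minutes: float = 13.0
    t_delay: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_start <= 100.0 and 0.0 <= self.a_end <= 100.0):
            raise ValueError("a_start and a_end must lie in [0, 100]")
        if self.a_start == self.a_end:
            raise ValueError("a_start and a_end must differ (a flat program has no ramp)")
        if self.ramp_minutes <= 0:
            raise ValueError("ramp_minutes must be positive")
        if self.t_delay < 0:
            raise ValueError("t_delay must be non-negative")

    @property
    def slope(self) -> float:
        """Ramp slope in %A per minute, as the exact endpoint ratio."""
        return (self.a_end - self.a_start) / self.ramp_minutes

    @property
    def intercept_b(self) -> float:
        """%A at effective time zero (start of the ramp)."""
        return self.a_start

    @property
    def composition_range(self) -> tuple[float, float]:
        """(low, high) bounds of %A reachable under this program."""
        lo, hi = sorted((self.a_start, self.a_end))
        return lo, hi

    def composition_at(self, t):
        """Mobile-phase composition (pct_a, pct_b) at run time ``t`` minutes.

        On the ramp, ``pct_a = a_start + slope * (t - t_delay)``.  Before the
        ramp the composition holds at the start value; after the ramp it
        holds at the end value (the method runs isocratically post-ramp), so
        the function is total on t >= 0.  ``pct_a + pct_b == 100`` always.

        Accepts a scalar or an array; returns the matching shape.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("run time t must be non-negative")
        on_ramp = np.clip(t_arr, self.t_delay, self.t_delay + self.ramp_minutes)
        pct_a = self.a_start + self.slope * (on_ramp - self.t_delay)
        pct_b = 100.0 - pct_a
        if np.isscalar(t) or t_arr.ndim == 0:
            return float(pct_a), float(pct_b)
        return pct_a, pct_b

    def time_at_composition(self, pct_a):
        """Invert the ramp: the run time at which %A equals ``pct_a``.

        Only defined for compositions within the program's range; used by the
        synthetic generator to derive retention times consistent with the
        gradient annotation.
        """
        p = np.asarray(pct_a, dtype=float)
        lo, hi = self.composition_range
        if np.any(p < lo) or np.any(p > hi):
            raise ValueError(f"composition outside the program range [{lo}, {hi}]")
        t = self.t_delay + (p - self.a_start) / self.slope
        if np.isscalar(pct_a) or p.ndim == 0:
            return float(t)
        return t


def annotate_gradient(table, program: GradientProgram):
    """Return a copy of ``table`` with gradient_pct_a set from each RT.

    Every record must carry ``rt_min``; the input table is left unmodified.
    """
    new_records = []
    for rec in table.records:
        pct_a, _ = program.composition_at(rec.rt_min)
        new_records.append(replace(rec, gradient_pct_a=pct_a))
    return table.with_records(new_records)
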