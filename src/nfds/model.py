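"""Frequency-dependent haplotype dynamics and selection-coefficient estimation.

Two mitochondrial haplotypes HI and HII segregate at frequencies ``p_I`` and
``p_II = 1 - p_I``.  Under the symmetric linear frequency-dependent fitness
map with an equilibrium at 0.5,

    W_I  = 1 - p_I  * s_I
    W_II = 1 - p_II * s_I

the deterministic one-generation change in ``p_I`` is

    dp_I = p_I * p_II * (W_I - W_II) / W_bar,   W_bar = p_I W_I + p_II W_II.

``s_I`` is the frequency-dependent selection coefficient: positive when the
observed change is toward the 0.5 attractor (negative frequency dependence),
negative when away from it.  Inverting the recursion for one generation gives
the closed-form estimator :func:`estimate_s`, which maps an observed
per-generation frequency change back to ``s_I``.

Everything here is pure computation on floats; the stochastic machinery lives
in :mod:`nfds.simulate` and the inferential layer in :mod:`nfds.inference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FitnessPair",
    "SelectionEstimate",
    "FrequencyChange",
    "LineRecord",
    "fitness_pair",
    "forward_delta_p",
    "estimate_s",
    "delta_f",
    "line_selection_estimates",
    "admissible_s_max",
    "clamp_frequency",
]

#: slack allowed before a frequency outside [0, 1] is treated as an error
#: rather than floating-point noise to be clamped away
CLAMP_TOL = 1e-12


class AdmissibilityError(ValueError):
    """The fitness model left its admissible regime (mean fitness <= 0)."""


def clamp_frequency(p: float, tol: float = CLAMP_TOL) -> float:
    """Clamp ``p`` to [0, 1], raising if it lies more than ``tol`` outside."""
    if p < -tol or p > 1.0 + tol:
        raise ValueError(f"frequency {p!r} outside [0, 1] beyond tolerance {tol}")
    return min(1.0, max(0.0, p))


def admissible_s_max(p_I: float) -> float:
    """Upper bound on ``s_I`` keeping mean fitness positive at frequency ``p_I``.

    W_bar = 1 - s_I (p_I^2 + p_II^2), so s_I must be below
    ``1 / (p_I^2 + p_II^2)``.  The bound is tightest (1.0) at the boundaries
    p_I in {0, 1} and loosest (2.0) at p_I = 0.5.
    """
    p = clamp_frequency(p_I)
    q = 1.0 - p
    return 1.0 / (p * p + q * q)


@dataclass(frozen=True)
class FitnessPair:
    """Haplotype fitnesses at a given frequency.

    ``valid`` is False when mean fitness is non-positive, i.e. the requested
    ``s_I`` is outside the admissible range at this frequency.
    """

    w_I: float
    w_II: float
    w_bar: float
    valid: bool


@dataclass(frozen=True)
class SelectionEstimate:
    """A selection-coefficient estimate with an explicit definedness flag.

    ``value`` is NaN whenever ``valid`` is False; ``reason`` says why the
    estimator was undefined (fixation, or a vanishing denominator such as the
    0/0 at p_I = 0.5 with no observed change, where any s is consistent with
    the data).
    """

    value: float
    valid: bool = True
    reason: str | None = None

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class FrequencyChange:
    """Per-generation frequency change over a generation interval."""

    delta_f: float
    interval_start_gen: int
    interval_end_gen: int
    f_start: float
    f_end: float

    @property
    def interval_length(self) -> int:
        return self.interval_end_gen - self.interval_start_gen


@dataclass(frozen=True)
class LineRecord:
    """One evolving line: design factors plus frequencies at generations 0, 5, 10.

    ``f0`` is the known founding frequency of HI; ``f5`` and ``f10`` are the
    pool-seq estimates at the two sampled generations.
    """

    line_id: str
    start_freq: float
    environment: str
    f0: float
    f5: float
    f10: float


def fitness_pair(p_I: float, s_I: float) -> FitnessPair:
    """Evaluate the linear frequency-dependent fitnesses at frequency ``p_I``.

    Returns W_I = 1 - p_I s_I, W_II = 1 - p_II s_I and their frequency-weighted
    mean W_bar = 1 - s_I (p_I^2 + p_II^2).  ``valid`` flags W_bar > 0.
    """
    p = clamp_frequency(p_I)
    q = 1.0 - p
    w_i = 1.0 - p * s_I
    w_ii = 1.0 - q * s_I
    w_bar = p * w_i + q * w_ii
    return FitnessPair(w_i, w_ii, w_bar, valid=w_bar > 0.0)


def forward_delta_p(p_I: float, s_I: float) -> float:
    """Deterministic one-generation change in ``p_I`` under selection ``s_I``.

    Raises :class:`AdmissibilityError` when mean fitness is non-positive.
    The returned change keeps ``p_I + dp`` inside [0, 1] for admissible
    ``s_I``; it is exactly zero at p_I in {0, 0.5, 1}.
    """
    fit = fitness_pair(p_I, s_I)
    if not fit.valid:
        raise AdmissibilityError(
            f"mean fitness {fit.w_bar:.6g} <= 0 at p_I={p_I!r}, s_I={s_I!r}; "
            f"s_I must be < {admissible_s_max(p_I):.6g}"
        )
    p = clamp_frequency(p_I)
    q = 1.0 - p
    return p * q * (fit.w_I - fit.w_II) / fit.w_bar


def estimate_s(p_I: float, delta_p: float) -> SelectionEstimate:
    """Closed-form selection coefficient implied by an observed change.

    Given the frequency ``p_I`` at the start of a generation and the observed
    per-generation change ``delta_p``, inverts the one-generation recursion:

        s_I = (-dp p_I - dp p_II) /
              (-dp p_II^2 - p_I p_II^2 + p_I^2 p_II - dp p_I^2)

    This is the exact one-generation inverse of :func:`forward_delta_p`.  The
    estimator is undefined at fixation (p_I in {0, 1}) and whenever the
    denominator vanishes — notably the 0/0 at p_I = 0.5 with ``delta_p = 0``,
    where any selection strength is consistent with no change.  Undefined
    cases are returned flagged, never as silent numbers.
    """
    p = clamp_frequency(p_I)
    if p == 0.0 or p == 1.0:
        return SelectionEstimate(math.nan, valid=False, reason="fixation")
    q = 1.0 - p
    dp = delta_p
    num = -dp * p - dp * q
    den = -dp * q * q - p * q * q + p * p * q - dp * p * p
    if den == 0.0:
        return SelectionEstimate(math.nan, valid=False, reason="zero denominator")
    return SelectionEstimate(num / den)


def delta_f(
    f_start: float, f_end: float, gen_start: int, gen_end: int
) -> FrequencyChange:
    """Per-generation frequency change over the interval [gen_start, gen_end].

    delta_f = (f_end - f_start) / (gen_end - gen_start); the interval length
    must be positive.
    """
    if gen_end <= gen_start:
        raise ValueError(
            f"non-positive interval length: generations {gen_start} to {gen_end}"
        )
    fs = clamp_frequency(f_start)
    fe = clamp_frequency(f_end)
    return FrequencyChange(
        delta_f=(fe - fs) / (gen_end - gen_start),
        interval_start_gen=gen_start,
        interval_end_gen=gen_end,
        f_start=fs,
        f_end=fe,
    )


def line_selection_estimates(
    line: LineRecord,
) -> tuple[SelectionEstimate, SelectionEstimate]:
    """Two repeated selection-coefficient measures for one line.

    Applies :func:`estimate_s` to the per-generation frequency change of each
    interval (generations 0-5 and 5-10), paired with the frequency observed at
    the start of that interval.  Undefined-estimator flags propagate.
    """
    d1 = delta_f(line.f0, line.f5, 0, 5)
    d2 = delta_f(line.f5, line.f10, 5, 10)
    return estimate_s(line.f0, d1.delta_f), estimate_s(line.f5, d2.delta_f)
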