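"""Replicated-line inference: split-plot ANOVA, permutation, bootstrap, t-test.

Each evolving line is the experimental unit.  Two between-line factors —
starting frequency of HI (rare 0.2 vs common 0.8) and resource environment
(homogeneous vs heterogeneous) — form a balanced 2x2 design, and the two
generation intervals (0-5 vs 5-10) supply two repeated measures per line of
either the per-generation frequency change or the selection coefficient.

The ANOVA is the classical split-plot / within-subjects decomposition:
between-line sums of squares (SF, E, SF x E) are tested against the
line-within-cell residual, and the within-line stratum (generation G and its
interactions with the between factors) against the G x line residual.  Drift
among replicate lines lands in the residual terms, which is what makes the
F-tests honest for a drift-prone system like mtDNA.

Between-line F-tests can be validated with label-permutation tests (the
(SF, E) label pairs are shuffled across lines, keeping each line's repeated
measures intact), and group means summarized with percentile bootstrap
intervals.  All resampling is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import LineRecord, line_selection_estimates

__all__ = [
    "ResponseMatrix",
    "BootstrapSummary",
    "UnbalancedDesignError",
    "response_matrix",
    "rm_anova",
    "permutation_test_between",
    "bootstrap_mean_ci",
    "global_t_test",
    "group_means",
    "BETWEEN_TERMS",
]

BETWEEN_TERMS = ("SF", "E", "SF:E")
WITHIN_TERMS = ("G", "G:SF", "G:E", "G:SF:E")


class UnbalancedDesignError(ValueError):
    """The response matrix is not a balanced 2x2 design with 2 measures."""


@dataclass(frozen=True)
class ResponseMatrix:
    """Responses for the repeated-measures analysis.

    ``y`` has one row per line and one column per repeated measure (interval
    0-5, then 5-10).  ``start_freq`` and ``environment`` are the between-line
    factor levels, ``kind`` names the response ("delta_f" or "s_I").
    """

    line_id: tuple[str, ...]
    start_freq: np.ndarray
    environment: np.ndarray
    y: np.ndarray
    kind: str = "response"

    @property
    def n_lines(self) -> int:
        return self.y.shape[0]

    def line_means(self) -> np.ndarray:
        """Per-line scalar response: mean of the two interval measures."""
        return self.y.mean(axis=1)

    def validate(self) -> "ResponseMatrix":
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise UnbalancedDesignError(
                f"expected exactly 2 repeated measures per line, got shape {y.shape}"
            )
        if np.isnan(y).any():
            bad = [self.line_id[i] for i in np.where(np.isnan(y).any(axis=1))[0]]
            raise ValueError(f"undefined responses for lines: {bad}")
        sf_levels = np.unique(self.start_freq)
        env_levels = np.unique(self.environment)
        if len(sf_levels) != 2 or len(env_levels) != 2:
            raise UnbalancedDesignError(
                f"need 2 levels per between factor, got SF={sf_levels.tolist()}, "
                f"E={env_levels.tolist()}"
            )
        counts = {
            (a, b): int(np.sum((self.start_freq == a) & (self.environment == b)))
            for a in sf_levels
            for b in env_levels
        }
        if len(set(counts.values())) != 1 or min(counts.values()) < 2:
            raise UnbalancedDesignError(f"unbalanced design cells: {counts}")
        return self


def response_matrix(lines: Sequence[LineRecord], kind: str = "s_I") -> ResponseMatrix:
    """Build the analysis response matrix from assembled line records.

    ``kind="delta_f"`` uses the per-generation frequency change of HI for each
    interval; ``kind="s_I"`` the closed-form selection coefficient.  Undefined
    selection estimates (fixation, vanishing denominator) raise, naming the
    line.
    """
    rows = []
    for ln in lines:
        if kind == "delta_f":
            rows.append(((ln.f5 - ln.f0) / 5.0, (ln.f10 - ln.f5) / 5.0))
        elif kind == "s_I":
            s1, s2 = line_selection_estimates(ln)
            if not (s1.valid and s2.valid):
                reason = s1.reason if not s1.valid else s2.reason
                raise ValueError(
                    f"selection estimate undefined for line {ln.line_id}: {reason}"
                )
            rows.append((s1.value, s2.value))
        else:
            raise ValueError(f"unknown response kind {kind!r}")
    return ResponseMatrix(
        line_id=tuple(ln.line_id for ln in lines),
        start_freq=np.asarray([ln.start_freq for ln in lines]),
        environment=np.asarray([ln.environment for ln in lines]),
        y=np.asarray(rows, dtype=float),
        kind=kind,
    ).validate()


def _twoway_ss(v: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Balanced two-way ANOVA sums of squares of ``v`` on factors a x b.

    ``v`` may be 1-D (n,) or 2-D (m, n) to decompose many response vectors at
    once over the same design.  Returns (ss_a, ss_b, ss_ab, ss_resid).
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    n = v.shape[1]
    grand = v.mean(axis=1, keepdims=True)
    ss_a = np.zeros(v.shape[0])
    ss_b = np.zeros(v.shape[0])
    ss_cells = np.zeros(v.shape[0])
    for lev in np.unique(a):
        mask = a == lev
        ss_a += mask.sum() * (v[:, mask].mean(axis=1) - grand[:, 0]) ** 2
    for lev in np.unique(b):
        mask = b == lev
        ss_b += mask.sum() * (v[:, mask].mean(axis=1) - grand[:, 0]) ** 2
    resid = np.empty_like(v)
    for la in np.unique(a):
        for lb in np.unique(b):
            mask = (a == la) & (b == lb)
            cell = v[:, mask].mean(axis=1)
            ss_cells += mask.sum() * (cell - grand[:, 0]) ** 2
            resid[:, mask] = v[:, mask] - cell[:, None]
    ss_ab = ss_cells - ss_a - ss_b
    ss_resid = (resid**2).sum(axis=1)
    return ss_a, ss_b, ss_ab, ss_resid


def _f_and_p(ss: float, df: int, ms_resid: float, df_resid: int, tiny: float = 0.0):
    ms = ss / df
    if ms_resid <= tiny:  # zero residual variance: F undefined, flagged
        return ms, math.nan, math.nan
    f = ms / ms_resid
    return ms, f, float(stats.f.sf(f, df, df_resid))


def rm_anova(data: ResponseMatrix) -> pd.DataFrame:
    """Split-plot repeated-measures ANOVA table.

    Returns one row per term with columns ``term, stratum, df, SS, MS, F, p``.
    Between-line terms (SF, E, SF:E) are tested against the line-within-cell
    residual; within-line terms (G and its interactions) against the G x line
    residual.  With a 12-line design the df column is (1, 1, 1, 8) between and
    (1, 1, 1, 1, 8) within.  Zero residual variance yields flagged (NaN) F.
    """
    data.validate()
    a, b = data.start_freq, data.environment
    n = data.n_lines
    n_cells = 4
    df_resid = n - n_cells

    m = data.y.mean(axis=1)  # line means (between stratum, x2 scaling)
    ss_a, ss_b, ss_ab, ss_res = (2.0 * s[0] for s in _twoway_ss(m, a, b))

    d = data.y[:, 1] - data.y[:, 0]  # interval differences (within stratum, /2)
    ss_g = d.sum() ** 2 / (2.0 * n)
    ssd_a, ssd_b, ssd_ab, ssd_res = (s[0] / 2.0 for s in _twoway_ss(d, a, b))

    # threshold below which a residual MS is floating-point noise, not signal
    tiny = np.finfo(float).eps * data.y.size * (np.abs(data.y).max() ** 2 + 1.0)

    rows = []
    ms_res_b = ss_res / df_resid
    for term, ss in zip(BETWEEN_TERMS, (ss_a, ss_b, ss_ab)):
        ms, f, p = _f_and_p(ss, 1, ms_res_b, df_resid, tiny)
        rows.append((term, "between", 1, ss, ms, f, p))
    rows.append(("Residual", "between", df_resid, ss_res, ms_res_b, math.nan, math.nan))

    ms_res_w = ssd_res / df_resid
    for term, ss in zip(WITHIN_TERMS, (ss_g, ssd_a, ssd_b, ssd_ab)):
        ms, f, p = _f_and_p(ss, 1, ms_res_w, df_resid, tiny)
        rows.append((term, "within", 1, ss, ms, f, p))
    rows.append(("Residual", "within", df_resid, ssd_res, ms_res_w, math.nan, math.nan))

    return pd.DataFrame(rows, columns=["term", "stratum", "df", "SS", "MS", "F", "p"])


def _between_f(m_rows: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[str, np.ndarray]:
    """Between-stratum F statistics from line-mean responses.

    ``m_rows`` is (n_perm, n_lines); F values for SF, E and SF:E are returned
    per row.  Because every between-stratum SS scales identically with the
    number of repeated measures, F computed from line means equals the
    split-plot F.
    """
    n = m_rows.shape[1]
    df_resid = n - 4
    ss_a, ss_b, ss_ab, ss_res = _twoway_ss(m_rows, a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ms_res = ss_res / df_resid
        return {
            "SF": ss_a / ms_res,
            "E": ss_b / ms_res,
            "SF:E": ss_ab / ms_res,
        }


def permutation_test_between(
    data: ResponseMatrix,
    term: str,
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for a between-line term of the split-plot ANOVA.

    The (SF, E) label pairs are randomly reassigned across lines — keeping
    each line's two repeated measures intact — and the term's F recomputed for
    each of ``n_perm`` permutations.  The p-value uses the add-one convention
    (count of permuted F >= observed, +1) / (n_perm + 1), upper tail of F.
    When the observed F is undefined (zero effect and residual variance) the
    maximal p-value 1.0 is returned.
    """
    if term not in BETWEEN_TERMS:
        raise ValueError(f"term must be one of {BETWEEN_TERMS}, got {term!r}")
    data.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a, b = data.start_freq, data.environment
    m = data.line_means()
    f_obs = _between_f(m[None, :], a, b)[term][0]
    if not np.isfinite(f_obs):
        return 1.0
    # permuting labels across lines == permuting line responses over fixed labels
    idx = np.argsort(rng.random((n_perm, m.size)), axis=1)
    f_perm = _between_f(m[idx], a, b)[term]
    exceed = int(np.sum(f_perm >= f_obs))
    return (exceed + 1) / (n_perm + 1)


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile bootstrap summary of a group mean."""

    estimate: float
    lower: float
    upper: float
    level: float = 0.95
    n_replicates: int = 9999

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def bootstrap_mean_ci(
    values: Sequence[float],
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> BootstrapSummary:
    """Percentile bootstrap confidence interval for a mean.

    Resamples the values (lines) with replacement ``n_boot`` times; the point
    estimate is the plain sample mean.  A single value yields a degenerate
    zero-width interval with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    if np.isnan(v).any():
        raise ValueError("bootstrap input contains undefined values")
    if v.size == 1:
        warnings.warn("single observation: degenerate zero-width bootstrap CI")
        return BootstrapSummary(float(v[0]), float(v[0]), float(v[0]), level, n_boot)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapSummary(float(v.mean()), float(lo), float(hi), level, n_boot)


def global_t_test(per_line_s: Sequence[float]) -> tuple[float, int, float]:
    """One-sample two-sided t-test of mean selection coefficient against zero.

    Input is one scalar per line (the mean of its two interval estimates).
    Returns ``(t, df, p)`` with df = n - 1.  A zero-variance sample at exactly
    zero mean returns (0, df, 1).
    """
    v = np.asarray(per_line_s, dtype=float)
    if v.size < 2:
        raise ValueError("t-test needs at least 2 lines")
    if np.isnan(v).any():
        raise ValueError("t-test input contains undefined values")
    if np.std(v, ddof=1) == 0.0:
        if v.mean() == 0.0:
            return 0.0, v.size - 1, 1.0
        raise ValueError("zero variance with non-zero mean: t undefined")
    res = stats.ttest_1samp(v, popmean=0.0)
    return float(res.statistic), v.size - 1, float(res.pvalue)


def group_means(
    data: ResponseMatrix,
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[float, str], BootstrapSummary]:
    """Bootstrap mean summaries per cell of the 2x2 design.

    Each line contributes the mean of its two interval responses; cells are
    keyed by ``(start_freq, environment)``.  Each cell consumes an
    independent, reproducible random substream.
    """
    data.validate()
    m = data.line_means()
    cells = [
        (float(a), str(b))
        for a in np.unique(data.start_freq)
        for b in np.unique(data.environment)
    ]
    if isinstance(seed, np.random.Generator):
        streams = seed.spawn(len(cells))
    else:
        streams = [
            np.random.Generator(np.random.PCG64(child))
            for child in np.random.SeedSequence(seed).spawn(len(cells))
        ]
    out: dict[tuple[float, str], BootstrapSummary] = {}
    for (a, b), stream in zip(cells, streams):
        mask = (data.start_freq == a) & (data.environment == b)
        out[(a, b)] = bootstrap_mean_ci(
            m[mask], n_boot=n_boot, level=level, seed=stream
        )
    return out
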