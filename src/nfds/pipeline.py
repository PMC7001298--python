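"""End-to-end analysis: read counts -> frequencies -> estimates -> inference.

`analyze_experiment` is the library's main entry point and what the CLI's
``analyze`` command wraps: it estimates per-line haplotype frequencies from
diagnostic-SNP read counts, derives per-interval frequency changes and
selection coefficients, runs the split-plot repeated-measures ANOVA (with
permutation validation of between-line terms) for both responses, and
summarizes selection with a global t-test and bootstrap group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqs import build_line_records, freqs_frame, snp_concordance
from .inference import (
    BETWEEN_TERMS,
    BootstrapSummary,
    bootstrap_mean_ci,
    global_t_test,
    group_means,
    permutation_test_between,
    response_matrix,
    rm_anova,
)
from .model import LineRecord, line_selection_estimates

__all__ = ["AnalysisResult", "analyze_experiment", "estimates_frame"]


@dataclass
class AnalysisResult:
    """Everything the analysis computes, ready for writing or inspection."""

    lines: list[LineRecord]
    freqs: pd.DataFrame
    estimates: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    snp_r: float
    per_line_s: np.ndarray = field(repr=False, default=None)
    t_stat: float = math.nan
    t_df: int = 0
    t_p: float = math.nan
    overall: BootstrapSummary | None = None
    groups: dict[tuple[float, str], BootstrapSummary] | None = None

    def anova_frame(self) -> pd.DataFrame:
        """All ANOVA tables stacked, tagged by response (anova.csv schema)."""
        parts = []
        for resp, table in self.anova.items():
            parts.append(table.assign(response=resp))
        df = pd.concat(parts, ignore_index=True)
        return df[["response", "term", "stratum", "df", "SS", "MS", "F", "p", "p_perm"]]

    def summary_frame(self) -> pd.DataFrame:
        """Global and per-group selection summaries (summary.csv schema)."""
        rows = [
            ("global_t", "all", self.t_stat),
            ("global_t_df", "all", float(self.t_df)),
            ("global_t_p", "all", self.t_p),
            ("mean_s", "all", self.overall.estimate),
            ("mean_s_ci_lower", "all", self.overall.lower),
            ("mean_s_ci_upper", "all", self.overall.upper),
            ("snp_concordance_r", "all", self.snp_r),
        ]
        for (sf, env), summ in self.groups.items():
            tag = f"sf={sf}/{env}"
            rows += [
                ("mean_s", tag, summ.estimate),
                ("mean_s_ci_lower", tag, summ.lower),
                ("mean_s_ci_upper", tag, summ.upper),
            ]
        return pd.DataFrame(rows, columns=["quantity", "group", "value"])


def estimates_frame(lines: list[LineRecord]) -> pd.DataFrame:
    """Per-line, per-interval frequency changes and selection coefficients."""
    rows = []
    for ln in lines:
        s1, s2 = line_selection_estimates(ln)
        d1 = (ln.f5 - ln.f0) / 5.0
        d2 = (ln.f10 - ln.f5) / 5.0
        rows.append((ln.line_id, "0-5", d1, s1.value, s1.valid))
        rows.append((ln.line_id, "5-10", d2, s2.value, s2.valid))
    return pd.DataFrame(
        rows, columns=["line_id", "interval", "delta_f", "s_I", "valid"]
    )


def analyze_experiment(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 9999,
    n_boot: int = 9999,
    seed: int = 0,
    depth_weighted: bool = False,
) -> AnalysisResult:
    """Run the full inferential pipeline on one experiment's tables.

    ``counts`` and ``design`` follow the counts.csv / design.csv schemas.
    Both responses (frequency change and selection coefficient) get a
    split-plot ANOVA; permutation p-values are attached to the between-line
    terms.  Stochastic steps (permutation, bootstrap) consume independent
    substreams of ``seed``.
    """
    lines = build_line_records(counts, design, depth_weighted=depth_weighted)
    freqs = freqs_frame(lines)
    estimates = estimates_frame(lines)
    snp_r = snp_concordance(counts)

    ss = np.random.SeedSequence(seed)
    perm_children = iter(ss.spawn(2 * len(BETWEEN_TERMS) + 2))

    anova_tables: dict[str, pd.DataFrame] = {}
    matrices = {}
    for kind in ("delta_f", "s_I"):
        rm = response_matrix(lines, kind=kind)
        matrices[kind] = rm
        table = rm_anova(rm)
        p_perm = []
        for _, row in table.iterrows():
            if row["term"] in BETWEEN_TERMS:
                rng = np.random.Generator(np.random.PCG64(next(perm_children)))
                p_perm.append(
                    permutation_test_between(rm, row["term"], n_perm=n_perm, seed=rng)
                )
            else:
                p_perm.append(math.nan)
        anova_tables[kind] = table.assign(p_perm=p_perm)

    rm_s = matrices["s_I"]
    per_line_s = rm_s.line_means()
    t, df, p = global_t_test(per_line_s)
    boot_rng = np.random.Generator(np.random.PCG64(next(perm_children)))
    overall = bootstrap_mean_ci(per_line_s, n_boot=n_boot, seed=boot_rng)
    group_rng = np.random.Generator(np.random.PCG64(next(perm_children)))
    groups = group_means(rm_s, n_boot=n_boot, seed=group_rng)

    return AnalysisResult(
        lines=lines,
        freqs=freqs,
        estimates=estimates,
        anova=anova_tables,
        snp_r=snp_r,
        per_line_s=per_line_s,
        t_stat=t,
        t_df=df,
        t_p=p,
        overall=overall,
        groups=groups,
    )
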