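"""Synthetic experimental-evolution data with the structure the analysis assumes.

The generator emulates a 12-line fly-cage experiment: lines founded at
contrasting HI starting frequencies (0.2 or 0.8) in two resource environments
(homogeneous or heterogeneous), three replicate lines per cell of the 2x2
design.  Each line evolves for 10 discrete generations as a haploid
Wright-Fisher population: the expected frequency moves by the deterministic
negative-frequency-dependent step (:func:`nfds.model.forward_delta_p`) and the
realized count of HI carriers is a binomial draw at the per-generation census
size (drift).  At the sampled generations a pool of flies is drawn without
replacement from the cage (hypergeometric), and read counts at each diagnostic
SNP are binomial draws at the configured sequencing depth with success
probability equal to the pool's HI fraction.

Randomness: one global seed spawns an independent child stream per line
(``numpy.random.SeedSequence.spawn``), so adding lines never perturbs
existing trajectories and every output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AdmissibilityError, clamp_frequency, forward_delta_p

__all__ = [
    "ExperimentDesign",
    "TrueTrajectory",
    "simulate_line",
    "sample_pool",
    "sample_reads",
    "generate_experiment",
    "ramp_trajectory",
    "resolve_s",
]

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one synthetic experimental-evolution run.

    Defaults mirror the fly-cage study design: a 2x2 crossed design of HI
    starting frequency (0.2 or 0.8) and resource environment, three replicate
    lines per cell (12 lines), 10 generations, pools of 105 flies sequenced at
    generations 5 and 10, two diagnostic SNPs (one in Nad5, one in the 12S
    rRNA).  The census is an *effective* population size governing drift, held
    constant at 773 (the study's mean adult count) unless an explicit
    per-generation trajectory is supplied (see :func:`ramp_trajectory` for a
    founder-to-adult growth ramp).  ``true_s`` is the frequency-dependent
    selection coefficient; it may be a scalar, a mapping keyed by environment,
    or a mapping keyed by ``(start_freq, environment)`` so that the
    environment-by-frequency interaction has a non-null synthetic regime.

    ``deterministic=True`` switches off every stochastic stage (infinite
    census, exact pool composition, exact read proportions) for use as an
    analytic oracle.
    """

    start_freqs: tuple[float, ...] = (0.2, 0.8)
    environments: tuple[str, ...] = (HOMOGENEOUS, HETEROGENEOUS)
    replicates_per_cell: int = 3
    n_generations: int = 10
    sample_generations: tuple[int, ...] = (5, 10)
    founder_census: int = 100
    census: int = 773
    census_trajectory: tuple[int, ...] | None = None
    pool_size: int = 105
    read_depth_per_snp: int = 2000
    snp_ids: tuple[str, ...] = ("nad5", "rrnS")
    true_s: float | Mapping = 0.2
    deterministic: bool = False
    seed: int = 0

    @property
    def n_lines(self) -> int:
        return len(self.start_freqs) * len(self.environments) * self.replicates_per_cell

    @property
    def n_diagnostic_snps(self) -> int:
        return len(self.snp_ids)

    def census_sizes(self) -> tuple[int, ...]:
        """Per-generation census sizes for generations 1..n_generations."""
        if self.census_trajectory is not None:
            traj = tuple(int(n) for n in self.census_trajectory)
            if len(traj) != self.n_generations:
                raise ValueError(
                    f"census_trajectory has {len(traj)} entries, "
                    f"expected n_generations={self.n_generations}"
                )
            return traj
        return (self.census,) * self.n_generations

    def validate(self) -> None:
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")
        sizes = self.census_sizes()
        if any(n < 1 for n in sizes):
            raise ValueError("census sizes must be >= 1")
        if not set(self.sample_generations) <= set(range(1, self.n_generations + 1)):
            raise ValueError(
                f"sample_generations {self.sample_generations} not within "
                f"[1, {self.n_generations}]"
            )
        if not self.deterministic:
            for g in self.sample_generations:
                if self.pool_size > sizes[g - 1]:
                    raise ValueError(
                        f"pool_size {self.pool_size} exceeds census {sizes[g - 1]} "
                        f"at generation {g}"
                    )
        for p0 in self.start_freqs:
            clamp_frequency(p0)


def ramp_trajectory(
    n_generations: int = 10,
    founder_census: int = 100,
    adult_census: int = 773,
    ramp_generations: int = 5,
) -> tuple[int, ...]:
    """Two-phase census series: geometric growth from founders, then constant.

    Mimics a population that grows markedly over its first generations and
    plateaus at the adult count thereafter.
    """
    ratio = (adult_census / founder_census) ** (1.0 / ramp_generations)
    sizes = [
        int(round(founder_census * ratio ** min(g, ramp_generations)))
        for g in range(1, n_generations + 1)
    ]
    return tuple(sizes)


def resolve_s(true_s: float | Mapping, start_freq: float, environment: str) -> float:
    """Selection coefficient for one design cell.

    A mapping may be keyed by ``(start_freq, environment)`` pairs or by
    environment alone; a scalar applies everywhere.
    """
    if isinstance(true_s, Mapping):
        if (start_freq, environment) in true_s:
            return float(true_s[(start_freq, environment)])
        if environment in true_s:
            return float(true_s[environment])
        raise KeyError(
            f"true_s mapping has no entry for ({start_freq}, {environment!r})"
        )
    return float(true_s)


@dataclass(frozen=True)
class TrueTrajectory:
    """Latent state of one simulated line: true p_I at generations 0..G."""

    line_id: str
    start_freq: float
    environment: str
    p: tuple[float, ...]
    census: tuple[int, ...]
    s: float

    def __post_init__(self):
        if len(self.p) != len(self.census) + 1:
            raise ValueError("trajectory length must be n_generations + 1")


def simulate_line(
    design: ExperimentDesign,
    start_p: float,
    line_id: str,
    rng: np.random.Generator,
    environment: str = HOMOGENEOUS,
) -> TrueTrajectory:
    """One Wright-Fisher line under frequency-dependent selection.

    Each generation the expectation moves deterministically by the selection
    step; the realized frequency is then a binomial draw of HI carriers at the
    generation's census size (skipped entirely when the design is
    deterministic).  Reproducible given ``rng``'s state.
    """
    sizes = design.census_sizes()
    s = resolve_s(design.true_s, start_p, environment)
    p = clamp_frequency(start_p)
    traj = [p]
    for n in sizes:
        p_exp = p + forward_delta_p(p, s)
        if p_exp < -1e-12 or p_exp > 1.0 + 1e-12:
            raise AdmissibilityError(
                f"expected frequency {p_exp!r} left [0,1] at line {line_id} "
                f"(s={s!r} inadmissible)"
            )
        p_exp = clamp_frequency(p_exp)
        if design.deterministic:
            p = p_exp
        else:
            p = rng.binomial(n, p_exp) / n
        traj.append(p)
    return TrueTrajectory(
        line_id=line_id,
        start_freq=start_p,
        environment=environment,
        p=tuple(traj),
        census=sizes,
        s=s,
    )


def sample_pool(
    true_p: float,
    census: int,
    pool_size: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw a pool of flies without replacement from a cage.

    The cage holds ``round(census * true_p)`` HI carriers; the pool is a
    hypergeometric sample of ``pool_size`` flies.  Returns (HI, HII) counts
    summing to ``pool_size``.
    """
    if pool_size > census:
        raise ValueError(f"pool_size {pool_size} > census {census}")
    n_hi = int(round(census * clamp_frequency(true_p)))
    hi = int(rng.hypergeometric(n_hi, census - n_hi, pool_size))
    return hi, pool_size - hi


def sample_reads(
    pool_hi: int,
    pool_size: int,
    depth: int,
    n_snps: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Read counts at each diagnostic SNP for one pooled sample.

    Reads at each SNP are independent binomial draws at the given depth with
    success probability equal to the pool's HI fraction.  Returns one
    (count_HI, count_HII) pair per SNP, each summing to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= pool_hi <= pool_size:
        raise ValueError(f"pool_hi {pool_hi} outside [0, {pool_size}]")
    frac = pool_hi / pool_size
    out = []
    for _ in range(n_snps):
        hi = int(rng.binomial(depth, frac))
        out.append((hi, depth - hi))
    return out


def _line_table(design: ExperimentDesign) -> list[tuple[str, float, str, int, tuple]]:
    """Line ids, factors and stable per-line spawn keys.

    The spawn key depends only on the line's design cell and replicate
    number, so enlarging the design never changes existing lines' streams.
    """
    rows = []
    i = 0
    for ip, p0 in enumerate(design.start_freqs):
        for ie, env in enumerate(design.environments):
            for rep in range(1, design.replicates_per_cell + 1):
                i += 1
                rows.append((f"L{i:02d}", p0, env, rep, (ip, ie, rep)))
    return rows


def generate_experiment(
    design: ExperimentDesign,
) -> tuple[list[TrueTrajectory], pd.DataFrame, pd.DataFrame]:
    """Simulate a complete experiment: trajectories, read counts, design table.

    Returns ``(trajectories, counts, design_table)`` where ``counts`` has one
    row per (line, sampled generation, SNP) in the counts.csv schema and
    ``design_table`` the design.csv schema.  Fully determined by
    ``design.seed``: each line consumes an independent child stream, in a
    fixed order (trajectory first, then pool and reads per sampled
    generation).

    In deterministic mode the pool stage is bypassed (the pool fraction equals
    the true frequency) and read counts are the rounded expected counts, so
    downstream frequency estimates recover the true trajectory to within half
    a read.
    """
    design.validate()
    lines = _line_table(design)

    trajectories: list[TrueTrajectory] = []
    count_rows = []
    design_rows = []
    for line_id, p0, env, rep, spawn_key in lines:
        child = np.random.SeedSequence(design.seed, spawn_key=spawn_key)
        rng = np.random.Generator(np.random.PCG64(child))
        traj = simulate_line(design, p0, line_id, rng, environment=env)
        trajectories.append(traj)
        design_rows.append((line_id, p0, env, rep))
        for g in design.sample_generations:
            sample_id = f"{line_id}_g{g}"
            depth = design.read_depth_per_snp
            if design.deterministic:
                snp_counts = [
                    (int(round(traj.p[g] * depth)), depth - int(round(traj.p[g] * depth)))
                    for _ in design.snp_ids
                ]
            else:
                hi, _ = sample_pool(traj.p[g], traj.census[g - 1], design.pool_size, rng)
                snp_counts = sample_reads(
                    hi, design.pool_size, depth, design.n_diagnostic_snps, rng
                )
            for snp_id, (c_hi, c_hii) in zip(design.snp_ids, snp_counts):
                count_rows.append((sample_id, line_id, g, snp_id, c_hi, c_hii))

    counts = pd.DataFrame(
        count_rows,
        columns=["sample_id", "line_id", "generation", "snp_id", "count_HI", "count_HII"],
    )
    design_table = pd.DataFrame(
        design_rows, columns=["line_id", "start_freq", "environment", "replicate"]
    )
    return trajectories, counts, design_table


def truth_frame(trajectories: Sequence[TrueTrajectory]) -> pd.DataFrame:
    """Latent trajectories as a tidy table (truth.csv schema)."""
    rows = []
    for t in trajectories:
        for g, p in enumerate(t.p):
            census = t.census[g - 1] if g > 0 else t.census[0]
            rows.append((t.line_id, g, p, census))
    return pd.DataFrame(rows, columns=["line_id", "generation", "true_p", "census"])


def with_seed(design: ExperimentDesign, seed: int) -> ExperimentDesign:
    """Copy of a design with a different seed."""
    return replace(design, seed=seed)
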