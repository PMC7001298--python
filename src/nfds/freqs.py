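"""Haplotype-frequency estimation from diagnostic-SNP read counts.

Pooled flies are sequenced and reads supporting the HI versus HII haplotype
are counted at each diagnostic SNP.  The per-sample HI frequency estimate is
the unweighted mean of the per-SNP read proportions (depth-weighting is
available behind a flag but off by default).  Founding frequencies are known
by construction, so generation 0 comes from the design table rather than from
sequencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import LineRecord

__all__ = [
    "SnpCountRecord",
    "snp_proportion",
    "combine_snps",
    "build_line_records",
    "snp_concordance",
    "freqs_frame",
]


@dataclass(frozen=True)
class SnpCountRecord:
    """Read counts supporting HI vs HII at one diagnostic SNP in one pool."""

    sample_id: str
    line_id: str
    generation: int
    snp_id: str
    count_HI: int
    count_HII: int

    @property
    def depth(self) -> int:
        return self.count_HI + self.count_HII


def snp_proportion(record: SnpCountRecord) -> float:
    """Proportion of HI-supporting reads at one SNP."""
    if record.count_HI < 0 or record.count_HII < 0:
        raise ValueError(f"negative read count in {record}")
    total = record.count_HI + record.count_HII
    if total == 0:
        raise ValueError(f"zero total read count for {record.sample_id}/{record.snp_id}")
    return record.count_HI / total


def combine_snps(
    records: Sequence[SnpCountRecord], depth_weighted: bool = False
) -> float:
    """Per-sample HI frequency: mean read proportion across diagnostic SNPs.

    The default is the unweighted mean of per-SNP proportions; pass
    ``depth_weighted=True`` to weight SNPs by their read depth instead.  With
    a single usable SNP the available proportion is used with a warning.
    """
    usable = [r for r in records if r.depth >= 1]
    if not usable:
        raise ValueError("no usable SNP count records for this sample")
    sample_ids = {r.sample_id for r in usable}
    if len(sample_ids) > 1:
        raise ValueError(f"records mix samples: {sorted(sample_ids)}")
    if len(usable) == 1:
        warnings.warn(
            f"sample {usable[0].sample_id}: only one diagnostic SNP usable; "
            "frequency estimated from a single SNP",
            stacklevel=2,
        )
    if depth_weighted:
        hi = sum(r.count_HI for r in usable)
        return hi / sum(r.depth for r in usable)
    return float(np.mean([snp_proportion(r) for r in usable]))


def _records_from_frame(counts: pd.DataFrame) -> list[SnpCountRecord]:
    return [
        SnpCountRecord(
            sample_id=str(r.sample_id),
            line_id=str(r.line_id),
            generation=int(r.generation),
            snp_id=str(r.snp_id),
            count_HI=int(r.count_HI),
            count_HII=int(r.count_HII),
        )
        for r in counts.itertuples(index=False)
    ]


def build_line_records(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sample_generations: Iterable[int] = (5, 10),
    depth_weighted: bool = False,
) -> list[LineRecord]:
    """Assemble one :class:`~nfds.model.LineRecord` per line.

    ``f0`` comes from the design table's starting frequency; later
    frequencies from :func:`combine_snps` applied to each (line, generation)
    sample.  Missing samples and count rows for unknown lines fail loudly,
    naming the offending identifiers.
    """
    sample_generations = sorted(sample_generations)
    if set(sample_generations) != {5, 10}:
        raise ValueError(
            f"line records require samples at generations 5 and 10, "
            f"got {sample_generations}"
        )
    known = set(design["line_id"].astype(str))
    records = _records_from_frame(counts)
    unknown = sorted({r.line_id for r in records} - known)
    if unknown:
        raise ValueError(f"count rows reference unknown lines: {unknown}")

    by_key: dict[tuple[str, int], list[SnpCountRecord]] = {}
    for r in records:
        by_key.setdefault((r.line_id, r.generation), []).append(r)

    out = []
    for row in design.itertuples(index=False):
        line_id = str(row.line_id)
        freqs = {}
        for g in sample_generations:
            recs = by_key.get((line_id, g))
            if not recs:
                raise ValueError(f"missing sample for line {line_id} generation {g}")
            freqs[g] = combine_snps(recs, depth_weighted=depth_weighted)
        out.append(
            LineRecord(
                line_id=line_id,
                start_freq=float(row.start_freq),
                environment=str(row.environment),
                f0=float(row.start_freq),
                f5=freqs[5],
                f10=freqs[10],
            )
        )
    return out


def snp_concordance(counts: pd.DataFrame) -> float:
    """Pearson correlation of HI read proportions between the two SNPs.

    A diagnostic of agreement between the diagnostic SNPs across pooled
    samples (both estimate the same pool fraction, so near-1 values are
    expected at reasonable depth).  Returns NaN with a warning when either
    SNP's proportions are constant across samples (correlation undefined).
    """
    snps = sorted(counts["snp_id"].unique())
    if len(snps) != 2:
        raise ValueError(f"concordance needs exactly 2 SNPs, found {snps}")
    prop = (
        counts.assign(p=lambda d: d["count_HI"] / (d["count_HI"] + d["count_HII"]))
        .pivot_table(index="sample_id", columns="snp_id", values="p")
        .dropna()
    )
    if len(prop) < 3:
        raise ValueError("concordance needs >= 3 samples with both SNPs present")
    x, y = prop[snps[0]].to_numpy(), prop[snps[1]].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("SNP proportions constant across samples; correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def freqs_frame(lines: Sequence[LineRecord]) -> pd.DataFrame:
    """Line frequencies as a tidy table (freqs.csv schema)."""
    rows = []
    for ln in lines:
        for g, f in ((0, ln.f0), (5, ln.f5), (10, ln.f10)):
            rows.append((ln.line_id, g, f))
    return pd.DataFrame(rows, columns=["line_id", "generation", "f_HI"])
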