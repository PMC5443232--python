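"""Genome summary metrics and habitat-level group statistics.

Covers the descriptive layer of a comparative study: per-genome size and GC
content from assemblies, per-habitat means and standard deviations, and a
fixed-effects one-way ANOVA testing whether a metric (genome size, GC, ...)
differs between habitats.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sp_stats


@dataclass(frozen=True)
class GenomeMetrics:
    genome_id: str
    size: int            # bp, multi-contig assemblies summed
    gc: float            # % G+C over unambiguous (ACGT) bases
    gene_count: int | None = None


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]


def genome_metrics(source: str | Path | Iterable[str], genome_id: str = "") -> GenomeMetrics:
    """Size and GC content of a genome.

    ``source`` may be a FASTA path or an iterable of contig sequences (a
    plain sequence string counts as one contig).  GC is computed over
    unambiguous bases only: ``(G+C) / (A+C+G+T) * 100``, case-insensitive;
    ambiguity codes add to the size but not to the GC denominator.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        from Bio import SeqIO

        contigs = [str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")]
        genome_id = genome_id or Path(str(source)).stem
    elif isinstance(source, str):
        contigs = [source]
    else:
        contigs = [str(s) for s in source]
    if not contigs or not any(contigs):
        raise ValueError("no sequence data found")
    size = 0
    gc = 0
    unambiguous = 0
    for contig in contigs:
        upper = contig.upper()
        size += len(upper)
        gc += upper.count("G") + upper.count("C")
        unambiguous += sum(upper.count(b) for b in "ACGT")
    gc_percent = 100.0 * gc / unambiguous if unambiguous else 0.0
    return GenomeMetrics(genome_id=genome_id, size=size, gc=gc_percent)


def group_summary(
    values: Mapping[str, float],
    grouping: Mapping[str, Iterable[str]],
    ddof: int = 1,
) -> dict[str, tuple[int, float, float]]:
    """Per-group (n, mean, SD) for a per-genome metric.

    SD uses the sample convention (``ddof=1``) by default; pass ``ddof=0``
    for the population convention.
    """
    out = {}
    for group, members in grouping.items():
        data = np.array([values[m] for m in members], dtype=float)
        if data.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(data.std(ddof=ddof)) if data.size > ddof else 0.0
        out[group] = (int(data.size), float(data.mean()), sd)
    return out


def one_way_anova(
    values: Mapping[str, float], grouping: Mapping[str, Iterable[str]]
) -> AnovaResult:
    """Fixed-effects one-way ANOVA of a per-genome metric across groups.

    F is invariant under affine rescaling of the metric (bp and Mbp give the
    same statistic).  If every value is identical the test degenerates to
    F = 0, p = 1.
    """
    groups = {g: np.array([values[m] for m in ms], dtype=float) for g, ms in grouping.items()}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    small = [g for g, data in groups.items() if data.size < 2]
    if small:
        raise ValueError(f"ANOVA needs n >= 2 per group; too small: {small}")
    arrays = list(groups.values())
    n_total = sum(a.size for a in arrays)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = sp_stats.f_oneway(*arrays)
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=float(p_value),
        group_means={g: float(a.mean()) for g, a in groups.items()},
        group_sds={g: float(a.std(ddof=1)) for g, a in groups.items()},
    )
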