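"""Assembly, annotation and per-contig summary arithmetic.

Follows the BBMap stats.sh naming for N/L50: N is the *count* of largest
contigs needed to reach half (or 90%) of the assembly, L is the length of
the smallest contig among them — the reverse of some communities' usage, so
outputs spell both out. All printed percentages and means use half-up
rounding at the number of decimals requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percent denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


def mean_sd(values: Sequence[float]) -> Tuple[float, float, float]:
    """(mean, sample sd, standard error); sd and se are NaN for n < 2."""
    vals = np.asarray(list(values), dtype=float)
    n = vals.size
    if n < 1:
        raise ValueError("mean_sd requires at least one value")
    mean = float(vals.mean())
    if n < 2:
        return mean, float("nan"), float("nan")
    sd = float(vals.std(ddof=1))
    return mean, sd, sd / math.sqrt(n)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50_count: int
    l50_bp: int
    n90_count: int
    l90_bp: int
    max_bp: int
    n_over_50kb: int
    pct_over_50kb: float
    gc_pct: Optional[float] = None


def _nl(sorted_desc: np.ndarray, frac: float) -> Tuple[int, int]:
    target = frac * sorted_desc.sum()
    cum = np.cumsum(sorted_desc)
    m = int(np.searchsorted(cum, target)) + 1
    return m, int(sorted_desc[m - 1])


def gc_fraction(sequence: str) -> float:
    """GC fraction over non-N bases (case-insensitive)."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    return gc / acgt if acgt else 0.0


def assembly_stats(
    contig_lengths: Sequence[int],
    sequences: Optional[Iterable[object]] = None,
) -> AssemblyStats:
    """Assembly summary over contig lengths (BBMap stats.sh conventions).

    ``pct_over_50kb`` is the percent of total assembly *bases* held in
    contigs longer than 50 kb.
    """
    lengths = np.asarray(sorted(contig_lengths, reverse=True), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("assembly_stats requires at least one contig")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    total = int(lengths.sum())
    n50, l50 = _nl(lengths, 0.5)
    n90, l90 = _nl(lengths, 0.9)
    over = lengths[lengths > 50_000]
    gc = None
    if sequences is not None:
        seqs = [getattr(s, "sequence", s) for s in sequences]
        gc_bases = sum(s.upper().count("G") + s.upper().count("C") for s in seqs)
        acgt = sum(len(s) - s.upper().count("N") for s in seqs)
        gc = percent(gc_bases, acgt, 2) if acgt else 0.0
    return AssemblyStats(
        n_contigs=int(lengths.size),
        total_bp=total,
        n50_count=n50,
        l50_bp=l50,
        n90_count=n90,
        l90_bp=l90,
        max_bp=int(lengths[0]),
        n_over_50kb=int(over.size),
        pct_over_50kb=percent(int(over.sum()), total, 2),
        gc_pct=gc,
    )


@dataclass(frozen=True)
class BlobRow:
    contig_id: str
    gc_fraction: float
    mean_depth: float
    taxon: str


def blob_table(contigs, alignments, calls) -> pd.DataFrame:
    """Per-contig (GC, mean depth, taxon) rows for blob-style binning plots.

    Mean depth is total aligned bases on the contig divided by contig length;
    a contig missing from ``calls`` is labelled unclassified.
    """
    from .taxonomy import UNCLASSIFIED

    call_map = {c.seq_id: c.taxon for c in calls} if calls is not None else {}
    per_contig_bp: Dict[str, int] = {}
    for a in alignments or []:
        iv = a.target
        per_contig_bp[iv.contig] = per_contig_bp.get(iv.contig, 0) + len(iv)
    rows = []
    for contig in contigs:
        depth = per_contig_bp.get(contig.id, 0) / len(contig)
        rows.append(
            (contig.id, gc_fraction(contig.sequence), depth,
             call_map.get(contig.id, UNCLASSIFIED))
        )
    return pd.DataFrame(rows, columns=["contig_id", "gc_fraction", "mean_depth", "taxon"])


def gene_prediction_summary(gene_models) -> pd.DataFrame:
    """Annotation summary in the Gene/Exon/Intron/CDS class layout.

    Per class: count, total length, longest, shortest, mean length, and mean
    count per gene. The companion single/multi-exon gene split is appended as
    two extra rows. Exon/intron/CDS features pool all mRNAs of a gene.
    """
    genes: List[int] = []
    exons: List[int] = []
    introns: List[int] = []
    cds: List[int] = []
    single_exon = multi_exon = 0
    for g in gene_models:
        genes.append(len(g.span))
        n_ex = 0
        for m in g.mrnas:
            n_ex += len(m.exons)
            exons.extend(len(e) for e in m.exons)
            cds.extend(len(c) for c in m.cds)
        introns.extend(len(i) for i in g.introns())
        if n_ex <= 1:
            single_exon += 1
        else:
            multi_exon += 1

    n_genes = max(len(genes), 1)

    def _row(name: str, lens: List[int]) -> tuple:
        if not lens:
            return (name, 0, 0, 0, 0, 0.0, 0.0)
        return (
            name,
            len(lens),
            int(sum(lens)),
            int(max(lens)),
            int(min(lens)),
            round_half_up(sum(lens) / len(lens), 2),
            round_half_up(len(lens) / n_genes, 2),
        )

    rows = [
        _row("gene", genes),
        _row("exon", exons),
        _row("intron", introns),
        _row("CDS", cds),
    ]
    df = pd.DataFrame(
        rows,
        columns=["class", "count", "total_bp", "longest_bp", "shortest_bp",
                 "mean_bp", "mean_per_gene"],
    )
    extra = pd.DataFrame(
        [("single_exon_genes", single_exon, 0, 0, 0, 0.0, 0.0),
         ("multi_exon_genes", multi_exon, 0, 0, 0, 0.0, 0.0)],
        columns=df.columns,
    )
    return pd.concat([df, extra], ignore_index=True)
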