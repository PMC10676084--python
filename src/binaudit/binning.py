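"""Consensus binning of reads and contigs from two classification arms.

A sequence is retained for (or after) assembly only when the k-mer arm and
the alignment arm agree on the target phylum, or when exactly one arm calls
the target and the other fails to classify. Any conflicting call — even one
target call against a different phylum — drops the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .summary_stats import percent
from .taxonomy import ClassificationCall, UNCLASSIFIED


@dataclass(frozen=True)
class BinDecision:
    seq_id: str
    call_kmer: str
    call_aln: str
    kept: bool


def consensus_keep(call_a: str, call_b: str, target_taxon: str) -> bool:
    """The retention rule: keep iff both arms call the target, or one arm
    calls the target and the other is unclassified."""
    a_t, b_t = call_a == target_taxon, call_b == target_taxon
    a_u, b_u = call_a == UNCLASSIFIED, call_b == UNCLASSIFIED
    return (a_t and b_t) or (a_t and b_u) or (a_u and b_t)


def _call_map(calls: Iterable[ClassificationCall], method: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for c in calls:
        if c.seq_id in out:
            raise ValueError(f"duplicate {method} call for sequence {c.seq_id!r}")
        out[c.seq_id] = c.taxon
    return out


def bin_sequences(
    seqs: Sequence[object],
    calls_kmer: Iterable[ClassificationCall],
    calls_aln: Iterable[ClassificationCall],
    target: str,
) -> Tuple[List[object], pd.DataFrame]:
    """Apply the consensus rule to every sequence.

    ``seqs`` may be SeqRecords or bare ids; a sequence absent from one arm's
    calls is treated as unclassified by that arm. Returns the kept sequences
    (input order preserved) and the full decision table.
    """
    kmer = _call_map(calls_kmer, "kmer")
    aln = _call_map(calls_aln, "alignment")
    kept: List[object] = []
    rows: List[BinDecision] = []
    for seq in seqs:
        seq_id = getattr(seq, "id", seq)
        a = kmer.get(seq_id, UNCLASSIFIED)
        b = aln.get(seq_id, UNCLASSIFIED)
        keep = consensus_keep(a, b, target)
        rows.append(BinDecision(seq_id, a, b, keep))
        if keep:
            kept.append(seq)
    table = pd.DataFrame(
        [(r.seq_id, r.call_kmer, r.call_aln, r.kept) for r in rows],
        columns=["seq_id", "call_kmer", "call_aln", "kept"],
    )
    return kept, table


def binning_summary(
    calls: Iterable[ClassificationCall] | pd.DataFrame,
    denominator: int,
    decimals: int = 2,
) -> pd.DataFrame:
    """Per-class (taxon, count, percent-of-denominator) table.

    Accepts either one arm's calls or a decision table (then the k-mer column
    is summarised). Percentages are rounded half-up.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if isinstance(calls, pd.DataFrame):
        labels = list(calls["call_kmer"])
    else:
        labels = [c.taxon for c in calls]
    counts: Dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    rows = [
        (taxon, n, percent(n, denominator, decimals))
        for taxon, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["class", "count", "percent"])
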