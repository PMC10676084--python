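"""The intragenic contamination audit.

Reads classified as contaminant (by the k-mer arm) are traced two ways into
assembly coordinates: where the assembler placed them inside contigs (GFA
A-lines) and where they map back by alignment after duplicate removal and a
mapping-quality cut. The per-contig evidence set — by default the
intersection of the two — is intersected with every gene feature class
(gene, transcript, exon, intron, CDS) to yield per-gene contamination
metrics, which feed a linear model of contaminant depth on total depth and a
logistic model of contamination incidence on total depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import _intervals
from .formats_io import AlignmentRecord, GeneModel, ReadPlacement
from .summary_stats import mean_sd, percent, round_half_up

FEATURE_CLASSES = ("gene", "transcript", "exon", "intron", "CDS")


@dataclass(frozen=True)
class AuditConfig:
    mapq_min: int = 20
    contaminant_label: str = "Bacteria"
    evidence_mode: str = "intersection"  # or "union"

    def __post_init__(self) -> None:
        if not 0 <= self.mapq_min <= 60:
            raise ValueError(f"mapq_min {self.mapq_min} out of range")
        if self.evidence_mode not in ("intersection", "union"):
            raise ValueError(f"unknown evidence_mode {self.evidence_mode!r}")


@dataclass(frozen=True)
class RegressionFit:
    kind: str  # "ols" or "logistic"
    intercept: float
    slope: float
    n: int
    r2: Optional[float] = None
    intercept_se: Optional[float] = None
    slope_se: Optional[float] = None
    loglik_full: Optional[float] = None
    loglik_null: Optional[float] = None
    llr_pvalue: Optional[float] = None


def filter_alignments(
    records: Iterable[AlignmentRecord], config: AuditConfig = AuditConfig()
) -> List[AlignmentRecord]:
    """Deduplicate and quality-filter read-to-contig alignments.

    Duplicate and secondary records are removed; of the remainder each read
    keeps its single highest-mapq record (ties broken by leftmost target
    coordinate); records below ``mapq_min`` are then dropped (mapq exactly at
    the threshold is retained).
    """
    by_read: Dict[str, List[AlignmentRecord]] = {}
    for r in records:
        if r.is_duplicate or not r.is_primary:
            continue
        by_read.setdefault(r.read_id, []).append(r)
    kept: List[AlignmentRecord] = []
    for read_id in by_read:
        best = min(
            by_read[read_id],
            key=lambda r: (-r.mapq, r.target.contig, r.target.start, r.target.end),
        )
        if best.mapq >= config.mapq_min:
            kept.append(best)
    kept.sort(key=lambda r: (r.target.contig, r.target.start, r.read_id))
    return kept


def _per_contig(pairs: Iterable[Tuple[str, Tuple[int, int]]]) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for contig, pair in pairs:
        out.setdefault(contig, []).append(pair)
    return {c: _intervals.merge(ivs) for c, ivs in out.items()}


def contamination_evidence(
    placements: Iterable[ReadPlacement],
    alignments: Iterable[AlignmentRecord],
    contaminant_reads: Set[str],
    config: AuditConfig = AuditConfig(),
) -> Dict[str, List[Tuple[int, int]]]:
    """Per-contig evidence intervals for contaminant incorporation.

    A = union of assembler placements of contaminant reads; M = union of
    filtered alignment positions of contaminant reads (``filter_alignments``
    is applied here). Evidence is A ∩ M per contig (default) or A ∪ M when
    ``evidence_mode="union"``; returned as sorted maximal disjoint intervals.
    """
    a_set = _per_contig(
        (p.target.contig, p.target.pair)
        for p in placements
        if p.read_id in contaminant_reads
    )
    m_set = _per_contig(
        (r.target.contig, r.target.pair)
        for r in filter_alignments(alignments, config)
        if r.read_id in contaminant_reads
    )
    contigs = set(a_set) | set(m_set)
    evidence: Dict[str, List[Tuple[int, int]]] = {}
    for contig in contigs:
        a = a_set.get(contig, [])
        m = m_set.get(contig, [])
        ivs = (
            _intervals.intersect(a, m)
            if config.evidence_mode == "intersection"
            else _intervals.union(a, m)
        )
        if ivs:
            evidence[contig] = ivs
    return evidence


def depth_arrays(
    alignments: Iterable[AlignmentRecord], contig_lengths: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Piecewise-constant per-base depth per contig from alignment intervals."""
    pairs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contig_lengths}
    for r in alignments:
        if r.target.contig in pairs:
            pairs[r.target.contig].append(r.target.pair)
    return {
        c: _intervals.coverage(pairs[c], contig_lengths[c]) for c in contig_lengths
    }


def _feature_intervals(gene: GeneModel) -> Dict[str, List[Tuple[int, int]]]:
    feats: Dict[str, List[Tuple[int, int]]] = {
        "gene": [gene.span.pair],
        "transcript": [m.span.pair for m in gene.mrnas],
        "exon": [e.pair for m in gene.mrnas for e in m.exons],
        "intron": [i.pair for i in gene.introns()],
        "CDS": [c.pair for m in gene.mrnas for c in m.cds],
    }
    return {k: _intervals.merge(v) for k, v in feats.items()}


def per_feature_audit(
    gene_models: Sequence[GeneModel],
    evidence: Mapping[str, List[Tuple[int, int]]],
    all_read_depth: Mapping[str, np.ndarray],
    contam_read_depth: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Per-gene, per-feature-class contamination metrics.

    For each feature class of each gene: ``unique_contam_bp`` is the union
    length of the feature's overlap with the evidence set; ``contam_depth``
    is the mean contaminant-read depth over those positions (0 when none);
    ``total_depth`` is the mean all-read depth over the same positions, or
    over the whole feature when the feature is uncontaminated.
    """
    rows = []
    for gene in gene_models:
        if gene.contig not in all_read_depth:
            raise KeyError(f"gene {gene.gene_id} on contig {gene.contig!r} absent from depth map")
        ev = evidence.get(gene.contig, [])
        total = all_read_depth[gene.contig]
        contam = contam_read_depth[gene.contig]
        for fclass, ivs in _feature_intervals(gene).items():
            if not ivs:  # e.g. a single-exon gene has no introns
                rows.append((gene.gene_id, fclass, 0, 0.0, 0.0, False))
                continue
            overlap = _intervals.intersect(ivs, ev)
            ubp = _intervals.total_length(overlap)
            if ubp > 0:
                pos = np.concatenate([np.arange(s, e) for s, e in overlap])
                c_depth = float(contam[pos].mean())
                t_depth = float(total[pos].mean())
            else:
                pos = np.concatenate([np.arange(s, e) for s, e in ivs])
                c_depth = 0.0
                t_depth = float(total[pos].mean())
            rows.append(
                (gene.gene_id, fclass, ubp, c_depth, t_depth, ubp > 0)
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "feature_class", "unique_contam_bp",
                 "contam_depth", "total_depth", "contaminated"],
    )


def run_audit(
    gene_models: Sequence[GeneModel],
    placements: Iterable[ReadPlacement],
    alignments: Iterable[AlignmentRecord],
    contaminant_reads: Set[str],
    contig_lengths: Mapping[str, int],
    config: AuditConfig = AuditConfig(),
) -> Tuple[pd.DataFrame, Dict[str, List[Tuple[int, int]]]]:
    """Full audit: evidence, depths and per-feature rows in one call.

    Total depth pools every filtered alignment; contaminant depth restricts
    to alignments of contaminant-classified reads.
    """
    alignments = list(alignments)
    evidence = contamination_evidence(placements, alignments, contaminant_reads, config)
    filtered = filter_alignments(alignments, config)
    all_depth = depth_arrays(filtered, contig_lengths)
    contam_depth = depth_arrays(
        [r for r in filtered if r.read_id in contaminant_reads], contig_lengths
    )
    rows = per_feature_audit(gene_models, evidence, all_depth, contam_depth)
    return rows, evidence


# ---------------------------------------------------------------------------
# Regressions
# ---------------------------------------------------------------------------

def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Ordinary least squares of y on x with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("ols_fit requires n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    # constant response: the flat line fits perfectly but explains nothing
    r2 = 0.0 if np.ptp(y) == 0 else float(res.rsquared)
    return RegressionFit(
        kind="ols",
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        r2=r2,
        n=int(x.size),
    )


def logistic_fit(x: Sequence[float], y: Sequence[int]) -> RegressionFit:
    """Logistic regression of a 0/1 outcome on x, fit by Newton's method.

    The likelihood-ratio p-value compares the full model against the
    intercept-only model (upper χ²₁ tail of twice the log-likelihood gap).
    Complete separation (the slope diverging past ±50) is a hard error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 10:
        raise ValueError("logistic_fit requires n >= 10")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present")
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, sm.add_constant(x)).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
        except Exception as exc:  # statsmodels raises on perfect separation
            raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    slope = float(res.params[1])
    if abs(slope) > 50:
        raise ValueError("complete separation: slope diverged past +/-50")
    return RegressionFit(
        kind="logistic",
        intercept=float(res.params[0]),
        slope=slope,
        intercept_se=float(res.bse[0]),
        slope_se=float(res.bse[1]),
        loglik_full=float(res.llf),
        loglik_null=float(res.llnull),
        llr_pvalue=float(res.llr_pvalue),
        n=int(x.size),
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def audit_report(
    rows: pd.DataFrame,
    total_genes: Optional[int] = None,
    hex_bin_width: float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise audit rows per feature class, plus a 2-D binned density table.

    The summary gives, per class, the contaminated-feature count and
    mean ± SE of contaminant depth, unique overlap length and total depth
    over contaminated rows, and the integer percent of genes contaminated.
    The density ("hexbin") table counts contaminated gene rows on a fixed
    square grid over (total_depth, contam_depth) with the given bin width.
    """
    out = []
    gene_rows = rows[rows["feature_class"] == "gene"]
    n_total_genes = total_genes if total_genes is not None else len(gene_rows)
    for fclass in FEATURE_CLASSES:
        sub = rows[(rows["feature_class"] == fclass) & rows["contaminated"]]
        n = len(sub)
        if n == 0:
            out.append((fclass, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
            continue
        cd_m, _, cd_se = mean_sd(sub["contam_depth"])
        bp_m, _, bp_se = mean_sd(sub["unique_contam_bp"])
        td_m, _, td_se = mean_sd(sub["total_depth"])
        out.append((
            fclass, n,
            round_half_up(cd_m, 2), round_half_up(0.0 if math.isnan(cd_se) else cd_se, 2),
            round_half_up(bp_m, 2), round_half_up(0.0 if math.isnan(bp_se) else bp_se, 2),
            round_half_up(td_m, 2), round_half_up(0.0 if math.isnan(td_se) else td_se, 2),
        ))
    summary = pd.DataFrame(
        out,
        columns=["feature_class", "n_contaminated",
                 "contam_depth_mean", "contam_depth_se",
                 "unique_contam_bp_mean", "unique_contam_bp_se",
                 "total_depth_mean", "total_depth_se"],
    )
    n_contam_genes = int(gene_rows["contaminated"].sum()) if len(gene_rows) else 0
    summary.attrs["n_total_genes"] = n_total_genes
    summary.attrs["n_contaminated_genes"] = n_contam_genes
    summary.attrs["pct_genes_contaminated"] = (
        percent(n_contam_genes, n_total_genes, 0) if n_total_genes else 0.0
    )

    contam_genes = gene_rows[gene_rows["contaminated"]]
    if len(contam_genes):
        xb = np.floor(contam_genes["total_depth"].to_numpy() / hex_bin_width).astype(int)
        yb = np.floor(contam_genes["contam_depth"].to_numpy() / hex_bin_width).astype(int)
        density = (
            pd.DataFrame({"total_depth_bin": xb * hex_bin_width,
                          "contam_depth_bin": yb * hex_bin_width})
            .value_counts()
            .rename("count")
            .reset_index()
            .sort_values(["total_depth_bin", "contam_depth_bin"])
            .reset_index(drop=True)
        )
    else:
        density = pd.DataFrame(columns=["total_depth_bin", "contam_depth_bin", "count"])
    return summary, density
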