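"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-contig host genome carrying multi-exon gene models; HiFi-like reads
(length ~ Normal(15,105, 1,070), truncated below at 1 kb) sampled uniformly
from host and contaminant genomes; contaminant reads implanted into host
contigs as assembler placements plus matching alignments, with per-gene
contamination following a logistic model in local coverage
(sigmoid(β₀ + β₁·depth), defaults β₀ = −2.6527, β₁ = −0.0184); and two
classifier outputs with configurable miss/cross-classification rates.

Sequence-level chimerism is represented as interval structure only — the
audit operates on coordinates, not base identity — so implanted reads keep
their contaminant-genome sequence. Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _intervals
from .formats_io import (
    AlignmentRecord,
    GeneModel,
    Interval,
    MRNA,
    ReadPlacement,
    SeqRecord,
)
from .taxonomy import ClassificationCall, HitRecord, TaxonomyTree, UNCLASSIFIED

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Read-length and regression defaults follow the sequencing-run and
    fitted-model values the pipeline is designed around; genome sizes are
    desk-scale so the full pipeline runs in seconds.
    """

    seed: int
    # host genome
    n_host_contigs: int = 4
    contig_len_range: Tuple[int, int] = (90_000, 120_000)
    n_genes: int = 40
    exon_count_mean: float = 4.0
    exon_len_range: Tuple[int, int] = (160, 460)
    intron_len_range: Tuple[int, int] = (500, 3_300)
    intergenic_gap_range: Tuple[int, int] = (500, 3_000)
    # contaminant genomes
    n_contaminant_genomes: int = 2
    contaminant_genome_len: int = 40_000
    # reads
    read_len_mean: float = 15_105.0
    read_len_sd: float = 1_070.0
    read_len_min: int = 1_000
    host_depth: float = 16.0
    # contamination model
    contam_beta0: float = -2.6527
    contam_beta1: float = -0.0184
    contam_rate: Optional[float] = None  # fixed per-gene rate overriding the logistic
    contam_reads_per_gene_mean: float = 2.0
    contam_mapq_below20_frac: float = 0.2
    min_contam_overlap: int = 200
    # classifier confusion (per arm): miss -> unclassified, cross -> wrong phylum
    kmer_miss: float = 0.008
    kmer_cross: float = 0.002
    aln_miss: float = 0.95
    aln_cross: float = 0.001

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("kmer_miss", "kmer_cross", "aln_miss", "aln_cross",
                     "contam_mapq_below20_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.kmer_miss + self.kmer_cross > 1 or self.aln_miss + self.aln_cross > 1:
            raise ValueError("miss + cross rates must not exceed 1 for an arm")
        if self.contam_rate is not None and not 0.0 <= self.contam_rate <= 1.0:
            raise ValueError("contam_rate must be in [0, 1]")
        for name in ("contig_len_range", "exon_len_range", "intron_len_range",
                     "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")

    @classmethod
    def from_dict(cls, data: Dict) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        for key in data:
            if key not in known:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(**data)

    def _rng(self, stream: int) -> np.random.Generator:
        # one independent, reproducible stream per generator stage
        return np.random.default_rng([int(self.seed), stream])


def default_taxonomy() -> TaxonomyTree:
    """Small fixed taxonomy: host phylum, bacterial contaminants, bystanders."""
    parent = {
        "root": "root",
        "Arthropoda": "root",
        "Bacteria": "root",
        "Nematoda": "root",
        "Streptophyta": "root",
        "Cosmopolites_sordidus": "Arthropoda",
        "Pseudomonas_sp": "Bacteria",
        "Enterobacter_sp": "Bacteria",
        "Caenorhabditis_sp": "Nematoda",
        "Musa_acuminata": "Streptophyta",
    }
    rank = {
        "root": "root",
        "Arthropoda": "phylum",
        "Bacteria": "phylum",
        "Nematoda": "phylum",
        "Streptophyta": "phylum",
        "Cosmopolites_sordidus": "species",
        "Pseudomonas_sp": "species",
        "Enterobacter_sp": "species",
        "Caenorhabditis_sp": "species",
        "Musa_acuminata": "species",
    }
    return TaxonomyTree(parent, rank)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# Genomes and gene models
# ---------------------------------------------------------------------------

def simulate_genomes(
    config: SimConfig,
) -> Tuple[List[SeqRecord], List[Tuple[SeqRecord, str]], List[GeneModel]]:
    """Host contigs, taxon-labelled contaminant genomes, and gene models.

    Genes are packed left-to-right on the host contigs with random
    intergenic gaps; exon counts are 1 + Poisson(mean − 1); CDS intervals are
    the exons with short UTR trims at the mRNA ends. Raises when ``n_genes``
    genes cannot be packed into the configured contig space.
    """
    rng = config._rng(1)
    contigs = [
        SeqRecord(
            f"contig{i + 1}",
            _random_sequence(rng, int(rng.integers(*config.contig_len_range, endpoint=True))),
        )
        for i in range(config.n_host_contigs)
    ]
    bact_species = ["Pseudomonas_sp", "Enterobacter_sp"]
    contaminants = [
        (
            SeqRecord(f"bactgenome{i + 1}", _random_sequence(rng, config.contaminant_genome_len)),
            bact_species[i % len(bact_species)],
        )
        for i in range(config.n_contaminant_genomes)
    ]

    genes: List[GeneModel] = []
    gene_no = 0
    for contig in contigs:
        pos = int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        clen = len(contig)
        while gene_no < config.n_genes:
            n_exons = 1 + int(rng.poisson(max(config.exon_count_mean - 1.0, 0.0)))
            exon_lens = rng.integers(*config.exon_len_range, size=n_exons, endpoint=True)
            intron_lens = rng.integers(*config.intron_len_range, size=max(n_exons - 1, 0),
                                       endpoint=True)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            if pos + gene_len > clen:
                break
            gene_no += 1
            gid = f"gene{gene_no}"
            exons: List[Interval] = []
            cursor = pos
            for i, el in enumerate(exon_lens):
                exons.append(Interval(contig.id, cursor, cursor + int(el)))
                cursor += int(el)
                if i < len(intron_lens):
                    cursor += int(intron_lens[i])
            trim = 30
            cds: List[Interval] = []
            for i, ex in enumerate(exons):
                s, e = ex.start, ex.end
                if i == 0:
                    s = min(s + trim, e - 1)
                if i == len(exons) - 1:
                    e = max(e - trim, s + 1)
                cds.append(Interval(contig.id, s, e))
            span = Interval(contig.id, pos, cursor)
            genes.append(GeneModel(gid, contig.id, span, (MRNA(f"{gid}.t1", tuple(exons), tuple(cds)),)))
            pos = cursor + int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        if gene_no >= config.n_genes:
            break
    if gene_no < config.n_genes:
        raise ValueError(
            f"infeasible packing: only {gene_no} of {config.n_genes} genes fit "
            f"on {config.n_host_contigs} contigs"
        )
    return contigs, contaminants, genes


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: Sequence[SeqRecord],
    config: SimConfig,
    taxon: str,
    prefix: str = "read",
    n_reads: Optional[int] = None,
    stream: int = 2,
) -> Tuple[List[SeqRecord], pd.DataFrame]:
    """Error-free reads sampled uniformly from a genome, with truth.

    Read lengths are Normal(read_len_mean, read_len_sd) truncated to
    [read_len_min, contig length]; when ``n_reads`` is None the count per
    contig targets an expected mean depth of ``host_depth``. Truth columns:
    read_id, contig, start, end, taxon.
    """
    rng = config._rng(stream)
    reads: List[SeqRecord] = []
    truth_rows = []
    counter = 0
    for contig in genome:
        clen = len(contig)
        n = (
            n_reads
            if n_reads is not None
            else int(round(config.host_depth * clen / config.read_len_mean))
        )
        for _ in range(n):
            length = int(round(rng.normal(config.read_len_mean, config.read_len_sd)))
            length = max(config.read_len_min, min(length, clen))
            start = int(rng.integers(0, clen - length + 1))
            counter += 1
            rid = f"{prefix}{counter}"
            reads.append(SeqRecord(rid, contig.sequence[start : start + length]))
            truth_rows.append((rid, contig.id, start, start + length, taxon))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "contig", "start", "end", "taxon"])
    return reads, truth


# ---------------------------------------------------------------------------
# Contamination implantation
# ---------------------------------------------------------------------------

def implant_contamination(
    host_contigs: Sequence[SeqRecord],
    gene_models: Sequence[GeneModel],
    contaminant_reads: Sequence[SeqRecord],
    host_truth: pd.DataFrame,
    config: SimConfig,
) -> Tuple[List[ReadPlacement], List[AlignmentRecord], pd.DataFrame, List[str]]:
    """Insert contaminant-read placements over genes, with matching alignments.

    Each gene is contaminated with probability sigmoid(β₀ + β₁·depth) —
    depth being the host-read coverage over the gene span — or with the fixed
    ``contam_rate`` when set. Contaminated genes receive 1 + Poisson
    placements drawn from the contaminant read pool (each read used at most
    once); every placement gets one matching alignment whose mapq falls below
    20 with probability ``contam_mapq_below20_frac``. Host reads appear as
    placements and mapq-60 alignments at their truth positions.

    Returns (placements, alignments, per-gene truth, used contaminant ids).
    The truth's ``truth_unique_bp`` counts each gene span's overlap with the
    union of all implanted intervals on its contig, i.e. what a noise-free
    audit should recover.
    """
    rng = config._rng(3)
    contig_len = {c.id: len(c) for c in host_contigs}
    host_pairs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contig_len}
    for row in host_truth.itertuples(index=False):
        host_pairs[row.contig].append((row.start, row.end))
    host_depth = {
        c: _intervals.coverage(host_pairs[c], contig_len[c]) for c in contig_len
    }

    placements: List[ReadPlacement] = []
    alignments: List[AlignmentRecord] = []
    for row in host_truth.itertuples(index=False):
        iv = Interval(row.contig, row.start, row.end)
        placements.append(ReadPlacement(row.read_id, iv, "+"))
        alignments.append(AlignmentRecord(row.read_id, iv, 60, True, False))

    pool = list(contaminant_reads)
    pool_i = 0
    implanted: Dict[str, List[Tuple[int, int]]] = {c: [] for c in contig_len}
    used_ids: List[str] = []
    gene_rows = []
    for gene in gene_models:
        depth = float(host_depth[gene.contig][gene.span.start : gene.span.end].mean())
        p = (
            config.contam_rate
            if config.contam_rate is not None
            else _sigmoid(config.contam_beta0 + config.contam_beta1 * depth)
        )
        hit = bool(rng.random() < p)
        n_place = 0
        intervals_here: List[Tuple[int, int]] = []
        if hit:
            n_place = 1 + int(rng.poisson(max(config.contam_reads_per_gene_mean - 1.0, 0.0)))
            for _ in range(n_place):
                if pool_i >= len(pool):
                    raise ValueError("contaminant read pool exhausted during implantation")
                read = pool[pool_i]
                pool_i += 1
                used_ids.append(read.id)
                clen = contig_len[gene.contig]
                length = min(len(read), clen)
                ov = min(config.min_contam_overlap, len(gene.span))
                lo = max(0, gene.span.start - length + ov)
                hi = min(clen - length, gene.span.end - ov)
                start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(
                    0, min(gene.span.start, clen - length)
                )
                iv = Interval(gene.contig, start, start + length)
                orient = "+" if rng.random() < 0.5 else "-"
                placements.append(ReadPlacement(read.id, iv, orient))
                if rng.random() < config.contam_mapq_below20_frac:
                    mapq = int(rng.integers(0, 20))
                else:
                    mapq = int(rng.integers(20, 61))
                alignments.append(AlignmentRecord(read.id, iv, mapq, True, False))
                implanted[gene.contig].append(iv.pair)
                intervals_here.append(iv.pair)
        gene_rows.append(
            (gene.gene_id, gene.contig, gene.span.start, gene.span.end, depth,
             hit, n_place,
             ";".join(f"{s}-{e}" for s, e in intervals_here))
        )

    truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "contig", "start", "end", "host_depth",
                 "implanted", "n_contam_reads", "implanted_intervals"],
    )
    truth["truth_unique_bp"] = [
        _intervals.total_length(
            _intervals.clip(implanted[row.contig], row.start, row.end)
        )
        for row in truth.itertuples(index=False)
    ]
    return placements, alignments, truth, used_ids


# ---------------------------------------------------------------------------
# Classifier emulation
# ---------------------------------------------------------------------------

def simulate_classifier_calls(
    truth: pd.DataFrame,
    config: SimConfig,
    tree: TaxonomyTree,
) -> Tuple[List[ClassificationCall], List[HitRecord]]:
    """Emulated k-mer-arm calls and alignment-arm hit tables with error.

    Per sequence and per arm, the call equals the true phylum with
    probability 1 − miss − cross, is unclassified with probability miss, and
    is a uniformly chosen wrong phylum with probability cross. The hit table
    is constructed so that bestsum aggregation reproduces the intended
    alignment-arm call: the intended taxon's species receives the dominant
    bitscore, an occasional decoy hit scores at most half of it, and misses
    emit either nothing or a hit too weak to survive the e-value cutoff.
    """
    rng = config._rng(4)
    phyla = sorted(t for t, r in tree.rank.items() if r == "phylum")
    species_of = {
        p: sorted(t for t in tree.parent if tree.parent[t] == p) or [p] for p in phyla
    }

    def draw(true_phylum: str, miss: float, cross: float) -> str:
        u = rng.random()
        if u < miss:
            return UNCLASSIFIED
        if u < miss + cross:
            others = [p for p in phyla if p != true_phylum]
            return str(others[int(rng.integers(len(others)))]) if others else true_phylum
        return true_phylum

    kmer_calls: List[ClassificationCall] = []
    hits: List[HitRecord] = []
    for row in truth.itertuples(index=False):
        k_call = draw(row.taxon, config.kmer_miss, config.kmer_cross)
        support = float(rng.integers(50, 500)) if k_call != UNCLASSIFIED else 0.0
        kmer_calls.append(ClassificationCall(row.read_id, k_call, "kmer", support))

        a_call = draw(row.taxon, config.aln_miss, config.aln_cross)
        if a_call == UNCLASSIFIED:
            if rng.random() < 0.5:  # weak hit killed by the e-value cutoff
                subj = species_of[row.taxon][0] if row.taxon in species_of else row.taxon
                hits.append(HitRecord(row.read_id, subj, float(rng.uniform(40, 80)), 1e-10))
            continue
        subj_pool = species_of.get(a_call, [a_call])
        subj = subj_pool[int(rng.integers(len(subj_pool)))]
        score = float(rng.uniform(800, 1500))
        hits.append(HitRecord(row.read_id, subj, score, 10.0 ** -float(rng.uniform(60, 180))))
        if rng.random() < 0.3:
            others = [p for p in phyla if p != a_call]
            decoy_phylum = others[int(rng.integers(len(others)))]
            decoy = species_of[decoy_phylum][0]
            hits.append(
                HitRecord(row.read_id, decoy, score * float(rng.uniform(0.1, 0.5)),
                          10.0 ** -float(rng.uniform(55, 100)))
            )
    return kmer_calls, hits


# ---------------------------------------------------------------------------
# Regression-recovery harnesses (gene-table level, no sequences)
# ---------------------------------------------------------------------------

def simulate_logistic_gene_table(
    n_genes: int,
    beta0: float = -2.6527,
    beta1: float = -0.0184,
    depth_shape: float = 2.0,
    depth_scale: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene (total_depth, contaminated) draws from the logistic truth.

    Depth is Gamma(shape, scale) — mean 16 at the defaults, matching the
    background coverage the contamination model is conditioned on.
    """
    rng = np.random.default_rng([int(seed), 101])
    depth = rng.gamma(depth_shape, depth_scale, size=n_genes)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * depth)))
    y = (rng.random(n_genes) < p).astype(int)
    return pd.DataFrame({"total_depth": depth, "contaminated": y})


def simulate_linear_gene_table(
    n_genes: int,
    slope: float = 0.25,
    intercept: float = 1.83,
    noise_sd: float = 5.49,
    depth_shape: float = 2.0,
    depth_scale: float = 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene (total_depth, contam_depth) draws from the linear truth.

    The default noise sd makes the coefficient of determination of the
    generating process ≈ 0.21 given the Gamma(2, 8) depth distribution.
    """
    rng = np.random.default_rng([int(seed), 102])
    depth = rng.gamma(depth_shape, depth_scale, size=n_genes)
    contam = intercept + slope * depth + rng.normal(0.0, noise_sd, size=n_genes)
    return pd.DataFrame({"total_depth": depth, "contam_depth": contam})


# ---------------------------------------------------------------------------
# One-call dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: TaxonomyTree
    host_contigs: List[SeqRecord]
    contaminant_refs: List[Tuple[SeqRecord, str]]
    gene_models: List[GeneModel]
    reads: List[SeqRecord]
    read_truth: pd.DataFrame
    placements: List[ReadPlacement]
    alignments: List[AlignmentRecord]
    gene_truth: pd.DataFrame
    kmer_calls: List[ClassificationCall] = field(default_factory=list)
    hits: List[HitRecord] = field(default_factory=list)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full input set: genomes, genes, reads, placements,
    alignments, classifier outputs and truth tables."""
    tree = default_taxonomy()
    host, contaminants, genes = simulate_genomes(config)
    host_reads, host_truth = simulate_reads(host, config, taxon="Arthropoda",
                                            prefix="hostread", stream=2)
    pool_n = max(50, config.n_genes * max(int(config.contam_reads_per_gene_mean * 3), 3))
    per_genome = max(1, -(-pool_n // max(config.n_contaminant_genomes, 1)))
    contam_reads: List[SeqRecord] = []
    contam_truths = []
    for i, (genome, _species) in enumerate(contaminants):
        r, t = simulate_reads([genome], config, taxon="Bacteria",
                              prefix=f"bactread{i + 1}_", n_reads=per_genome,
                              stream=10 + i)
        contam_reads.extend(r)
        contam_truths.append(t)
    placements, alignments, gene_truth, used = implant_contamination(
        host, genes, contam_reads, host_truth, config
    )
    used_set = set(used)
    used_reads = [r for r in contam_reads if r.id in used_set]
    contam_truth = pd.concat(contam_truths, ignore_index=True) if contam_truths else pd.DataFrame(
        columns=host_truth.columns
    )
    contam_truth = contam_truth[contam_truth["read_id"].isin(used_set)]
    read_truth = pd.concat([host_truth, contam_truth], ignore_index=True)
    kmer_calls, hits = simulate_classifier_calls(read_truth, config, tree)
    return SimulatedDataset(
        config=config,
        tree=tree,
        host_contigs=host,
        contaminant_refs=contaminants,
        gene_models=genes,
        reads=host_reads + used_reads,
        read_truth=read_truth,
        placements=placements,
        alignments=alignments,
        gene_truth=gene_truth,
        kmer_calls=kmer_calls,
        hits=hits,
    )
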