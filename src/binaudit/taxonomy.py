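"""Taxonomy tree with LCA queries and the two classification arms.

The pipeline classifies every read and contig twice: a k-mer arm that mimics
the lowest-common-ancestor logic of k-mer classifiers (each query k-mer votes
for the taxon its canonical form maps to; the deepest node whose root-to-node
path accumulates the most votes wins), and an alignment arm that aggregates
BLAST-style hits with the "bestsum" rule (sum bitscores per phylum-level
taxon after an e-value cut, keep the argmax, call ties unclassified).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

#: Distinguished label for a sequence neither arm could place in the tree.
UNCLASSIFIED = "unclassified"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ClassificationCall:
    """Per-sequence taxon label from one classification arm."""

    seq_id: str
    taxon: str
    method: str  # "kmer" or "bestsum"
    support: float = 0.0


@dataclass(frozen=True)
class HitRecord:
    """One BLAST-style hit of a query against a taxon-labelled subject."""

    query_id: str
    subject_taxon: str
    bitscore: float
    evalue: float
    query_interval: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_id}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}")


class TaxonomyTree:
    """Rooted taxonomy supporting LCA queries and rank lookups.

    Parameters
    ----------
    parent
        Mapping taxon -> parent taxon. The root maps to itself.
    rank
        Mapping taxon -> rank name (e.g. "phylum", "species").
    name
        Optional mapping taxon -> display name; defaults to the taxon id.
    """

    def __init__(
        self,
        parent: Mapping[str, str],
        rank: Mapping[str, str],
        name: Optional[Mapping[str, str]] = None,
    ) -> None:
        self.parent: Dict[str, str] = dict(parent)
        self.rank: Dict[str, str] = dict(rank)
        self.name: Dict[str, str] = dict(name) if name else {t: t for t in self.parent}
        roots = [t for t, p in self.parent.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for t, p in self.parent.items():
            if p not in self.parent:
                raise ValueError(f"parent {p!r} of taxon {t!r} is not a node")
        self._depth: Dict[str, int] = {}
        for t in self.parent:
            self._depth[t] = len(self.path_to_root(t)) - 1

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def path_to_root(self, taxon: str) -> List[str]:
        """Nodes from ``taxon`` up to and including the root."""
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon {taxon!r}")
        path = [taxon]
        seen = {taxon}
        while path[-1] != self.root:
            nxt = self.parent[path[-1]]
            if nxt in seen:
                raise ValueError(f"cycle in taxonomy at {nxt!r}")
            path.append(nxt)
            seen.add(nxt)
        return path

    def depth(self, taxon: str) -> int:
        return self._depth[taxon]

    def is_ancestor(self, ancestor: str, taxon: str) -> bool:
        """True if ``ancestor`` is an ancestor-or-self of ``taxon``."""
        return ancestor in self.path_to_root(taxon)

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty set is undefined")
        for t in taxa:
            if t not in self.parent:
                raise KeyError(f"unknown taxon {t!r}")
        cur = taxa[0]
        for t in taxa[1:]:
            cur = self._lca2(cur, t)
        return cur

    def _lca2(self, a: str, b: str) -> str:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.parent[a]
            da -= 1
        while db > da:
            b = self.parent[b]
            db -= 1
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def ancestor_at_rank(self, taxon: str, rank: str) -> Optional[str]:
        """First ancestor-or-self of ``taxon`` with the given rank, else None."""
        for node in self.path_to_root(taxon):
            if self.rank.get(node) == rank:
                return node
        return None

    @classmethod
    def from_table(cls, path: str | Path) -> "TaxonomyTree":
        """Read a tab-separated (taxon_id, parent_id, rank, name) file."""
        parent: Dict[str, str] = {}
        rank: Dict[str, str] = {}
        name: Dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
                tid, pid, rk, nm = fields[:4]
                parent[tid] = pid
                rank[tid] = rk
                name[tid] = nm
        return cls(parent, rank, name)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.parent):
                fh.write(f"{t}\t{self.parent[t]}\t{self.rank.get(t, '')}\t{self.name.get(t, t)}\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer -> taxon table; the taxon is the LCA of all
    reference genomes containing that k-mer."""

    k: int
    table: Dict[str, str] = field(default_factory=dict)


def _clean_kmers(sequence: str, k: int) -> Iterable[str]:
    """Canonical k-mers of all windows made only of uppercase A/C/G/T.

    Lowercase (soft-masked) and N-containing windows are skipped, mirroring
    dust-style masking of low-complexity reference regions.
    """
    n = len(sequence)
    for i in range(n - k + 1):
        window = sequence[i : i + k]
        if any(c not in "ACGT" for c in window):
            continue
        yield canonical_kmer(window)


def build_kmer_index(
    references: Iterable[Tuple[object, str]],
    tree: TaxonomyTree,
    k: int = 21,
) -> KmerIndex:
    """Index reference genomes for the k-mer arm.

    ``references`` yields (sequence, taxon) pairs; a sequence may be a plain
    string or any object with a ``sequence`` attribute. Each canonical k-mer
    maps to the LCA of every taxon whose references contain it.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    index = KmerIndex(k=k)
    for ref, taxon in references:
        if taxon not in tree:
            raise KeyError(f"reference taxon {taxon!r} not in taxonomy")
        seq = getattr(ref, "sequence", ref)
        for kmer in _clean_kmers(seq, k):
            prev = index.table.get(kmer)
            index.table[kmer] = taxon if prev is None else tree.lca([prev, taxon])
    return index


def classify_kmer(
    seq: object,
    index: KmerIndex,
    tree: TaxonomyTree,
    min_hits: int = 1,
) -> ClassificationCall:
    """Classify one sequence with the k-mer/LCA arm.

    Every query k-mer found in the index tallies one hit for its taxon. Each
    tallied node is scored by the sum of tallies along its root-to-node path;
    the deepest node with the maximal path score is returned (the LCA of the
    tied nodes when the maximum is shared by incomparable nodes). Queries
    with fewer than ``min_hits`` total hits are unclassified; a query shorter
    than k is unclassified with support 0.
    """
    seq_id = getattr(seq, "id", "query")
    sequence = getattr(seq, "sequence", seq)
    if len(sequence) < index.k:
        return ClassificationCall(seq_id, UNCLASSIFIED, "kmer", 0.0)
    tally: Counter[str] = Counter()
    for kmer in _clean_kmers(sequence.upper(), index.k):
        taxon = index.table.get(kmer)
        if taxon is not None:
            tally[taxon] += 1
    if sum(tally.values()) < max(min_hits, 1):
        return ClassificationCall(seq_id, UNCLASSIFIED, "kmer", 0.0)
    scores = {
        node: sum(tally.get(a, 0) for a in tree.path_to_root(node)) for node in tally
    }
    best = max(scores.values())
    winners = [n for n, s in scores.items() if s == best]
    # drop winners that are proper ancestors of another winner; if several
    # incomparable nodes remain, their LCA is the call
    deepest = [
        n for n in winners
        if not any(m != n and tree.is_ancestor(n, m) for m in winners)
    ]
    call = deepest[0] if len(deepest) == 1 else tree.lca(deepest)
    return ClassificationCall(seq_id, call, "kmer", float(best))


def bestsum_assign(
    hits: Sequence[HitRecord],
    tree: TaxonomyTree,
    rank: str = "phylum",
    evalue_max: float = 1e-50,
) -> ClassificationCall:
    """Aggregate one query's hits with the bestsum rule.

    Hits above the e-value cutoff are discarded; surviving hits contribute
    their bitscore to their subject taxon's ancestor at the target rank (the
    taxon itself when it has no ancestor at that rank). The rank-level taxon
    with the largest bitscore sum is assigned; no surviving hits, or an exact
    tie of the top sums, yields unclassified (the "undef" class).
    """
    if not hits:
        return ClassificationCall("query", UNCLASSIFIED, "bestsum", 0.0)
    query_ids = {h.query_id for h in hits}
    if len(query_ids) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(query_ids)}")
    query_id = hits[0].query_id
    scores: Dict[str, List[float]] = {}
    for h in hits:
        if h.subject_taxon not in tree:
            raise KeyError(f"hit taxon {h.subject_taxon!r} not in taxonomy")
        if h.evalue > evalue_max:
            continue
        level = tree.ancestor_at_rank(h.subject_taxon, rank) or h.subject_taxon
        scores.setdefault(level, []).append(h.bitscore)
    # summing in sorted order makes the result independent of hit order
    sums = {t: math.fsum(sorted(v)) for t, v in scores.items()}
    if not sums:
        return ClassificationCall(query_id, UNCLASSIFIED, "bestsum", 0.0)
    best = max(sums.values())
    winners = sorted(t for t, s in sums.items() if s == best)
    if len(winners) > 1:
        return ClassificationCall(query_id, UNCLASSIFIED, "bestsum", float(best))
    return ClassificationCall(query_id, winners[0], "bestsum", float(best))
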