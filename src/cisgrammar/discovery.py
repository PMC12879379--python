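"""Permissive de novo motif discovery by k-mer Hamming clustering.

Unique regulatory-region sequences are decomposed into overlapping k-mers
(k = 12 by default); k-mers are clustered into the connected components of
the Hamming-distance <= 1 graph (single linkage, so chains are allowed); each
cluster becomes a position probability matrix weighted by k-mer occurrence
counts.  Candidate novel motifs are then filtered against a known-motif
database and de-duplicated by similarity clustering.

The motif-similarity statistic is deliberately simple: the best mean
per-column Pearson correlation over all gapless offsets with at least
``min_overlap`` aligned columns, taking the better of the forward and
reverse-complement orientation of the second motif.  Constant (zero
variance) columns compare as r = 1 when equal and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cisgrammar.motifs import ALPHABET, PPM

_LETTER_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def decompose_kmers(
    sequences, k: int = 12, collapse_rc: bool = False
) -> dict[str, int]:
    """Count every length-k window over the given strand of unique sequences.

    ``sequences`` is an iterable of ``(region_id, sequence)`` pairs (or
    Biopython SeqRecords); each region id is recorded once, so repeated
    records of the same region do not double-count.  Windows containing
    non-ACGT letters are skipped.  With ``collapse_rc`` each k-mer and its
    reverse complement are pooled under the lexicographically smaller string.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    from cisgrammar.motifs import revcomp

    counts: dict[str, int] = {}
    seen: set[str] = set()
    for rec in sequences:
        if hasattr(rec, "seq"):
            rid, seq = rec.id, str(rec.seq)
        else:
            rid, seq = rec
        if rid in seen:
            continue
        seen.add(rid)
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(b not in _LETTER_INDEX for b in kmer):
                continue
            if collapse_rc:
                kmer = min(kmer, revcomp(kmer))
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_hamming(kmers: dict[str, int] | list[str]) -> list[dict[str, int]]:
    """Connected components of the Hamming-distance <= 1 graph on k-mers.

    Single linkage: two k-mers at distance 2 fall in one cluster whenever a
    chain of distance-1 neighbours connects them.  Runs in O(n * k * 4) by
    hashing every 1-substitution variant instead of comparing all pairs.
    Returns clusters as kmer -> count dicts, ordered by smallest member.
    """
    if isinstance(kmers, dict):
        counts = dict(kmers)
    else:
        counts = {k: 1 for k in kmers}
    words = sorted(counts)
    if not words:
        return []
    if len({len(w) for w in words}) > 1:
        raise ValueError("all k-mers must have the same length")
    index = {w: i for i, w in enumerate(words)}
    uf = _UnionFind(len(words))
    for w, i in index.items():
        for pos in range(len(w)):
            for b in ALPHABET:
                if b == w[pos]:
                    continue
                j = index.get(w[:pos] + b + w[pos + 1 :])
                if j is not None:
                    uf.union(i, j)
    groups: dict[int, dict[str, int]] = {}
    for w, i in index.items():
        groups.setdefault(uf.find(i), {})[w] = counts[w]
    return [groups[r] for r in sorted(groups, key=lambda r: min(groups[r]))]


def build_ppm(cluster: dict[str, int], motif_id: str, source: str = "novel") -> PPM:
    """Count-weighted PPM of a k-mer cluster (no pseudocount at this stage)."""
    if not cluster:
        raise ValueError("empty cluster")
    k = len(next(iter(cluster)))
    mat = np.zeros((k, 4))
    total = 0.0
    for kmer, count in cluster.items():
        for j, b in enumerate(kmer):
            mat[j, _LETTER_INDEX[b]] += count
        total += count
    return PPM(motif_id, mat / total, source=source, total_weight=total)


def _column_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two probability 4-vectors, with a constant-column convention."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.dot(a - a.mean(), b - b.mean()) / (4 * sa * sb))


def motif_similarity(
    a: PPM, b: PPM, min_overlap: int = 8
) -> tuple[float, int, str]:
    """Best mean per-column Pearson correlation over gapless alignments.

    Returns ``(best_score, offset, strand)`` where ``offset`` is the position
    of b's first column relative to a's first column (may be negative) and
    strand is ``"+"`` or ``"-"`` (b reverse-complemented).
    """
    la, lb = len(a), len(b)
    if min_overlap > min(la, lb):
        raise ValueError("min_overlap exceeds the shorter motif length")
    best = (-np.inf, 0, "+")
    for strand, bm in (("+", b.matrix), ("-", b.matrix[::-1, ::-1])):
        for offset in range(-(lb - min_overlap), la - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(la, offset + lb)
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = bm[lo_a - offset : hi_a - offset]
            score = float(
                np.mean([_column_r(x, y) for x, y in zip(cols_a, cols_b)])
            )
            if score > best[0]:
                best = (score, offset, strand)
    return best


def filter_known(
    novel: list[PPM],
    known: list[PPM],
    r_match: float = 0.75,
    min_overlap: int = 8,
) -> tuple[list[PPM], list[tuple[str, str, float]]]:
    """Drop novel PPMs whose best similarity to any known PPM reaches r_match.

    Returns the retained novel PPMs and the (novel_id, known_id, score)
    matches that caused removals.
    """
    if not known:
        return list(novel), []
    retained, matched = [], []
    for p in novel:
        best_score, best_id = -np.inf, None
        for q in known:
            if min(len(p), len(q)) < min_overlap:
                continue
            s, _, _ = motif_similarity(p, q, min_overlap=min_overlap)
            if s > best_score:
                best_score, best_id = s, q.motif_id
        if best_id is not None and best_score >= r_match:
            matched.append((p.motif_id, best_id, best_score))
        else:
            retained.append(p)
    return retained, matched


def cluster_redundant(
    ppms: list[PPM], r_cluster: float = 0.9, min_overlap: int = 8
) -> list[PPM]:
    """Single-linkage similarity clustering; keep one representative per cluster.

    Edges join PPMs with similarity >= ``r_cluster``.  The representative is
    the member with the largest ``total_weight`` (ties: lexicographically
    smallest motif id); output is sorted by representative motif id.
    """
    n = len(ppms)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if min(len(ppms[i]), len(ppms[j])) < min_overlap:
                continue
            s, _, _ = motif_similarity(ppms[i], ppms[j], min_overlap=min_overlap)
            if s >= r_cluster:
                uf.union(i, j)
    clusters: dict[int, list[PPM]] = {}
    for i, p in enumerate(ppms):
        clusters.setdefault(uf.find(i), []).append(p)
    reps = [
        min(members, key=lambda p: (-p.total_weight, p.motif_id))
        for members in clusters.values()
    ]
    return sorted(reps, key=lambda p: p.motif_id)


def discover(
    sequences,
    known: list[PPM],
    k: int = 12,
    r_match: float = 0.75,
    r_cluster: float = 0.9,
    min_overlap: int = 8,
    min_weight: float = 0.0,
    collapse_rc: bool = False,
) -> list[PPM]:
    """Full discovery pipeline: k-mers -> clusters -> PPMs -> filter -> dedupe."""
    counts = decompose_kmers(sequences, k=k, collapse_rc=collapse_rc)
    clusters = cluster_hamming(counts)
    width = len(str(len(clusters)))
    ppms = [
        build_ppm(c, f"NOV{i:0{width}d}")
        for i, c in enumerate(clusters)
        if sum(c.values()) >= min_weight
    ]
    retained, _ = filter_known(ppms, known, r_match=r_match, min_overlap=min_overlap)
    return cluster_redundant(retained, r_cluster=r_cluster, min_overlap=min_overlap)
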