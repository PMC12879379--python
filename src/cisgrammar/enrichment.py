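"""Monte Carlo enrichment of motifs and motif pairs in gene-linked regions.

The observed statistic for a motif (or pair) is the number of target-set
genes linked to at least one regulatory region of the requested class that
contains a filtered hit of the motif (for a pair: of both motifs, in any of
the gene's regions).  The null samples size-matched gene sets from the
comparator set without replacement; the p-value is the proportion of
iterations whose sampled count is >= the observed count (no smoothing), and
fold change is observed / mean sampled count.  A motif is called enriched
when p < 0.05 and fold change > 2 (both configurable).

Because presence is a boolean per gene, the count of presences in a
uniformly drawn size-matched subset of the comparator genes follows the
hypergeometric distribution exactly; ``mc_test`` therefore draws the
per-iteration counts directly from ``rng.hypergeometric``, which is
statistically identical to materialising each sampled gene set and far
cheaper.  ``method="subset"`` keeps the explicit sampler for cross-checks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cisgrammar.regions import GeneRegionMap


def presence_table(
    gene_map: GeneRegionMap,
    hits: pd.DataFrame,
    motif_ids: list[str],
    region_class: str = "both",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Boolean genes x motifs table: gene g has >= 1 hit of m in a linked region.

    ``hits`` must already be filtered by p-value/score thresholds and carry
    ``motif_id`` and ``region_id`` columns.
    """
    if genes is None:
        genes = sorted(set(gene_map.proximal) | set(gene_map.distal))
    regions_with = {
        m: frozenset(hits.loc[hits["motif_id"] == m, "region_id"]) for m in motif_ids
    }
    out = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"), columns=motif_ids)
    for g in genes:
        linked = gene_map.regions_of(g, region_class)
        if not linked:
            continue
        for m in motif_ids:
            if linked & regions_with[m]:
                out.loc[g, m] = True
    return out


def pair_presence(presence: pd.DataFrame, pair: tuple[str, str]) -> pd.Series:
    """Genes carrying BOTH motifs (in any of their linked regions of the class)."""
    m1, m2 = pair
    return presence[m1] & presence[m2]


@dataclass
class EnrichmentResult:
    subject: str
    region_class: str
    observed: int
    null_mean: float
    p_value: float
    fold_change: float
    enriched: bool
    n_iter: int
    seed: int | None
    null_counts: np.ndarray | None = None


def mc_test(
    presence: pd.Series,
    target_genes: list[str],
    comparator_genes: list[str],
    n_iter: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: str = "",
    region_class: str = "both",
    p_max: float = 0.05,
    fc_min: float = 2.0,
    keep_null: bool = False,
    method: str = "count",
) -> EnrichmentResult:
    """Monte Carlo enrichment test of one motif (or pair) presence vector.

    ``presence`` is a boolean Series over genes.  Each iteration draws
    ``len(target_genes)`` comparator genes without replacement and counts
    presences; see the module docstring for why the default draws the counts
    hypergeometrically.  With ``method="subset"`` gene subsets are sampled
    explicitly (same distribution, slower).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n_t = len(target_genes)
    if len(comparator_genes) < n_t:
        raise ValueError("comparator set smaller than target set")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = int(presence.loc[list(target_genes)].sum())
    comp = presence.loc[list(comparator_genes)].to_numpy(dtype=bool)
    K, N = int(comp.sum()), len(comp)
    if method == "count":
        null = rng.hypergeometric(K, N - K, n_t, size=n_iter)
    elif method == "subset":
        u = rng.random((n_iter, N))
        idx = np.argpartition(u, n_t - 1, axis=1)[:, :n_t]
        null = comp[idx].sum(axis=1)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    null_mean = float(null.mean())
    p_value = float((null >= observed).mean())
    if observed == 0:
        fold, enriched = (0.0 if null_mean > 0 else np.nan), False
    elif null_mean == 0:
        fold, enriched = np.inf, p_value < p_max
    else:
        fold = observed / null_mean
        enriched = (p_value < p_max) and (fold > fc_min)
    return EnrichmentResult(
        subject=subject,
        region_class=region_class,
        observed=observed,
        null_mean=null_mean,
        p_value=p_value,
        fold_change=fold,
        enriched=bool(enriched),
        n_iter=n_iter,
        seed=seed,
        null_counts=null if keep_null else None,
    )


def pair_universe(motif_ids: list[str], mode: str = "unordered"):
    """Candidate motif-pair universe.

    ``unordered``: all unordered pairs of distinct motifs;
    ``cross``: the full ordered cross-product including self-pairs
    (m identifiers give m**2 pairs).
    """
    if mode == "unordered":
        yield from itertools.combinations(motif_ids, 2)
    elif mode == "cross":
        yield from itertools.product(motif_ids, repeat=2)
    else:
        raise ValueError(f"unknown pair mode {mode!r}")


def expression_filter_tfbs(
    motif_ids: list[str],
    motif_to_genes: dict[str, list[str]],
    agg_target: pd.Series,
    threshold: float,
) -> list[str]:
    """Keep motifs whose every mapped TF gene meets the aggregate-expression bar.

    Dimeric motifs map to multiple genes and all components must pass.
    Unmapped motifs are retained with a warning.
    """
    retained = []
    for m in motif_ids:
        genes = motif_to_genes.get(m)
        if not genes:
            warnings.warn(f"motif {m!r} has no TF gene mapping; retained")
            retained.append(m)
            continue
        if all(g in agg_target.index and agg_target[g] >= threshold for g in genes):
            retained.append(m)
    return retained


def rank_pairs(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Rank motif pairs by summed ranks of observed (desc) and null_mean (asc).

    Ties in the final rank sum break lexicographically on the subject id.
    """
    df = pd.DataFrame(
        {
            "subject": [r.subject for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
        }
    )
    df["rank_observed"] = rankdata(-df["observed"], method="average")
    df["rank_null"] = rankdata(df["null_mean"], method="average")
    df["rank_sum"] = df["rank_observed"] + df["rank_null"]
    return df.sort_values(["rank_sum", "subject"], kind="stable").reset_index(drop=True)


def select_candidates(
    ranked_tfbs_pairs: list[tuple[str, str]],
    ranked_novel_pairs: list[tuple[str, str]],
    archetype_map: dict[str, str],
    novel_ids: set[str],
    n_tfbs: int = 9,
    n_novel: int = 9,
) -> tuple[list[str], list[str]]:
    """Pick candidate motifs for the reporter library from ranked pair lists.

    Walk the ranked TFBS:TFBS pairs collecting member TFBS, skipping any
    whose DNA-binding archetype is already represented, until ``n_tfbs`` are
    found.  Then walk the ranked TFBS:novel pairs restricted to pairs whose
    TFBS member was selected, collecting novel motifs until ``n_novel``.
    """
    tfbs: list[str] = []
    archetypes: set[str] = set()
    for pair in ranked_tfbs_pairs:
        for m in pair:
            if len(tfbs) >= n_tfbs:
                break
            if m in tfbs:
                continue
            arch = archetype_map.get(m)
            if arch is not None and arch in archetypes:
                continue
            tfbs.append(m)
            if arch is not None:
                archetypes.add(arch)
        if len(tfbs) >= n_tfbs:
            break
    if len(tfbs) < n_tfbs:
        warnings.warn(f"only {len(tfbs)} of {n_tfbs} TFBS candidates found")

    novel: list[str] = []
    selected = set(tfbs)
    for pair in ranked_novel_pairs:
        if len(novel) >= n_novel:
            break
        members = set(pair)
        if not (members & selected):
            continue
        for m in pair:
            if m in novel_ids and m not in novel and len(novel) < n_novel:
                novel.append(m)
    if len(novel) < n_novel:
        warnings.warn(f"only {len(novel)} of {n_novel} novel candidates found")
    return tfbs, novel


def representative_site(
    motif_id: str, hits: pd.DataFrame, sequences: dict[str, str]
) -> str:
    """Most prevalent genomic subsequence matched by the motif's hits.

    Ties break first on the highest scan score of the sequence, then
    lexicographically.  Reverse-strand hits contribute the reverse complement
    of the genomic window (the sequence matching the motif as written).
    """
    from cisgrammar.motifs import revcomp

    sub = hits[hits["motif_id"] == motif_id]
    if len(sub) == 0:
        raise ValueError(f"no hits for motif {motif_id!r}")
    counts: dict[str, int] = {}
    best_score: dict[str, float] = {}
    for _, h in sub.iterrows():
        seq = sequences[h["region_id"]]
        site = seq[int(h["offset"]) : int(h["offset"]) + int(h["width"])].upper()
        if h["strand"] == "-":
            site = revcomp(site)
        counts[site] = counts.get(site, 0) + 1
        best_score[site] = max(best_score.get(site, -np.inf), float(h["score"]))
    return min(counts, key=lambda s: (-counts[s], -best_score[s], s))
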