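"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's real inputs: a normalized expression
matrix with planted cell-type-specific genes, a small regulatory genome
(sequences, open-chromatin regions, TSSs, chromatin loops) with motif sites
planted at class-dependent odds, and STARR-seq DNA/RNA count tables with
planted orientation, copy-number, position and pair effects.

All counts are negative binomial.  The NB dispersion ``alpha`` parameterises
variance as ``mu + alpha * mu**2``, so at deep coverage the per-count CV
approaches ``sqrt(alpha)``; the default 0.2 reproduces the loose replicate
correlation seen in T-lymphoblast reporter data, while an optional
per-replicate random effect can be switched on to push correlations lower
still.  Every generator is a pure function of its seed and parameters.

STARR effects act additively on the log2 activity scale:

    eta(oligo) = sum over present oriented motifs of beta(motif, orient)
               + sum over motifs of slope(motif) * (copies - 1)
               + gamma(unordered motif pair present)
               + sum over occupied slots of delta(motif, slot index)

with eta(background) = 0; the expected RNA rate of an oligo is proportional
to its DNA CPM times 2**eta.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cisgrammar.motifs import ALPHABET


@dataclass
class SimTruth:
    """Ground truth serialized alongside every simulated dataset."""

    seed: int | None = None
    planted_genes: list = field(default_factory=list)
    planted_motifs: dict = field(default_factory=dict)  # motif_id -> consensus site
    site_placements: list = field(default_factory=list)  # (region_id, offset, strand, motif)
    enrichment_odds: dict = field(default_factory=dict)
    starr_effects: dict = field(default_factory=dict)


def _nb(rng: np.random.Generator, mu, dispersion: float):
    """Negative binomial with mean mu and variance mu + dispersion * mu**2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


# ---------------------------------------------------------------------------
# expression


def synth_expression(
    n_genes: int = 2000,
    n_target_samples: int = 8,
    n_background_samples: int = 6,
    n_planted: int = 20,
    fold: float = 8.0,
    dispersion: float = 0.2,
    base_mean: float = 50.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Expression matrix with ``n_planted`` genes specific to the target group.

    Gene baselines are log-normal around ``base_mean``; planted genes are
    multiplied by ``fold`` in target samples and divided by ``fold`` in
    background samples.
    """
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    planted = list(rng.choice(genes, size=n_planted, replace=False))
    base = base_mean * rng.lognormal(0, 1, size=n_genes)
    mu_t = np.tile(base[:, None], (1, n_target_samples))
    mu_b = np.tile(base[:, None], (1, n_background_samples))
    mask = np.isin(genes, planted)
    mu_t[mask] *= fold
    mu_b[mask] /= fold
    counts = np.concatenate(
        [_nb(rng, mu_t, dispersion), _nb(rng, mu_b, dispersion)], axis=1
    ).astype(float)
    samples = [f"T{i:02d}" for i in range(n_target_samples)] + [
        f"B{i:02d}" for i in range(n_background_samples)
    ]
    values = pd.DataFrame(counts, index=genes, columns=samples)
    groups = pd.Series(
        ["target"] * n_target_samples + ["background"] * n_background_samples,
        index=samples,
    )
    truth = SimTruth(seed=seed, planted_genes=planted)
    return values, groups, truth


# ---------------------------------------------------------------------------
# regulatory genome


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def synth_regulatory_genome(
    target_genes: list[str],
    comparator_genes: list[str],
    motif_sites: dict[str, str],
    odds_target: float = 0.8,
    odds_comparator: float = 0.1,
    regions_per_gene: int = 2,
    region_length: int = 300,
    proximal_length: int = 300,
    gene_spacing: int = 20_000,
    seed: int | None = None,
) -> dict:
    """A small synthetic genome with planted motif sites and loop links.

    Every gene gets a TSS, one proximal region centred on it, and
    ``regions_per_gene`` distal regions linked by loops whose anchor bins
    cover the proximal region and the distal region respectively.  Each
    motif's consensus site is written into each region of a target gene with
    probability ``odds_target`` and of a comparator gene with
    ``odds_comparator`` (strand chosen at random).

    Returns a dict with sequences (region_id -> str), regions, tss and
    interactions DataFrames, gene region map inputs, and a SimTruth.
    """
    for odds in (odds_target, odds_comparator):
        if not 0 <= odds <= 1:
            raise ValueError("odds must lie in [0, 1]")
    from cisgrammar.motifs import revcomp

    rng = np.random.default_rng(seed)
    genes = [(g, "target") for g in target_genes] + [
        (g, "comparator") for g in comparator_genes
    ]
    sequences: dict[str, str] = {}
    regions, tss_rows, loops, placements = [], [], [], []
    chrom = "chr1"
    for gi, (gene, klass) in enumerate(genes):
        tss_pos = gene_spacing * (gi + 1)
        tss_rows.append((gene, chrom, tss_pos, "+"))
        odds = odds_target if klass == "target" else odds_comparator
        # proximal region centred on the TSS
        p_start = tss_pos - proximal_length // 2
        prox = (chrom, p_start, p_start + proximal_length)
        regions.append(prox)
        _plant(rng, sequences, placements, prox, motif_sites, odds, revcomp)
        for d in range(regions_per_gene):
            d_start = tss_pos + 3000 + d * 2000
            dist = (chrom, d_start, d_start + region_length)
            regions.append(dist)
            _plant(rng, sequences, placements, dist, motif_sites, odds, revcomp)
            loops.append(
                (chrom, prox[1] - 100, prox[2] + 100, chrom, d_start - 100,
                 d_start + region_length + 100, f"loop_{gene}_{d}", 1.0)
            )
    regions_df = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    tss_df = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss", "strand"])
    loops_df = pd.DataFrame(
        loops,
        columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"],
    )
    truth = SimTruth(
        seed=seed,
        planted_motifs=dict(motif_sites),
        site_placements=placements,
        enrichment_odds={"target": odds_target, "comparator": odds_comparator},
    )
    return {
        "sequences": sequences,
        "regions": regions_df,
        "tss": tss_df,
        "interactions": loops_df,
        "truth": truth,
    }


def _plant(rng, sequences, placements, region, motif_sites, odds, revcomp):
    chrom, start, end = region
    rid = f"{chrom}:{start}-{end}"
    seq = list(_random_seq(rng, end - start))
    cursor = 5
    for motif_id, site in motif_sites.items():
        if rng.random() < odds and cursor + len(site) + 5 < len(seq):
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else revcomp(site)
            seq[cursor : cursor + len(site)] = placed
            placements.append((rid, cursor, strand, motif_id))
            cursor += len(site) + 5
    sequences[rid] = "".join(seq)


# ---------------------------------------------------------------------------
# STARR-seq counts


def _eta(slots, effects: dict) -> float:
    occ = [s for s in slots if s is not None]
    beta = effects.get("beta", {})
    slope = effects.get("slope", {})
    gamma = effects.get("gamma", {})
    delta = effects.get("delta", {})
    eta = 0.0
    oriented_counts: dict[tuple[str, str], int] = {}
    for s in occ:
        oriented_counts[s] = oriented_counts.get(s, 0) + 1
    for om, c in oriented_counts.items():
        eta += beta.get(om, 0.0)
        eta += slope.get(om[0], 0.0) * (c - 1)
    motifs = sorted({s[0] for s in occ})
    for pair in itertools.combinations(motifs, 2):
        eta += gamma.get(frozenset(pair), 0.0)
    # position effects key on occupied order: 0 = promoter-proximal, matching
    # the left-to-right packing of occupied slots in the rendered oligo
    for pos_idx, s in enumerate(occ):
        eta += delta.get((s[0], pos_idx), 0.0)
    return eta


def synth_starr(
    designs: pd.DataFrame,
    effects: dict,
    depth: float = 500.0,
    dispersion: float = 0.2,
    n_rna_reps: int = 3,
    n_dna_reps: int = 8,
    replicate_effect_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """DNA and RNA count tables for a library manifest with planted effects.

    DNA counts are NB around ``depth`` per oligo.  The expected RNA rate of
    an oligo is its mean DNA CPM times ``2**eta`` (eta = 0 for the
    background), rescaled so the mean RNA depth matches ``depth``.  A
    nonzero ``replicate_effect_sd`` multiplies each RNA replicate's rates by
    oligo-specific log-normal noise, loosening inter-replicate correlation.
    """
    from cisgrammar.activity import parse_slots

    rng = np.random.default_rng(seed)
    slots = parse_slots(designs)
    missing = set(effects.get("beta", {})) - {
        s for sl in slots for s in sl if s is not None
    }
    if missing:
        raise ValueError(f"effects reference motifs absent from the manifest: {missing}")
    oligos = designs["oligo_id"].to_numpy()
    n = len(oligos)
    dna = _nb(rng, np.full((n, n_dna_reps), depth), dispersion).astype(np.int64)
    dna_cpm_mean = (dna / dna.sum(axis=0) * 1e6).mean(axis=1)
    eta = np.array([_eta(slots[o], effects) for o in oligos])
    rate = dna_cpm_mean * np.power(2.0, eta)
    rate = rate / rate.mean() * depth
    rna_mu = np.tile(rate[:, None], (1, n_rna_reps))
    if replicate_effect_sd > 0:
        rna_mu = rna_mu * rng.lognormal(0, replicate_effect_sd, size=rna_mu.shape)
    rna = _nb(rng, rna_mu, dispersion).astype(np.int64)
    dna_df = pd.DataFrame(
        dna, index=oligos, columns=[f"DNA{r + 1}" for r in range(n_dna_reps)]
    )
    rna_df = pd.DataFrame(
        rna, index=oligos, columns=[f"RNA{r + 1}" for r in range(n_rna_reps)]
    )
    truth = SimTruth(seed=seed, starr_effects=effects)
    return dna_df, rna_df, truth


def replicate_starr_study(
    designs: pd.DataFrame,
    effects: dict,
    background_oligo_id: str,
    n_replicate_sims: int = 25,
    seed: int | None = None,
    **starr_kwargs,
) -> tuple[pd.Series, pd.Series]:
    """Pool per-oligo mean activities over independent replicate simulations.

    Runs :func:`synth_starr` ``n_replicate_sims`` times with seeds spawned
    from ``seed``, scores each dataset (QC -> CPM -> background-adjusted
    activity), and concatenates the per-oligo means with replicate-suffixed
    oligo ids.  Pooling independent simulated libraries tightens the
    standard error of group contrasts without touching the per-dataset
    depth, replicate count or dispersion.

    Returns ``(oligo_mean, slots)`` ready for the effect tests.
    """
    from cisgrammar.activity import activity, cpm, parse_slots, qc_filter

    slots = parse_slots(designs)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicate_sims) % (2**31)
    means, slot_map = [], {}
    for r, s in enumerate(seeds):
        dna, rna, _ = synth_starr(designs, effects, seed=int(s), **starr_kwargs)
        keep = qc_filter(dna, rna)
        if background_oligo_id not in keep:
            continue
        amat = activity(cpm(dna.loc[keep]), cpm(rna.loc[keep]), background_oligo_id)
        m = amat.oligo_mean.copy()
        m.index = [f"sim{r}:{o}" for o in m.index]
        means.append(m)
        for oid, sl in slots.items():
            slot_map[f"sim{r}:{oid}"] = sl
    return pd.concat(means), pd.Series(slot_map)
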