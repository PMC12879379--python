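"""Curate regulatory regions and link them to genes.

Coordinates are 0-based half-open (BED convention) throughout; "overlap by at
least one base pair" means the intersection has length >= 1, so bookended
intervals (``end == start``) do not overlap.

The curation path mirrors an open-chromatin consensus workflow: a region is
kept only if it is annotated in at least one sample of *every* required
sample group, regions on excluded chromosomes are dropped, overlapping
regions are merged, each merged region is classed proximal (within a fixed
window of any TSS) or distal, and distal regions are attached to genes via
chromatin interactions whose anchor bins touch the gene's proximal regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCLUDED_CHROMS = frozenset({"Y", "MT", "chrY", "chrM", "chrMT"})

REGION_COLS = ["chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame) -> None:
    if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
        raise ValueError("invalid interval: require 0 <= start < end")


def require_group_support(
    sample_regions: dict[str, pd.DataFrame],
    sample_groups: dict[str, str],
    required_groups: list[str],
    excluded_chroms: frozenset[str] = EXCLUDED_CHROMS,
    match: str = "exact",
) -> pd.DataFrame:
    """Retain regions supported by at least one sample of every required group.

    Parameters
    ----------
    sample_regions
        sample id -> BED3 DataFrame (chrom, start, end).
    sample_groups
        sample id -> group name.
    required_groups
        every group that must independently support a region.
    match
        ``"exact"``: support means the identical (chrom, start, end)
        annotation appears in the sample (the source annotations record the
        same region across samples).  ``"overlap"``: support means >= 1 bp
        overlap with any region of the sample.
    """
    unknown = set(required_groups) - set(sample_groups.values())
    if unknown:
        raise ValueError(f"required groups with no samples: {sorted(unknown)}")
    for s in sample_regions:
        if s not in sample_groups:
            raise ValueError(f"sample {s!r} has no group assignment")
        _check_intervals(sample_regions[s])

    all_regions = (
        pd.concat([df[REGION_COLS] for df in sample_regions.values()])
        .drop_duplicates()
        .reset_index(drop=True)
    )
    keep = np.ones(len(all_regions), dtype=bool)
    for group in required_groups:
        members = [s for s, g in sample_groups.items() if g == group]
        if match == "exact":
            seen: set[tuple] = set()
            for s in members:
                seen.update(map(tuple, sample_regions[s][REGION_COLS].to_numpy()))
            keep &= np.array(
                [tuple(r) in seen for r in all_regions.to_numpy()], dtype=bool
            )
        elif match == "overlap":
            pooled = pd.concat([sample_regions[s][REGION_COLS] for s in members])
            keep &= overlap_matrix(all_regions, pooled).any(axis=1)
        else:
            raise ValueError(f"unknown match mode {match!r}")
    out = all_regions[keep]
    out = out[~out["chrom"].isin(excluded_chroms)]
    return out.reset_index(drop=True)


def merge_overlapping(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge regions sharing >= 1 bp into single regions (sorted sweep).

    Bookended regions are left unmerged.  Idempotent; preserves the set of
    covered bases.
    """
    _check_intervals(regions)
    out = []
    for chrom, sub in regions.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur_s, cur_e = None, None
        for s, e in sub[["start", "end"]].to_numpy():
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # strict: touching intervals share no base
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=REGION_COLS)


def tss_distance(regions: pd.DataFrame, tss: pd.DataFrame) -> np.ndarray:
    """Nearest edge-to-point distance from each region to any TSS (inf if none).

    Distance is 0 when the TSS lies inside the half-open interval; otherwise
    it is the gap between the TSS point and the nearest interval boundary.
    """
    dist = np.full(len(regions), np.inf)
    for chrom, sub in regions.groupby("chrom"):
        pos = tss.loc[tss["chrom"] == chrom, "tss"].to_numpy()
        if pos.size == 0:
            continue
        s = sub["start"].to_numpy()[:, None]
        e = sub["end"].to_numpy()[:, None]
        d = np.maximum.reduce([s - pos[None, :], pos[None, :] - e, np.zeros((len(sub), pos.size))])
        dist[sub.index.to_numpy()] = d.min(axis=1)
    return dist


def classify_proximal_distal(
    regions: pd.DataFrame, tss: pd.DataFrame, window: int = 500
) -> pd.DataFrame:
    """Label each region ``proximal`` (within ``window`` bp of any TSS) or ``distal``."""
    regions = regions.reset_index(drop=True)
    unknown = set(tss["chrom"]) - set(regions["chrom"])
    if unknown:
        warnings.warn(f"TSS on chromosomes absent from the region set: {sorted(unknown)}")
    d = tss_distance(regions, tss)
    out = regions.copy()
    out["region_class"] = np.where(d <= window, "proximal", "distal")
    out["region_id"] = [
        f"{c}:{s}-{e}" for c, s, e in out[REGION_COLS].to_numpy()
    ]
    return out


def overlap_matrix(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean len(a) x len(b) matrix of >= 1 bp interval overlap."""
    out = np.zeros((len(a), len(b)), dtype=bool)
    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    for chrom in set(a["chrom"]) & set(b["chrom"]):
        ia = a.index[a["chrom"] == chrom].to_numpy()
        ib = b.index[b["chrom"] == chrom].to_numpy()
        s1 = a.loc[ia, "start"].to_numpy()[:, None]
        e1 = a.loc[ia, "end"].to_numpy()[:, None]
        s2 = b.loc[ib, "start"].to_numpy()[None, :]
        e2 = b.loc[ib, "end"].to_numpy()[None, :]
        out[np.ix_(ia, ib)] = (s1 < e2) & (s2 < e1)
    return out


@dataclass
class GeneRegionMap:
    """Per-gene proximal and distal region-id sets plus the region table."""

    proximal: dict[str, frozenset] = field(default_factory=dict)
    distal: dict[str, frozenset] = field(default_factory=dict)
    regions: pd.DataFrame | None = None
    tss: pd.DataFrame | None = None

    def regions_of(self, gene: str, region_class: str) -> frozenset:
        if region_class == "proximal":
            return self.proximal.get(gene, frozenset())
        if region_class == "distal":
            return self.distal.get(gene, frozenset())
        if region_class == "both":
            return self.proximal.get(gene, frozenset()) | self.distal.get(gene, frozenset())
        raise ValueError(f"unknown region class {region_class!r}")


def assign_proximal(
    labeled: pd.DataFrame, tss: pd.DataFrame, window: int = 500
) -> dict[str, frozenset]:
    """gene -> set of proximal region ids within ``window`` bp of that gene's TSS."""
    prox = labeled[labeled["region_class"] == "proximal"].reset_index(drop=True)
    out: dict[str, frozenset] = {}
    for gene, chrom, pos in tss[["gene_id", "chrom", "tss"]].to_numpy():
        sub = prox[prox["chrom"] == chrom]
        if len(sub) == 0:
            out[gene] = frozenset()
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        d = np.maximum.reduce([s - pos, pos - e, np.zeros(len(sub))])
        out[gene] = frozenset(sub.loc[d <= window, "region_id"])
    return out


def link_distal_regions(
    proximal: dict[str, frozenset],
    labeled: pd.DataFrame,
    interactions: pd.DataFrame,
    min_score: float | None = None,
) -> dict[str, frozenset]:
    """Attach distal regions to genes through interaction anchor bins.

    A distal region d is linked to gene g iff some interaction has an anchor
    bin overlapping (>= 1 bp) a proximal region of g and d overlaps either of
    that interaction's bins.

    ``interactions`` columns: chrom1 start1 end1 chrom2 start2 end2 [name score].
    """
    if min_score is not None and "score" in interactions.columns:
        interactions = interactions[interactions["score"] > min_score]
    labeled = labeled.reset_index(drop=True)
    distal_mask = (labeled["region_class"] == "distal").to_numpy()
    region_ids = labeled["region_id"].to_numpy()

    bin1 = interactions.rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
    )[REGION_COLS]
    bin2 = interactions.rename(
        columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
    )[REGION_COLS]
    o1 = overlap_matrix(bin1, labeled)  # n_int x n_regions
    o2 = overlap_matrix(bin2, labeled)
    either = o1 | o2

    id_to_idx: dict[str, list[int]] = {}
    for i, rid in enumerate(region_ids):
        id_to_idx.setdefault(rid, []).append(i)

    out: dict[str, frozenset] = {}
    for gene, prox_ids in proximal.items():
        idx = [i for rid in prox_ids for i in id_to_idx.get(rid, [])]
        if not idx:
            out[gene] = frozenset()
            continue
        anchored = either[:, idx].any(axis=1)  # interactions touching g's proximal regions
        hit = either[anchored].any(axis=0) & distal_mask
        out[gene] = frozenset(region_ids[hit])
    return out


def build_gene_region_map(
    regions: pd.DataFrame,
    tss: pd.DataFrame,
    interactions: pd.DataFrame,
    window: int = 500,
    min_score: float | None = None,
) -> GeneRegionMap:
    """Classify merged regions and build the full gene -> region map."""
    labeled = classify_proximal_distal(regions, tss, window=window)
    prox = assign_proximal(labeled, tss, window=window)
    dist = link_distal_regions(prox, labeled, interactions, min_score=min_score)
    return GeneRegionMap(proximal=prox, distal=dist, regions=labeled, tss=tss)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = REGION_COLS
    return df


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score"]
    df.columns = cols[: df.shape[1]]
    return df


def read_tss_tsv(path) -> pd.DataFrame:
    """TSS table TSV: gene_id, chrom, tss, strand."""
    return pd.read_csv(path, sep="\t")
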