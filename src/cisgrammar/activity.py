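"""STARR-seq count QC, activity scoring, and regulatory-grammar statistics.

Counts arrive as per-oligo UMI tables, one column per replicate, with DNA
(input library) and RNA (reporter transcript) assays kept separate.  The
analysis chain is: QC-filter oligos, normalise each replicate to counts per
million, collapse the DNA replicates by averaging, score activity as
log2(RNA CPM / mean DNA CPM) per RNA replicate, and subtract the motif-free
background oligo's score so the background sits at exactly zero.

The grammar statistics compare per-oligo mean activities between design
groups defined on the slot manifest: single oriented motifs (Welch t-test),
copy-number response (OLS slope), slot position (Wilcoxon rank-sum), motif
pairs (Welch t-test), motif order (rank-sum plus a fold-ratio gate), and a
synergy call that requires the pair's effect size to significantly exceed
the strongest single motif's and the pair's mean activity to exceed the sum
of the singles' means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# QC, normalization, activity


def qc_filter(
    dna: pd.DataFrame,
    rna: pd.DataFrame,
    min_dna: int = 10,
    min_rna_reps: int = 2,
) -> pd.Index:
    """Oligos with DNA >= ``min_dna`` in every DNA replicate and RNA > 0 in
    at least ``min_rna_reps`` RNA replicates."""
    common = dna.index.intersection(rna.index)
    keep = ((dna.loc[common] >= min_dna).all(axis=1)) & (
        (rna.loc[common] > 0).sum(axis=1) >= min_rna_reps
    )
    retained = common[keep]
    if len(retained) == 0:
        raise ValueError("QC removed every oligo")
    return retained


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization; every column sums to 1e6 afterwards."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("replicate with zero total count")
    return counts / totals * 1e6


@dataclass
class ActivityMatrix:
    """Per-oligo, per-RNA-replicate adjusted activity scores."""

    adjusted: pd.DataFrame  # oligo x RNA replicate, NaN where undefined
    oligo_mean: pd.Series
    background_oligo_id: str
    background_adjusted: bool = True


def activity(
    dna_cpm: pd.DataFrame,
    rna_cpm: pd.DataFrame,
    background_oligo_id: str,
) -> ActivityMatrix:
    """log2(RNA CPM / mean DNA CPM), background-subtracted per replicate.

    DNA replicates are collapsed by averaging their CPM values.  Scores are
    defined only where both the RNA CPM and the collapsed DNA CPM are
    positive; RNA replicates in which the background oligo itself has no
    score are dropped with a warning.
    """
    if background_oligo_id not in rna_cpm.index or background_oligo_id not in dna_cpm.index:
        raise ValueError("background oligo missing from the count tables")
    mean_dna = dna_cpm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.log2(rna_cpm.div(mean_dna, axis=0))
    raw[(rna_cpm <= 0) | (mean_dna.to_numpy()[:, None] <= 0)] = np.nan
    bg = raw.loc[background_oligo_id]
    missing = bg.index[bg.isna()]
    if len(missing):
        warnings.warn(f"background oligo undefined in replicates {list(missing)}; dropped")
        raw = raw.drop(columns=missing)
        bg = bg.drop(index=missing)
    adjusted = raw.sub(bg, axis=1)
    return ActivityMatrix(
        adjusted=adjusted,
        oligo_mean=adjusted.mean(axis=1),
        background_oligo_id=background_oligo_id,
    )


def cohens_d(x, y) -> float:
    """Standardized mean difference with pooled SD (Bessel-corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per sample")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if sp2 == 0:
        warnings.warn("zero pooled SD; Cohen's d is infinite")
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float(diff / np.sqrt(sp2))


# ---------------------------------------------------------------------------
# design-manifest helpers


def parse_slots(designs: pd.DataFrame) -> pd.Series:
    """oligo_id -> tuple of slot entries (None or (motif, orient)) from a manifest."""
    slot_cols = [c for c in designs.columns if c.startswith("slot")]

    def _parse(row):
        out = []
        for c in slot_cols:
            v = row[c]
            if v == "." or pd.isna(v):
                out.append(None)
            else:
                m, o = str(v).rsplit(":", 1)
                out.append((m, o))
        return tuple(out)

    return pd.Series(
        [_parse(r) for _, r in designs.iterrows()],
        index=designs["oligo_id"].to_numpy(),
    )


def _occupied(slots):
    return [s for s in slots if s is not None]


def _motifs_of(slots):
    return {s[0] for s in _occupied(slots)}


@dataclass
class EffectResult:
    subject: str
    n_in: int
    n_out: int
    mean_in: float
    mean_out: float
    statistic: float
    p_raw: float
    alpha_bonferroni: float
    cohens_d: float
    significant: bool
    testable: bool = True
    extra: dict | None = None


def _untestable(subject, alpha, n_in=0, n_out=0) -> EffectResult:
    return EffectResult(
        subject, n_in, n_out, np.nan, np.nan, np.nan, np.nan, alpha, np.nan,
        significant=False, testable=False,
    )


def motif_effect(
    oligo_mean: pd.Series,
    slots: pd.Series,
    motif: str,
    orientation: str,
    alpha_family: float = 0.05,
    n_tests: int = 1,
    d_min: float = 0.5,
) -> EffectResult:
    """Welch t-test of one oriented motif against motif-free-of-it oligos.

    In-group: oligos whose occupied slots contain ONLY the motif of interest,
    1-3 copies, all in the given orientation.  Out-group: oligos with no
    instance of the motif in any orientation (including the background).
    Significance requires Bonferroni-corrected p and |Cohen's d| > ``d_min``.
    """
    subject = f"{motif}:{orientation}"
    alpha = alpha_family / n_tests
    idx = oligo_mean.index.intersection(slots.index)
    in_ids, out_ids = [], []
    for oid in idx:
        occ = _occupied(slots[oid])
        if occ and all(s == (motif, orientation) for s in occ):
            in_ids.append(oid)
        elif motif not in _motifs_of(slots[oid]):
            out_ids.append(oid)
    x = oligo_mean.loc[in_ids].dropna()
    y = oligo_mean.loc[out_ids].dropna()
    if len(x) < 2 or len(y) < 2:
        return _untestable(subject, alpha, len(x), len(y))
    t, p = stats.ttest_ind(x, y, equal_var=False)
    d = cohens_d(x, y)
    return EffectResult(
        subject, len(x), len(y), float(x.mean()), float(y.mean()),
        float(t), float(p), alpha, d,
        significant=bool(p < alpha and abs(d) > d_min),
    )


def copy_number_fit(
    oligo_mean: pd.Series, slots: pd.Series, motif: str, orientation: str
) -> dict:
    """OLS of mean activity on copy number (1-3 copies, single-motif oligos).

    Returns slope, intercept, r_squared, p (two-sided slope test), stderr and
    the 95% CI of the slope.
    """
    idx = oligo_mean.index.intersection(slots.index)
    xs, ys = [], []
    for oid in idx:
        occ = _occupied(slots[oid])
        if occ and all(s == (motif, orientation) for s in occ):
            if not np.isnan(oligo_mean[oid]):
                xs.append(len(occ))
                ys.append(oligo_mean[oid])
    if len(set(xs)) < 2:
        return {"testable": False, "n": len(xs)}
    fit = stats.linregress(xs, ys)
    tcrit = stats.t.ppf(0.975, len(xs) - 2)
    return {
        "testable": True,
        "n": len(xs),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "stderr": float(fit.stderr),
        "ci95": (float(fit.slope - tcrit * fit.stderr), float(fit.slope + tcrit * fit.stderr)),
    }


def position_effect(
    oligo_mean: pd.Series,
    slots: pd.Series,
    motif: str,
    alpha_family: float = 0.05,
    n_tests: int = 1,
) -> EffectResult:
    """Wilcoxon rank-sum: motif promoter-proximal vs promoter-distal.

    Uses oligos with exactly two occupied slots holding two distinct motifs,
    one of which is the motif of interest; group A has it in the occupied
    slot nearer the promoter (lower slot index), group B in the farther one.
    """
    alpha = alpha_family / n_tests
    idx = oligo_mean.index.intersection(slots.index)
    a_ids, b_ids = [], []
    for oid in idx:
        occ = _occupied(slots[oid])
        if len(occ) != 2 or len(_motifs_of(slots[oid])) != 2:
            continue
        motifs = [s[0] for s in occ]
        if motif not in motifs:
            continue
        (a_ids if motifs[0] == motif else b_ids).append(oid)
    x = oligo_mean.loc[a_ids].dropna()
    y = oligo_mean.loc[b_ids].dropna()
    if len(x) < 1 or len(y) < 1:
        return _untestable(motif, alpha, len(x), len(y))
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    d = cohens_d(x, y) if len(x) > 1 and len(y) > 1 else np.nan
    return EffectResult(
        motif, len(x), len(y), float(x.mean()), float(y.mean()),
        float(u), float(p), alpha, d,
        significant=bool(p < alpha),
    )


def pair_effect(
    oligo_mean: pd.Series,
    slots: pd.Series,
    pair: tuple[tuple[str, str], tuple[str, str]],
    alpha_family: float = 0.05,
    n_tests: int = 1,
    d_min: float = 0.5,
) -> EffectResult:
    """Welch t-test of an oriented motif pair against oligos lacking it.

    In-group: occupied slots comprise exactly the two motifs, each 1-2
    copies in its fixed orientation, total <= 3 occupied slots.  Out-group:
    oligos lacking at least one of the two motifs in any orientation.
    """
    (m1, o1), (m2, o2) = pair
    if m1 == m2:
        raise ValueError("pair must use two distinct motifs")
    subject = f"{m1}:{o1}+{m2}:{o2}"
    alpha = alpha_family / n_tests
    idx = oligo_mean.index.intersection(slots.index)
    in_ids, out_ids = [], []
    for oid in idx:
        occ = _occupied(slots[oid])
        motifs = _motifs_of(slots[oid])
        c1 = occ.count((m1, o1))
        c2 = occ.count((m2, o2))
        if (
            motifs == {m1, m2}
            and c1 + c2 == len(occ)  # orientations all as fixed
            and 1 <= c1 <= 2
            and 1 <= c2 <= 2
        ):
            in_ids.append(oid)
        elif not ({m1, m2} <= motifs):
            out_ids.append(oid)
    x = oligo_mean.loc[in_ids].dropna()
    y = oligo_mean.loc[out_ids].dropna()
    if len(x) < 2 or len(y) < 2:
        return _untestable(subject, alpha, len(x), len(y))
    t, p = stats.ttest_ind(x, y, equal_var=False)
    d = cohens_d(x, y)
    return EffectResult(
        subject, len(x), len(y), float(x.mean()), float(y.mean()),
        float(t), float(p), alpha, d,
        significant=bool(p < alpha and abs(d) > d_min),
    )


def order_effect(
    oligo_mean: pd.Series,
    slots: pd.Series,
    ordered_pair: tuple[str, str],
    alpha_family: float = 0.05,
    n_tests: int = 1,
    ratio_min: float = 2.0,
) -> EffectResult:
    """Rank-sum test of motif order for oligos with one copy each of two motifs.

    Group 1 carries ``ordered_pair[0]`` nearer the promoter; group 2 the
    reverse order.  Significance requires Bonferroni-corrected p and
    |mean1 / mean2| > ``ratio_min``.
    """
    m_a, m_b = ordered_pair
    subject = f"{m_a}->{m_b}"
    alpha = alpha_family / n_tests
    idx = oligo_mean.index.intersection(slots.index)
    g1, g2 = [], []
    for oid in idx:
        occ = _occupied(slots[oid])
        motifs = [s[0] for s in occ]
        if len(occ) != 2 or set(motifs) != {m_a, m_b}:
            continue
        (g1 if motifs[0] == m_a else g2).append(oid)
    x = oligo_mean.loc[g1].dropna()
    y = oligo_mean.loc[g2].dropna()
    if len(x) < 1 or len(y) < 1:
        return _untestable(subject, alpha, len(x), len(y))
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    if y.mean() == 0:
        warnings.warn("order group 2 has zero mean activity; ratio is infinite")
        ratio = np.inf
    else:
        ratio = abs(x.mean() / y.mean())
    d = cohens_d(x, y) if len(x) > 1 and len(y) > 1 else np.nan
    return EffectResult(
        subject, len(x), len(y), float(x.mean()), float(y.mean()),
        float(u), float(p), alpha, d,
        significant=bool(p < alpha and ratio > ratio_min),
        extra={"ratio": float(ratio)},
    )


def _se_d(d: float, n_in: int, n_out: int) -> float:
    """Large-sample SE of Cohen's d."""
    n = n_in + n_out
    return float(np.sqrt(n / (n_in * n_out) + d**2 / (2 * n)))


def synergy_test(
    pair_result: EffectResult,
    result_m1: EffectResult,
    result_m2: EffectResult,
    z_alpha: float = 0.05,
) -> tuple[bool, float]:
    """Is the pair's effect more than its strongest member's?

    Condition 1: one-sided Z-test that |d_pair| exceeds |d_best| (the larger
    individual |d|), using large-sample SEs of d.  Condition 2: the pair's
    in-group mean exceeds the sum of the individual in-group means.  Synergy
    requires both.  Returns (synergy, z_p).
    """
    for r in (pair_result, result_m1, result_m2):
        if not r.testable:
            raise ValueError(f"result for {r.subject!r} is untestable")
        if not np.isfinite(r.cohens_d):
            raise ValueError(f"infinite Cohen's d for {r.subject!r}")
    best = max(result_m1, result_m2, key=lambda r: abs(r.cohens_d))
    se_pair = _se_d(pair_result.cohens_d, pair_result.n_in, pair_result.n_out)
    se_best = _se_d(best.cohens_d, best.n_in, best.n_out)
    z = (abs(pair_result.cohens_d) - abs(best.cohens_d)) / np.hypot(se_pair, se_best)
    z_p = float(stats.norm.sf(z))
    additive = pair_result.mean_in > result_m1.mean_in + result_m2.mean_in
    return bool(z_p < z_alpha and additive), z_p


def effect_results_frame(results: list[EffectResult]) -> pd.DataFrame:
    """Flatten EffectResults into a report table."""
    rows = []
    for r in results:
        row = {
            "subject": r.subject, "n_in": r.n_in, "n_out": r.n_out,
            "mean_in": r.mean_in, "mean_out": r.mean_out,
            "statistic": r.statistic, "p_raw": r.p_raw,
            "alpha_bonferroni": r.alpha_bonferroni, "cohens_d": r.cohens_d,
            "significant": r.significant, "testable": r.testable,
        }
        if r.extra:
            row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)
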