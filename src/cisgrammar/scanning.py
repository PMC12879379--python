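"""Two-strand PWM scanning with exact score-distribution p-values.

The p-value of a score s is P(a random iid-background L-mer scores >= s),
computed by dynamic programming over the discretized per-column score
distribution — the same semantics FIMO uses.  Column scores are rounded to a
fixed granularity (default 1e-3 log2 units), which is the only source of
p-value error; sequences containing an impossible letter (a -inf PWM entry,
possible only at pseudocount 0) carry their probability mass at score -inf.

Hits are reported on both strands; the reverse-strand score of a window is
the forward score of its reverse complement, obtained by scoring with the
position- and letter-reversed matrix.  Overlapping hits are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cisgrammar.motifs import PWM

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

HIT_COLUMNS = ["motif_id", "region_id", "offset", "strand", "score", "p_value", "width"]


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScoreDistribution:
    """Discretized null score distribution of a PWM under its background."""

    granularity: float
    min_int: int  # integer score of index 0
    sf: np.ndarray  # sf[i] = P(int score >= min_int + i)
    p_neginf: float  # mass of sequences containing an impossible letter

    def pvalue(self, score: float) -> float:
        if not np.isfinite(score):
            return 1.0 if score < 0 else float(self.sf[-1])
        t = int(np.rint(score / self.granularity)) - self.min_int
        if t <= 0:
            # everything at or below the minimum attainable finite score;
            # only -inf sequences (pseudocount 0) fall outside this mass
            return float(self.sf[0])
        if t >= len(self.sf):
            # above the attainable maximum only by rounding; clamp to the top tail
            return float(self.sf[-1])
        return float(self.sf[t])

    def score_threshold(self, p_thresh: float) -> float:
        """Smallest float score whose p-value is <= p_thresh."""
        idx = np.searchsorted(-self.sf, -p_thresh, side="left")
        return (self.min_int + idx) * self.granularity


def score_distribution(pwm: PWM, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact DP over discretized column scores under the iid background."""
    finite = np.isfinite(pwm.matrix)
    ints = np.zeros_like(pwm.matrix, dtype=np.int64)
    ints[finite] = np.rint(pwm.matrix[finite] / granularity).astype(np.int64)

    col_min = np.where(finite, ints, np.iinfo(np.int64).max).min(axis=1)
    col_max = np.where(finite, ints, np.iinfo(np.int64).min).max(axis=1)
    total_min, total_max = int(col_min.sum()), int(col_max.sum())
    span = total_max - total_min + 1

    dist = np.zeros(span)
    dist[0] = 1.0  # offset: current sum - (running min)
    p_neginf = 0.0
    run_min = 0
    for j in range(len(pwm)):
        new = np.zeros(span)
        col_mass = 0.0
        for b in range(4):
            if not finite[j, b]:
                continue
            shift = int(ints[j, b] - col_min[j])
            new[shift:] += pwm.background[b] * dist[: span - shift if shift else span]
            col_mass += pwm.background[b]
        # letters with -inf entries divert their mass (given the prefix survived)
        p_neginf += (1 - col_mass) * dist.sum()
        dist = new
        run_min += int(col_min[j])

    sf = np.cumsum(dist[::-1])[::-1]
    return ScoreDistribution(granularity, total_min, sf, p_neginf)


def score_pvalue(pwm: PWM, score: float, granularity: float = 1e-3) -> float:
    """P(random background L-mer scores >= ``score``); 1.0 at or below the minimum."""
    return score_distribution(pwm, granularity).pvalue(score)


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Float score of every window; NaN where the window contains non-ACGT."""
    L = matrix.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win < 4).all(axis=1)
    scores = np.full(n, np.nan)
    if valid.any():
        idx = win[valid].astype(np.intp)
        with np.errstate(invalid="ignore"):
            scores[valid] = matrix[np.arange(L), idx].sum(axis=1)
    return scores


def scan(
    pwm: PWM,
    sequence: str,
    region_id: str = "seq",
    p_thresh: float = 1e-4,
    score_min: float | None = None,
    granularity: float = 1e-3,
    dist: ScoreDistribution | None = None,
) -> pd.DataFrame:
    """Report motif hits on both strands of ``sequence``.

    A hit is a window with p_value <= ``p_thresh`` and, when ``score_min`` is
    given, score strictly greater than it.  Offsets are 0-based positions of
    the window start on the forward strand.  Windows containing N are skipped.
    """
    if dist is None:
        dist = score_distribution(pwm, granularity)
    codes = encode(sequence)
    rows = []
    for strand, matrix in (("+", pwm.matrix), ("-", pwm.matrix[::-1, ::-1])):
        scores = _window_scores(codes, matrix)
        for off in np.flatnonzero(~np.isnan(scores)):
            s = float(scores[off])
            p = dist.pvalue(s)
            if p <= p_thresh and (score_min is None or s > score_min):
                rows.append((pwm.motif_id, region_id, int(off), strand, s, p, len(pwm)))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def scan_all(
    pwms: list[PWM],
    sequences: dict[str, str],
    p_thresh: float = 1e-4,
    score_min: float | None = None,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Scan every PWM against every sequence; one distribution DP per PWM."""
    frames = []
    for pwm in pwms:
        dist = score_distribution(pwm, granularity)
        for rid, seq in sequences.items():
            frames.append(
                scan(pwm, seq, rid, p_thresh=p_thresh, score_min=score_min, dist=dist)
            )
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def derive_score_cutoff(hits: pd.DataFrame) -> float:
    """Arithmetic mean hit score — the data-driven score cutoff of the pipeline."""
    if len(hits) == 0:
        raise ValueError("cannot derive a score cutoff from zero hits")
    return float(hits["score"].mean())
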