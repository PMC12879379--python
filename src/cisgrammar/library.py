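"""Design the combinatorial oriented-motif reporter library.

An oligo is a fixed-length insert (default 88 bp) carrying 0-3 motif site
sequences in ordered slots; slot 1 is closest to the core promoter.  Each
slot is either empty or holds one candidate site in forward ("template") or
reverse-complement ("non-template") orientation; consecutive sites are
separated by 10 bp spacers drawn from the synthetic background sequence so
that all unused positions show identical background context.  With m
candidate motifs and s slots the enumeration yields (2m + 1)**s designs,
including the all-empty background design.

The background itself is designed iteratively: draw a random sequence,
scan it with every screened motif, mutate only the bases inside hit windows,
repeat until no motif hits remain.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cisgrammar.motifs import ALPHABET, PWM, revcomp
from cisgrammar.scanning import score_distribution

Slot = tuple[str, str] | None  # (motif_id, "fwd"|"rev") or empty

AGE_I = "ACCGGT"
SAL_I = "GTCGAC"


@dataclass
class BackgroundSequence:
    sequence: str
    screened_motifs: list[str]
    seed: int | None
    rounds: int = 0


@dataclass
class OligoDesign:
    oligo_id: str
    assignment: tuple[Slot, ...]
    sequence: str
    copies: dict = field(default_factory=dict)
    is_control: bool = False


def design_background(
    motifs: list[PWM],
    length: int = 125,
    p_thresh: float = 1e-4,
    score_min: float | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_rounds: int = 100,
) -> BackgroundSequence:
    """Iteratively mutate a random sequence until no screened motif hits remain.

    Each round scans both strands of the current sequence with every motif
    and substitutes every base inside a hit window with a uniformly chosen
    *different* base.  Deterministic given the seed.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(ALPHABET), size=length))
    dists = [score_distribution(m) for m in motifs]
    for round_no in range(max_rounds):
        hits = _scan_background(motifs, dists, "".join(seq), p_thresh, score_min)
        if not hits:
            return BackgroundSequence("".join(seq), [m.motif_id for m in motifs], seed, round_no)
        bad = sorted({i for off, w in hits for i in range(off, off + w)})
        for i in bad:
            others = [b for b in ALPHABET if b != seq[i]]
            seq[i] = others[rng.integers(len(others))]
    remaining = _scan_background(motifs, dists, "".join(seq), p_thresh, score_min)
    raise RuntimeError(
        f"background design failed after {max_rounds} rounds; "
        f"{len(remaining)} hit windows remain"
    )


def _scan_background(motifs, dists, seq, p_thresh, score_min):
    from cisgrammar.scanning import scan

    hits = []
    for pwm, dist in zip(motifs, dists):
        df = scan(pwm, seq, p_thresh=p_thresh, score_min=score_min, dist=dist)
        hits.extend((int(o), len(pwm)) for o in df["offset"])
    return hits


def enumerate_designs(
    motif_ids: list[str], n_slots: int = 3, include_empty: bool = True
) -> list[tuple[Slot, ...]]:
    """All slot assignments: each slot is empty or an oriented motif.

    Deterministic order (itertools.product over a fixed per-slot alphabet).
    ``include_empty=False`` drops the all-empty background design.
    """
    if not motif_ids:
        raise ValueError("need at least one motif")
    options: list[Slot] = [None] + [
        (m, o) for m in motif_ids for o in ("fwd", "rev")
    ]
    designs = list(itertools.product(options, repeat=n_slots))
    if not include_empty:
        designs = [d for d in designs if any(s is not None for s in d)]
    return designs


def render_oligo(
    assignment: tuple[Slot, ...],
    background: str,
    site_sequences: dict[str, str],
    spacing: int = 10,
    oligo_len: int = 88,
    left_margin: int = 0,
    oligo_id: str = "",
) -> OligoDesign:
    """Render a slot assignment into a fixed-length insert sequence.

    Occupied slots are packed left to right starting at ``left_margin``, each
    followed by a ``spacing``-bp spacer taken from the background at the
    corresponding coordinates; empty slots contribute nothing, and the
    remainder is filled with the background so the all-empty assignment
    renders ``background[:oligo_len]`` exactly.
    """
    if len(background) < oligo_len:
        raise ValueError("background shorter than the oligo length")
    parts = [background[:left_margin]]
    cursor = left_margin
    occupied = [s for s in assignment if s is not None]
    for i, (motif_id, orient) in enumerate(occupied):
        site = site_sequences[motif_id]
        if orient == "rev":
            site = revcomp(site)
        parts.append(site)
        cursor += len(site)
        if i < len(occupied) - 1:
            parts.append(background[cursor : cursor + spacing])
            cursor += spacing
        if cursor > oligo_len:
            raise ValueError(f"assignment {assignment!r} overflows the {oligo_len}-bp oligo")
    parts.append(background[cursor:oligo_len])
    seq = "".join(parts)
    copies: dict[str, int] = {}
    for s in occupied:
        copies[s[0]] = copies.get(s[0], 0) + 1
    return OligoDesign(oligo_id, assignment, seq, copies)


def tile_sequence(sequence: str, tile_len: int = 88, step: int = 1) -> list[str]:
    """Every ``tile_len`` window of ``sequence``; duplicates dropped, order kept."""
    if len(sequence) < tile_len:
        raise ValueError("sequence shorter than the tile length")
    tiles = [sequence[i : i + tile_len] for i in range(0, len(sequence) - tile_len + 1, step)]
    return list(dict.fromkeys(tiles))


def add_cloning_flanks(
    sequence: str,
    five_site: str = AGE_I,
    three_site: str = SAL_I,
    adapters: tuple[str, str] = ("", ""),
) -> str:
    """Wrap an insert with restriction sites and optional outer adapters."""
    if five_site in sequence or three_site in sequence:
        warnings.warn("restriction site occurs inside the insert; cloning may cut it")
    return adapters[0] + five_site + sequence + three_site + adapters[1]


def strip_cloning_flanks(
    construct: str,
    five_site: str = AGE_I,
    three_site: str = SAL_I,
    adapters: tuple[str, str] = ("", ""),
) -> str:
    """Inverse of :func:`add_cloning_flanks`."""
    start = len(adapters[0]) + len(five_site)
    end = len(construct) - len(adapters[1]) - len(three_site)
    return construct[start:end]


def build_library(
    site_sequences: dict[str, str],
    background: str,
    n_slots: int = 3,
    spacing: int = 10,
    oligo_len: int = 88,
    left_margin: int = 0,
    controls: list[str] | None = None,
) -> pd.DataFrame:
    """Render the full combinatorial library into a manifest DataFrame.

    Columns: oligo_id, slot1..slotN ("motif:orient" or "."), sequence,
    is_control.  Warns when two distinct assignments collide on sequence.
    """
    motif_ids = sorted(site_sequences)
    designs = enumerate_designs(motif_ids, n_slots=n_slots)
    rows = []
    for i, assignment in enumerate(designs):
        oligo = render_oligo(
            assignment, background, site_sequences,
            spacing=spacing, oligo_len=oligo_len, left_margin=left_margin,
            oligo_id=f"OL{i:06d}",
        )
        slot_strs = ["." if s is None else f"{s[0]}:{s[1]}" for s in assignment]
        rows.append([oligo.oligo_id, *slot_strs, oligo.sequence, False])
    for j, ctrl in enumerate(controls or []):
        rows.append([f"CT{j:04d}", *["."] * n_slots, ctrl, True])
    cols = ["oligo_id", *[f"slot{i + 1}" for i in range(n_slots)], "sequence", "is_control"]
    df = pd.DataFrame(rows, columns=cols)
    dup = df.duplicated(subset="sequence", keep=False) & ~df["is_control"]
    if dup.any():
        warnings.warn(f"{int(dup.sum())} designs collide on rendered sequence")
    return df
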