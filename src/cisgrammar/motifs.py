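"""Position probability matrices, log-odds PWMs, and MEME minimal-format IO.

Columns are indexed by position, letters by the fixed alphabet order ACGT.
Reverse complementation of a matrix is ``matrix[::-1, ::-1]``: reversing the
letter axis swaps A<->T and C<->G because of that alphabet order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BG = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PPM:
    """A position probability matrix: L columns of letter probabilities."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    source: str = "novel"  # "novel" | "known"
    total_weight: float = 1.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PPM matrix must have shape (L, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PPM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PPM columns must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PPM":
        return PPM(self.motif_id, self.matrix[::-1, ::-1], self.source, self.total_weight)


@dataclass
class PWM:
    """Log2-odds matrix derived from a PPM against a 0-order background."""

    motif_id: str
    matrix: np.ndarray  # (L, 4) log2-odds; -inf allowed only when pseudocount == 0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pseudocount: float = 1e-4

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())


def ppm_to_pwm(
    ppm: PPM, background: np.ndarray | None = None, pseudocount: float = 1e-4
) -> PWM:
    """Log-odds transform: log2(((p + c) / (1 + 4c)) / bg).

    The pseudocount ``c`` is a small probability added to every cell before
    renormalization, guarding against -inf scores for zero-probability
    letters; with ``c = 0`` those cells become -inf (impossible letters).
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 letter probabilities summing to 1")
    with np.errstate(divide="ignore"):
        m = np.log2(((ppm.matrix + pseudocount) / (1 + 4 * pseudocount)) / bg)
    return PWM(ppm.motif_id, m, bg, pseudocount)


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(ppms: list[PPM], handle_or_path, background: np.ndarray | None = None) -> None:
    """Write PPMs in MEME minimal motif format."""
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for p in ppms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} "
                f"nsites= {max(1, int(round(p.total_weight)))} E= 0\n"
            )
            for row in p.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


def read_meme(handle_or_path, source: str = "known") -> list[PPM]:
    """Read motifs from a MEME minimal-format file into PPMs.

    Only the fields this toolkit uses are parsed: motif ids, the
    letter-probability matrix, and ``nsites`` (stored as ``total_weight``).
    """
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path) if own else handle_or_path
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()

    ppms: list[PPM] = []
    lines = io.StringIO(text).read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(ppms)}"
            nsites = 1.0
            # seek the matrix header
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i == len(lines):
                break
            header = lines[i]
            for tok_k, tok_v in zip(header.split(), header.split()[1:]):
                if tok_k == "nsites=":
                    nsites = float(tok_v)
            i += 1
            rows = []
            while i < len(lines):
                vals = lines[i].split()
                try:
                    row = [float(v) for v in vals]
                except ValueError:
                    break
                if len(row) != 4:
                    break
                rows.append(row)
                i += 1
            mat = np.array(rows)
            mat = mat / mat.sum(axis=1, keepdims=True)  # tolerate rounded input
            ppms.append(PPM(motif_id, mat, source=source, total_weight=nsites))
        else:
            i += 1
    return ppms
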