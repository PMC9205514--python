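"""JASPAR-style position frequency matrices.

A transcription-factor motif is represented by a position frequency matrix
(PFM): per-position counts of A, C, G and T observed in aligned binding
sites.  Scoring needs the probability form q(k, b) — the probability of
observing base ``b`` at motif position ``k`` — which is obtained by adding a
small pseudocount to every cell and normalising each position to sum to one,
so that every log-likelihood ratio stays finite.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, List, Sequence, TextIO, Union

import numpy as np

ALPHABET = "ACGT"

#: Pseudocount added to every matrix cell before normalisation (0.8 per
#: position, spread uniformly over the four bases).  Large enough to keep
#: log-likelihood ratios finite, small enough not to wash out informative
#: columns of typical JASPAR matrices (total counts in the tens to
#: thousands).
DEFAULT_PSEUDOCOUNT = 0.2


class MotifParseError(ValueError):
    """Raised when a JASPAR PFM file cannot be parsed; names the line."""


def normalize_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    """Turn a w×4 count matrix into a w×4 probability matrix.

    Each cell becomes ``(count + pseudocount) / sum_b(count_b + pseudocount)``
    within its position (row).  ``pseudocount`` is per cell and must be
    positive whenever any cell of the matrix is zero, otherwise a zero
    probability would make downstream log-likelihood ratios infinite.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
        raise ValueError(f"counts must be a w×4 matrix, got shape {counts.shape}")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    adjusted = counts + pseudocount
    if np.any(adjusted <= 0):
        raise ValueError(
            "zero cell with zero pseudocount: probabilities would not be strictly positive"
        )
    return adjusted / adjusted.sum(axis=1, keepdims=True)


@dataclasses.dataclass(frozen=True, eq=False)
class Motif:
    """A PFM plus its pseudocounted probability matrix.

    ``counts`` and ``probs`` are w×4 arrays over the fixed alphabet order
    A, C, G, T.  ``probs[k, b]`` is q(k, b), the probability of base ``b`` at
    motif position ``k``; every row sums to one and every entry is positive.
    """

    id: str
    name: str
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    probs: np.ndarray = dataclasses.field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"motif counts must be w×4, got shape {counts.shape}")
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError("every motif position needs at least one positive count")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", normalize_counts(counts, self.pseudocount))

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


def reverse_complement(motif: Motif) -> Motif:
    """Motif describing the same sites read on the opposite strand.

    Positions are reversed and A<->T, C<->G swapped; in A,C,G,T order the
    base swap is simply a column reversal.  Applying twice is the identity.
    """
    return Motif(
        id=motif.id,
        name=motif.name,
        counts=motif.counts[::-1, ::-1].copy(),
        pseudocount=motif.pseudocount,
    )


def _parse_count_row(line: str, lineno: int, expected_base: str) -> List[float]:
    stripped = line.strip()
    if not stripped or stripped[0].upper() != expected_base:
        raise MotifParseError(
            f"line {lineno}: expected a '{expected_base}' count row, got {stripped[:40]!r}"
        )
    body = stripped[1:].strip()
    if body.startswith("["):
        if not body.endswith("]"):
            raise MotifParseError(f"line {lineno}: unbalanced brackets in count row")
        body = body[1:-1]
    fields = body.split()
    if not fields:
        raise MotifParseError(f"line {lineno}: empty count row")
    try:
        return [float(x) for x in fields]
    except ValueError as exc:
        raise MotifParseError(f"line {lineno}: non-numeric count in row: {exc}") from None


def read_jaspar(
    source: Union[str, TextIO], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> List[Motif]:
    """Read one or more motifs from a JASPAR PFM text file.

    The dialect is a ``>ID NAME`` header followed by four count rows in
    strict A, C, G, T order, e.g. ``A [ 4 19 0 ]``.  Counts may be floats.
    Malformed records raise :class:`MotifParseError` naming the line.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as handle:
            lines = handle.read().splitlines()

    motifs: List[Motif] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise MotifParseError(f"line {i + 1}: expected '>' header, got {line[:40]!r}")
        header = line[1:].split(None, 1)
        if not header or not header[0]:
            raise MotifParseError(f"line {i + 1}: empty motif header")
        motif_id = header[0]
        motif_name = header[1].strip() if len(header) > 1 else motif_id
        rows = []
        row_idx = i + 1
        for base in ALPHABET:
            while row_idx < n and not lines[row_idx].strip():
                row_idx += 1
            if row_idx >= n or lines[row_idx].strip().startswith(">"):
                raise MotifParseError(
                    f"line {row_idx + 1}: missing '{base}' count row for motif {motif_id}"
                )
            rows.append(_parse_count_row(lines[row_idx], row_idx + 1, base))
            row_idx += 1
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise MotifParseError(
                f"line {row_idx}: ragged count rows for motif {motif_id} "
                f"(column counts {sorted(len(r) for r in rows)})"
            )
        counts = np.array(rows, dtype=float).T  # rows were per-base; motif wants w x 4
        try:
            motifs.append(
                Motif(id=motif_id, name=motif_name, counts=counts, pseudocount=pseudocount)
            )
        except ValueError as exc:
            raise MotifParseError(f"motif {motif_id}: {exc}") from None
        i = row_idx
    return motifs


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_jaspar(motifs: Iterable[Motif], path: str) -> None:
    """Write motifs in JASPAR PFM dialect; counts round-trip exactly."""
    with open(path, "w") as handle:
        for motif in motifs:
            handle.write(f">{motif.id} {motif.name}\n")
            for b, base in enumerate(ALPHABET):
                vals = " ".join(_format_number(v) for v in motif.counts[:, b])
                handle.write(f"{base} [ {vals} ]\n")


def motif_from_probs(
    motif_id: str, name: str, probs: Sequence[Sequence[float]], total: float = 100.0
) -> Motif:
    """Build a Motif whose probability matrix is (up to pseudocount) ``probs``.

    Convenience for constructing exact test motifs: counts are ``probs *
    total`` with pseudocount 0, so ``motif.probs`` equals the given matrix.
    """
    probs = np.asarray(probs, dtype=float)
    return Motif(id=motif_id, name=name, counts=probs * total, pseudocount=0.0)
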