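"""Raw-score computation: the log of the average likelihood ratio.

For a motif of width ``w`` and a promoter of length ``l`` the raw score is

    RS = ln( (1/M) * sum_s prod_k q(k, L_k) / p(L_k) )

where the sum runs over all windows ``s`` (M = l - w + 1 on one strand,
doubled when both strands are scanned), ``q(k, b)`` is the motif probability
matrix and ``p(b)`` is the background probability of base ``b`` estimated
from that sequence's own composition.  RS is high when the sequence contains
one or more windows resembling the motif much more than the background, and
it dilutes toward the background value as non-motif sequence is added.

Windows containing N are excluded from the average (rather than scored as
likelihood ratio 1) so masked regions do not drag RS toward zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import logsumexp

from .motifs import ALPHABET, Motif, reverse_complement

_ENCODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("N")] = -1
_ENCODE[ord("n")] = -1


def encode_sequence(seq: str) -> np.ndarray:
    """Map a sequence over A,C,G,T,N (any case) to integers 0..3, N -> -1."""
    if not seq:
        raise ValueError("empty sequence")
    idx = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(idx == -2):
        bad = sorted(set(seq) - set("ACGTNacgtn"))
        raise ValueError(f"sequence contains characters outside A,C,G,T,N: {bad}")
    return idx


@dataclasses.dataclass(frozen=True, eq=False)
class SequenceComposition:
    """Per-base background probabilities p(b) in A,C,G,T order."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be 4 non-negative probabilities summing to 1")
        object.__setattr__(self, "p", p)

    def log_p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.p)


def composition(seq: str) -> SequenceComposition:
    """Base composition of a sequence, N excluded, floored at 1/(2l).

    Frequencies of A,C,G,T among the non-N characters are floored at
    ``1/(2*len(seq))`` (so a base absent from the sequence still has a small
    positive probability and likelihood ratios stay finite) and renormalised
    to sum to one.
    """
    idx = encode_sequence(seq)
    valid = idx[idx >= 0]
    if valid.size == 0:
        raise ValueError("cannot estimate composition: sequence is all N")
    freq = np.bincount(valid, minlength=4).astype(float) / valid.size
    floor = 1.0 / (2.0 * len(seq))
    p = np.maximum(freq, floor)
    return SequenceComposition(p / p.sum())


@dataclasses.dataclass(frozen=True)
class ScoreResult:
    """Raw score plus the best-scoring site.

    ``rs`` is on the natural-log scale.  ``n_windows`` is the number of
    valid windows that entered the average (both strands counted in
    both-strand mode).  Coordinates are 0-based half-open on the input
    sequence; ``best_strand`` is '+' or '-'.
    """

    rs: float
    n_windows: int
    best_start: int
    best_end: int
    best_strand: str


def window_lr(motif: Motif, seq: str, s: int, comp: SequenceComposition) -> float:
    """Likelihood ratio of one forward-strand window [s, s+w).

    Reference (scalar) implementation of the inner product
    prod_k q(k, L_k) / p(L_k); windows containing N are invalid and raise.
    """
    idx = encode_sequence(seq)
    w = motif.width
    if s < 0 or s + w > len(idx):
        raise ValueError(f"window [{s}, {s + w}) outside sequence of length {len(idx)}")
    window = idx[s : s + w]
    if np.any(window < 0):
        raise ValueError(f"window [{s}, {s + w}) contains N and has no likelihood ratio")
    lr = 1.0
    for k, b in enumerate(window):
        lr *= motif.probs[k, b] / comp.p[b]
    return lr


def window_llrs(
    motif: Motif, idx: np.ndarray, comp: SequenceComposition, step: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood ratios of all valid forward windows of ``idx``.

    Returns ``(starts, llrs)`` restricted to windows free of N, visiting
    start positions 0, step, 2*step, ...
    """
    w = motif.width
    l = len(idx)
    if l < w:
        return np.empty(0, dtype=int), np.empty(0)
    starts = np.arange(0, l - w + 1, step)
    has_n = np.concatenate(([0], np.cumsum(idx < 0)))
    valid = (has_n[starts + w] - has_n[starts]) == 0
    starts = starts[valid]
    if starts.size == 0:
        return starts, np.empty(0)
    logq = motif.log_probs()
    logp = comp.log_p()
    safe = np.maximum(idx, 0)
    llrs = np.zeros(starts.size)
    for k in range(w):
        col = safe[starts + k]
        llrs += logq[k, col] - logp[col]
    return starts, llrs


def raw_score(
    motif: Motif,
    seq: str,
    strand_mode: str = "both",
    step: int = 1,
    comp: SequenceComposition | None = None,
) -> ScoreResult:
    """Raw score of ``motif`` on ``seq`` and the best-scoring site.

    ``strand_mode`` is ``"forward"`` or ``"both"`` (default: TF binding is
    strand-agnostic).  ``step`` visits every ``step``-th window start.
    ``comp`` overrides the sequence's own composition (used for testing and
    for scoring against a fixed background model).

    Raises ``ValueError`` when the sequence is shorter than the motif or has
    no N-free window; callers scanning many sequences skip such entries.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if step < 1:
        raise ValueError("step must be >= 1")
    idx = encode_sequence(seq)
    if comp is None:
        comp = composition(seq)
    starts_f, llrs_f = window_llrs(motif, idx, comp, step)
    all_starts = [starts_f]
    all_llrs = [llrs_f]
    all_strands = [np.zeros(starts_f.size, dtype=np.int8)]
    if strand_mode == "both":
        rc = reverse_complement(motif)
        starts_r, llrs_r = window_llrs(rc, idx, comp, step)
        all_starts.append(starts_r)
        all_llrs.append(llrs_r)
        all_strands.append(np.ones(starts_r.size, dtype=np.int8))
    starts = np.concatenate(all_starts)
    llrs = np.concatenate(all_llrs)
    strands = np.concatenate(all_strands)
    m = starts.size
    if m == 0:
        raise ValueError(
            f"no valid window: sequence length {len(idx)} vs motif width {motif.width}, "
            "or all windows contain N"
        )
    rs = float(logsumexp(llrs) - np.log(m))
    # best site: maximal LR, ties broken by smallest start then forward strand
    best_llr = llrs.max()
    tie = llrs == best_llr
    tie_starts = starts[tie]
    tie_strands = strands[tie]
    best_start = int(tie_starts.min())
    at_start = tie_starts == best_start
    best_strand = "+" if np.any(tie_strands[at_start] == 0) else "-"
    return ScoreResult(
        rs=rs,
        n_windows=int(m),
        best_start=best_start,
        best_end=best_start + motif.width,
        best_strand=best_strand,
    )
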