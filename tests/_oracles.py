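"""Independent brute-force reference implementations used by the tests.

These deliberately use plain Python loops and scalar arithmetic so they
share no code path with the vectorised implementations they check.
"""

import math

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_raw_score(motif, seq, strand_mode="both", comp=None, step=1):
    """RS by direct window enumeration: ln of the mean likelihood ratio.

    Scans forward windows with the motif and (in both-strand mode) forward
    windows with the position-and-base reversed matrix, skipping windows
    containing N.  Returns (rs, n_windows).
    """
    seq = seq.upper()
    w = motif.width
    probs = [[float(motif.probs[k, b]) for b in range(4)] for k in range(w)]
    rc_probs = [[probs[w - 1 - k][3 - b] for b in range(4)] for k in range(w)]
    if comp is None:
        counts = [0, 0, 0, 0]
        total = 0
        for ch in seq:
            if ch in _BASE_INDEX:
                counts[_BASE_INDEX[ch]] += 1
                total += 1
        floor = 1.0 / (2.0 * len(seq))
        p = [max(c / total, floor) for c in counts]
        s = sum(p)
        p = [x / s for x in p]
    else:
        p = [float(x) for x in comp.p]
    matrices = [probs] if strand_mode == "forward" else [probs, rc_probs]
    lrs = []
    for matrix in matrices:
        for start in range(0, len(seq) - w + 1, step):
            window = seq[start : start + w]
            if "N" in window:
                continue
            lr = 1.0
            for k, ch in enumerate(window):
                b = _BASE_INDEX[ch]
                lr *= matrix[k][b] / p[b]
            lrs.append(lr)
    if not lrs:
        raise ValueError("no valid window")
    return math.log(sum(lrs) / len(lrs)), len(lrs)


def step_up_fdr(pvalues):
    """Benjamini-Hochberg step-up by the textbook recipe, input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def best_hit_table(hits):
    """Best subject per query: min E-value, then max bitscore, then lexicographic."""
    best = {}
    for h in hits:
        key = (h.evalue, -h.bitscore, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: k[2] for q, k in best.items()}
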