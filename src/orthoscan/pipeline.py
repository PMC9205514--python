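"""The three-step scan: score, test, FDR-filter.

For every motif x cluster pair the scan (1) computes the raw score of each
sequence in the cluster (``obs``, whose first element ``one`` is the target
promoter) and of background promoters sampled from the universe, (2) runs
the mixed Student's t-test with the CCV and SD diagnostics, and (3) applies
Benjamini-Hochberg FDR across all tests jointly, keeping calls with
q <= threshold.  Background subsets are sampled once per motif per run from
a seed derived deterministically from the root seed, and background raw
scores are computed once per motif and reused across clusters.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Union

import numpy as np

from .motifs import Motif
from .promoters import OrthologCluster, PromoterRecord, sample_background
from .scoring import ScoreResult, raw_score
from .stats import bh_fdr, ccv, mixed_t, p_value, sd_effect

logger = logging.getLogger(__name__)

_FLOAT_COLS = ("rs", "t_prime", "df", "ccv", "sd")
_SCI_COLS = ("p", "q")
_INT_COLS = ("site_start", "site_end")
_STR_COLS = ("motif_id", "motif_name", "gene_id", "site_strand", "site_seq")


@dataclasses.dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``n_subsets`` (-n) and ``subset_size`` (-z) control the background
    sample; ``step`` (-s) is the window step for scanning (1 = every
    position); ``fdr_threshold`` (-t) filters calls on BH q-values;
    ``tail`` (-p: 0 = lower, 1 = two-sided) picks the p-value sidedness.
    ``bkg_pooling`` chooses between pooling all n*z background scores into
    one sample ("pooled") or testing once per subset and averaging
    ("per_subset").  ``fdr_scope`` applies BH jointly over all motif x gene
    tests ("joint") or within each motif ("per_motif").
    """

    n_subsets: int = 10
    subset_size: int = 200
    step: int = 1
    fdr_threshold: float = 0.05
    seed: int = 0
    strand_mode: str = "both"
    tail: str = "lower"
    bkg_pooling: str = "pooled"
    fdr_scope: str = "joint"
    min_orthologs: int = 3

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.strand_mode not in ("forward", "both"):
            raise ValueError("strand_mode must be 'forward' or 'both'")
        if self.tail not in ("lower", "two_sided"):
            raise ValueError("tail must be 'lower' or 'two_sided'")
        if self.bkg_pooling not in ("pooled", "per_subset"):
            raise ValueError("bkg_pooling must be 'pooled' or 'per_subset'")
        if self.fdr_scope not in ("joint", "per_motif"):
            raise ValueError("fdr_scope must be 'joint' or 'per_motif'")


@dataclasses.dataclass(frozen=True)
class BindingCall:
    """One surviving motif x gene test with its best site on the target promoter.

    ``site_start``/``site_end`` are 0-based half-open on the target promoter;
    ``site_seq`` is the forward-strand text of that window.
    """

    motif_id: str
    motif_name: str
    gene_id: str
    rs: float
    t_prime: float
    df: float
    p: float
    q: float
    ccv: float
    sd: float
    site_start: int
    site_end: int
    site_strand: str
    site_seq: str


def _score_record(
    motif: Motif, record: PromoterRecord, config: ScanConfig, cache: Dict[str, ScoreResult]
) -> ScoreResult | None:
    key = record.record_id
    if key not in cache:
        try:
            cache[key] = raw_score(
                motif, record.sequence, strand_mode=config.strand_mode, step=config.step
            )
        except ValueError as exc:
            logger.warning("skipping sequence %s for motif %s: %s", key, motif.id, exc)
            cache[key] = None  # type: ignore[assignment]
    return cache[key]


def scan(
    motifs: Sequence[Motif],
    clusters: Sequence[OrthologCluster],
    background: Sequence[PromoterRecord],
    config: ScanConfig = ScanConfig(),
) -> List[BindingCall]:
    """Run the full scan and return FDR-filtered binding calls.

    Calls are sorted by (motif id, q ascending, gene id).  Clusters smaller
    than ``config.min_orthologs`` sequences, or with degenerate score
    variance, are skipped with a logged warning.
    """
    if not motifs or not clusters:
        raise ValueError("scan needs at least one motif and one cluster")
    root = np.random.SeedSequence(config.seed)
    motif_seeds = [int(child.generate_state(1)[0] % (2**31)) for child in root.spawn(len(motifs))]

    pending: List[dict] = []
    for motif, mseed in zip(motifs, motif_seeds):
        logger.info("motif %s: background seed %d", motif.id, mseed)
        subsets = sample_background(background, config.subset_size, config.n_subsets, mseed)
        cache: Dict[str, ScoreResult] = {}
        subset_scores: List[List[float]] = []
        for subset in subsets:
            scores = []
            for rec in subset:
                res = _score_record(motif, rec, config, cache)
                if res is not None:
                    scores.append(res.rs)
            subset_scores.append(scores)
        pooled_bkg = [s for subset in subset_scores for s in subset]

        for cluster in clusters:
            if cluster.size < config.min_orthologs:
                logger.warning(
                    "skipping cluster %s for motif %s: only %d sequences (< %d)",
                    cluster.target_gene_id, motif.id, cluster.size, config.min_orthologs,
                )
                continue
            target_res = _score_record(motif, cluster.target, config, cache)
            if target_res is None:
                continue
            one = target_res.rs
            obs = [one]
            for rec in cluster.references:
                res = _score_record(motif, rec, config, cache)
                if res is not None:
                    obs.append(res.rs)
            if len(obs) < config.min_orthologs:
                logger.warning(
                    "skipping cluster %s for motif %s: only %d scorable sequences",
                    cluster.target_gene_id, motif.id, len(obs),
                )
                continue
            try:
                if config.bkg_pooling == "pooled":
                    t_prime, df = mixed_t(one, obs, pooled_bkg)
                    p = p_value(t_prime, df, config.tail)
                    sd = sd_effect(one, pooled_bkg)
                else:
                    parts = [
                        (mixed_t(one, obs, s), sd_effect(one, s)) for s in subset_scores
                    ]
                    t_prime = float(np.mean([t for (t, _), _ in parts]))
                    df = float(np.mean([d for (_, d), _ in parts]))
                    p = float(
                        np.mean([p_value(t, d, config.tail) for (t, d), _ in parts])
                    )
                    sd = float(np.mean([s for _, s in parts]))
            except ValueError as exc:
                logger.warning(
                    "skipping cluster %s for motif %s: %s",
                    cluster.target_gene_id, motif.id, exc,
                )
                continue
            pending.append(
                dict(
                    motif_id=motif.id,
                    motif_name=motif.name,
                    gene_id=cluster.target_gene_id,
                    rs=one,
                    t_prime=t_prime,
                    df=df,
                    p=p,
                    ccv=ccv(one, obs),
                    sd=sd,
                    site_start=target_res.best_start,
                    site_end=target_res.best_end,
                    site_strand=target_res.best_strand,
                    site_seq=cluster.target.sequence[
                        target_res.best_start : target_res.best_end
                    ],
                )
            )

    if not pending:
        return []
    if config.fdr_scope == "joint":
        qvals = bh_fdr([rec["p"] for rec in pending])
    else:
        qvals = np.empty(len(pending))
        by_motif: Dict[str, List[int]] = {}
        for i, rec in enumerate(pending):
            by_motif.setdefault(rec["motif_id"], []).append(i)
        for idxs in by_motif.values():
            qvals[idxs] = bh_fdr([pending[i]["p"] for i in idxs])
    calls = [
        BindingCall(q=float(q), **rec)
        for rec, q in zip(pending, qvals)
        if q <= config.fdr_threshold
    ]
    calls.sort(key=lambda c: (c.motif_id, c.q, c.gene_id))
    return calls


def assign_genes(calls: Iterable[BindingCall]) -> Dict[str, Set[str]]:
    """Map each gene to the set of motifs with at least one surviving call."""
    mapping: Dict[str, Set[str]] = {}
    for call in calls:
        mapping.setdefault(call.gene_id, set()).add(call.motif_id)
    return mapping


def _fmt(value: float, sci: bool = False) -> str:
    return f"{value:.6e}" if sci else f"{value:.6g}"


def write_results(calls: Sequence[BindingCall], path: Union[str, Path]) -> None:
    """Write calls as a TSV with one header line; floats at 6 significant
    digits, p and q in scientific notation."""
    fields = [f.name for f in dataclasses.fields(BindingCall)]
    with open(path, "w") as handle:
        handle.write("\t".join(fields) + "\n")
        for call in calls:
            row = []
            for name in fields:
                value = getattr(call, name)
                if name in _SCI_COLS:
                    row.append(_fmt(value, sci=True))
                elif name in _FLOAT_COLS:
                    row.append(_fmt(value))
                else:
                    row.append(str(value))
            handle.write("\t".join(row) + "\n")


def read_results(path: Union[str, Path]) -> List[BindingCall]:
    """Read a TSV written by :func:`write_results` back into calls."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = [f.name for f in dataclasses.fields(BindingCall)]
        if header != expected:
            raise ValueError(f"{path}: unexpected header {header}")
        calls = []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            values = line.split("\t")
            if len(values) != len(expected):
                raise ValueError(f"{path}: line {lineno}: wrong column count")
            kwargs: dict = {}
            for name, raw in zip(expected, values):
                if name in _INT_COLS:
                    kwargs[name] = int(raw)
                elif name in _FLOAT_COLS or name in _SCI_COLS:
                    kwargs[name] = float(raw)
                else:
                    kwargs[name] = raw
            calls.append(BindingCall(**kwargs))
    return calls


def write_calls_bed(calls: Sequence[BindingCall], path: Union[str, Path]) -> None:
    """Export calls as BED6: chrom = gene id, name = motif id, score =
    -10*log10(p) capped at 1000, 0-based half-open site coordinates."""
    with open(path, "w") as handle:
        for call in calls:
            if call.p <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * math.log10(call.p))))
            score = max(0, score)
            handle.write(
                f"{call.gene_id}\t{call.site_start}\t{call.site_end}\t"
                f"{call.motif_id}\t{score}\t{call.site_strand}\n"
            )
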