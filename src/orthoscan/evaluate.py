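"""Benchmarking predictions against experiment-supported binding sites.

A predicted site is a true positive when it overlaps a reference
(ChIP-seq-supported) site by at least 80% of the predicted site's length;
otherwise it is a false positive.  Reference sites with no qualifying
prediction are false negatives.  Matching is greedy one-to-one by
decreasing overlap so each reference site validates at most one prediction.

Performance is summarised by sensitivity Sn = TP/(TP+FN), positive
predictive value PPV = TP/(TP+FP), and geometric accuracy
ACCg = sqrt(Sn * PPV) — the geometric mean of the two (published benchmark
tables of these scanners are reproduced by the geometric mean, not the
plain product).
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

import pandas as pd

_BENCHMARK_RESOURCE = "chipatlas_scanner_benchmark.tsv"


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts plus Sn, PPV and ACCg (NaN where undefined)."""

    tp: int
    fp: int
    fn: int
    sn: float
    ppv: float
    accg: float


def _overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def geometric_accuracy(sn: float, ppv: float) -> float:
    """ACCg, the geometric mean sqrt(Sn * PPV); NaN if either is NaN."""
    if math.isnan(sn) or math.isnan(ppv):
        return math.nan
    if sn < 0 or ppv < 0:
        raise ValueError("Sn and PPV must be non-negative")
    return math.sqrt(sn * ppv)


def metrics(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """(Sn, PPV, ACCg) from counts; undefined denominators give NaN."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    sn = tp / (tp + fn) if tp + fn > 0 else math.nan
    ppv = tp / (tp + fp) if tp + fp > 0 else math.nan
    return sn, ppv, geometric_accuracy(sn, ppv)


def match_sites(
    predicted: Sequence[GenomicInterval],
    reference: Sequence[GenomicInterval],
    min_overlap_frac: float = 0.8,
    reciprocal: bool = False,
    one_to_one: bool = True,
) -> EvalResult:
    """Match predicted to reference sites and count TP/FP/FN.

    A prediction qualifies against a reference site when their overlap is at
    least ``min_overlap_frac`` of the *predicted* length (and of the
    reference length too if ``reciprocal``).  Matching is greedy by
    decreasing overlap, ties broken leftmost; with ``one_to_one`` (default)
    each reference site validates at most one prediction.
    """
    if not (0 < min_overlap_frac <= 1):
        raise ValueError("min_overlap_frac must be in (0, 1]")
    candidates = []
    for i, pred in enumerate(predicted):
        need = min_overlap_frac * pred.length
        for j, ref in enumerate(reference):
            ov = _overlap(pred, ref)
            if ov >= need and (not reciprocal or ov >= min_overlap_frac * ref.length):
                candidates.append((-ov, pred.start, ref.start, i, j))
    candidates.sort()
    matched_pred: set = set()
    matched_ref: set = set()
    for _, _, _, i, j in candidates:
        if i in matched_pred:
            continue
        if one_to_one and j in matched_ref:
            continue
        matched_pred.add(i)
        matched_ref.add(j)
    tp = len(matched_pred)
    fp = len(predicted) - tp
    fn = len(reference) - len(matched_ref)
    sn, ppv, accg = metrics(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, sn=sn, ppv=ppv, accg=accg)


def read_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read BED (3-6 columns, 0-based half-open); strict about coordinates."""
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, strand=strand, name=name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    """Write intervals as BED6 (score column 0)."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def load_published_benchmark() -> pd.DataFrame:
    """Published ChIP-Atlas benchmark of promoter motif scanners.

    Long-format table with columns ``motif``, ``tool``, ``sn``, ``ppv`` and
    ``accg`` as printed in a published comparison of 25 transcription
    factors across three scanners; used to check the ACCg arithmetic and as
    input to the reproduction script.
    """
    with resources.files("orthoscan.data").joinpath(_BENCHMARK_RESOURCE).open() as handle:
        return pd.read_csv(handle, sep="\t")
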