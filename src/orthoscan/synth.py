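"""Synthetic ortholog promoter studies with planted motif sites.

The generator emulates the structure the scanner consumes: clusters of one
target promoter plus reference-species promoters, and a background promoter
set.  In a planted cluster the target always carries a motif instance and
each reference carries one independently with probability ``c`` (the
cross-species conservation rate); unplanted clusters and the background are
kept motif-free by rejection sampling, so the returned truth table is clean
at desk scale.  Sequences are i.i.d. draws from a fixed base composition —
no phylogeny, substitution model or indels — so passing tests demonstrate
the statistical machinery, not robustness to real promoter evolution.

All randomness flows from a single root seed through numpy SeedSequence
spawning, so every study is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .motifs import ALPHABET, Motif, reverse_complement, write_jaspar
from .promoters import (
    OrthologCluster,
    PromoterRecord,
    write_clusters,
    write_promoters,
)
from .scoring import SequenceComposition, encode_sequence, window_llrs

_BASES = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Study design parameters.

    Defaults describe the reference desk-scale study: 200 clusters of 2 kb
    promoters (the upstream window the scanner targets), 30 reference
    species, a quarter of clusters carrying the motif, conservation rate
    0.9, one site per carrying sequence, uniform base composition, and a
    400-promoter motif-free background universe (at least twice the default
    background subset size).
    """

    n_clusters: int = 200
    n_species: int = 30
    promoter_length: int = 2000
    planted_fraction: float = 0.25
    conservation_rate: float = 0.9
    sites_per_sequence: int = 1
    background_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_background: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        if not (0 <= self.planted_fraction <= 1):
            raise ValueError("planted_fraction must be in [0, 1]")
        if not (0 <= self.conservation_rate <= 1):
            raise ValueError("conservation_rate must be in [0, 1]")
        if self.n_clusters < 1 or self.n_species < 1 or self.promoter_length < 1:
            raise ValueError("n_clusters, n_species and promoter_length must be >= 1")
        if self.sites_per_sequence < 1:
            raise ValueError("sites_per_sequence must be >= 1")


def _rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_promoter(
    length: int,
    composition: Sequence[float],
    seed: Union[int, np.random.Generator],
) -> str:
    """I.i.d. random sequence of ``length`` bases from ``composition``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 probabilities summing to 1")
    rng = _rng(seed)
    idx = rng.choice(4, size=length, p=comp)
    return _BASES[idx].tobytes().decode()


def plant_site(
    seq: str,
    motif: Motif,
    position: int,
    seed: Union[int, np.random.Generator],
) -> str:
    """Replace the window at ``position`` with a site sampled from the motif.

    Each base of the window is drawn independently from the motif's
    probability matrix column; the rest of the sequence is unchanged.
    """
    w = motif.width
    if position < 0 or position + w > len(seq):
        raise ValueError(
            f"site at [{position}, {position + w}) does not fit in sequence of length {len(seq)}"
        )
    rng = _rng(seed)
    site = "".join(ALPHABET[rng.choice(4, p=motif.probs[k])] for k in range(w))
    return seq[:position] + site + seq[position + w :]


def make_informative_motif(
    width: int = 8,
    dominant: float = 0.85,
    total: float = 100.0,
    seed: int = 0,
    motif_id: str = "SYN0001",
    name: str = "SYNTF1",
) -> Motif:
    """A synthetic motif with one dominant base per position.

    ``dominant`` is the probability of the consensus base at each position
    (0.85 by default, ~1.1 bits per column — comparable to the informative
    core columns of curated TF matrices); the consensus itself is random.
    """
    if not (0.25 < dominant < 1):
        raise ValueError("dominant must be in (0.25, 1)")
    rng = np.random.default_rng(seed)
    counts = np.full((width, 4), (1 - dominant) / 3 * total)
    consensus = rng.choice(4, size=width)
    counts[np.arange(width), consensus] = dominant * total
    return Motif(id=motif_id, name=name, counts=counts, pseudocount=0.0)


def null_lr_threshold(
    motif: Motif,
    composition: Sequence[float],
    quantile: float = 0.999,
    n_samples: int = 100_000,
    seed: Union[int, np.random.Generator] = 0,
) -> float:
    """Null window log-likelihood-ratio quantile for rejection sampling.

    Samples ``n_samples`` random windows from ``composition`` and returns
    the ``quantile`` of their LLR under the motif (max over both strands).
    """
    rng = _rng(seed)
    comp = np.asarray(composition, dtype=float)
    w = motif.width
    idx = rng.choice(4, size=(n_samples, w), p=comp)
    logp = np.log(comp)
    llrs = np.zeros(n_samples)
    llrs_rc = np.zeros(n_samples)
    logq = motif.log_probs()
    logq_rc = reverse_complement(motif).log_probs()
    for k in range(w):
        col = idx[:, k]
        llrs += logq[k, col] - logp[col]
        llrs_rc += logq_rc[k, col] - logp[col]
    return float(np.quantile(np.maximum(llrs, llrs_rc), quantile))


def _motif_free_indices(
    length: int,
    comp_vec: np.ndarray,
    motif: Motif,
    threshold: float,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> np.ndarray:
    """Random index sequence whose windows all score below ``threshold``
    on both strands (rejection sampling: offending windows are redrawn)."""
    scomp = SequenceComposition(comp_vec)
    rc = reverse_complement(motif)
    w = motif.width
    idx = rng.choice(4, size=length, p=comp_vec).astype(np.int8)
    for _ in range(max_rounds):
        starts_f, llrs_f = window_llrs(motif, idx, scomp)
        starts_r, llrs_r = window_llrs(rc, idx, scomp)
        bad = np.concatenate(
            [starts_f[llrs_f > threshold], starts_r[llrs_r > threshold]]
        )
        if bad.size == 0:
            return idx
        redraw = np.unique(
            np.concatenate([np.arange(s, s + w) for s in np.unique(bad)])
        )
        idx[redraw] = rng.choice(4, size=redraw.size, p=comp_vec).astype(np.int8)
    raise RuntimeError("rejection sampling failed to converge; motif too permissive")


def _indices_to_str(idx: np.ndarray) -> str:
    return _BASES[idx.astype(np.intp)].tobytes().decode()


def _site_positions(
    length: int, width: int, k: int, rng: np.random.Generator
) -> List[int]:
    """k random non-overlapping site start positions."""
    positions: List[int] = []
    for _ in range(200):
        if len(positions) == k:
            break
        pos = int(rng.integers(0, length - width + 1))
        if all(abs(pos - q) >= width for q in positions):
            positions.append(pos)
    if len(positions) < k:
        raise ValueError(f"could not place {k} non-overlapping sites of width {width}")
    return sorted(positions)


def make_study(
    spec: SyntheticSpec, motif: Motif
) -> Tuple[List[OrthologCluster], List[PromoterRecord], pd.DataFrame]:
    """Generate clusters, a background set and the truth table.

    The truth table has one row per (cluster, record) with columns
    ``cluster_id, motif_id, record_id, species, planted, site_start,
    site_end`` (-1 coordinates when no site was planted) plus the
    cluster-level flag ``cluster_planted``.
    """
    comp_vec = np.asarray(spec.background_composition, dtype=float)
    root = np.random.SeedSequence(spec.seed)
    ss_threshold, ss_clusters, ss_background, ss_plant = root.spawn(4)
    threshold = null_lr_threshold(
        motif, comp_vec, seed=np.random.default_rng(ss_threshold)
    )
    cluster_rng = np.random.default_rng(ss_clusters)
    plant_rng = np.random.default_rng(ss_plant)
    n_planted = int(round(spec.planted_fraction * spec.n_clusters))
    planted_ids = set(
        cluster_rng.choice(spec.n_clusters, size=n_planted, replace=False).tolist()
    )

    width = len(str(spec.n_clusters))
    species_names = [f"ref{j + 1:02d}" for j in range(spec.n_species)]
    clusters: List[OrthologCluster] = []
    truth_rows: List[dict] = []

    def make_record(
        gene_id: str, species: str, is_target: bool, carries: bool, cluster_id: str,
        cluster_planted: bool,
    ) -> PromoterRecord:
        idx = _motif_free_indices(
            spec.promoter_length, comp_vec, motif, threshold, cluster_rng
        )
        seq = _indices_to_str(idx)
        positions: List[int] = []
        if carries:
            positions = _site_positions(
                spec.promoter_length, motif.width, spec.sites_per_sequence, plant_rng
            )
            for pos in positions:
                seq = plant_site(seq, motif, pos, plant_rng)
        rec = PromoterRecord(gene_id, species, seq, is_target=is_target)
        first = positions[0] if positions else -1
        truth_rows.append(
            dict(
                cluster_id=cluster_id,
                motif_id=motif.id,
                record_id=rec.record_id,
                species=species,
                planted=bool(carries),
                site_start=first,
                site_end=first + motif.width if positions else -1,
                cluster_planted=cluster_planted,
            )
        )
        return rec

    for c in range(spec.n_clusters):
        gene = f"g{c + 1:0{width}d}"
        is_planted = c in planted_ids
        target = make_record(gene, "target", True, is_planted, gene, is_planted)
        refs = []
        for species in species_names:
            carries = is_planted and (cluster_rng.random() < spec.conservation_rate)
            refs.append(
                make_record(f"{gene}_{species}", species, False, carries, gene, is_planted)
            )
        clusters.append(OrthologCluster(target=target, references=tuple(refs)))

    background_rng = np.random.default_rng(ss_background)
    background = [
        PromoterRecord(
            f"bkg{b + 1:04d}",
            "background",
            _indices_to_str(
                _motif_free_indices(
                    spec.promoter_length, comp_vec, motif, threshold, background_rng
                )
            ),
        )
        for b in range(spec.n_background)
    ]
    truth = pd.DataFrame(truth_rows)
    return clusters, background, truth


def planted_cluster_ids(truth: pd.DataFrame) -> set:
    """Cluster ids whose target carries a planted site."""
    return set(truth.loc[truth["cluster_planted"], "cluster_id"])


def save_study(
    clusters: Sequence[OrthologCluster],
    background: Sequence[PromoterRecord],
    truth: pd.DataFrame,
    motif: Motif,
    outdir: Union[str, Path],
) -> None:
    """Write a study in the formats the scanner consumes: cluster FASTA +
    index, background FASTA, JASPAR motif file and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_clusters(clusters, outdir / "clusters.fasta", outdir / "clusters.index.tsv")
    write_promoters(background, outdir / "background.fasta")
    write_jaspar([motif], outdir / "motif.jaspar")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
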