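"""Ortholog promoter clusters and background promoter sets.

A cluster groups the 2 kb upstream promoter of one target-genome gene (the
target promoter sequence) with the promoters of its orthologs in reference
genomes.  Orthology is pairwise reciprocal best hit (mutual best hit by
E-value) computed from standard 12-column tabular alignment output; the
alignment step itself is an external commodity and is consumed, not re-run.

File conventions:
  - promoter FASTA headers are ``geneID|species`` with ``|T`` appended for
    the target record (``geneID`` alone is accepted for plain backgrounds);
  - multi-cluster files pair a single FASTA with a tab-separated sidecar
    index of ``cluster_id<TAB>record_id`` lines; a FASTA without an index is
    read as one cluster.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO

_VALID_BASES = set("ACGTN")


@dataclasses.dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence with its gene and species of origin."""

    gene_id: str
    species: str
    sequence: str
    is_target: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"promoter {self.gene_id}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"promoter {self.gene_id}: characters outside A,C,G,T,N: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def record_id(self) -> str:
        tag = f"{self.gene_id}|{self.species}"
        return tag + "|T" if self.is_target else tag


@dataclasses.dataclass(frozen=True)
class OrthologCluster:
    """One target promoter plus its ortholog promoters from reference genomes."""

    target: PromoterRecord
    references: Tuple[PromoterRecord, ...]

    def __post_init__(self) -> None:
        if not self.target.is_target:
            raise ValueError("cluster target record must have is_target=True")
        if any(r.is_target for r in self.references):
            raise ValueError("cluster may contain exactly one target record")
        species = [r.species for r in self.references]
        if len(species) != len(set(species)):
            raise ValueError(
                f"cluster {self.target.gene_id}: duplicate reference species tags"
            )
        object.__setattr__(self, "references", tuple(self.references))

    @property
    def target_gene_id(self) -> str:
        return self.target.gene_id

    @property
    def size(self) -> int:
        return 1 + len(self.references)

    def sequences(self) -> List[PromoterRecord]:
        return [self.target, *self.references]


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output (query, subject, E-value, bitscore)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative E-value")


def read_hits(path: Union[str, Path]) -> List[AlignmentHit]:
    """Read 12-column blast-tab alignment hits (columns 1, 2, 11, 12 used)."""
    hits: List[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric E-value/bitscore "
                    f"({fields[10]!r}, {fields[11]!r})"
                ) from None
            hits.append(AlignmentHit(fields[0], fields[1], evalue, bitscore))
    return hits


def _best_per_query(hits: Iterable[AlignmentHit]) -> Dict[str, str]:
    # best = minimum E-value, ties by maximum bitscore, then lexicographic subject
    best: Dict[str, Tuple[float, float, str]] = {}
    for h in hits:
        key = (h.evalue, -h.bitscore, h.subject_id)
        if h.query_id not in best or key < best[h.query_id]:
            best[h.query_id] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(
    hits_ab: Iterable[AlignmentHit], hits_ba: Iterable[AlignmentHit]
) -> List[Tuple[str, str]]:
    """Mutual-best-hit gene pairs between two genomes.

    The best hit of each query is the minimum-E-value subject (ties broken
    by higher bitscore, then lexicographically smallest subject id); a pair
    (a, b) is emitted iff best(a) = b and best(b) = a.  Sorted by gene a.
    """
    best_ab = _best_per_query(hits_ab)
    best_ba = _best_per_query(hits_ba)
    pairs = [(a, b) for a, b in best_ab.items() if best_ba.get(b) == a]
    return sorted(pairs)


def _as_sequence_mapping(source: Union[str, Path, Mapping[str, str]]) -> Mapping[str, str]:
    if isinstance(source, Mapping):
        return source
    return {rec.id.split("|")[0]: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def build_clusters(
    target_fasta: Union[str, Path, Mapping[str, str]],
    reference_fastas: Mapping[str, Union[str, Path, Mapping[str, str]]],
    pair_lists: Mapping[str, Sequence[Tuple[str, str]]],
    target_species: str = "target",
) -> List[OrthologCluster]:
    """Assemble ortholog promoter clusters from per-species ortholog pairs.

    ``pair_lists`` maps reference species to ``(target_gene, reference_gene)``
    pairs (e.g. from :func:`reciprocal_best_hits`).  One cluster is built per
    target gene with at least one ortholog; target genes absent from every
    pair list are omitted.  A paired id missing from its FASTA is an error.
    """
    targets = _as_sequence_mapping(target_fasta)
    refs_by_gene: Dict[str, List[PromoterRecord]] = {}
    for species, pairs in pair_lists.items():
        if species not in reference_fastas:
            raise KeyError(f"no reference FASTA supplied for species {species!r}")
        seqs = _as_sequence_mapping(reference_fastas[species])
        seen_targets = set()
        for target_gene, ref_gene in pairs:
            if target_gene in seen_targets:
                raise ValueError(
                    f"species {species}: target gene {target_gene} paired more than once"
                )
            seen_targets.add(target_gene)
            if ref_gene not in seqs:
                raise ValueError(
                    f"species {species}: paired gene {ref_gene!r} missing from its FASTA"
                )
            refs_by_gene.setdefault(target_gene, []).append(
                PromoterRecord(ref_gene, species, seqs[ref_gene])
            )
    clusters = []
    for target_gene in sorted(refs_by_gene):
        if target_gene not in targets:
            raise ValueError(f"paired target gene {target_gene!r} missing from target FASTA")
        clusters.append(
            OrthologCluster(
                target=PromoterRecord(
                    target_gene, target_species, targets[target_gene], is_target=True
                ),
                references=tuple(refs_by_gene[target_gene]),
            )
        )
    return clusters


def sample_background(
    universe: Sequence[PromoterRecord], z: int, n: int, seed: int
) -> List[List[PromoterRecord]]:
    """Draw ``n`` background subsets of ``z`` distinct promoters each.

    Sampling is without replacement within a subset (subsets may overlap)
    and deterministic given ``seed``.
    """
    if z < 1 or n < 1:
        raise ValueError("z and n must be >= 1")
    if len(universe) < z:
        raise ValueError(f"universe of {len(universe)} promoters is smaller than z={z}")
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n):
        pick = rng.choice(len(universe), size=z, replace=False)
        subsets.append([universe[i] for i in pick])
    return subsets


def cluster_universe(clusters: Iterable[OrthologCluster]) -> List[PromoterRecord]:
    """Union of all cluster sequences — the promoter 'universe' that
    background subsets are drawn from."""
    universe: List[PromoterRecord] = []
    seen = set()
    for cluster in clusters:
        for rec in cluster.sequences():
            if rec.record_id not in seen:
                seen.add(rec.record_id)
                universe.append(rec)
    return universe


def _parse_header(token: str) -> Tuple[str, str, bool]:
    parts = token.split("|")
    if len(parts) == 1:
        return parts[0], "", False
    if len(parts) == 2:
        return parts[0], parts[1], False
    if len(parts) == 3 and parts[2] == "T":
        return parts[0], parts[1], True
    raise ValueError(f"unrecognised promoter FASTA header {token!r}")


def read_promoters(path: Union[str, Path]) -> List[PromoterRecord]:
    """Read promoters from FASTA, honouring the ``geneID|species[|T]`` header."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, species, is_target = _parse_header(rec.id)
        records.append(PromoterRecord(gene_id, species, str(rec.seq), is_target))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_promoters(records: Iterable[PromoterRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.record_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def read_clusters(
    fasta_path: Union[str, Path], index_path: Union[str, Path, None] = None
) -> List[OrthologCluster]:
    """Read ortholog clusters from FASTA plus an optional sidecar index.

    With an index (``cluster_id<TAB>record_id`` per line) the FASTA may hold
    many clusters; without one, the whole file is one cluster.  Each cluster
    must contain exactly one ``|T`` target record.
    """
    records = {rec.record_id: rec for rec in read_promoters(fasta_path)}
    if index_path is None:
        groups = {"cluster": list(records)}
    else:
        groups = {}
        with open(index_path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{index_path}: line {lineno}: expected 'cluster_id<TAB>record_id'"
                    )
                groups.setdefault(fields[0], []).append(fields[1])
    clusters = []
    for cluster_id in sorted(groups):
        members = []
        for rid in groups[cluster_id]:
            if rid not in records:
                raise ValueError(f"cluster {cluster_id}: record {rid!r} missing from FASTA")
            members.append(records[rid])
        targets = [m for m in members if m.is_target]
        if len(targets) != 1:
            raise ValueError(
                f"cluster {cluster_id}: expected exactly one target (|T) record, "
                f"found {len(targets)}"
            )
        refs = tuple(m for m in members if not m.is_target)
        clusters.append(OrthologCluster(target=targets[0], references=refs))
    return clusters


def write_clusters(
    clusters: Iterable[OrthologCluster],
    fasta_path: Union[str, Path],
    index_path: Union[str, Path],
) -> None:
    """Write clusters as a single FASTA plus a cluster-index sidecar."""
    clusters = list(clusters)
    all_records: List[PromoterRecord] = []
    seen = set()
    with open(index_path, "w") as idx:
        for cluster in clusters:
            for rec in cluster.sequences():
                idx.write(f"{cluster.target_gene_id}\t{rec.record_id}\n")
                if rec.record_id not in seen:
                    seen.add(rec.record_id)
                    all_records.append(rec)
    write_promoters(all_records, fasta_path)
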