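import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import orthoscan as osc
from _oracles import best_hit_table

HIT_LINE = "geneA\tgeneB\t95.0\t100\t3\t0\t1\t100\t1\t100\t1e-50\t180.5\n"


def _hit(q, s, e, bits=100.0):
    return osc.AlignmentHit(q, s, e, bits)


class TestReadHits:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert osc.read_hits(path) == []

    def test_single_line_fields(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(HIT_LINE)
        (hit,) = osc.read_hits(path)
        assert (hit.query_id, hit.subject_id) == ("geneA", "geneB")
        assert hit.evalue == 1e-50 and hit.bitscore == 180.5

    def test_eleven_columns_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("\t".join(HIT_LINE.split("\t")[:11]) + "\n")
        with pytest.raises(ValueError, match="line 1"):
            osc.read_hits(path)

    def test_non_numeric_evalue_names_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        fields = HIT_LINE.rstrip("\n").split("\t")
        fields[10] = "abc"
        path.write_text(HIT_LINE + "\t".join(fields) + "\n")
        with pytest.raises(ValueError, match="line 2"):
            osc.read_hits(path)


class TestReciprocalBestHits:
    def test_mutual_pair(self):
        ab = [_hit("a1", "b1", 1e-50)]
        ba = [_hit("b1", "a1", 1e-48)]
        assert osc.reciprocal_best_hits(ab, ba) == [("a1", "b1")]

    def test_non_mutual_excluded(self):
        ab = [_hit("a1", "b1", 1e-50)]
        ba = [_hit("b1", "a2", 1e-60), _hit("b1", "a1", 1e-48)]
        assert osc.reciprocal_best_hits(ab, ba) == []

    def test_evalue_tie_broken_by_bitscore(self):
        ab = [_hit("a1", "b1", 1e-10, 80.0), _hit("a1", "b2", 1e-10, 90.0)]
        ba = [_hit("b2", "a1", 1e-12)]
        assert osc.reciprocal_best_hits(ab, ba) == [("a1", "b2")]

    @given(
        evalues=st.lists(
            st.tuples(
                st.integers(0, 2),  # query
                st.integers(0, 2),  # subject
                st.sampled_from([1e-5, 1e-10, 1e-20]),
                st.sampled_from([50.0, 80.0, 90.0]),
            ),
            min_size=0,
            max_size=12,
        )
    )
    def test_symmetry_and_best_hit_oracle(self, evalues):
        ab = [_hit(f"a{q}", f"b{s}", e, b) for q, s, e, b in evalues]
        ba = [_hit(f"b{q}", f"a{s}", e, b) for q, s, e, b in evalues]
        pairs = osc.reciprocal_best_hits(ab, ba)
        # swapping direction lists swaps pair elements
        swapped = osc.reciprocal_best_hits(ba, ab)
        assert sorted((b, a) for a, b in pairs) == sorted(swapped)
        # agreement with a plain-dict best-hit oracle
        best_ab, best_ba = best_hit_table(ab), best_hit_table(ba)
        expected = sorted(
            (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
        )
        assert pairs == expected


class TestBuildClusters:
    def test_references_aggregated_across_species(self):
        target = {"g1": "ACGTACGT"}
        refs = {
            "sp1": {"g1h": "ACGTACGT"},
            "sp2": {"g1x": "ACGTACGT"},
            "sp3": {"g1y": "ACGTACGT"},
        }
        pairs = {"sp1": [("g1", "g1h")], "sp2": [("g1", "g1x")], "sp3": [("g1", "g1y")]}
        (cluster,) = osc.build_clusters(target, refs, pairs)
        assert cluster.target_gene_id == "g1" and len(cluster.references) == 3
        assert {r.species for r in cluster.references} == {"sp1", "sp2", "sp3"}

    def test_gene_without_pairs_omitted(self):
        clusters = osc.build_clusters(
            {"g1": "ACGT", "g2": "ACGT"},
            {"sp1": {"h1": "ACGT"}},
            {"sp1": [("g1", "h1")]},
        )
        assert [c.target_gene_id for c in clusters] == ["g1"]

    def test_two_species_pairing_same_gene(self):
        clusters = osc.build_clusters(
            {"g": "ACGT"},
            {"sp1": {"h1": "ACGT"}, "sp2": {"h2": "ACGT"}},
            {"sp1": [("g", "h1")], "sp2": [("g", "h2")]},
        )
        assert clusters[0].size == 3

    def test_missing_paired_id_is_an_error(self):
        with pytest.raises(ValueError, match="h9"):
            osc.build_clusters(
                {"g": "ACGT"}, {"sp1": {"h1": "ACGT"}}, {"sp1": [("g", "h9")]}
            )


class TestSampleBackground:
    @pytest.fixture
    def universe(self):
        return [
            osc.PromoterRecord(f"u{i}", "bg", "ACGTACGT") for i in range(5)
        ]

    def test_full_size_subset_is_a_permutation(self, universe):
        (subset,) = osc.sample_background(universe, z=5, n=1, seed=0)
        assert sorted(r.gene_id for r in subset) == sorted(r.gene_id for r in universe)

    def test_deterministic_given_seed(self, universe):
        first = osc.sample_background(universe, z=3, n=4, seed=9)
        second = osc.sample_background(universe, z=3, n=4, seed=9)
        assert [[r.gene_id for r in s] for s in first] == [
            [r.gene_id for r in s] for s in second
        ]

    def test_subsets_have_distinct_members(self, universe):
        subsets = osc.sample_background(universe, z=2, n=3, seed=1)
        assert len(subsets) == 3
        for subset in subsets:
            ids = [r.gene_id for r in subset]
            assert len(ids) == 2 and len(set(ids)) == 2

    def test_universe_smaller_than_z_rejected(self, universe):
        with pytest.raises(ValueError):
            osc.sample_background(universe, z=6, n=1, seed=0)


class TestClusterIO:
    def test_round_trip(self, tmp_path, tiny_study):
        _, clusters, _, _, _ = tiny_study
        fasta = tmp_path / "c.fasta"
        index = tmp_path / "c.tsv"
        osc.write_clusters(clusters[:3], fasta, index)
        back = osc.read_clusters(fasta, index)
        assert [c.target_gene_id for c in back] == sorted(
            c.target_gene_id for c in clusters[:3]
        )
        by_gene = {c.target_gene_id: c for c in clusters[:3]}
        for cluster in back:
            orig = by_gene[cluster.target_gene_id]
            assert cluster.target.sequence == orig.target.sequence
            assert {r.record_id for r in cluster.references} == {
                r.record_id for r in orig.references
            }

    def test_target_header_convention(self, tmp_path):
        fasta = tmp_path / "one.fasta"
        fasta.write_text(">g1|human|T\nACGT\n>g1h|mouse\nACGT\n")
        (cluster,) = osc.read_clusters(fasta)
        assert cluster.target.gene_id == "g1" and cluster.target.is_target
        assert cluster.references[0].species == "mouse"

    def test_cluster_without_target_rejected(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(">g1|human\nACGT\n")
        with pytest.raises(ValueError, match="target"):
            osc.read_clusters(fasta)


def test_cluster_universe_deduplicates(tiny_study):
    _, clusters, _, _, _ = tiny_study
    universe = osc.cluster_universe(clusters + clusters)
    assert len(universe) == sum(c.size for c in clusters)
    assert len(universe) <= len({r.record_id for r in universe}) + 0  # all unique


def test_duplicate_reference_species_rejected():
    target = osc.PromoterRecord("g", "t", "ACGT", is_target=True)
    ref = osc.PromoterRecord("h", "sp1", "ACGT")
    ref2 = osc.PromoterRecord("h2", "sp1", "ACGT")
    with pytest.raises(ValueError, match="duplicate"):
        osc.OrthologCluster(target=target, references=(ref, ref2))


def test_promoter_record_rejects_bad_alphabet():
    with pytest.raises(ValueError):
        osc.PromoterRecord("g", "sp", "ACGU")
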