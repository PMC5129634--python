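"""Gold-standard construction: source merge, hit filtering, consolidation."""

import random

import pytest

from pgdbcompare import (
    AlignmentHit,
    AmbiguousCrossLinkError,
    CrossLink,
    SourceAnnotation,
    UnresolvedMappingError,
    best_hit_per_query,
    consolidate_to_genes,
    filter_hits,
    merge_sources,
)
from pgdbcompare.gold_standard import (
    read_blast_tabular,
    read_gold_standard,
    write_blast_tabular,
    write_gold_standard,
)


def hit(q="Q", s="S", pident=99.0, evalue=1e-50, bitscore=200.0):
    return AlignmentHit(q, s, pident, evalue, bitscore)


class TestMergeSources:
    def test_cross_linked_duplicate_collapses_with_merged_provenance(self):
        merged = merge_sources(
            {SourceAnnotation("P1", "1.1.1.1", "reviewed")},
            {SourceAnnotation("B9", "1.1.1.1", "experimental")},
            {CrossLink("B9", "P1")},
        )
        assert merged == {("P1", "1.1.1.1"): {"reviewed", "experimental"}}

    def test_disjoint_sources_union(self):
        merged = merge_sources(
            {SourceAnnotation(f"P{i}", "1.1.1.1", "reviewed") for i in range(3)},
            {SourceAnnotation(f"B{i}", "2.2.2.2", "experimental") for i in range(4)},
            set(),
        )
        assert len(merged) == 7

    def test_unlinked_experimental_accession_keeps_its_key(self):
        merged = merge_sources(
            set(), {SourceAnnotation("B2", "2.2.2.2", "experimental")}, set()
        )
        assert ("B2", "2.2.2.2") in merged

    def test_conflicting_cross_links_raise(self):
        with pytest.raises(AmbiguousCrossLinkError, match="B1"):
            merge_sources(
                set(), set(), {CrossLink("B1", "P1"), CrossLink("B1", "P2")}
            )


class TestFilterHits:
    @pytest.mark.parametrize(
        "pident, evalue, kept",
        [
            (96.0, 1e-20, True),   # both boundaries inclusive
            (95.9, 1e-30, False),  # identity below cutoff
            (99.0, 1e-19, False),  # e-value above cutoff
            (100.0, 0.0, True),
        ],
    )
    def test_inclusive_boundaries(self, pident, evalue, kept):
        h = hit(pident=pident, evalue=evalue)
        assert (h in filter_hits({h})) is kept

    def test_monotone_in_both_thresholds(self):
        rng = random.Random(42)
        hits = {
            hit(q=f"Q{i}", pident=rng.uniform(50, 100),
                evalue=10 ** -rng.uniform(0, 60), bitscore=rng.uniform(40, 400))
            for i in range(300)
        }
        loose = filter_hits(hits, min_identity=90.0, max_evalue=1e-10)
        tighter_id = filter_hits(hits, min_identity=96.0, max_evalue=1e-10)
        tighter_ev = filter_hits(hits, min_identity=90.0, max_evalue=1e-25)
        assert tighter_id <= loose
        assert tighter_ev <= loose


class TestBestHit:
    def test_highest_bitscore_wins(self):
        h1, h2 = hit(bitscore=200.0), hit(s="S2", bitscore=150.0)
        assert best_hit_per_query({h1, h2}) == {"Q": h1}

    def test_bitscore_tie_broken_by_lowest_evalue(self):
        h1 = hit(s="S1", evalue=1e-50, bitscore=200.0)
        h2 = hit(s="S2", evalue=1e-40, bitscore=200.0)
        assert best_hit_per_query({h1, h2})["Q"] is h1

    def test_full_tie_broken_by_subject_id(self):
        h1, h2 = hit(s="S1"), hit(s="S2")
        assert best_hit_per_query({h1, h2})["Q"].subject_protein_id == "S1"

    def test_single_hit_is_its_own_best(self):
        h = hit()
        assert best_hit_per_query({h}) == {"Q": h}

    def test_deterministic_under_permutation(self):
        rng = random.Random(7)
        hits = {
            hit(q=f"Q{i % 10}", s=f"S{i}", bitscore=rng.choice([100.0, 200.0]),
                evalue=rng.choice([1e-30, 1e-40]))
            for i in range(60)
        }
        results = [best_hit_per_query(set(rng.sample(sorted(
            hits, key=lambda h: h.subject_protein_id), len(hits))))
            for _ in range(5)]
        assert all(r == results[0] for r in results)


class TestConsolidate:
    def test_isoform_labels_union_at_gene_level(self):
        merged = {("A1", "1.1.1.1"): {"reviewed"}, ("A2", "2.2.2.2"): {"experimental"}}
        best = {"A1": hit(q="A1", s="T1"), "A2": hit(q="A2", s="T2")}
        gold = consolidate_to_genes(merged, best, {"T1": "G", "T2": "G"})
        assert gold.annotations == {"G": {"1.1.1.1", "2.2.2.2"}}
        assert gold.annotation_count == 2

    def test_identical_labels_on_isoforms_count_once(self):
        merged = {("A1", "1.1.1.1"): {"reviewed"}, ("A2", "1.1.1.1"): {"experimental"}}
        best = {"A1": hit(q="A1", s="T1"), "A2": hit(q="A2", s="T2")}
        gold = consolidate_to_genes(merged, best, {"T1": "G", "T2": "G"})
        assert gold.annotation_count == 1
        assert gold.provenance[("G", "1.1.1.1")] == {"reviewed", "experimental"}

    def test_missing_protein_mapping_raises(self):
        with pytest.raises(UnresolvedMappingError, match="T9"):
            consolidate_to_genes(
                {("A1", "1.1.1.1"): {"reviewed"}}, {"A1": hit(q="A1", s="T9")}, {}
            )

    def test_agrees_with_brute_force_group_by_union(self):
        # 100 accessions randomly assigned to 40 genes; oracle is a plain
        # dict-of-sets group-by built independently of the pipeline path
        rng = random.Random(123)
        merged, best, protein_to_gene = {}, {}, {}
        for i in range(100):
            acc, prot = f"A{i:03d}", f"T{i:03d}"
            gene = f"G{rng.randrange(40):02d}"
            label = f"{rng.randrange(1, 7)}.{rng.randrange(1, 30)}.1.{rng.randrange(1, 30)}"
            merged[(acc, label)] = {"reviewed"}
            best[acc] = hit(q=acc, s=prot)
            protein_to_gene[prot] = gene
        expected = {}
        for (acc, label), _ in merged.items():
            expected.setdefault(protein_to_gene[best[acc].subject_protein_id], set()).add(label)
        gold = consolidate_to_genes(merged, best, protein_to_gene)
        assert gold.annotations == expected

    def test_one_isoform_one_label_count_equals_surviving_queries(self):
        rng = random.Random(5)
        hits, merged, p2g = set(), {}, {}
        for i in range(50):
            acc, prot = f"A{i}", f"T{i}"
            h = hit(q=acc, s=prot, pident=rng.uniform(90, 100),
                    evalue=10 ** -rng.uniform(10, 40))
            hits.add(h)
            merged[(acc, f"1.1.1.{i + 1}")] = {"reviewed"}
            p2g[prot] = f"G{i}"
        surviving = filter_hits(hits)
        gold = consolidate_to_genes(merged, best_hit_per_query(surviving), p2g)
        assert gold.annotation_count == len(surviving)


def test_blast_tabular_and_gold_tsv_round_trip(tmp_path):
    hits = {hit(q=f"Q{i}", s=f"S{i}", pident=96.5, evalue=1e-30, bitscore=100.0 + i)
            for i in range(5)}
    write_blast_tabular(hits, tmp_path / "hits.tsv")
    assert read_blast_tabular(tmp_path / "hits.tsv") == hits

    merged = {("A1", "1.1.1.1"): {"reviewed"}}
    gold = consolidate_to_genes(merged, {"A1": hit(q="A1", s="T1")}, {"T1": "G1"})
    write_gold_standard(gold, tmp_path / "gold.tsv")
    back = read_gold_standard(tmp_path / "gold.tsv")
    assert back.annotations == gold.annotations
    assert back.provenance == gold.provenance
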