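"""Gene models, read-term construction, catalog reduction, count matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biisq import (
    GeneModel,
    MalformedAnnotationError,
    MixedGeneError,
    ReadTerm,
    ReadTermMatrix,
    ReadTruncationError,
    TranscriptRecord,
    UnmappableReadError,
    build_count_matrix,
    build_gene_model,
    gene_model_from_gff,
    read_to_term,
    reduce_catalog,
    term_from_blocks,
)
from biisq.errors import GeneNotFoundError

from conftest import write_small_gtf


class TestGeneModel:
    def test_exons_sorted_and_validated(self):
        g = GeneModel("g", ((250, 400), (0, 150)))
        assert g.exons == ((0, 150), (250, 400))
        assert g.E == 2

    def test_minus_strand_transcription_order(self):
        g = GeneModel("g", ((0, 150), (250, 400)), strand="-")
        # exon 1 is 5'-most, i.e. the highest-coordinate exon on the minus strand
        assert g.exons == ((250, 400), (0, 150))
        assert g.transcript_to_genomic(0) == 399

    def test_overlapping_exons_rejected(self):
        with pytest.raises(MalformedAnnotationError):
            GeneModel("g", ((0, 150), (100, 250)))

    def test_empty_interval_rejected(self):
        with pytest.raises(MalformedAnnotationError):
            GeneModel("g", ((10, 10),))


class TestReadToTerm:
    def test_junction_spanning_read(self, brca2_head):
        """A 100 bp read 40 bp into the gene crosses the first junction."""
        term = read_to_term(40, 100, brca2_head)
        assert (term.start, term.end, term.exon_set) == (40, 2690, (1, 2))

    def test_read_within_single_exon(self, brca2_head):
        term = read_to_term(2617, 50, brca2_head)
        assert (term.start, term.end, term.exon_set) == (2617, 2667, (2,))

    def test_three_exon_walk_matches_base_oracle(self, gene3):
        """90 bp from the first base covers all three 30 bp exons."""
        # oracle: walk the concatenated exonic coordinates base by base
        exonic = [p for s, e in gene3.exons for p in range(s, e)]
        covered = exonic[0:90]
        expected_exons = tuple(
            sorted({i + 1 for i, (s, e) in enumerate(gene3.exons)
                    if any(s <= p < e for p in covered)})
        )
        term = read_to_term(0, 90, gene3)
        assert term.exon_set == expected_exons == (1, 2, 3)
        assert term.end == covered[-1] + 1 == 230

    def test_intronic_start_rejected(self, brca2_head):
        with pytest.raises(UnmappableReadError):
            read_to_term(100, 50, brca2_head)

    def test_overrun_rejected(self, brca2_head):
        with pytest.raises(ReadTruncationError):
            read_to_term(2860, 100, brca2_head)

    def test_walk_restricted_to_isoform_chain(self, gene3):
        term = read_to_term(20, 20, gene3, chain=(1, 3))
        assert term.exon_set == (1, 3)
        assert term.end == 210

    @given(start_off=st.integers(0, 60), length=st.integers(1, 30))
    @settings(max_examples=60, deadline=None)
    def test_overlap_lengths_sum_to_read_length(self, start_off, length):
        gene = GeneModel("g", ((0, 30), (100, 130), (200, 230)))
        exonic = [p for s, e in gene.exons for p in range(s, e)]
        if start_off + length > len(exonic):
            return
        term = read_to_term(exonic[start_off], length, gene)
        overlap = 0
        lo, hi = sorted((term.start, term.end))
        if gene.strand == "-":
            lo, hi = hi + 1, lo + 1
        for i in term.exon_set:
            s, e = gene.exons[i - 1]
            overlap += max(0, min(e, hi) - max(s, lo))
        assert overlap == length

    def test_end_monotone_in_start_within_exon(self, brca2_head):
        ends = [read_to_term(s, 80, brca2_head).end for s in range(1, 60)]
        assert all(b >= a for a, b in zip(ends, ends[1:]))


class TestTermFromBlocks:
    def test_spliced_blocks(self, brca2_head):
        term = term_from_blocks([(40, 67), (2617, 2690)], brca2_head)
        assert (term.start, term.end, term.exon_set) == (40, 2690, (1, 2))

    def test_intron_overhang_rejected(self, brca2_head):
        with pytest.raises(UnmappableReadError):
            term_from_blocks([(40, 80)], brca2_head)


class TestBuildGeneModel:
    def test_single_transcript_identity(self):
        rec = TranscriptRecord("g", "t1", ((0, 100), (200, 300), (400, 500)))
        model = build_gene_model([rec], "g")
        assert model.E == 3
        assert model.exons == rec.exons

    def test_most_exons_wins_among_basic(self):
        r4 = TranscriptRecord("g", "t4", tuple((i * 200, i * 200 + 100) for i in range(4)))
        r7 = TranscriptRecord("g", "t7", tuple((i * 200, i * 200 + 100) for i in range(7)))
        model = build_gene_model([r4, r7], "g")
        assert model.E == 7

    def test_tied_transcripts_collapse_overlapping_exons(self):
        a = TranscriptRecord("g", "ta", ((100, 200),))
        b = TranscriptRecord("g", "tb", ((150, 250),))
        model = build_gene_model([a, b], "g")
        assert model.exons == ((100, 250),)

    def test_absent_gene(self):
        with pytest.raises(GeneNotFoundError):
            build_gene_model([TranscriptRecord("g", "t", ((0, 1),))], "other")

    def test_exonless_transcript(self):
        with pytest.raises(MalformedAnnotationError):
            build_gene_model([TranscriptRecord("g", "t", ())], "g")

    def test_gff_parsing_prefers_most_exons(self, tmp_path):
        gtf = write_small_gtf(tmp_path / "small.gtf")
        model = gene_model_from_gff(str(gtf), "GENE1")
        assert model.E == 3
        assert model.exons == ((0, 150), (250, 400), (500, 650))


def _random_matrix(rng, n_terms, m=3, max_start=5000):
    terms, seen = [], set()
    while len(terms) < n_terms:
        start = int(rng.integers(0, max_start))
        exon_set = (1,) if start < 2500 else (1, 2)
        key = (start, exon_set)
        if key in seen:
            continue
        seen.add(key)
        terms.append(ReadTerm(start, start + 100, exon_set))
    X = rng.integers(0, 5, size=(n_terms, m))
    X[0, :] += 1
    return ReadTermMatrix(terms, X, [f"s{j}" for j in range(m)])


class TestReduceCatalog:
    def test_under_target_unchanged(self):
        rng = np.random.default_rng(0)
        matrix = _random_matrix(rng, 100)
        out = reduce_catalog(matrix, 2500)
        assert out is matrix

    def test_reduction_toward_target_conserves_counts(self):
        rng = np.random.default_rng(1)
        matrix = _random_matrix(rng, 5000, max_start=100000)
        out = reduce_catalog(matrix, 2500)
        assert 1250 <= out.V <= 5000
        assert out.V <= matrix.V
        assert out.X.sum() == matrix.X.sum()
        # terms with different exon sets are never merged
        assert {t.exon_set for t in out.catalog} == {t.exon_set for t in matrix.catalog}

    def test_hand_collapse_of_two_nearby_terms(self):
        terms = [ReadTerm(40, 140, (1,)), ReadTerm(41, 141, (1,))]
        matrix = ReadTermMatrix(terms, np.array([[3], [2]]), ["s0"])
        out = reduce_catalog(matrix, 1)
        assert out.V == 1
        assert out.X.sum() == 5
        assert out.catalog[0].start == 40  # count-weighted mode of starts

    def test_column_totals_preserved_per_sample(self):
        rng = np.random.default_rng(2)
        matrix = _random_matrix(rng, 800, m=4, max_start=20000)
        out = reduce_catalog(matrix, 100)
        np.testing.assert_array_equal(out.column_totals(), matrix.column_totals())


class TestBuildCountMatrix:
    def test_single_sample_repeated_term(self):
        t = ReadTerm(0, 50, (1,))
        matrix = build_count_matrix({"s0": [t] * 7})
        assert matrix.X.tolist() == [[7]]

    def test_union_of_disjoint_term_sets(self):
        a = [ReadTerm(i, i + 50, (1,)) for i in (0, 10)]
        b = [ReadTerm(i, i + 50, (1,)) for i in (20, 30, 40)]
        matrix = build_count_matrix({"sa": a, "sb": b})
        assert matrix.V == 5
        assert (matrix.X > 0).sum() == 5
        np.testing.assert_array_equal(matrix.column_totals(), [2, 3])

    def test_column_sums_equal_retained_read_counts(self):
        rng = np.random.default_rng(3)
        per_sample = {}
        counts = {}
        for j in range(4):
            n = int(rng.integers(5, 30))
            per_sample[f"s{j}"] = [
                ReadTerm(int(rng.integers(0, 20)) * 10, 0, (1,)) for _ in range(n)
            ]
            counts[f"s{j}"] = n
        matrix = build_count_matrix(per_sample)
        for j, sid in enumerate(matrix.sample_ids):
            assert matrix.X[:, j].sum() == counts[sid]

    def test_mixed_genes_rejected(self):
        with pytest.raises(MixedGeneError):
            build_count_matrix({
                "s0": [ReadTerm(0, 50, (1,), gene_id="A")],
                "s1": [ReadTerm(0, 50, (1,), gene_id="B")],
            })


def test_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    matrix = _random_matrix(rng, 20)
    path = tmp_path / "terms.tsv"
    matrix.to_tsv(path)
    back = ReadTermMatrix.from_tsv(path)
    assert back.catalog == matrix.catalog
    assert back.sample_ids == matrix.sample_ids
    np.testing.assert_array_equal(back.X, matrix.X)
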