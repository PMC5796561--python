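"""Sequence I/O, ORF calling and the naive protein search."""
import math

import numpy as np
import pytest

from phageome.errors import ParameterError, ParseError
from phageome.seq_io import (
    Gene,
    HitRecord,
    Scaffold,
    SeqRecord,
    call_orfs,
    filter_hits,
    naive_protein_search,
    read_fasta,
    read_fastq,
    read_genes,
    read_hits,
    translate_cds,
    write_fasta,
    write_fastq,
    write_genes,
    write_hits,
)

# ---------------------------------------------------------------------------
# FASTA / FASTQ


class TestFasta:
    def test_round_trip(self, tmp_path):
        records = [
            SeqRecord("a", "ACGT"), SeqRecord("b", "GGGTTT"), SeqRecord("c", "A"),
        ]
        path = tmp_path / "x.fasta"
        write_fasta(records, path, width=3)
        assert read_fasta(path) == records

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        assert read_fasta(path) == []

    def test_lowercase_upper_cased(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">r\nacgTn\n")
        assert read_fasta(path)[0].seq == "ACGTN"

    def test_missing_header_raises_with_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("\nACGT\n>r\nACGT\n")
        with pytest.raises(ParseError) as err:
            read_fasta(path)
        assert err.value.line == 2

    def test_fastq_round_trip(self, tmp_path):
        records = [SeqRecord("r1", "ACGTACGT"), SeqRecord("r2", "TTTT")]
        path = tmp_path / "x.fastq"
        write_fastq(records, path)
        assert read_fastq(path) == records


# ---------------------------------------------------------------------------
# ORF calling


def _brute_force_orfs(seq: str, min_aa: int):
    """Independent oracle: scan all 6 frames codon by codon."""
    from phageome._kmers import revcomp

    stops = {"TAA", "TAG", "TGA"}
    found = set()
    L = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            i = frame
            start = None
            while i + 3 <= len(s):
                codon = s[i : i + 3]
                if codon in stops:
                    if start is not None and (i - start) // 3 >= min_aa:
                        a, b = start, i + 3
                        if strand == "-":
                            a, b = L - b, L - a
                        found.add((a, b, strand))
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
                i += 3
    return found


class TestCallOrfs:
    def test_minimal_gene(self):
        genes = call_orfs(Scaffold("s", "x", "ATGAAATAA"), min_aa=2)
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end, g.strand, g.protein) == (0, 9, "+", "MK")

    def test_too_short_sequence_empty(self):
        assert call_orfs(Scaffold("s", "x", "ATGAAA"), min_aa=5) == []

    def test_min_aa_validated(self):
        with pytest.raises(ParameterError):
            call_orfs(Scaffold("s", "x", "ATGAAATAA"), min_aa=0)

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 2000))
            genes = call_orfs(Scaffold("s", "x", seq), min_aa=20)
            got = {(g.start, g.end, g.strand) for g in genes}
            assert got == _brute_force_orfs(seq, 20)

    def test_planted_markers_recovered_exactly(self, small_world):
        _, refs, _, _ = small_world
        for m in refs.marker_genes:
            genome = refs.phage_genomes[m.phage_id]
            genes = call_orfs(Scaffold(m.phage_id, "x", genome))
            coords = {(g.start, g.end, g.strand) for g in genes}
            assert (m.start, m.end, "+") in coords
            assert translate_cds(genome[m.start : m.end]) == m.protein

    def test_ambiguous_bases_translate_to_x(self):
        genes = call_orfs(Scaffold("s", "x", "ATGNNTAAATAA"), min_aa=2)
        assert any("X" in g.protein for g in genes)

    def test_gene_table_round_trip(self, tmp_path):
        genes = [Gene("g1", "s1", 0, 9, "+", "MK"), Gene("g2", "s1", 3, 12, "-", "MW")]
        path = tmp_path / "genes.tsv"
        write_genes(genes, path)
        assert read_genes(path) == genes


# ---------------------------------------------------------------------------
# hit tables


def _hit_line(q, s, ev, bits, ident=90.0):
    return f"{q}\t{s}\t{ident}\t50\t5\t0\t1\t50\t1\t50\t{ev}\t{bits}\n"


class TestReadHits:
    def test_evalue_filter_count(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            _hit_line("q1", "s1", 1e-10, 50) + _hit_line("q1", "s2", 1e-3, 40)
            + _hit_line("q2", "s1", 1e-8, 45) + _hit_line("q2", "s3", 0.5, 20)
            + _hit_line("q3", "s1", 1e-6, 44)
        )
        hits = read_hits(path, max_evalue=1e-5)
        assert len(hits) == 3

    def test_duplicate_pair_keeps_best_evalue(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            _hit_line("q", "s", 1e-4, 30) + _hit_line("q", "s", 1e-9, 60)
        )
        hits = read_hits(path)
        assert len(hits) == 1
        assert hits[0].evalue == 1e-9

    def test_infinite_cutoff_keeps_all(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(_hit_line("q1", "s1", 10.0, 20) + _hit_line("q2", "s1", 5.0, 22))
        assert len(read_hits(path, max_evalue=math.inf)) == 2

    def test_non_numeric_evalue_raises(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q\ts\t90\t50\t5\t0\t1\t50\t1\t50\tnot-a-number\t30\n")
        with pytest.raises(ParseError):
            read_hits(path)

    def test_filtering_idempotent(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            _hit_line("q1", "s1", 1e-10, 50) + _hit_line("q2", "s2", 1e-2, 10)
        )
        once = filter_hits(read_hits(path, max_evalue=1e-5), 1e-5)
        twice = filter_hits(once, 1e-5)
        assert once == twice

    def test_write_read_round_trip(self, tmp_path):
        hits = [HitRecord("q", "s", 1e-8, 52.0, 0.9)]
        path = tmp_path / "h.tsv"
        write_hits(hits, path)
        back = read_hits(path)
        assert back[0].query_id == "q" and back[0].evalue == pytest.approx(1e-8)


# ---------------------------------------------------------------------------
# naive protein search

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), n))


class TestNaiveProteinSearch:
    def test_identical_query_is_top_hit(self):
        rng = np.random.default_rng(0)
        db = [SeqRecord(f"d{i}", _random_protein(rng, 80)) for i in range(5)]
        hits = naive_protein_search([SeqRecord("q", db[2].seq)], db)
        assert hits[0].subject_id == "d2"
        assert hits[0].evalue == 0.0 or hits[0].evalue < 1e-50

    def test_no_shared_kmers_no_hits(self):
        db = [SeqRecord("d", "MKLVNQWERTYIPASDFGHC" * 4)]
        hits = naive_protein_search([SeqRecord("q", "W" * 40)], db)
        assert hits == []

    def test_empty_db_raises(self):
        with pytest.raises(ParameterError):
            naive_protein_search([SeqRecord("q", "MKLV" * 10)], [])

    def test_k_larger_than_shortest_raises(self):
        with pytest.raises(ParameterError):
            naive_protein_search(
                [SeqRecord("q", "MKLVWY")], [SeqRecord("d", "MKL")], k=5
            )

    def test_ranking_matches_brute_force_kmer_counting(self):
        rng = np.random.default_rng(7)
        k = 5
        db = [SeqRecord(f"d{i}", _random_protein(rng, 120)) for i in range(8)]
        queries = []
        for i in range(50):
            base = db[int(rng.integers(0, len(db)))].seq
            a = int(rng.integers(0, 60))
            queries.append(
                SeqRecord(f"q{i}", base[a : a + 50] + _random_protein(rng, 20))
            )
        hits = naive_protein_search(queries, db, k=k)
        by_query = {}
        for h in hits:
            by_query.setdefault(h.query_id, []).append(h)
        for q in queries:
            qk = {q.seq[i : i + k] for i in range(len(q.seq) - k + 1)}
            expected = {}
            for d in db:
                dk = {d.seq[i : i + k] for i in range(len(d.seq) - k + 1)}
                n = len(qk & dk)
                if n:
                    expected[d.id] = n
            got = {h.subject_id: h.bitscore / 2.0 for h in by_query.get(q.id, [])}
            assert got == pytest.approx(expected)
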