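"""Weighted-vote PFR/BGR assignment and terminase identification."""
import numpy as np
import pytest

from phageome.seq_io import Gene, HitRecord, SeqRecord
from phageome.synthetic_data import SYNTHETIC_TERMINASE_MOTIFS, TERMINASE_DOMAINS
from phageome.taxonomy import (
    assign_bacterial_genus,
    assign_phage_family,
    identify_lst,
    lst_tree,
    weighted_votes,
)


def _gene(gid):
    return Gene(gid, "sc", 0, 33, "+", "M" * 10)


def _hit(q, s, ev=1e-20, bits=100.0):
    return HitRecord(q, s, ev, bits, 0.9)


class TestPhageFamilyAssignment:
    def test_single_gene_single_hit(self):
        a = assign_phage_family(
            "sc", [_gene("g1")], [_hit("g1", "p1")], {"p1": "Siphoviridae"}
        )
        assert a.label == "Siphoviridae"
        assert a.ratio == pytest.approx(1.0)
        assert a.gene_votes == 1

    def test_two_gene_weighted_vote(self):
        # gene1: top Sipho (1.0), second Myo (0.5)
        # gene2: top Myo (1.0), second Myo (0.5) -> Myo 2.0, Sipho 1.0
        fam = {"p1": "Siphoviridae", "p2": "Myoviridae", "p3": "Myoviridae",
               "p4": "Myoviridae"}
        hits = [
            _hit("g1", "p1", ev=1e-30), _hit("g1", "p2", ev=1e-20),
            _hit("g2", "p3", ev=1e-25), _hit("g2", "p4", ev=1e-22),
        ]
        a = assign_phage_family("sc", [_gene("g1"), _gene("g2")], hits, fam)
        assert a.label == "Myoviridae"
        assert a.ratio == pytest.approx(2.0 / 3.0)
        assert a.gene_votes == 2

    def test_exact_half_ratio_is_unclassified(self):
        # two genes, each voting 1.5 for a different family -> PFR 0.5
        fam = {"p1": "Siphoviridae", "p2": "Siphoviridae",
               "p3": "Myoviridae", "p4": "Myoviridae"}
        hits = [
            _hit("g1", "p1", ev=1e-30), _hit("g1", "p2", ev=1e-20),
            _hit("g2", "p3", ev=1e-30), _hit("g2", "p4", ev=1e-20),
        ]
        a = assign_phage_family("sc", [_gene("g1"), _gene("g2")], hits, fam)
        assert a.label == "unclassified"
        assert a.ratio == pytest.approx(0.5)

    def test_no_voting_genes_unclassified_zero(self):
        a = assign_phage_family("sc", [_gene("g1")], [], {"p1": "Siphoviridae"})
        assert (a.label, a.ratio, a.gene_votes) == ("unclassified", 0.0, 0)

    def test_evalue_cutoff_excludes_weak_hits(self):
        a = assign_phage_family(
            "sc", [_gene("g1")], [_hit("g1", "p1", ev=1e-3)],
            {"p1": "Siphoviridae"},
        )
        assert a.label == "unclassified"

    def test_gene_order_invariance(self):
        fam = {f"p{i}": ("A" if i % 2 else "B") for i in range(10)}
        rng = np.random.default_rng(4)
        genes = [_gene(f"g{i}") for i in range(6)]
        hits = [
            _hit(f"g{i}", f"p{int(rng.integers(0, 10))}",
                 ev=float(rng.uniform(1e-40, 1e-10)))
            for i in range(6) for _ in range(3)
        ]
        a1 = assign_phage_family("sc", genes, hits, fam)
        a2 = assign_phage_family("sc", genes[::-1], hits[::-1], fam)
        assert (a1.label, a1.ratio) == (a2.label, a2.ratio)


class TestBacterialGenusAssignment:
    def test_exactly_70_percent_assigned(self):
        # 10 genes voting 1.0 each: 7 for A, 3 for B -> BGR(A) = 0.70
        genus = {f"a{i}": "GenusA" for i in range(7)}
        genus.update({f"b{i}": "GenusB" for i in range(3)})
        genes = [_gene(f"g{i}") for i in range(10)]
        hits = [_hit(f"g{i}", s) for i, s in enumerate(genus)]
        a = assign_bacterial_genus("sc", genes, hits, genus)
        assert a.ratio == pytest.approx(0.70)
        assert a.label == "GenusA"

    def test_below_70_percent_unclassified(self):
        # 13 top-hit votes: 9 for A, 4 for B -> BGR(A) ~ 0.692 < 0.70
        genus = {f"a{i}": "GenusA" for i in range(9)}
        genus.update({f"b{i}": "GenusB" for i in range(4)})
        genes = [_gene(f"g{i}") for i in range(13)]
        hits = [_hit(f"g{i}", s) for i, s in enumerate(genus)]
        a = assign_bacterial_genus("sc", genes, hits, genus)
        assert a.ratio < 0.70
        assert a.label == "unclassified"

    def test_synthetic_scaffolds_recover_their_genus(self, small_world):
        """Bacterial marker genes on synthetic scaffolds drive a perfect
        genus call through the full search path."""
        from phageome.seq_io import call_orfs, naive_protein_search

        _, refs, community, _ = small_world
        genus_of_subject = refs.genus_of_subject()
        checked = 0
        pro = {sid for sid, *_ in community.truth.prophage_intervals}
        for sc in community.all_scaffolds():
            if sc.id in pro or checked >= 5:
                continue
            genes = call_orfs(sc)
            hits = naive_protein_search(
                [SeqRecord(g.gene_id, g.protein) for g in genes],
                [SeqRecord(p.id, p.seq) for p in refs.protein_db],
                max_evalue=1e-5,
            )
            a = assign_bacterial_genus(sc.id, genes, hits, genus_of_subject)
            assert a.label == community.truth.scaffold_genus[sc.id]
            checked += 1
        assert checked == 5


class TestWeightedVotes:
    def test_single_hit_gene_contributes_only_top_weight(self):
        scores, n = weighted_votes(
            {"g1": [_hit("g1", "p1")]}, {"p1": "FamA"}
        )
        assert scores == {"FamA": 1.0}
        assert n == 1

    def test_duplicate_subject_not_double_counted(self):
        scores, _ = weighted_votes(
            {"g1": [_hit("g1", "p1", ev=1e-30), _hit("g1", "p1", ev=1e-20),
                    _hit("g1", "p2", ev=1e-10)]},
            {"p1": "FamA", "p2": "FamB"},
        )
        assert scores == {"FamA": 1.0, "FamB": 0.5}

    def test_same_family_top_two_accumulates_1_5(self):
        scores, _ = weighted_votes(
            {"g1": [_hit("g1", "p1", ev=1e-30), _hit("g1", "p2", ev=1e-20)]},
            {"p1": "FamA", "p2": "FamA"},
        )
        assert scores == {"FamA": 1.5}


class TestIdentifyLst:
    def test_planted_motifs_recovered_with_correct_domain(self, small_world):
        _, refs, _, _ = small_world
        terminases = [
            SeqRecord(m.gene_id, m.protein)
            for m in refs.marker_genes if m.gene_id.endswith("_m1")
        ]
        calls = identify_lst(terminases, SYNTHETIC_TERMINASE_MOTIFS)
        assert len(calls) == len(terminases)
        expected = {
            f"phage_{i + 1:03d}_m1": TERMINASE_DOMAINS[i % 4]
            for i in range(len(refs.phage_genomes))
        }
        for c in calls:
            assert c.domain == expected[c.gene_id]
            assert c.score == pytest.approx(1.0)

    def test_protein_without_motif_absent(self):
        calls = identify_lst(
            [SeqRecord("x", "MKLVNQERTIPASDFGHC" * 10)],
            SYNTHETIC_TERMINASE_MOTIFS,
        )
        assert calls == []

    def test_tie_broken_by_domain_name_order(self):
        m1 = SYNTHETIC_TERMINASE_MOTIFS["Terminase_1"]
        m3 = SYNTHETIC_TERMINASE_MOTIFS["Terminase_3"]
        protein = "M" + m3 + "AAAA" + m1 + "KKKK"
        calls = identify_lst([SeqRecord("x", protein)], SYNTHETIC_TERMINASE_MOTIFS)
        assert len(calls) == 1
        assert calls[0].domain == "Terminase_1"

    def test_pwm_motif_supported(self):
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        word = "WKRHFDEY"
        pwm = np.zeros((len(word), len(alphabet)))
        for i, aa in enumerate(word):
            pwm[i, alphabet.index(aa)] = 1.0
        calls = identify_lst(
            [SeqRecord("x", "MMM" + word + "MMM")], {"DomZ": pwm}
        )
        assert calls and calls[0].score == pytest.approx(1.0)

    def test_lst_tree_smoke(self, small_world):
        _, refs, _, _ = small_world
        terminases = [
            SeqRecord(m.gene_id, m.protein)
            for m in refs.marker_genes if m.gene_id.endswith("_m1")
        ][:5]
        tree = lst_tree(terminases)
        tips = {t.name for t in tree.tips()}
        assert tips == {t.id for t in terminases}
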