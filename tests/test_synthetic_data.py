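"""Generator correctness: determinism, truth-table closure, read origins."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from phageome.errors import ConfigError, GenerationError
from phageome.seq_io import translate_cds
from phageome.synthetic_data import (
    WorldConfig,
    expected_phage_fraction,
    generate_community,
    generate_references,
    generate_world,
    load_world,
    potu_keys,
    save_world,
    simulate_reads,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_phage_genomes", 0),
            ("prophage_rate", 1.5),
            ("crispr_rate", -0.1),
            ("read_len", -5),
            ("n_repeats_per_array", 2),
            ("phage_genome_len_range", (5000, 8000)),
            ("effect_fold_change", 0.5),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = dataclasses.replace(WorldConfig(), **{field: value})
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        assert field in str(err.value)

    def test_json_round_trip(self):
        cfg = WorldConfig(n_phage_genomes=9, rng_seed=3)
        assert WorldConfig.from_json(cfg.to_json()) == cfg


class TestReferences:
    def test_seeded_determinism_byte_identical(self, small_world):
        cfg, refs, community, reads = small_world
        refs2, community2, reads2 = generate_world(cfg)
        assert refs2.phage_genomes == refs.phage_genomes
        assert refs2.phage_taxonomy == refs.phage_taxonomy
        assert [s.seq for s in community2.all_scaffolds()] == [
            s.seq for s in community.all_scaffolds()
        ]
        assert {
            s: [r.seq for r in reads2.wcms[s]] for s in reads2.wcms
        } == {s: [r.seq for r in reads.wcms[s]] for s in reads.wcms}

    def test_taxonomy_has_one_row_of_six_fields_per_genome(self):
        cfg = dataclasses.replace(
            WorldConfig(), n_phage_genomes=5, n_effect_potus=0
        )
        refs = generate_references(cfg)
        assert len(refs.phage_taxonomy) == 5
        for tax in refs.phage_taxonomy.values():
            assert len(tax.astuple()) == 6
            assert all(tax.astuple())

    def test_markers_retranslate_to_protein_db_entries(self, small_world):
        _, refs, _, _ = small_world
        prot_db = {p.id: p.seq for p in refs.protein_db}
        for m in refs.marker_genes:
            genome = refs.phage_genomes[m.phage_id]
            assert translate_cds(genome[m.start : m.end]) == m.protein
            assert prot_db[m.gene_id] == m.protein

    def test_each_phage_has_enough_markers(self, small_world):
        cfg, refs, _, _ = small_world
        per_phage = {}
        for m in refs.marker_genes:
            per_phage[m.phage_id] = per_phage.get(m.phage_id, 0) + 1
        assert all(n >= 3 for n in per_phage.values())

    def test_protein_db_mixes_sources(self, small_world):
        _, refs, _, _ = small_world
        sources = {p.source for p in refs.protein_db}
        assert sources == {"phage", "bacteria"}


class TestCommunity:
    def test_prophage_rate_zero_no_intervals(self):
        cfg = dataclasses.replace(
            WorldConfig(),
            n_samples_per_group=1, n_scaffolds_per_sample=6, n_phage_genomes=4,
            prophage_rate=0.0, n_effect_potus=0, n_16s_copies_range=(2, 3),
        )
        refs = generate_references(cfg)
        community = generate_community(cfg, refs)
        assert community.truth.prophage_intervals == []

    def test_truth_closure_prophages_verbatim(self, small_world, scaffold_map):
        _, refs, community, _ = small_world
        for sid, a, b, pid in community.truth.prophage_intervals:
            assert scaffold_map[sid].seq[a:b] == refs.phage_genomes[pid]

    def test_truth_closure_spacers_verbatim(self, small_world, scaffold_map):
        _, refs, community, _ = small_world
        origin = {
            (aid, si): (pid, pos)
            for aid, si, pid, pos in community.truth.spacer_origins
        }
        for arr in community.truth.arrays:
            sc = scaffold_map[arr.scaffold_id]
            for si, (spid, a, b, seq) in enumerate(arr.spacers):
                assert sc.seq[a:b] == seq
                pid, pos = origin[(arr.array_id, si)]
                assert refs.phage_genomes[pid][pos : pos + len(seq)] == seq

    def test_truth_closure_16s_verbatim(self, small_world, scaffold_map):
        _, refs, community, _ = small_world
        for sid, a, b, genus in community.truth.ribosomal_intervals:
            assert scaffold_map[sid].seq[a:b] == refs.ribosomal[genus]

    def test_arrays_have_fence_post_spacer_count(self, small_world):
        cfg, _, community, _ = small_world
        for arr in community.truth.arrays:
            assert len(arr.repeat_starts) == cfg.n_repeats_per_array
            assert len(arr.spacers) == cfg.n_repeats_per_array - 1

    def test_group_design_balanced(self, small_world):
        cfg, _, community, _ = small_world
        groups = list(community.truth.sample_groups.values())
        assert groups.count("control") == cfg.n_samples_per_group
        assert groups.count("case") == cfg.n_samples_per_group

    def test_planted_effects_reference_real_potus(self, small_world):
        _, refs, community, _ = small_world
        keys = set(potu_keys(refs.phage_taxonomy))
        assert set(community.truth.planted_effects) <= keys

    def test_scaffold_too_short_raises(self):
        # a 100 bp backbone cannot host the marker/prophage/16S inserts
        cfg = dataclasses.replace(
            WorldConfig(), bacterial_scaffold_len_range=(100, 100)
        )
        refs = generate_references(cfg)
        with pytest.raises(GenerationError):
            generate_community(cfg, refs)


class TestReads:
    def test_vlp_reads_are_phage_substrings(self, small_world):
        _, refs, community, reads = small_world
        truth = community.truth
        for sample, pool in reads.vlp.items():
            for rec in pool[:50]:
                origin = truth.read_origins[rec.id]
                assert origin.kind == "phage"
                genome = refs.phage_genomes[origin.source_id]
                assert genome[origin.pos : origin.pos + len(rec.seq)] == rec.seq

    def test_wcms_read_origins_verbatim(self, small_world, scaffold_map):
        _, _, community, reads = small_world
        truth = community.truth
        for sample, pool in reads.wcms.items():
            for rec in pool[:50]:
                origin = truth.read_origins[rec.id]
                sc = scaffold_map[origin.source_id]
                assert sc.seq[origin.pos : origin.pos + len(rec.seq)] == rec.seq

    def test_phage_origin_count_within_binomial_bounds(self, small_world):
        cfg, refs, community, reads = small_world
        # 99% two-sided binomial interval around the exact expected fraction
        for sample in sorted(community.scaffolds):
            f = expected_phage_fraction(community, refs, sample, cfg.read_len)
            n = int(reads.totals.loc[sample, "wcms_total"])
            observed = int(reads.totals.loc[sample, "wcms_phage_origin"])
            lo, hi = stats.binom.ppf([0.005, 0.995], n, f)
            assert lo <= observed <= hi

    def test_zero_reads_allowed(self):
        cfg = dataclasses.replace(
            WorldConfig(),
            n_samples_per_group=1, n_scaffolds_per_sample=4, n_phage_genomes=4,
            reads_per_sample=0, vlp_reads_per_sample=0, n_effect_potus=0,
            n_16s_copies_range=(1, 2),
        )
        refs, community, reads = generate_world(cfg)
        assert all(len(v) == 0 for v in reads.wcms.values())
        assert all(len(v) == 0 for v in reads.vlp.values())

    def test_case_fold_boosts_effect_potu_read_share(self):
        """With fold 2 the case/control ratio of phage-origin read share for
        effect pOTUs is near 2 (averaged over samples)."""
        cfg = dataclasses.replace(
            WorldConfig(),
            n_samples_per_group=10, n_scaffolds_per_sample=12,
            n_phage_genomes=8, n_bacterial_genera=4, reads_per_sample=2000,
            vlp_reads_per_sample=0, n_effect_potus=2, effect_fold_change=2.0,
            n_16s_copies_range=(6, 8), rng_seed=9,
        )
        refs, community, reads = generate_world(cfg)
        truth = community.truth
        effect_phages = {
            pid for pid, tax in refs.phage_taxonomy.items()
            if tax.potu_key in truth.planted_effects
        }
        share = {"control": [], "case": []}
        counts_by_sample: dict[str, int] = {}
        for rid, origin in truth.read_origins.items():
            if origin.kind == "phage" and origin.phage_id in effect_phages \
                    and "|w" in rid:
                counts_by_sample[origin.sample_id] = (
                    counts_by_sample.get(origin.sample_id, 0) + 1
                )
        for sample, group in truth.sample_groups.items():
            share[group].append(counts_by_sample.get(sample, 0))
        ratio = np.mean(share["case"]) / np.mean(share["control"])
        assert 1.5 <= ratio <= 2.6


class TestPersistence:
    def test_save_load_round_trip(self, small_world, tmp_path):
        cfg, refs, community, reads = small_world
        save_world(tmp_path / "w", cfg, refs, community, reads)
        cfg2, refs2, community2, reads2 = load_world(tmp_path / "w")
        assert cfg2 == cfg
        assert refs2.phage_genomes == refs.phage_genomes
        assert refs2.phage_taxonomy == refs.phage_taxonomy
        assert sorted(community2.truth.prophage_intervals) == sorted(
            community.truth.prophage_intervals
        )
        assert community2.truth.sample_groups == community.truth.sample_groups
        for sample in reads.wcms:
            assert [r.seq for r in reads2.wcms[sample]] == [
                r.seq for r in reads.wcms[sample]
            ]
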