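"""End-to-end orchestration of the phageome analysis stages.

Stages run in dependency order (simulate -> annotate -> map -> crispr ->
discover -> assign -> profile -> hostnet -> coocc -> stats). Every stage is
a file-driven function on a run directory: it loads only the declared
outputs of earlier stages, writes its own report files, and returns its
results; :func:`run_all` is simply their composition. One structured log
line per stage records the counts at each filter, and a manifest records
package version, seed, parameters and output checksums — rerunning with
the same configuration reproduces identical checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cooccurrence as coocc_mod
from . import crispr as crispr_mod
from . import discovery, group_stats, host_network, mapping
from . import potu as potu_mod
from . import synthetic_data as synth
from . import taxonomy as tax_mod
from .errors import DataError
from .seq_io import (
    SeqRecord,
    call_orfs,
    naive_protein_search,
    read_genes,
    read_hits,
    write_genes,
    write_hits,
)

log = logging.getLogger("phageome")

_WORLD_CACHE: dict[str, tuple] = {}


@dataclass
class RunConfig:
    """All stage parameters with the pipeline's canonical defaults."""

    world: synth.WorldConfig = field(default_factory=synth.WorldConfig)
    min_scaffold_len: int = discovery.MIN_PHAGE_SCAFFOLD_LEN   # 10 kb
    vlp_min_breadth: float = discovery.VLP_MIN_BREADTH          # >= 0.40
    known_genome_min_breadth: float = 0.30                      # strict >
    homology_max_evalue: float = 1e-5
    min_phage_genes: int = 1
    ambiguity_factor: float = 2.0
    min_orf_aa: int = 33
    seed_len: int = 25
    min_identity: float = 0.95
    spacer_max_mismatch: int = 1
    prevalence_min_samples: int | None = None                   # default floor(N/2)
    r_threshold: float = coocc_mod.R_THRESHOLD                  # > 0.3
    p_threshold: float = coocc_mod.P_THRESHOLD                  # < 0.01
    n_permutations: int = 200
    p_flag: float = group_stats.P_FLAG                          # < 0.05
    q_flag: float = group_stats.Q_FLAG                          # FDR < 0.25
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        world = data.pop("world", {})
        cfg = cls(**data)
        if world:
            cfg.world = synth.WorldConfig.from_json(json.dumps(world))
        return cfg


#: per-stage log entries of the most recent stage invocations (run_all
#: snapshots this into the manifest)
_STAGE_LOG: dict[str, dict] = {}


def _log_stage(name: str, t0: float, **counts) -> dict:
    entry = {"time": round(time.time() - t0, 2), **counts}
    _STAGE_LOG[name] = entry
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))
    return entry


def _load_run(outdir: str | Path):
    out = Path(outdir)
    cfg_path = out / "run_config.json"
    if not cfg_path.exists():
        raise DataError(f"{out} is not a run directory (missing run_config.json)")
    config = RunConfig.from_json(cfg_path.read_text())
    key = str(out.resolve())
    if key not in _WORLD_CACHE:
        _WORLD_CACHE[key] = synth.load_world(out / "world")
    _, refs, community, reads = _WORLD_CACHE[key]
    return out, config, refs, community, reads


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: str | Path):
    """Generate the synthetic world and initialize the run directory."""
    t0 = time.time()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(config.to_json())
    world_cfg = dataclasses.replace(config.world, rng_seed=config.seed)
    refs, community, reads = synth.generate_world(world_cfg)
    synth.save_world(out / "world", world_cfg, refs, community, reads)
    _WORLD_CACHE[str(out.resolve())] = (world_cfg, refs, community, reads)
    return _log_stage(
        "simulate", t0,
        samples=len(community.scaffolds),
        scaffolds=len(community.all_scaffolds()),
        prophages=len(community.truth.prophage_intervals),
        arrays=len(community.truth.arrays),
    )


def stage_annotate(outdir: str | Path):
    """Call ORFs on large scaffolds and search them against the mixed
    bacterial+phage protein database."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    big = discovery.large_scaffolds(
        community.all_scaffolds(), config.min_scaffold_len
    )
    genes = []
    for sc in big:
        genes.extend(call_orfs(sc, min_aa=config.min_orf_aa))
    hits = naive_protein_search(
        [SeqRecord(g.gene_id, g.protein) for g in genes],
        [SeqRecord(p.id, p.seq) for p in refs.protein_db],
        max_evalue=config.homology_max_evalue,
    )
    write_genes(genes, out / "genes.tsv")
    write_hits(hits, out / "gene_hits.tsv")
    _log_stage(
        "annotate", t0, large_scaffolds=len(big), genes=len(genes), hits=len(hits)
    )
    return genes, hits


def stage_map(outdir: str | Path):
    """Map VLP reads to each sample's large scaffolds and write coverage.

    Without VLP reads the coverage table is empty, which disables Strategy
    II downstream; the degradation is recorded in the stage log."""
    t0 = time.time()
    out, config, refs, community, reads = _load_run(outdir)
    big_ids = {
        sc.id for sc in discovery.large_scaffolds(
            community.all_scaffolds(), config.min_scaffold_len
        )
    }
    vlp_cov: list[mapping.CoverageRecord] = []
    n_vlp = 0
    for sample in sorted(community.scaffolds):
        sample_refs = [
            sc for sc in community.scaffolds[sample] if sc.id in big_ids
        ]
        vreads = (reads.vlp if reads else {}).get(sample, [])
        n_vlp += len(vreads)
        if not vreads or not sample_refs:
            continue
        alns = mapping.map_reads(
            vreads, sample_refs, seed_len=config.seed_len,
            min_identity=config.min_identity,
        )
        vlp_cov.extend(
            mapping.coverage_stats(alns, {s.id: s.length for s in sample_refs})
        )
    with open(out / "vlp_coverage.tsv", "w") as fh:
        fh.write("ref_id\tn_reads\tbreadth\tdepth\n")
        for c in vlp_cov:
            fh.write(f"{c.ref_id}\t{c.n_reads}\t{c.breadth:.6g}\t{c.depth:.6g}\n")
    _log_stage(
        "map", t0, vlp_reads=n_vlp, coverage_records=len(vlp_cov),
        strategy_II="enabled" if n_vlp else "disabled(no VLP reads)",
    )
    return vlp_cov


def _read_vlp_coverage(out: Path) -> list[mapping.CoverageRecord]:
    path = out / "vlp_coverage.tsv"
    if not path.exists():
        return []
    df = pd.read_csv(path, sep="\t")
    return [
        mapping.CoverageRecord(r.ref_id, float(r.breadth), float(r.depth),
                               int(r.n_reads))
        for r in df.itertuples()
    ]


def stage_crispr(outdir: str | Path):
    """Detect CRISPR arrays on large scaffolds, extract spacers and match
    them against all large scaffolds."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    big = discovery.large_scaffolds(
        community.all_scaffolds(), config.min_scaffold_len
    )
    arrays = []
    for sc in big:
        arrays.extend(crispr_mod.detect_arrays(sc))
    sample_of_scaffold = {sc.id: sc.sample_id for sc in community.all_scaffolds()}
    spacers = crispr_mod.extract_spacers(arrays, sample_of_scaffold)
    matches = crispr_mod.match_spacers(
        spacers, big, max_mismatch=config.spacer_max_mismatch
    )
    with open(out / "crispr_arrays.tsv", "w") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        fh.write("array_id\tscaffold_id\trepeat_consensus\tn_repeats\tn_spacers\n")
        for arr in arrays:
            fh.write(
                f"{arr.array_id}\t{arr.scaffold_id}\t{arr.repeat_consensus}\t"
                f"{len(arr.repeats)}\t{len(arr.spacers)}\n"
            )
    with open(out / "spacers.tsv", "w") as fh:
        fh.write("spacer_id\tscaffold_id\tsample_id\tseq\n")
        for sp in spacers:
            fh.write(f"{sp.spacer_id}\t{sp.scaffold_id}\t{sp.sample_id}\t{sp.seq}\n")
    with open(out / "spacer_matches.tsv", "w") as fh:
        fh.write("spacer_id\ttarget\tposition\tstrand\tmismatches\tsame_sample\n")
        for m in matches:
            fh.write(
                f"{m.spacer_id}\t{m.target_id}\t{m.position}\t{m.strand}\t"
                f"{m.mismatches}\t{int(m.same_sample)}\n"
            )
    _log_stage(
        "crispr", t0, arrays=len(arrays), spacers=len(spacers),
        matches=len(matches),
    )
    return arrays, spacers, matches


def _read_spacer_matches(out: Path) -> list[crispr_mod.SpacerMatch]:
    path = out / "spacer_matches.tsv"
    if not path.exists():
        return []
    df = pd.read_csv(path, sep="\t")
    return [
        crispr_mod.SpacerMatch(
            r.spacer_id, r.target, int(r.position), r.strand,
            int(r.mismatches), bool(r.same_sample),
        )
        for r in df.itertuples()
    ]


def _read_spacer_table(out: Path) -> dict[str, str]:
    path = out / "spacers.tsv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.spacer_id, df.scaffold_id))


def stage_discover(outdir: str | Path):
    """Combine the three evidence strategies and the ambiguity screen."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    genes = read_genes(out / "genes.tsv")
    hits = read_hits(out / "gene_hits.tsv")
    vlp_cov = _read_vlp_coverage(out)
    matches = _read_spacer_matches(out)
    scaffold_of_spacer = _read_spacer_table(out)
    big = discovery.large_scaffolds(
        community.all_scaffolds(), config.min_scaffold_len
    )
    big_ids = [sc.id for sc in big]
    set_i = discovery.strategy_spacer(big_ids, matches, scaffold_of_spacer)
    set_ii = discovery.strategy_vlp(big_ids, vlp_cov, config.vlp_min_breadth)
    phage_subjects = {p.id for p in refs.protein_db if p.source == "phage"}
    set_iii = discovery.strategy_homology(
        genes, hits, phage_subjects,
        max_evalue=config.homology_max_evalue,
        min_phage_genes=config.min_phage_genes,
    )
    spacer_evidence: dict[str, tuple[str, ...]] = {}
    for m in matches:
        if scaffold_of_spacer.get(m.spacer_id) != m.target_id:
            spacer_evidence[m.target_id] = spacer_evidence.get(m.target_id, ()) + (
                m.spacer_id,
            )
    calls, venn = discovery.merge_and_screen(
        {"I": set_i, "II": set_ii, "III": set_iii},
        {sc.id: sc for sc in big},
        genes,
        hits,
        {p.id: p.source for p in refs.protein_db},
        ambiguity_factor=config.ambiguity_factor,
        max_evalue=config.homology_max_evalue,
        spacer_evidence=spacer_evidence,
        vlp_breadth=discovery.best_vlp_breadth(vlp_cov),
    )
    with open(out / "phage_calls.tsv", "w") as fh:
        fh.write(
            "scaffold_id\tlength\tstrategies\tstatus\tn_phage_gene_hits\t"
            "vlp_breadth\n"
        )
        for c in calls:
            fh.write(
                f"{c.scaffold_id}\t{c.length}\t{''.join(sorted(c.strategies))}\t"
                f"{c.status}\t{c.n_phage_gene_hits}\t{c.vlp_breadth:.4g}\n"
            )
    (out / "venn.json").write_text(json.dumps(venn, indent=2))
    _log_stage(
        "discover", t0,
        strategy_I=len(set_i), strategy_II=len(set_ii), strategy_III=len(set_iii),
        candidates=len(calls),
        accepted=sum(c.accepted for c in calls),
    )
    return calls, venn


def _read_calls(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "phage_calls.tsv", sep="\t")


def stage_assign(outdir: str | Path):
    """PFR family assignment of accepted phage scaffolds, BGR genus
    assignment of array-bearing scaffolds, and terminase identification."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    genes = read_genes(out / "genes.tsv")
    hits = read_hits(out / "gene_hits.tsv")
    calls = _read_calls(out)
    accepted = set(calls[calls.status == "accepted"].scaffold_id)
    arrays = pd.read_csv(out / "crispr_arrays.tsv", sep="\t", comment="#")
    array_scaffolds = sorted(set(arrays.scaffold_id))
    genes_by_scaffold: dict[str, list] = {}
    for g in genes:
        genes_by_scaffold.setdefault(g.scaffold_id, []).append(g)
    hits_by_scaffold: dict[str, list] = {}
    gene_scaffold = {g.gene_id: g.scaffold_id for g in genes}
    for h in hits:
        sid = gene_scaffold.get(h.query_id)
        if sid is not None:
            hits_by_scaffold.setdefault(sid, []).append(h)
    fam_of_subject = refs.family_of_subject()
    genus_of_subject = refs.genus_of_subject()
    family_assignments = {
        sid: tax_mod.assign_phage_family(
            sid, genes_by_scaffold.get(sid, []), hits_by_scaffold.get(sid, []),
            fam_of_subject, max_evalue=config.homology_max_evalue,
        )
        for sid in sorted(accepted)
    }
    genus_assignments = {
        sid: tax_mod.assign_bacterial_genus(
            sid, genes_by_scaffold.get(sid, []), hits_by_scaffold.get(sid, []),
            genus_of_subject, max_evalue=config.homology_max_evalue,
        )
        for sid in array_scaffolds
    }
    lst_calls = tax_mod.identify_lst(
        [
            SeqRecord(g.gene_id, g.protein)
            for sid in sorted(accepted)
            for g in genes_by_scaffold.get(sid, [])
        ],
        synth.SYNTHETIC_TERMINASE_MOTIFS,
    )
    with open(out / "taxonomy.tsv", "w") as fh:
        fh.write("scaffold_id\tlevel\tlabel\tratio\tgene_votes\n")
        for a in list(family_assignments.values()) + list(genus_assignments.values()):
            fh.write(
                f"{a.scaffold_id}\t{a.level}\t{a.label}\t{a.ratio:.4g}\t"
                f"{a.gene_votes}\n"
            )
    with open(out / "lst_calls.tsv", "w") as fh:
        fh.write("gene_id\tdomain\tscore\n")
        for c in lst_calls:
            fh.write(f"{c.gene_id}\t{c.domain}\t{c.score:.4g}\n")
    _log_stage(
        "assign", t0,
        family_assigned=sum(
            a.label != "unclassified" for a in family_assignments.values()
        ),
        genus_assigned=sum(
            a.label != "unclassified" for a in genus_assignments.values()
        ),
        lst_calls=len(lst_calls),
    )
    return family_assignments, genus_assignments, lst_calls


def stage_profile(outdir: str | Path):
    """pOTU definition and 16S-normalized abundance, plus per-sample phage
    load over the accepted scaffolds."""
    t0 = time.time()
    out, config, refs, community, reads = _load_run(outdir)
    if reads is None:
        raise DataError("profiling requires simulated reads in the run directory")
    potus = potu_mod.define_potus(refs.phage_taxonomy)
    genome_counts = potu_mod.count_genome_reads(
        reads.wcms, refs.marker_genes,
        seed_len=config.seed_len, min_identity=config.min_identity,
    )
    n16s = potu_mod.count_16s(
        reads.wcms, refs.ribosomal,
        seed_len=config.seed_len, min_identity=config.min_identity,
    )
    abundance, family_abundance = potu_mod.potu_abundance(
        genome_counts, potus, n16s
    )
    abundance.to_csv(out / "potu_abundance.tsv", sep="\t")
    family_abundance.to_csv(out / "family_abundance.tsv", sep="\t")
    genome_counts.to_csv(out / "genome_counts.tsv", sep="\t")
    (out / "potu_registry.json").write_text(
        json.dumps({p.potu_id: sorted(p.members) for p in potus}, indent=2)
    )

    calls = _read_calls(out)
    accepted = set(calls[calls.status == "accepted"].scaffold_id)
    accepted_alns: dict[str, list] = {}
    totals: dict[str, int] = {}
    for sample in sorted(community.scaffolds):
        wreads = reads.wcms.get(sample, [])
        totals[sample] = max(len(wreads), 1)
        sample_accepted = [
            sc for sc in community.scaffolds[sample] if sc.id in accepted
        ]
        accepted_alns[sample] = (
            mapping.map_reads(
                wreads, sample_accepted, seed_len=config.seed_len,
                min_identity=config.min_identity,
            )
            if wreads and sample_accepted
            else []
        )
    _, phage_load = mapping.scaffold_relative_abundance(accepted_alns, totals)
    phage_load.to_frame().to_csv(out / "phage_load.tsv", sep="\t")
    _log_stage(
        "profile", t0, potus=len(potus), mean_n16s=round(float(n16s.mean()), 2),
        mean_phage_load=round(float(phage_load.mean()), 4),
    )
    return potus, genome_counts, n16s, abundance, family_abundance, phage_load


def stage_hostnet(outdir: str | Path):
    """Spacer-based phage-host network over accepted scaffolds."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    matches = _read_spacer_matches(out)
    scaffold_of_spacer = _read_spacer_table(out)
    calls = _read_calls(out)
    accepted = set(calls[calls.status == "accepted"].scaffold_id)
    taxa = pd.read_csv(out / "taxonomy.tsv", sep="\t")
    fam = dict(
        zip(taxa[taxa.level == "family"].scaffold_id,
            taxa[taxa.level == "family"].label)
    )
    gen = dict(
        zip(taxa[taxa.level == "genus"].scaffold_id,
            taxa[taxa.level == "genus"].label)
    )
    phage_matches = [m for m in matches if m.target_id in accepted]
    edges = host_network.build_network(phage_matches, scaffold_of_spacer, fam, gen)
    specificity = host_network.specificity_stats(
        host_network.genus_network(edges), phage_matches
    )
    host_network.write_edges(edges, out / "host_edges.tsv")
    host_network.write_graphml(edges, out / "host_network.graphml")
    clean = {
        k: v for k, v in specificity.items() if k != "host_genera_per_phage"
    }
    (out / "host_specificity.json").write_text(json.dumps(clean, indent=2))
    _log_stage("hostnet", t0, edges=len(edges), **{
        k: round(v, 4) if isinstance(v, float) else v
        for k, v in clean.items() if not isinstance(v, list)
    })
    return edges, specificity


def stage_coocc(outdir: str | Path):
    """SparCC-style co-occurrence network between genera and pOTUs."""
    t0 = time.time()
    out, config, refs, community, reads = _load_run(outdir)
    genome_counts = pd.read_csv(out / "genome_counts.tsv", sep="\t", index_col=0)
    registry = json.loads((out / "potu_registry.json").read_text())
    potu_counts = pd.DataFrame(
        {
            potu_id: genome_counts[
                [m for m in members if m in genome_counts.columns]
            ].sum(axis=1)
            for potu_id, members in registry.items()
        },
        index=genome_counts.index,
    )
    # SparCC operates on counts: scale the relative genus profile back to
    # integer pseudo-counts with each sample's sequencing depth
    genus_profile = community.truth.genus_profile
    depth = (
        reads.totals["wcms_total"]
        if reads is not None
        else pd.Series(10_000, index=genus_profile.index)
    )
    genus_counts = (
        genus_profile.mul(depth, axis=0).round().astype(int)
    )
    joint = pd.concat([genus_counts, potu_counts], axis=1)
    min_prev = (
        config.prevalence_min_samples
        if config.prevalence_min_samples is not None
        else len(joint.index) // 2
    )
    filtered = coocc_mod.prevalence_filter(joint, min_samples=min_prev)
    edges: list = []
    if filtered.shape[1] >= 4:
        corr = coocc_mod.sparcc_corr(filtered, seed=config.seed + 101)
        pmat = coocc_mod.permutation_p(
            filtered, corr, n_perm=config.n_permutations, seed=config.seed + 202
        )
        node_types = {
            c: ("bacterium" if c in genus_profile.columns else "pOTU")
            for c in filtered.columns
        }
        edges, _nodes = coocc_mod.build_coocc_network(
            corr, pmat, node_types,
            r_threshold=config.r_threshold, p_threshold=config.p_threshold,
        )
        coocc_mod.write_coocc_edges(edges, out / "coocc_edges.tsv")
        prevalence = (filtered > 0).sum(axis=0).to_dict()
        coocc_mod.write_coocc_graphml(
            edges, out / "coocc_network.graphml", prevalence
        )
    _log_stage(
        "coocc", t0, taxa_after_prevalence=int(filtered.shape[1]),
        edges=len(edges),
    )
    return edges


def stage_stats(outdir: str | Path):
    """Differential pOTU analysis, phage-load test, Chao2 and rarefaction."""
    t0 = time.time()
    out, config, refs, community, _ = _load_run(outdir)
    truth = community.truth
    abundance = pd.read_csv(out / "potu_abundance.tsv", sep="\t", index_col=0)
    abund_vals = potu_mod.abundance_values(abundance)
    diff_results = group_stats.differential_phageome(
        abund_vals, truth.sample_groups,
        p_flag=config.p_flag, q_flag=config.q_flag,
    )
    load = pd.read_csv(out / "phage_load.tsv", sep="\t", index_col=0)["phage_load"]
    load_result = group_stats.phage_load_test(load, truth.sample_groups)
    incidence = (abund_vals.fillna(0.0) > 0).T
    chao2_potu = group_stats.chao2(incidence)
    curves = group_stats.rarefaction_by_group(
        incidence, truth.sample_groups, n_permutations=50, seed=config.seed + 303
    )
    with open(out / "differential.tsv", "w") as fh:
        fh.write("feature_id\tlevel\tU\tp\tq\tdirection\tprevalence\tsignificant\n")
        for r in diff_results + [load_result]:
            fh.write(
                f"{r.feature_id}\t{r.level}\t{r.u_statistic:.6g}\t{r.p:.6g}\t"
                f"{r.q:.6g}\t{r.direction}\t{r.prevalence}\t{int(r.significant)}\n"
            )
    summary = {
        "chao2_potu_richness": chao2_potu,
        "n_significant": int(sum(r.significant for r in diff_results)),
        "phage_load_p": load_result.p,
        "rarefaction": {g: list(map(float, c)) for g, c in curves.items()},
    }
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=2))
    _log_stage("stats", t0, significant=summary["n_significant"])
    return diff_results, load_result, chao2_potu, curves


# ---------------------------------------------------------------------------
# full run


@dataclass
class RunResult:
    """In-memory results of a full run (also materialized in outdir)."""

    refs: synth.ReferenceSet
    community: synth.Community
    reads: synth.ReadSet
    calls: list
    venn: dict
    accepted: set[str]
    family_assignments: dict
    genus_assignments: dict
    lst_calls: list
    potus: list
    genome_counts: pd.DataFrame
    n16s: pd.Series
    abundance: pd.DataFrame
    family_abundance: pd.DataFrame
    phage_load: pd.Series
    host_edges: list
    specificity: dict
    coocc_edges: list
    diff_results: list
    load_result: object
    chao2_potu: float
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> RunResult:
    """Run every stage in dependency order and write the manifest."""
    out = Path(outdir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": json.loads(config.to_json()),
        "stages": {},
        "checksums": {},
    }
    _STAGE_LOG.clear()
    stage_simulate(config, out)
    stage_annotate(out)
    stage_map(out)
    stage_crispr(out)
    calls, venn = stage_discover(out)
    family_assignments, genus_assignments, lst_calls = stage_assign(out)
    potus, genome_counts, n16s, abundance, family_abundance, phage_load = (
        stage_profile(out)
    )
    host_edges, specificity = stage_hostnet(out)
    coocc_edges = stage_coocc(out)
    diff_results, load_result, chao2_potu, _curves = stage_stats(out)
    manifest["stages"] = dict(_STAGE_LOG)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    _, refs, community, reads = _WORLD_CACHE[str(out.resolve())]
    return RunResult(
        refs=refs, community=community, reads=reads, calls=calls, venn=venn,
        accepted={c.scaffold_id for c in calls if c.accepted},
        family_assignments=family_assignments,
        genus_assignments=genus_assignments, lst_calls=lst_calls,
        potus=potus, genome_counts=genome_counts, n16s=n16s,
        abundance=abundance, family_abundance=family_abundance,
        phage_load=phage_load, host_edges=host_edges, specificity=specificity,
        coocc_edges=coocc_edges, diff_results=diff_results,
        load_result=load_result, chao2_potu=chao2_potu, manifest=manifest,
    )
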