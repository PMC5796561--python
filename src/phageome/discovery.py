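"""Identification of large phage scaffolds by three evidence strategies.

Only large scaffolds (>= 10 kb) are considered. A scaffold is called as
putative phage when (I) it is probed by CRISPR spacer(s) carried by a
different scaffold, (II) reads from the virus-like-particle (VLP)
metagenome cover it with breadth >= 40%, or (III) it encodes gene(s)
homologous to known phage genes. Candidates whose genes look predominantly
bacterial are discarded as ambiguous: the manual curation step of the
original procedure is codified here as a deterministic bit-score ratio
rule against a mixed bacterial+phage protein database. Free phage and
integrated prophage are deliberately not distinguished.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .crispr import SpacerMatch
from .mapping import CoverageRecord
from .seq_io import Gene, HitRecord, Scaffold

MIN_PHAGE_SCAFFOLD_LEN = 10_000
VLP_MIN_BREADTH = 0.40
HOMOLOGY_MAX_EVALUE = 1e-5

STRATEGY_SPACER = "I"
STRATEGY_VLP = "II"
STRATEGY_HOMOLOGY = "III"


@dataclass(frozen=True)
class PhageCall:
    scaffold_id: str
    length: int
    strategies: frozenset[str]
    status: str  # 'accepted' | 'discarded_ambiguous'
    spacer_ids: tuple[str, ...] = ()
    vlp_breadth: float = 0.0
    n_phage_gene_hits: int = 0
    bacterial_bitscore: float = 0.0
    phage_bitscore: float = 0.0

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def large_scaffolds(
    scaffolds: Iterable[Scaffold], min_len: int = MIN_PHAGE_SCAFFOLD_LEN
) -> list[Scaffold]:
    """The length filter applied before every strategy."""
    return [s for s in scaffolds if s.length >= min_len]


def strategy_spacer(
    scaffold_ids: Iterable[str],
    spacer_matches: Iterable[SpacerMatch],
    scaffold_of_spacer: Mapping[str, str],
) -> set[str]:
    """Strategy I: scaffolds probed by >= 1 CRISPR spacer whose array lives
    on a *different* scaffold (self-targeting matches are ignored)."""
    eligible = set(scaffold_ids)
    out = set()
    for m in spacer_matches:
        if m.target_id not in eligible:
            continue
        if scaffold_of_spacer.get(m.spacer_id) == m.target_id:
            continue
        out.add(m.target_id)
    return out


def strategy_vlp(
    scaffold_ids: Iterable[str],
    vlp_coverage: Iterable[CoverageRecord],
    min_breadth: float = VLP_MIN_BREADTH,
) -> set[str]:
    """Strategy II: scaffolds mapped by VLP reads with breadth >= 40%
    (inclusive comparator, distinct from the strict > 30% known-genome
    screen)."""
    eligible = set(scaffold_ids)
    return {
        c.ref_id
        for c in vlp_coverage
        if c.ref_id in eligible and c.breadth >= min_breadth
    }


def best_vlp_breadth(vlp_coverage: Iterable[CoverageRecord]) -> dict[str, float]:
    best: dict[str, float] = {}
    for c in vlp_coverage:
        if c.breadth > best.get(c.ref_id, -1.0):
            best[c.ref_id] = c.breadth
    return best


def strategy_homology(
    genes: Iterable[Gene],
    hits: Iterable[HitRecord],
    phage_subjects: Iterable[str],
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
    min_phage_genes: int = 1,
) -> set[str]:
    """Strategy III: scaffolds with >= ``min_phage_genes`` genes hitting
    phage proteins at e <= 1e-05."""
    phage_subjects = set(phage_subjects)
    scaffold_of_gene = {g.gene_id: g.scaffold_id for g in genes}
    voting: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if h.evalue > max_evalue or h.subject_id not in phage_subjects:
            continue
        sid = scaffold_of_gene.get(h.query_id)
        if sid is not None:
            voting[sid].add(h.query_id)
    return {sid for sid, gs in voting.items() if len(gs) >= min_phage_genes}


def merge_and_screen(
    strategy_sets: Mapping[str, set[str]],
    scaffolds: Mapping[str, Scaffold],
    genes: Iterable[Gene],
    hits: Iterable[HitRecord],
    subject_source: Mapping[str, str],
    ambiguity_factor: float = 2.0,
    max_evalue: float = HOMOLOGY_MAX_EVALUE,
    spacer_evidence: Mapping[str, tuple[str, ...]] | None = None,
    vlp_breadth: Mapping[str, float] | None = None,
) -> tuple[list[PhageCall], dict[str, int]]:
    """Union the strategy sets, apply the ambiguity screen, and report the
    per-strategy Venn counts of the accepted calls.

    A candidate is ``discarded_ambiguous`` when the summed best bit-score of
    its genes against bacterial-source proteins exceeds ``ambiguity_factor``
    times the summed best bit-score against phage-source proteins — a
    deterministic stand-in for the original manual curation.
    """
    spacer_evidence = spacer_evidence or {}
    vlp_breadth = vlp_breadth or {}
    union: set[str] = set()
    for s in strategy_sets.values():
        union |= s
    genes_by_scaffold: dict[str, list[str]] = defaultdict(list)
    for g in genes:
        genes_by_scaffold[g.scaffold_id].append(g.gene_id)
    best_by_gene: dict[str, dict[str, float]] = defaultdict(
        lambda: {"phage": 0.0, "bacteria": 0.0}
    )
    n_phage_hits: dict[str, set[str]] = defaultdict(set)
    gene_scaffold = {
        gid: sid for sid, gids in genes_by_scaffold.items() for gid in gids
    }
    for h in hits:
        if h.evalue > max_evalue:
            continue
        src = subject_source.get(h.subject_id)
        if src not in ("phage", "bacteria"):
            continue
        slot = best_by_gene[h.query_id]
        slot[src] = max(slot[src], h.bitscore)
        if src == "phage" and h.query_id in gene_scaffold:
            n_phage_hits[gene_scaffold[h.query_id]].add(h.query_id)

    calls: list[PhageCall] = []
    for sid in sorted(union):
        strategies = frozenset(
            name for name, members in strategy_sets.items() if sid in members
        )
        phage_score = sum(
            best_by_gene[gid]["phage"]
            for gid in genes_by_scaffold.get(sid, ())
            if gid in best_by_gene
        )
        bact_score = sum(
            best_by_gene[gid]["bacteria"]
            for gid in genes_by_scaffold.get(sid, ())
            if gid in best_by_gene
        )
        ambiguous = bact_score > ambiguity_factor * phage_score and bact_score > 0
        calls.append(
            PhageCall(
                scaffold_id=sid,
                length=scaffolds[sid].length if sid in scaffolds else 0,
                strategies=strategies,
                status="discarded_ambiguous" if ambiguous else "accepted",
                spacer_ids=tuple(spacer_evidence.get(sid, ())),
                vlp_breadth=float(vlp_breadth.get(sid, 0.0)),
                n_phage_gene_hits=len(n_phage_hits.get(sid, ())),
                bacterial_bitscore=bact_score,
                phage_bitscore=phage_score,
            )
        )
    venn = venn_counts([c for c in calls if c.accepted])
    return calls, venn


def venn_counts(calls: Sequence[PhageCall]) -> dict[str, int]:
    """Disjoint cell counts over the three strategies; cells sum to the
    number of calls."""
    cells = {
        "I": 0, "II": 0, "III": 0, "I&II": 0, "I&III": 0, "II&III": 0,
        "I&II&III": 0,
    }
    for c in calls:
        key = "&".join(
            s for s in (STRATEGY_SPACER, STRATEGY_VLP, STRATEGY_HOMOLOGY)
            if s in c.strategies
        )
        if key:
            cells[key] += 1
    return cells
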