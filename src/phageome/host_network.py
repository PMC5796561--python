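"""Spacer-based phage-host bipartite network and specificity statistics.

Each CRISPR spacer match links the bacterial scaffold carrying the array
(the spacer records that bacterium's infection history) to the targeted
phage scaffold. Edges aggregate spacer multiplicity per (phage scaffold,
bacterial scaffold) pair; self-links are excluded, consistent with the
self-targeting guard of the discovery stage. The genus-level network view
keeps only bacterial scaffolds that could be assigned taxonomically.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .crispr import SpacerMatch
from .taxonomy import TaxAssignment


@dataclass(frozen=True)
class HostEdge:
    phage_scaffold_id: str
    bacterial_scaffold_id: str
    n_spacers: int
    phage_family: str
    host_genus: str


def build_network(
    spacer_matches: Iterable[SpacerMatch],
    scaffold_of_spacer: Mapping[str, str],
    phage_family: Mapping[str, str] | Iterable[TaxAssignment] = (),
    bacterial_genus: Mapping[str, str] | Iterable[TaxAssignment] = (),
) -> list[HostEdge]:
    """One edge per (phage scaffold, bacterial scaffold) pair with spacer
    multiplicity. Taxonomic labels default to 'unclassified'; unclassified
    bacteria are kept in this raw edge list and dropped only by
    :func:`genus_network`."""
    fam = _as_label_map(phage_family)
    gen = _as_label_map(bacterial_genus)
    spacer_sets: dict[tuple[str, str], set[str]] = defaultdict(set)
    for m in spacer_matches:
        bact = scaffold_of_spacer.get(m.spacer_id)
        if bact is None or bact == m.target_id:
            continue
        spacer_sets[(m.target_id, bact)].add(m.spacer_id)
    return [
        HostEdge(
            phage, bact, len(spacers),
            fam.get(phage, "unclassified"), gen.get(bact, "unclassified"),
        )
        for (phage, bact), spacers in sorted(spacer_sets.items())
    ]


def _as_label_map(source) -> dict[str, str]:
    if isinstance(source, Mapping):
        return dict(source)
    return {a.scaffold_id: a.label for a in source}


def genus_network(edges: Iterable[HostEdge]) -> list[HostEdge]:
    """Only edges whose bacterial scaffold was taxonomically assigned."""
    return [e for e in edges if e.host_genus != "unclassified"]


def specificity_stats(
    edges: Sequence[HostEdge],
    spacer_matches: Iterable[SpacerMatch] = (),
) -> dict:
    """Host-specificity summary of the network.

    Reports, per phage scaffold, the number of distinct host genera among
    its assigned partners; the fraction of phage scaffolds with exactly one
    host genus; the multi-genus phages; and (when matches are supplied) the
    fraction of spacer-phage pairings whose spacer and target co-existed in
    the same sample.
    """
    if not edges:
        return {
            "n_phage_scaffolds": 0,
            "n_bacterial_scaffolds": 0,
            "n_edges": 0,
            "host_genera_per_phage": {},
            "specificity_fraction": float("nan"),
            "multi_genus_phages": [],
            "same_sample_fraction": float("nan"),
            "n_same_sample": 0,
            "n_pairings": 0,
        }
    genera_of: dict[str, set[str]] = defaultdict(set)
    for e in edges:
        if e.host_genus != "unclassified":
            genera_of[e.phage_scaffold_id].add(e.host_genus)
    counts = {p: len(gs) for p, gs in genera_of.items()}
    single = [p for p, c in counts.items() if c == 1]
    multi = sorted(p for p, c in counts.items() if c > 1)
    matches = list(spacer_matches)
    n_same = sum(m.same_sample for m in matches)
    return {
        "n_phage_scaffolds": len({e.phage_scaffold_id for e in edges}),
        "n_bacterial_scaffolds": len({e.bacterial_scaffold_id for e in edges}),
        "n_edges": len(edges),
        "host_genera_per_phage": counts,
        "specificity_fraction": (
            len(single) / len(counts) if counts else float("nan")
        ),
        "multi_genus_phages": multi,
        "same_sample_fraction": (
            n_same / len(matches) if matches else float("nan")
        ),
        "n_same_sample": n_same,
        "n_pairings": len(matches),
    }


def to_graph(edges: Iterable[HostEdge]) -> nx.Graph:
    """Bipartite graph; edge direction is conceptually bacterium -> phage,
    encoded on the edge attribute since the graph is undirected."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.phage_scaffold_id, kind="phage", family=e.phage_family)
        g.add_node(e.bacterial_scaffold_id, kind="bacterium", genus=e.host_genus)
        g.add_edge(
            e.bacterial_scaffold_id,
            e.phage_scaffold_id,
            n_spacers=e.n_spacers,
            direction="bacterium->phage",
        )
    return g


def write_graphml(edges: Iterable[HostEdge], path: str | Path) -> None:
    nx.write_graphml(to_graph(edges), str(path))


def write_edges(edges: Iterable[HostEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "phage_scaffold_id\tbacterial_scaffold_id\tn_spacers\t"
            "phage_family\thost_genus\n"
        )
        for e in edges:
            fh.write(
                f"{e.phage_scaffold_id}\t{e.bacterial_scaffold_id}\t"
                f"{e.n_spacers}\t{e.phage_family}\t{e.host_genus}\n"
            )
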