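"""Phage OTU definition and 16S-normalized read-level profiling.

A pOTU is the collection of all phages sharing the same taxonomic names at
all five levels (group|order|family|subfamily|genus) and hosts within the
same bacterial genus; missing levels must carry explicit
"unclassified_<level>" tokens so the partition stays well defined. The
relative number of a pOTU in a sample is the summed read count of its
member genomes divided by the sample's 16S rRNA gene read count — a
dimensionless, per-16S quantity that is deliberately not renormalized
across pOTUs.

Reads are attributed to genomes by nucleotide matching against the
phage-specific marker-gene database: each read is assigned to the genome of
its best marker hit, and reads tying between genomes are discarded.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .mapping import map_reads
from .seq_io import SeqRecord
from .synthetic_data import MarkerGene, PhageTaxonomy


@dataclass(frozen=True)
class POTU:
    potu_id: str                  # "group|order|family|subfamily|genus|host_genus"
    members: frozenset[str]       # phage genome ids
    family: str


def define_potus(taxonomy: Mapping[str, PhageTaxonomy]) -> list[POTU]:
    """Partition genomes by (five-level taxonomy, host genus); ids are the
    joined taxon strings, hence deterministic."""
    for pid, tax in taxonomy.items():
        for level, value in zip(
            ("group", "order", "family", "subfamily", "genus", "host_genus"),
            tax.astuple(),
        ):
            if not value:
                raise DataError(
                    f"genome {pid!r} has an empty {level} level; use an "
                    f"explicit 'unclassified_{level}' token"
                )
    groups: dict[str, set[str]] = defaultdict(set)
    family: dict[str, str] = {}
    for pid, tax in taxonomy.items():
        key = tax.potu_key
        groups[key].add(pid)
        family[key] = tax.family
    return [
        POTU(key, frozenset(members), family[key])
        for key, members in sorted(groups.items())
    ]


def count_genome_reads(
    reads_by_sample: Mapping[str, Sequence[SeqRecord]],
    marker_genes: Sequence[MarkerGene],
    seed_len: int = 25,
    min_identity: float = 0.95,
) -> pd.DataFrame:
    """Per (sample, genome) read counts by best marker-gene hit.

    A read counts for a genome when all of its best-scoring marker
    placements belong to that genome; reads with equally good hits to
    markers of different genomes are discarded.
    """
    genome_of = {m.gene_id: m.phage_id for m in marker_genes}
    marker_seqs = [SeqRecord(m.gene_id, m.cds) for m in marker_genes]
    genomes = sorted({m.phage_id for m in marker_genes})
    rows = {}
    for sample in sorted(reads_by_sample):
        counts = dict.fromkeys(genomes, 0)
        reads = reads_by_sample[sample]
        if reads:
            placements = map_reads(
                reads, marker_seqs, seed_len=seed_len,
                min_identity=min_identity, all_best=True,
            )
            for rid, alns in placements.items():
                hit_genomes = {genome_of[a.ref_id] for a in alns}
                if len(hit_genomes) == 1:
                    counts[hit_genomes.pop()] += 1
        rows[sample] = counts
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def count_16s(
    reads_by_sample: Mapping[str, Sequence[SeqRecord]],
    ribosomal_db: Mapping[str, str] | Sequence[SeqRecord],
    seed_len: int = 25,
    min_identity: float = 0.95,
) -> pd.Series:
    """16S read count per sample: reads mapping to any ribosomal reference,
    counted once. Samples with zero 16S reads are reported as 0 and flagged
    downstream (their pOTU values become missing)."""
    if isinstance(ribosomal_db, Mapping):
        refs = [SeqRecord(k, v) for k, v in sorted(ribosomal_db.items())]
    else:
        refs = list(ribosomal_db)
    if not refs:
        raise ParameterError("ribosomal reference set is empty")
    out = {}
    for sample in sorted(reads_by_sample):
        reads = reads_by_sample[sample]
        if not reads:
            out[sample] = 0
            continue
        placements = map_reads(
            reads, refs, seed_len=seed_len, min_identity=min_identity,
            all_best=True,
        )
        out[sample] = len(placements)
    return pd.Series(out, name="n16S").sort_index()


def potu_abundance(
    genome_counts: pd.DataFrame,
    potus: Sequence[POTU],
    n16s: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative numbers: value(sample, pOTU) = sum of member-genome counts /
    n16S(sample). Returns (pOTU matrix, family-level rollup); samples with
    n16S == 0 get missing values."""
    samples = genome_counts.index
    if not samples.equals(n16s.index):
        n16s = n16s.reindex(samples)
        if n16s.isna().any():
            raise DataError("n16S is missing for some samples in genome_counts")
    data = {}
    for potu in potus:
        members = [m for m in potu.members if m in genome_counts.columns]
        summed = (
            genome_counts[members].sum(axis=1)
            if members
            else pd.Series(0, index=samples)
        )
        data[potu.potu_id] = summed
    counts = pd.DataFrame(data, index=samples)
    denom = n16s.replace(0, np.nan)
    abundance = counts.div(denom, axis=0)
    abundance.insert(0, "n16S", n16s)
    fam_cols: dict[str, list[str]] = defaultdict(list)
    for potu in potus:
        fam_cols[potu.family].append(potu.potu_id)
    family = pd.DataFrame(
        {
            fam: abundance[cols].sum(axis=1, min_count=1)
            for fam, cols in sorted(fam_cols.items())
        },
        index=samples,
    )
    return abundance, family


def abundance_values(abundance: pd.DataFrame) -> pd.DataFrame:
    """The pOTU value columns of an abundance matrix (drops n16S)."""
    return abundance.drop(columns=["n16S"], errors="ignore")
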