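"""Synthetic multi-sample gut metagenome with full ground truth.

The generator emulates the study design this pipeline targets: a two-group
(control vs case) cohort of whole-community metagenomes in which bacterial
scaffolds of known genus carry planted prophages (verbatim copies of a mini
reference phage panel with five-level taxonomy and a host genus), CRISPR
arrays whose spacers are copied from phages infecting the scaffold's genus,
16S gene copies for read-level normalization, and group-wise fold-changes on
a chosen subset of pOTUs. Whole-community (WCMS) reads are drawn from the
scaffolds in proportion to planted abundance weights; VLP reads are drawn
from phage genomes only.

Everything referenced by the truth tables is extractable verbatim from the
emitted sequences, and all coordinates are 0-based, half-open.

Deliberate simplifications (documented in the methods note): background
sequence is i.i.d. uniform A/C/G/T, reads are error-free by default, marker
genes are planted as exact ATG..stop ORFs preceded by an in-frame stop so
the simple ORF caller recovers them at their exact coordinates, and repeat
boundaries of planted CRISPR arrays are made locally unambiguous so detected
array coordinates are well defined.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._kmers import revcomp
from .errors import ConfigError, GenerationError
from .seq_io import (
    Scaffold,
    SeqRecord,
    read_fasta,
    translate_cds,
    write_fasta,
    write_fastq,
    read_fastq,
)

COORD_NOTE = "coordinates are 0-based, half-open"

TERMINASE_DOMAINS = ("Terminase_1", "Terminase_3", "Terminase_6", "Terminase_GpA")

#: Synthetic stand-in motifs for the four large-subunit-terminase domains.
#: These are fixed, arbitrary 15-residue words planted into one marker gene
#: per phage; they are not derived from any real Pfam model.
SYNTHETIC_TERMINASE_MOTIFS: dict[str, str] = {
    "Terminase_1": "WKRHFDEYAQCMLPG",
    "Terminase_3": "YMDPWCKGFRHLEQA",
    "Terminase_6": "FHWEYKQDMARCPGL",
    "Terminase_GpA": "CPYKWMHFGDLERQA",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[11]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in _table.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_STOP_CODONS = sorted(_table.stop_codons)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class WorldConfig:
    """Parameters of a synthetic world; defaults are the study conditions
    used throughout the test-suite and the acceptance run."""

    n_samples_per_group: int = 20
    n_scaffolds_per_sample: int = 46
    n_bacterial_genera: int = 8
    n_phage_genomes: int = 37
    phage_genome_len_range: tuple[int, int] = (12_000, 18_000)
    bacterial_scaffold_len_range: tuple[int, int] = (10_000, 16_000)
    prophage_rate: float = 0.8
    crispr_rate: float = 0.25
    spacer_len: int = 32
    repeat_len: int = 28
    n_repeats_per_array: int = 4
    reads_per_sample: int = 2000
    read_len: int = 100
    vlp_reads_per_sample: int = 8000
    n_16s_copies_range: tuple[int, int] = (30, 40)
    n_marker_genes_per_phage: int = 4
    marker_len_aa: int = 300
    n_bacterial_markers_per_scaffold: int = 3
    bacterial_proteins_per_genus: int = 12
    bacterial_marker_len_aa: int = 250
    ribosomal_len: int = 1500
    genus_abundance_sigma: float = 0.3
    scaffold_abundance_sigma: float = 0.3
    substitution_rate: float = 0.0
    spacer_mutations: int = 0
    effect_potus: dict[str, float] | None = None
    n_effect_potus: int = 7
    effect_fold_change: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        positive = [
            "n_samples_per_group", "n_scaffolds_per_sample", "n_bacterial_genera",
            "n_phage_genomes", "spacer_len", "repeat_len", "reads_per_sample",
            "read_len", "vlp_reads_per_sample", "n_marker_genes_per_phage",
            "marker_len_aa", "bacterial_proteins_per_genus",
            "bacterial_marker_len_aa", "ribosomal_len",
        ]
        for name in positive:
            v = getattr(self, name)
            if name in ("reads_per_sample", "vlp_reads_per_sample"):
                if v < 0:
                    raise ConfigError(f"{name} must be >= 0, got {v}")
            elif v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        for name in ("prophage_rate", "crispr_rate", "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "phage_genome_len_range", "bacterial_scaffold_len_range",
            "n_16s_copies_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        if self.n_repeats_per_array < 3:
            raise ConfigError(
                f"n_repeats_per_array must be >= 3, got {self.n_repeats_per_array}"
            )
        if self.phage_genome_len_range[0] < 10_000:
            raise ConfigError(
                "phage_genome_len_range lower bound must be >= 10000 so planted "
                "prophages pass the large-scaffold filter, got "
                f"{self.phage_genome_len_range[0]}"
            )
        if self.effect_fold_change <= 1.0:
            raise ConfigError(
                f"effect_fold_change must be > 1, got {self.effect_fold_change}"
            )
        if self.n_effect_potus > self.n_phage_genomes:
            raise ConfigError(
                "n_effect_potus cannot exceed n_phage_genomes "
                f"({self.n_effect_potus} > {self.n_phage_genomes})"
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WorldConfig":
        data = json.loads(text)
        for key in (
            "phage_genome_len_range", "bacterial_scaffold_len_range",
            "n_16s_copies_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# reference objects


@dataclass(frozen=True)
class PhageTaxonomy:
    """Five-level phage taxonomy plus the genus of the bacterial host."""

    group: str
    order: str
    family: str
    subfamily: str
    genus: str
    host_genus: str

    @property
    def potu_key(self) -> str:
        return "|".join(
            (self.group, self.order, self.family, self.subfamily, self.genus,
             self.host_genus)
        )

    def astuple(self) -> tuple[str, ...]:
        return (self.group, self.order, self.family, self.subfamily, self.genus,
                self.host_genus)


@dataclass(frozen=True)
class MarkerGene:
    """A phage-specific marker gene planted as an exact ORF."""

    gene_id: str
    phage_id: str
    start: int          # CDS start on the phage genome (the ATG)
    end: int            # CDS end (past the stop codon)
    protein: str
    cds: str


@dataclass(frozen=True)
class ProteinRecord:
    """A protein in the mixed bacterial+phage database with source labels."""

    id: str
    seq: str
    source: str                  # 'phage' | 'bacteria'
    family: str | None = None    # phage family (phage source)
    genus: str | None = None     # bacterial genus (bacterial source)
    phage_id: str | None = None


@dataclass
class ReferenceSet:
    phage_genomes: dict[str, str]
    phage_taxonomy: dict[str, PhageTaxonomy]
    marker_genes: list[MarkerGene]
    protein_db: list[ProteinRecord]
    ribosomal: dict[str, str]      # genus -> 16S-like reference
    genera: list[str]

    @property
    def marker_proteins(self) -> list[SeqRecord]:
        return [SeqRecord(m.gene_id, m.protein) for m in self.marker_genes]

    @property
    def marker_cds(self) -> list[SeqRecord]:
        return [SeqRecord(m.gene_id, m.cds) for m in self.marker_genes]

    def family_of_subject(self) -> dict[str, str]:
        return {
            p.id: p.family for p in self.protein_db
            if p.source == "phage" and p.family
        }

    def genus_of_subject(self) -> dict[str, str]:
        return {
            p.id: p.genus for p in self.protein_db
            if p.source == "bacteria" and p.genus
        }


# ---------------------------------------------------------------------------
# truth tables


@dataclass(frozen=True)
class PlantedArray:
    array_id: str
    scaffold_id: str
    repeat_starts: tuple[int, ...]
    repeat_len: int
    spacers: tuple[tuple[str, int, int, str], ...]  # (spacer_id, start, end, seq)


@dataclass(frozen=True)
class ReadOrigin:
    sample_id: str
    source_id: str   # scaffold id (WCMS) or phage id (VLP)
    pos: int
    kind: str        # 'bacterial' | 'phage' | '16s'
    phage_id: str | None = None


@dataclass
class TruthTables:
    """Ground truth emitted by the generator; the acceptance surface for
    every downstream stage."""

    prophage_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    spacer_origins: list[tuple[str, int, str, int]] = field(default_factory=list)
    phage_taxonomy: dict[str, PhageTaxonomy] = field(default_factory=dict)
    sample_groups: dict[str, str] = field(default_factory=dict)
    planted_effects: dict[str, float] = field(default_factory=dict)
    arrays: list[PlantedArray] = field(default_factory=list)
    ribosomal_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    scaffold_genus: dict[str, str] = field(default_factory=dict)
    scaffold_weights: dict[str, float] = field(default_factory=dict)
    genus_profile: pd.DataFrame | None = None
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    def prophage_scaffolds(self) -> set[str]:
        return {sid for sid, _, _, _ in self.prophage_intervals}

    def phage_of_scaffold(self) -> dict[str, str]:
        return {sid: pid for sid, _, _, pid in self.prophage_intervals}


@dataclass
class Community:
    scaffolds: dict[str, list[Scaffold]]   # sample -> scaffolds
    truth: TruthTables

    def all_scaffolds(self) -> list[Scaffold]:
        return [s for sample in sorted(self.scaffolds) for s in self.scaffolds[sample]]

    def scaffold_map(self) -> dict[str, Scaffold]:
        return {s.id: s for s in self.all_scaffolds()}


@dataclass
class ReadSet:
    wcms: dict[str, list[SeqRecord]]
    vlp: dict[str, list[SeqRecord]]
    totals: pd.DataFrame   # per-sample totals incl. 16S-origin read counts


# ---------------------------------------------------------------------------
# helpers


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=n_aa - 1))
    return "M" + body


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    codons = []
    for aa in protein:
        options = _CODONS_FOR[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(_STOP_CODONS[rng.integers(0, len(_STOP_CODONS))])
    return "".join(codons)


def _split_lengths(
    rng: np.random.Generator, total: int, parts: int, minimum: int = 20
) -> list[int]:
    """Split ``total`` into ``parts`` nonnegative chunks, each >= minimum."""
    spare = total - minimum * parts
    if spare < 0:
        raise GenerationError(
            f"scaffold too short to host the requested inserts "
            f"(need >= {minimum * parts}, have {total})"
        )
    if parts == 0:
        return []
    draw = rng.multinomial(spare, [1.0 / parts] * parts)
    return [minimum + int(d) for d in draw]


def potu_keys(taxonomy: Mapping[str, PhageTaxonomy]) -> list[str]:
    """Sorted distinct pOTU keys of a taxonomy table."""
    return sorted({t.potu_key for t in taxonomy.values()})


# ---------------------------------------------------------------------------
# stage 1: references


def generate_references(config: WorldConfig) -> ReferenceSet:
    """Mini reference set: phage genomes with planted marker genes, a mixed
    bacterial+phage protein database with source labels, and per-genus
    16S-like references. Deterministic given ``config.rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genera = [f"Genus_{i + 1:02d}" for i in range(config.n_bacterial_genera)]
    families = ("Siphoviridae", "Myoviridae", "Podoviridae")

    phage_genomes: dict[str, str] = {}
    taxonomy: dict[str, PhageTaxonomy] = {}
    markers: list[MarkerGene] = []
    protein_db: list[ProteinRecord] = []

    for i in range(config.n_phage_genomes):
        pid = f"phage_{i + 1:03d}"
        family = families[i % len(families)]
        subfamily = (
            "unclassified_subfamily" if i % 5 == 4 else f"Subfamily_{i % 4 + 1:02d}"
        )
        tax = PhageTaxonomy(
            group="dsDNA",
            order="Caudovirales",
            family=family,
            subfamily=subfamily,
            genus=f"Phagegenus_{i + 1:03d}",
            host_genus=genera[i % len(genera)],
        )
        taxonomy[pid] = tax

        genome_len = int(rng.integers(*config.phage_genome_len_range, endpoint=True))
        inserts: list[tuple[str, str, str]] = []  # (gene_id, cds, protein)
        for j in range(config.n_marker_genes_per_phage):
            prot = _random_protein(rng, config.marker_len_aa)
            if j == 0:
                # the first marker is the large-subunit-terminase stand-in
                motif = SYNTHETIC_TERMINASE_MOTIFS[
                    TERMINASE_DOMAINS[i % len(TERMINASE_DOMAINS)]
                ]
                prot = prot[:50] + motif + prot[50 + len(motif):]
            cds = _backtranslate(rng, prot)
            inserts.append((f"{pid}_m{j + 1}", cds, prot))

        # each insert carries an in-frame leading stop so the ORF caller
        # recovers the planted CDS at its exact coordinates
        insert_lens = [len(cds) + 3 for _, cds, _ in inserts]
        background = genome_len - sum(insert_lens)
        chunks = _split_lengths(rng, background, len(inserts) + 1)
        pieces: list[str] = []
        pos = 0
        for j, (gene_id, cds, prot) in enumerate(inserts):
            pieces.append(_random_dna(rng, chunks[j]))
            pos += chunks[j]
            pieces.append("TAA")
            pos += 3
            start = pos
            pieces.append(cds)
            pos += len(cds)
            markers.append(MarkerGene(gene_id, pid, start, pos, prot, cds))
            protein_db.append(
                ProteinRecord(gene_id, prot, "phage", family=family, phage_id=pid)
            )
        pieces.append(_random_dna(rng, chunks[-1]))
        phage_genomes[pid] = "".join(pieces)

    for genus in genera:
        for j in range(config.bacterial_proteins_per_genus):
            prot = _random_protein(rng, config.bacterial_marker_len_aa)
            protein_db.append(
                ProteinRecord(f"{genus}_p{j + 1:02d}", prot, "bacteria", genus=genus)
            )

    ribosomal = {genus: _random_dna(rng, config.ribosomal_len) for genus in genera}
    return ReferenceSet(phage_genomes, taxonomy, markers, protein_db, ribosomal, genera)


# ---------------------------------------------------------------------------
# stage 2: community


def planted_effect_map(config: WorldConfig, refs: ReferenceSet) -> dict[str, float]:
    if config.effect_potus is not None:
        keys = set(potu_keys(refs.phage_taxonomy))
        unknown = set(config.effect_potus) - keys
        if unknown:
            raise ConfigError(f"effect_potus references unknown pOTUs: {sorted(unknown)}")
        return dict(config.effect_potus)
    return {
        key: config.effect_fold_change
        for key in potu_keys(refs.phage_taxonomy)[: config.n_effect_potus]
    }


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    if n <= 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


def generate_community(config: WorldConfig, refs: ReferenceSet) -> Community:
    """Per-sample scaffolds with planted prophages, CRISPR arrays, bacterial
    marker genes and 16S copies; complete truth tables."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 1)
    truth = TruthTables(phage_taxonomy=dict(refs.phage_taxonomy))
    truth.planted_effects = planted_effect_map(config, refs)

    phage_ids = sorted(refs.phage_genomes)
    phages_by_host: dict[str, list[str]] = {}
    for pid in phage_ids:
        phages_by_host.setdefault(refs.phage_taxonomy[pid].host_genus, []).append(pid)
    bact_by_genus: dict[str, list[ProteinRecord]] = {}
    for p in refs.protein_db:
        if p.source == "bacteria":
            bact_by_genus.setdefault(p.genus, []).append(p)

    n_samples = 2 * config.n_samples_per_group
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    for i, sample in enumerate(samples):
        truth.sample_groups[sample] = (
            "control" if i < config.n_samples_per_group else "case"
        )

    seen_spacers: set[str] = set()
    # spacer source intervals are kept non-overlapping per phage so no two
    # planted spacers are near-duplicates (adjacent draws would otherwise
    # create spurious one-mismatch cross-links between arrays)
    spacer_positions: dict[str, list[int]] = {}
    scaffolds: dict[str, list[Scaffold]] = {}
    genus_rows = []

    for sample in samples:
        n_sc = config.n_scaffolds_per_sample
        n_pro = int(round(config.prophage_rate * n_sc))
        n_arr = int(round(config.crispr_rate * n_sc))
        genus_w = {
            g: float(rng.lognormal(0.0, config.genus_abundance_sigma))
            for g in refs.genera
        }
        # cycle a shuffled phage panel so every phage is planted evenly
        panel = list(rng.permutation(phage_ids))
        prophage_of: dict[int, str] = {
            j: panel[j % len(panel)] for j in range(n_pro)
        }
        array_scaffolds = set(rng.choice(n_sc, size=min(n_arr, n_sc), replace=False))
        n_16s = int(rng.integers(*config.n_16s_copies_range, endpoint=True))
        s16_scaffolds = list(rng.choice(n_sc, size=min(n_16s, n_sc), replace=False))
        s16_count = {int(j): 1 for j in s16_scaffolds}
        # a prophage-carrying scaffold is a fragment of its host's
        # chromosome, so it takes the phage's host genus; purely bacterial
        # scaffolds draw a genus uniformly
        genus_of = {
            j: (
                refs.phage_taxonomy[prophage_of[j]].host_genus
                if j in prophage_of
                else refs.genera[int(rng.integers(0, len(refs.genera)))]
            )
            for j in range(n_sc)
        }

        sample_scaffolds: list[Scaffold] = []
        for j in range(n_sc):
            sc_id = f"{sample}|sc{j + 1:03d}"
            genus = genus_of[j]
            features: list[tuple[str, object]] = []
            pool = bact_by_genus.get(genus, [])
            if pool:
                picks = rng.choice(
                    len(pool),
                    size=min(config.n_bacterial_markers_per_scaffold, len(pool)),
                    replace=False,
                )
                for idx in picks:
                    features.append(("bact_marker", pool[int(idx)]))
            if j in prophage_of:
                features.append(("prophage", prophage_of[j]))
            if j in array_scaffolds:
                features.append(("array", None))
            for _ in range(s16_count.get(j, 0)):
                features.append(("16s", genus))
            order = rng.permutation(len(features))
            features = [features[int(o)] for o in order]

            backbone = int(
                rng.integers(*config.bacterial_scaffold_len_range, endpoint=True)
            )
            chunks = _split_lengths(rng, backbone, len(features) + 1)
            pieces: list[str] = []
            pos = 0
            arr_counter = 0
            for fi, (kind, payload) in enumerate(features):
                pieces.append(_random_dna(rng, chunks[fi]))
                pos += chunks[fi]
                if kind == "bact_marker":
                    prot: ProteinRecord = payload  # type: ignore[assignment]
                    cds = _backtranslate(rng, prot.seq)
                    pieces.append("TAA" + cds)
                    pos += 3 + len(cds)
                elif kind == "prophage":
                    pid = str(payload)
                    genome = refs.phage_genomes[pid]
                    truth.prophage_intervals.append(
                        (sc_id, pos, pos + len(genome), pid)
                    )
                    pieces.append(genome)
                    pos += len(genome)
                elif kind == "16s":
                    ref16 = refs.ribosomal[str(payload)]
                    truth.ribosomal_intervals.append(
                        (sc_id, pos, pos + len(ref16), str(payload))
                    )
                    pieces.append(ref16)
                    pos += len(ref16)
                elif kind == "array":
                    arr_counter += 1
                    array_id = f"{sc_id}_crispr{arr_counter}"
                    repeat = _random_dna(rng, config.repeat_len)
                    n_spacers = config.n_repeats_per_array - 1
                    source_pool = phages_by_host.get(genus) or phage_ids
                    spacer_seqs: list[tuple[str, int, str]] = []
                    for si in range(n_spacers):
                        for _try in range(64):
                            pid = source_pool[int(rng.integers(0, len(source_pool)))]
                            genome = refs.phage_genomes[pid]
                            spos = int(
                                rng.integers(0, len(genome) - config.spacer_len + 1)
                            )
                            seq = genome[spos : spos + config.spacer_len]
                            taken = spacer_positions.setdefault(pid, [])
                            if seq not in seen_spacers and all(
                                abs(spos - q) >= config.spacer_len for q in taken
                            ):
                                break
                        seen_spacers.add(seq)
                        spacer_positions.setdefault(pid, []).append(spos)
                        seq = _mutate(rng, seq, config.spacer_mutations)
                        spacer_seqs.append((pid, spos, seq))
                    # guard bases break boundary ambiguity at the array edges
                    left_guard = next(
                        b for b in "ACGT" if b != spacer_seqs[0][2][-1]
                    )
                    right_guard = next(
                        b for b in "ACGT" if b != spacer_seqs[0][2][0]
                    )
                    arr_pieces = [left_guard]
                    arr_pos = pos + 1
                    repeat_starts: list[int] = []
                    spacer_records: list[tuple[str, int, int, str]] = []
                    for si in range(config.n_repeats_per_array):
                        repeat_starts.append(arr_pos)
                        arr_pieces.append(repeat)
                        arr_pos += config.repeat_len
                        if si < n_spacers:
                            spacer_id = f"{array_id}_s{si + 1}"
                            pid, spos, seq = spacer_seqs[si]
                            spacer_records.append(
                                (spacer_id, arr_pos, arr_pos + len(seq), seq)
                            )
                            truth.spacer_origins.append(
                                (array_id, si, pid, spos)
                            )
                            arr_pieces.append(seq)
                            arr_pos += len(seq)
                    arr_pieces.append(right_guard)
                    arr_pos += 1
                    truth.arrays.append(
                        PlantedArray(
                            array_id, sc_id, tuple(repeat_starts),
                            config.repeat_len, tuple(spacer_records),
                        )
                    )
                    pieces.append("".join(arr_pieces))
                    pos = arr_pos
            pieces.append(_random_dna(rng, chunks[-1]))
            seq = "".join(pieces)
            sample_scaffolds.append(Scaffold(sc_id, sample, seq))
            truth.scaffold_genus[sc_id] = genus
            truth.scaffold_weights[sc_id] = float(
                genus_w[genus] * rng.lognormal(0.0, config.scaffold_abundance_sigma)
            )
        scaffolds[sample] = sample_scaffolds

        mass = {g: 0.0 for g in refs.genera}
        for sc in sample_scaffolds:
            mass[truth.scaffold_genus[sc.id]] += (
                truth.scaffold_weights[sc.id] * sc.length
            )
        total = sum(mass.values())
        genus_rows.append(
            {"sample_id": sample, **{g: mass[g] / total for g in refs.genera}}
        )

    truth.genus_profile = pd.DataFrame(genus_rows).set_index("sample_id")
    return Community(scaffolds, truth)


# ---------------------------------------------------------------------------
# stage 3: reads


def _effect_scaffolds(truth: TruthTables, refs: ReferenceSet) -> set[str]:
    effect_keys = set(truth.planted_effects)
    effect_phages = {
        pid for pid, tax in refs.phage_taxonomy.items() if tax.potu_key in effect_keys
    }
    return {
        sid for sid, _, _, pid in truth.prophage_intervals if pid in effect_phages
    }


def expected_phage_fraction(
    community: Community, refs: ReferenceSet, sample: str, read_len: int,
    fold_effects: bool = True,
) -> float:
    """Exact expected fraction of WCMS reads of phage origin in ``sample``
    under the generator's sampling weights (used by tests as an oracle)."""
    truth = community.truth
    eff = _effect_scaffolds(truth, refs) if fold_effects else set()
    case = truth.sample_groups[sample] == "case"
    pro = {sid: (a, b) for sid, a, b, _ in truth.prophage_intervals}
    key_fold = dict(truth.planted_effects)
    phage_of = truth.phage_of_scaffold()
    num = den = 0.0
    for sc in community.scaffolds[sample]:
        w = truth.scaffold_weights[sc.id]
        fold = 1.0
        if case and sc.id in eff:
            fold = key_fold[refs.phage_taxonomy[phage_of[sc.id]].potu_key]
        n_pos = sc.length - read_len + 1
        if n_pos <= 0:
            continue
        inside = 0
        if sc.id in pro:
            a, b = pro[sc.id]
            inside = max(0, (b - read_len + 1) - a)
        # the fold-change models induced phage replication: it boosts the
        # prophage region's sampling weight only
        den += w * ((n_pos - inside) + fold * inside)
        num += w * fold * inside
    return num / den if den else 0.0


def simulate_reads(
    config: WorldConfig, community: Community, refs: ReferenceSet
) -> ReadSet:
    """WCMS reads drawn from sample scaffolds weighted by planted abundance
    (with group fold-changes applied to case samples) and VLP reads drawn
    from phage genomes only. Read origins are recorded in the truth tables."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed + 2)
    truth = community.truth
    effect_scaffolds = _effect_scaffolds(truth, refs)
    fold_of = {
        sid: max(truth.planted_effects.values()) if truth.planted_effects else 1.0
        for sid in effect_scaffolds
    }
    # a scaffold's effect fold is that of its prophage's pOTU
    key_fold = dict(truth.planted_effects)
    phage_of = truth.phage_of_scaffold()
    for sid in effect_scaffolds:
        tax = refs.phage_taxonomy[phage_of[sid]]
        fold_of[sid] = key_fold[tax.potu_key]

    rl = config.read_len
    sub = config.substitution_rate
    wcms: dict[str, list[SeqRecord]] = {}
    vlp: dict[str, list[SeqRecord]] = {}
    rows = []
    pro_by_scaffold: dict[str, tuple[int, int, str]] = {
        sid: (a, b, pid) for sid, a, b, pid in truth.prophage_intervals
    }
    s16_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for sid, a, b, _ in truth.ribosomal_intervals:
        s16_by_scaffold.setdefault(sid, []).append((a, b))

    for sample in sorted(community.scaffolds):
        case = truth.sample_groups[sample] == "case"
        scs = community.scaffolds[sample]
        # the fold-change boosts the prophage region's sampling weight only
        # (induced phage replication), not the host backbone
        inside_of: dict[str, tuple[int, int]] = {}
        weights = np.empty(len(scs))
        for i, s in enumerate(scs):
            n_pos = max(s.length - rl + 1, 0)
            fold = fold_of.get(s.id, 1.0) if case else 1.0
            n_in = 0
            if s.id in pro_by_scaffold:
                a, b = pro_by_scaffold[s.id][:2]
                n_in = max(0, (b - rl + 1) - a)
                inside_of[s.id] = (a, n_in)
            weights[i] = truth.scaffold_weights[s.id] * (
                (n_pos - n_in) + fold * n_in
            )
        reads: list[SeqRecord] = []
        n_phage = n_16s = 0
        if config.reads_per_sample > 0 and weights.sum() > 0:
            counts = rng.multinomial(
                config.reads_per_sample, weights / weights.sum()
            )
            ridx = 0
            for s, cnt in zip(scs, counts):
                if cnt == 0:
                    continue
                n_pos = s.length - rl + 1
                fold = fold_of.get(s.id, 1.0) if case else 1.0
                a, n_in = inside_of.get(s.id, (0, 0))
                if n_in > 0 and fold != 1.0:
                    p_in = fold * n_in / ((n_pos - n_in) + fold * n_in)
                    k_in = int(rng.binomial(cnt, p_in))
                    pos_in = rng.integers(a, a + n_in, size=k_in)
                    u = rng.integers(0, n_pos - n_in, size=cnt - k_in)
                    pos_out = np.where(u < a, u, u + n_in)
                    positions = np.concatenate([pos_in, pos_out])
                    rng.shuffle(positions)
                else:
                    positions = rng.integers(0, n_pos, size=cnt)
                for pos in positions:
                    pos = int(pos)
                    seq = s.seq[pos : pos + rl]
                    if sub > 0:
                        n_mut = rng.binomial(rl, sub)
                        seq = _mutate(rng, seq, int(n_mut))
                    rid = f"{sample}|w{ridx:06d}"
                    ridx += 1
                    kind, pid = "bacterial", None
                    if s.id in pro_by_scaffold:
                        a, b, ppid = pro_by_scaffold[s.id]
                        if a <= pos and pos + rl <= b:
                            kind, pid = "phage", ppid
                    if kind == "bacterial":
                        for a, b in s16_by_scaffold.get(s.id, ()):
                            if a <= pos and pos + rl <= b:
                                kind = "16s"
                                break
                    n_phage += kind == "phage"
                    n_16s += kind == "16s"
                    truth.read_origins[rid] = ReadOrigin(sample, s.id, pos, kind, pid)
                    reads.append(SeqRecord(rid, seq))
        wcms[sample] = reads

        # VLP: phage-enriched sequencing of the same community
        present = [
            (sid, pid) for sid, (a, b, pid) in pro_by_scaffold.items()
            if sid in {s.id for s in scs}
        ]
        vreads: list[SeqRecord] = []
        if config.vlp_reads_per_sample > 0 and present:
            pw = np.array(
                [
                    truth.scaffold_weights[sid]
                    * (fold_of.get(sid, 1.0) if case else 1.0)
                    * max(len(refs.phage_genomes[pid]) - rl + 1, 0)
                    for sid, pid in present
                ]
            )
            counts = rng.multinomial(config.vlp_reads_per_sample, pw / pw.sum())
            ridx = 0
            for (sid, pid), cnt in zip(present, counts):
                if cnt == 0:
                    continue
                genome = refs.phage_genomes[pid]
                positions = rng.integers(0, len(genome) - rl + 1, size=cnt)
                for pos in positions:
                    pos = int(pos)
                    seq = genome[pos : pos + rl]
                    if sub > 0:
                        seq = _mutate(rng, seq, int(rng.binomial(rl, sub)))
                    rid = f"{sample}|v{ridx:06d}"
                    ridx += 1
                    truth.read_origins[rid] = ReadOrigin(sample, pid, pos, "phage", pid)
                    vreads.append(SeqRecord(rid, seq))
        vlp[sample] = vreads
        rows.append(
            {
                "sample_id": sample,
                "group": truth.sample_groups[sample],
                "wcms_total": len(reads),
                "wcms_phage_origin": n_phage,
                "wcms_16s_origin": n_16s,
                "vlp_total": len(vreads),
            }
        )
    totals = pd.DataFrame(rows).set_index("sample_id")
    return ReadSet(wcms, vlp, totals)


def generate_world(config: WorldConfig) -> tuple[ReferenceSet, Community, ReadSet]:
    """Run all three generator stages."""
    refs = generate_references(config)
    community = generate_community(config, refs)
    reads = simulate_reads(config, community, refs)
    return refs, community, reads


# ---------------------------------------------------------------------------
# persistence (plain-text formats only)


def save_world(
    outdir: str | Path,
    config: WorldConfig,
    refs: ReferenceSet,
    community: Community,
    reads: ReadSet | None = None,
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    write_fasta(
        [SeqRecord(pid, seq) for pid, seq in sorted(refs.phage_genomes.items())],
        out / "phage_genomes.fasta",
    )
    write_fasta(refs.marker_proteins, out / "marker_proteins.faa")
    write_fasta(refs.marker_cds, out / "marker_cds.fna")
    write_fasta(
        [SeqRecord(p.id, p.seq) for p in refs.protein_db], out / "proteins.faa"
    )
    with open(out / "protein_labels.tsv", "w") as fh:
        fh.write("protein_id\tsource\tfamily\tgenus\tphage_id\n")
        for p in refs.protein_db:
            fh.write(
                f"{p.id}\t{p.source}\t{p.family or '.'}\t{p.genus or '.'}\t"
                f"{p.phage_id or '.'}\n"
            )
    with open(out / "marker_genes.tsv", "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write("gene_id\tphage_id\tstart\tend\n")
        for m in refs.marker_genes:
            fh.write(f"{m.gene_id}\t{m.phage_id}\t{m.start}\t{m.end}\n")
    write_fasta(
        [SeqRecord(g, s) for g, s in sorted(refs.ribosomal.items())],
        out / "ribosomal.fna",
    )
    with open(out / "phage_taxonomy.tsv", "w") as fh:
        fh.write("phage_id\tgroup\torder\tfamily\tsubfamily\tgenus\thost_genus\n")
        for pid in sorted(refs.phage_taxonomy):
            fh.write(pid + "\t" + "\t".join(refs.phage_taxonomy[pid].astuple()) + "\n")

    truth = community.truth
    write_fasta(community.all_scaffolds(), out / "scaffolds.fasta")
    with open(out / "scaffold_table.tsv", "w") as fh:
        fh.write("scaffold_id\tsample_id\tlength\tgenus\tweight\n")
        for sc in community.all_scaffolds():
            fh.write(
                f"{sc.id}\t{sc.sample_id}\t{sc.length}\t"
                f"{truth.scaffold_genus[sc.id]}\t"
                f"{truth.scaffold_weights[sc.id]:.8g}\n"
            )
    with open(out / "truth_prophages.tsv", "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write("scaffold_id\tstart\tend\tphage_id\n")
        for sid, a, b, pid in truth.prophage_intervals:
            fh.write(f"{sid}\t{a}\t{b}\t{pid}\n")
    with open(out / "truth_arrays.tsv", "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write(
            "array_id\tscaffold_id\trepeat_len\trepeat_starts\t"
            "spacer_id\tspacer_start\tspacer_end\tspacer_seq\n"
        )
        for arr in truth.arrays:
            starts = ",".join(map(str, arr.repeat_starts))
            for sp_id, a, b, seq in arr.spacers:
                fh.write(
                    f"{arr.array_id}\t{arr.scaffold_id}\t{arr.repeat_len}\t"
                    f"{starts}\t{sp_id}\t{a}\t{b}\t{seq}\n"
                )
    with open(out / "truth_spacer_origins.tsv", "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write("array_id\tspacer_index\tsource_phage_id\tsource_pos\n")
        for aid, si, pid, pos in truth.spacer_origins:
            fh.write(f"{aid}\t{si}\t{pid}\t{pos}\n")
    with open(out / "truth_16s.tsv", "w") as fh:
        fh.write(f"# {COORD_NOTE}\n")
        fh.write("scaffold_id\tstart\tend\tgenus\n")
        for sid, a, b, g in truth.ribosomal_intervals:
            fh.write(f"{sid}\t{a}\t{b}\t{g}\n")
    with open(out / "sample_groups.tsv", "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in sorted(truth.sample_groups):
            fh.write(f"{s}\t{truth.sample_groups[s]}\n")
    with open(out / "planted_effects.tsv", "w") as fh:
        fh.write("potu_key\tfold_change\n")
        for key in sorted(truth.planted_effects):
            fh.write(f"{key}\t{truth.planted_effects[key]}\n")
    if truth.genus_profile is not None:
        truth.genus_profile.to_csv(out / "genus_profile.tsv", sep="\t")

    if reads is not None:
        for name, pool in (("wcms", reads.wcms), ("vlp", reads.vlp)):
            with open(out / f"{name}_reads.fastq", "w") as fh:
                for sample in sorted(pool):
                    for rec in pool[sample]:
                        fh.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
        reads.totals.to_csv(out / "read_totals.tsv", sep="\t")
        with open(out / "truth_read_origins.tsv", "w") as fh:
            fh.write(f"# {COORD_NOTE}\n")
            fh.write("read_id\tsample_id\tsource_id\tpos\tkind\tphage_id\n")
            for rid in sorted(truth.read_origins):
                o = truth.read_origins[rid]
                fh.write(
                    f"{rid}\t{o.sample_id}\t{o.source_id}\t{o.pos}\t{o.kind}\t"
                    f"{o.phage_id or '.'}\n"
                )


def load_world(indir: str | Path) -> tuple[WorldConfig, ReferenceSet, Community, ReadSet | None]:
    """Reload a saved world (inverse of :func:`save_world`)."""
    ind = Path(indir)
    config = WorldConfig.from_json((ind / "config.json").read_text())
    genomes = {r.id: r.seq for r in read_fasta(ind / "phage_genomes.fasta")}
    tax_df = pd.read_csv(ind / "phage_taxonomy.tsv", sep="\t")
    taxonomy = {
        row.phage_id: PhageTaxonomy(
            row.group, row.order, row.family, row.subfamily, row.genus, row.host_genus
        )
        for row in tax_df.itertuples()
    }
    prot_seq = {r.id: r.seq for r in read_fasta(ind / "proteins.faa")}
    labels = pd.read_csv(ind / "protein_labels.tsv", sep="\t", na_values=["."])
    protein_db = [
        ProteinRecord(
            row.protein_id,
            prot_seq[row.protein_id],
            row.source,
            family=None if pd.isna(row.family) else row.family,
            genus=None if pd.isna(row.genus) else row.genus,
            phage_id=None if pd.isna(row.phage_id) else row.phage_id,
        )
        for row in labels.itertuples()
    ]
    marker_prot = {r.id: r.seq for r in read_fasta(ind / "marker_proteins.faa")}
    marker_cds = {r.id: r.seq for r in read_fasta(ind / "marker_cds.fna")}
    mtab = pd.read_csv(ind / "marker_genes.tsv", sep="\t", comment="#")
    markers = [
        MarkerGene(
            row.gene_id, row.phage_id, int(row.start), int(row.end),
            marker_prot[row.gene_id], marker_cds[row.gene_id],
        )
        for row in mtab.itertuples()
    ]
    ribosomal = {r.id: r.seq for r in read_fasta(ind / "ribosomal.fna")}
    genera = sorted(ribosomal)
    refs = ReferenceSet(genomes, taxonomy, markers, protein_db, ribosomal, genera)

    truth = TruthTables(phage_taxonomy=dict(taxonomy))
    sct = pd.read_csv(ind / "scaffold_table.tsv", sep="\t")
    seqs = {r.id: r.seq for r in read_fasta(ind / "scaffolds.fasta")}
    scaffolds: dict[str, list[Scaffold]] = {}
    for row in sct.itertuples():
        scaffolds.setdefault(row.sample_id, []).append(
            Scaffold(row.scaffold_id, row.sample_id, seqs[row.scaffold_id])
        )
        truth.scaffold_genus[row.scaffold_id] = row.genus
        truth.scaffold_weights[row.scaffold_id] = float(row.weight)
    pro = pd.read_csv(ind / "truth_prophages.tsv", sep="\t", comment="#")
    truth.prophage_intervals = [
        (r.scaffold_id, int(r.start), int(r.end), r.phage_id) for r in pro.itertuples()
    ]
    arr = pd.read_csv(ind / "truth_arrays.tsv", sep="\t", comment="#")
    by_array: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for r in arr.itertuples():
        by_array.setdefault(r.array_id, []).append(
            (r.spacer_id, int(r.spacer_start), int(r.spacer_end), r.spacer_seq)
        )
        meta[r.array_id] = (
            r.scaffold_id,
            tuple(int(x) for x in str(r.repeat_starts).split(",")),
            int(r.repeat_len),
        )
    truth.arrays = [
        PlantedArray(aid, meta[aid][0], meta[aid][1], meta[aid][2], tuple(sp))
        for aid, sp in sorted(by_array.items())
    ]
    sp = pd.read_csv(ind / "truth_spacer_origins.tsv", sep="\t", comment="#")
    truth.spacer_origins = [
        (r.array_id, int(r.spacer_index), r.source_phage_id, int(r.source_pos))
        for r in sp.itertuples()
    ]
    s16 = pd.read_csv(ind / "truth_16s.tsv", sep="\t", comment="#")
    truth.ribosomal_intervals = [
        (r.scaffold_id, int(r.start), int(r.end), r.genus) for r in s16.itertuples()
    ]
    sg = pd.read_csv(ind / "sample_groups.tsv", sep="\t")
    truth.sample_groups = dict(zip(sg.sample_id, sg.group))
    pe = pd.read_csv(ind / "planted_effects.tsv", sep="\t")
    truth.planted_effects = dict(zip(pe.potu_key, pe.fold_change))
    gp = ind / "genus_profile.tsv"
    if gp.exists():
        truth.genus_profile = pd.read_csv(gp, sep="\t", index_col=0)
    community = Community(scaffolds, truth)

    reads: ReadSet | None = None
    wq = ind / "wcms_reads.fastq"
    if wq.exists():
        wcms: dict[str, list[SeqRecord]] = {s: [] for s in scaffolds}
        for rec in read_fastq(wq):
            wcms.setdefault(rec.id.split("|")[0], []).append(rec)
        vlp: dict[str, list[SeqRecord]] = {s: [] for s in scaffolds}
        vq = ind / "vlp_reads.fastq"
        if vq.exists():
            for rec in read_fastq(vq):
                vlp.setdefault(rec.id.split("|")[0], []).append(rec)
        totals = pd.read_csv(ind / "read_totals.tsv", sep="\t", index_col=0)
        ro = ind / "truth_read_origins.tsv"
        if ro.exists():
            rot = pd.read_csv(ro, sep="\t", comment="#", na_values=["."])
            truth.read_origins = {
                r.read_id: ReadOrigin(
                    r.sample_id, r.source_id, int(r.pos), r.kind,
                    None if pd.isna(r.phage_id) else r.phage_id,
                )
                for r in rot.itertuples()
            }
        reads = ReadSet(wcms, vlp, totals)
    return config, refs, community, reads
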