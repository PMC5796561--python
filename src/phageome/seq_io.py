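"""Sequence I/O, minimal gene calling and a desk-scale protein search.

The pipeline exchanges data in plain formats: FASTA/FASTQ for sequences and
the 12-column tab-separated BLAST dialect (query, subject, identity, length,
mismatches, gapopens, qstart, qend, sstart, send, evalue, bitscore) for
homology hits, so externally computed BLAST tables can be dropped in.

Gene calling is a deterministic six-frame ATG-to-stop scan (bacterial code,
ATG-only starts); it is intentionally simple so that planted coding genes in
synthetic scaffolds are recovered exactly.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from ._kmers import encode, revcomp
from .errors import DataError, ParameterError, ParseError

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (DNA or protein)."""

    id: str
    seq: str


@dataclass(frozen=True)
class Scaffold:
    """An assembled contig attributed to the sample it came from."""

    id: str
    sample_id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Gene:
    """A predicted ORF on a scaffold; coordinates are 0-based half-open on the
    forward strand and include the stop codon. ``protein`` is the translation
    of the oriented CDS without the stop."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str


@dataclass(frozen=True)
class HitRecord:
    """A homology hit; the lingua franca between annotation stages."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    identity: float


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences are upper-cased. Raises :class:`ParseError`
    (with a line number) if the first non-blank line is not a header."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path.name}: expected FASTA header '>'", line=lineno
                    )
                break
    return [
        SeqRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = rec if isinstance(rec, tuple) else (rec.id, rec.seq)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return [
        SeqRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = rec if isinstance(rec, tuple) else (rec.id, rec.seq)
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# ORF calling

_STOPS = frozenset((48, 50, 56))  # TAA, TAG, TGA packed as 16a+4b+c
_ATG = 14


def _frame_orfs(codes: np.ndarray, frame: int, min_aa: int) -> list[tuple[int, int]]:
    """Maximal ATG-to-stop ORFs in one frame; returns (start_nt, end_nt) pairs
    in the coordinates of ``codes``, end exclusive of nothing (includes stop)."""
    n_cod = (len(codes) - frame) // 3
    if n_cod <= 0:
        return []
    c = codes[frame : frame + 3 * n_cod].reshape(-1, 3)
    cod = (
        c[:, 0].astype(np.int16) * 16
        + c[:, 1].astype(np.int16) * 4
        + c[:, 2].astype(np.int16)
    )
    cod[(c > 3).any(axis=1)] = 64  # ambiguous codons are neither starts nor stops
    stops = np.flatnonzero((cod == 48) | (cod == 50) | (cod == 56))
    if len(stops) == 0:
        return []
    atgs = np.flatnonzero(cod == _ATG)
    if len(atgs) == 0:
        return []
    prev = np.concatenate(([-1], stops[:-1]))
    first = np.searchsorted(atgs, prev + 1)
    out = []
    for j, stop in enumerate(stops):
        a = first[j]
        if a >= len(atgs):
            break
        start = atgs[a]
        if start < stop and (stop - start) >= min_aa:
            out.append((frame + 3 * int(start), frame + 3 * (int(stop) + 1)))
    return out


def translate_cds(cds: str) -> str:
    """Translate an oriented CDS (bacterial code, ambiguity -> X), no stop."""
    prot = str(Seq(cds).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


def call_orfs(scaffold: Scaffold | SeqRecord, min_aa: int = 33) -> list[Gene]:
    """All maximal ATG-to-stop ORFs on six frames with >= ``min_aa`` residues
    (stop excluded), non-nested per frame, sorted by forward-strand start."""
    if min_aa < 1:
        raise ParameterError(f"min_aa must be >= 1, got {min_aa}")
    seq = scaffold.seq.upper()
    L = len(seq)
    sid = scaffold.id
    raw: list[tuple[int, int, str, str]] = []
    fwd = encode(seq)
    rc_seq = revcomp(seq)
    rev = encode(rc_seq)
    for frame in range(3):
        for s, e in _frame_orfs(fwd, frame, min_aa):
            raw.append((s, e, "+", seq[s:e]))
        for s, e in _frame_orfs(rev, frame, min_aa):
            raw.append((L - e, L - s, "-", rc_seq[s:e]))
    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        Gene(f"{sid}_g{i + 1}", sid, s, e, strand, translate_cds(cds))
        for i, (s, e, strand, cds) in enumerate(raw)
    ]


def write_genes(genes: Iterable[Gene], path: str | Path) -> None:
    """Gene table TSV (coordinates 0-based, half-open, stop included)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        fh.write("gene_id\tscaffold_id\tstart\tend\tstrand\tprotein\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.scaffold_id}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.protein}\n"
            )


def read_genes(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError("expected 6 columns in gene table", line=lineno)
            genes.append(
                Gene(parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4],
                     parts[5])
            )
    return genes


# ---------------------------------------------------------------------------
# hit tables

_HIT_COLUMNS = 12


def read_hits(path: str | Path, max_evalue: float = math.inf) -> list[HitRecord]:
    """Read a 12-column BLAST-style TSV, drop hits above ``max_evalue`` and
    keep the best e-value per (query, subject) pair (ties: higher bitscore)."""
    best: dict[tuple[str, str], HitRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < _HIT_COLUMNS:
                raise ParseError(
                    f"expected {_HIT_COLUMNS} tab-separated columns", line=lineno
                )
            try:
                ident = float(parts[2]) / 100.0
                ev = float(parts[10])
                bits = float(parts[11])
            except ValueError as exc:
                raise ParseError(f"non-numeric hit field: {exc}", line=lineno) from exc
            if ev > max_evalue:
                continue
            key = (parts[0], parts[1])
            rec = HitRecord(parts[0], parts[1], ev, bits, ident)
            old = best.get(key)
            if old is None or (rec.evalue, -rec.bitscore) < (old.evalue, -old.bitscore):
                best[key] = rec
    return list(best.values())


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column dialect (alignment columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def filter_hits(hits: Iterable[HitRecord], max_evalue: float) -> list[HitRecord]:
    return [h for h in hits if h.evalue <= max_evalue]


# ---------------------------------------------------------------------------
# naive protein search


def _protein_kmers(seq: str, k: int) -> set[str]:
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if "X" not in seq[i : i + k] and "*" not in seq[i : i + k]
    }


def naive_protein_search(
    queries: Sequence[SeqRecord | tuple[str, str]],
    db: Sequence[SeqRecord | tuple[str, str]],
    k: int = 5,
    max_evalue: float = math.inf,
) -> list[HitRecord]:
    """Shared-k-mer protein search used at fixture scale in place of BLAST.

    Each (query, subject) pair is scored by the number of distinct amino-acid
    k-mers they share. The pseudo e-value ``qlen * db_len * 20**(-k*(score-1))``
    treats the first shared k-mer as the seed and each further shared k-mer
    as independent evidence, so a single chance k-mer stays insignificant
    while exact substring matches always outrank chance matches. K-mers
    containing X never match.
    """
    db = [(r.id, r.seq) if isinstance(r, SeqRecord) else r for r in db]
    queries = [(r.id, r.seq) if isinstance(r, SeqRecord) else r for r in queries]
    if not db:
        raise ParameterError("protein database is empty")
    shortest = min(len(s) for _, s in db)
    if k > shortest:
        raise ParameterError(
            f"k={k} exceeds shortest database sequence length {shortest}"
        )
    index: dict[str, list[int]] = {}
    for j, (_, dseq) in enumerate(db):
        for km in _protein_kmers(dseq, k):
            index.setdefault(km, []).append(j)
    total_db = sum(len(s) for _, s in db)
    log20 = math.log(20.0)
    hits: list[HitRecord] = []
    for qid, qseq in queries:
        counts: Counter[int] = Counter()
        for km in _protein_kmers(qseq, k):
            for j in index.get(km, ()):
                counts[j] += 1
        for j, score in counts.items():
            # evalue in log space to survive large scores (underflows to 0.0)
            log_e = math.log(max(len(qseq), 1) * total_db) - k * (score - 1) * log20
            evalue = math.exp(log_e) if log_e > -700 else 0.0
            if evalue > max_evalue:
                continue
            n_qk = max(len(qseq) - k + 1, 1)
            hits.append(
                HitRecord(qid, db[j][0], evalue, 2.0 * score, min(score / n_qk, 1.0))
            )
    hits.sort(key=lambda h: (h.query_id, h.evalue, -h.bitscore, h.subject_id))
    return hits
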