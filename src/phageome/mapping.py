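"""Read mapping and breadth/depth-of-coverage screening.

The built-in mapper is an exact-seed, ungapped aligner sized for desk-scale
data: a read is placed where one of its seed words matches a reference
exactly and the full-length extension reaches the identity threshold. It
reports a single best placement per read (fewest mismatches; ties broken by
(ref_id, position, strand) lexicographic order) so abundance counting never
double-counts multi-mapping reads. Externally produced SAM alignments can be
ingested instead; only primary, mapped records are used.

Breadth of coverage is the fraction of reference positions covered by at
least one read; depth is mean per-position coverage. Both are the screening
statistics used throughout the pipeline, with the comparator (strict "> 30%"
for the known-genome screen vs inclusive ">= 40%" for the VLP strategy)
passed explicitly because the two screens differ.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kmers import INVALID, encode, kmer_code, revcomp, window_codes
from .errors import DataError, ParameterError
from .seq_io import SeqRecord


@dataclass(frozen=True)
class Alignment:
    """An ungapped read placement; coordinates 0-based half-open."""

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    n_mismatch: int = 0


@dataclass(frozen=True)
class CoverageRecord:
    ref_id: str
    breadth: float
    depth: float
    n_reads: int


def _as_pairs(records: Iterable) -> list[tuple[str, str]]:
    """Accepts (id, seq) tuples or any object with .id/.seq (SeqRecord,
    Scaffold, ...)."""
    return [r if isinstance(r, tuple) else (r.id, r.seq) for r in records]


def map_reads(
    reads: Sequence[SeqRecord | tuple[str, str]],
    refs: Sequence[SeqRecord | tuple[str, str]],
    seed_len: int = 25,
    min_identity: float = 0.95,
    all_best: bool = False,
) -> list[Alignment] | dict[str, list[Alignment]]:
    """Map reads to references with an exact seed and ungapped extension.

    The seed is the first ``seed_len`` bases of the read (in each
    orientation), so error-free reads are always recovered. With
    ``all_best=True`` a dict read_id -> all placements with the minimal
    mismatch count is returned (used for tie-aware read assignment);
    otherwise a flat list with one best placement per read.
    """
    refs = _as_pairs(refs)
    reads = _as_pairs(reads)
    if not refs:
        raise ParameterError("empty reference set")
    if not reads:
        return {} if all_best else []
    shortest = min(len(s) for _, s in reads)
    if seed_len > shortest:
        raise ParameterError(
            f"seed_len={seed_len} exceeds shortest read length {shortest}"
        )

    index: dict[int, list[tuple[int, str]]] = defaultdict(list)
    for i, (_, seq) in enumerate(reads):
        fwd = kmer_code(seq[:seed_len])
        if fwd != INVALID:
            index[int(fwd)].append((i, "+"))
        rc = kmer_code(revcomp(seq)[:seed_len])
        if rc != INVALID:
            index[int(rc)].append((i, "-"))
    keys = np.array(sorted(index), dtype=np.uint64)

    best: dict[int, tuple[int, list[Alignment]]] = {}
    for ref_id, ref_seq in sorted(refs):
        codes = encode(ref_seq)
        wc = window_codes(codes, seed_len)
        if len(wc) == 0:
            continue
        hit_pos = np.flatnonzero(np.isin(wc, keys, assume_unique=False))
        for pos in hit_pos:
            pos = int(pos)
            for ridx, strand in index[int(wc[pos])]:
                rid, rseq = reads[ridx]
                L = len(rseq)
                if pos + L > len(ref_seq):
                    continue
                probe = rseq if strand == "+" else revcomp(rseq)
                seg = ref_seq[pos : pos + L]
                if seg == probe:
                    mm = 0
                else:
                    mm = sum(a != b for a, b in zip(seg, probe))
                    if 1.0 - mm / L < min_identity:
                        continue
                aln = Alignment(rid, ref_id, pos, pos + L, strand, mm)
                cur = best.get(ridx)
                if cur is None or mm < cur[0]:
                    best[ridx] = (mm, [aln])
                elif mm == cur[0]:
                    key = (aln.ref_id, aln.ref_start, aln.strand)
                    if all(
                        key != (a.ref_id, a.ref_start, a.strand) for a in cur[1]
                    ):
                        cur[1].append(aln)
    if all_best:
        return {
            reads[i][0]: sorted(
                alns, key=lambda a: (a.ref_id, a.ref_start, a.strand)
            )
            for i, (_, alns) in best.items()
        }
    out = []
    for i in sorted(best):
        alns = sorted(
            best[i][1], key=lambda a: (a.ref_id, a.ref_start, a.strand)
        )
        out.append(alns[0])
    return out


def read_sam(path: str | Path) -> list[Alignment]:
    """Ingest alignments from a SAM file (primary, mapped records only)."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            out.append(
                Alignment(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out


def coverage_stats(
    alignments: Iterable[Alignment], ref_lengths: Mapping[str, int]
) -> list[CoverageRecord]:
    """Per-reference breadth, depth and read count from a pile of alignments.

    breadth = covered positions / length; depth = aligned bases / length.
    References with no alignments get an explicit all-zero record.
    """
    by_ref: dict[str, list[Alignment]] = defaultdict(list)
    for aln in alignments:
        if aln.ref_id not in ref_lengths:
            raise DataError(f"alignment references unknown ref {aln.ref_id!r}")
        L = ref_lengths[aln.ref_id]
        if not (0 <= aln.ref_start < aln.ref_end <= L):
            raise DataError(
                f"alignment [{aln.ref_start}, {aln.ref_end}) out of bounds for "
                f"{aln.ref_id!r} of length {L}"
            )
        by_ref[aln.ref_id].append(aln)
    out = []
    for ref_id in sorted(ref_lengths):
        L = ref_lengths[ref_id]
        alns = by_ref.get(ref_id, [])
        if not alns:
            out.append(CoverageRecord(ref_id, 0.0, 0.0, 0))
            continue
        diff = np.zeros(L + 1, dtype=np.int64)
        total = 0
        for aln in alns:
            diff[aln.ref_start] += 1
            diff[aln.ref_end] -= 1
            total += aln.ref_end - aln.ref_start
        cov = np.cumsum(diff[:-1])
        out.append(
            CoverageRecord(
                ref_id,
                float((cov > 0).sum() / L),
                float(total / L),
                len(alns),
            )
        )
    return out


def select_covered(
    coverage: Iterable[CoverageRecord],
    min_breadth: float,
    inclusive: bool = False,
) -> set[str]:
    """References passing the breadth screen.

    The comparator is explicit because the two screens in this pipeline
    differ: the known-genome screen keeps strictly "> 30%" breadth
    (``inclusive=False``) while the VLP evidence strategy keeps ">= 40%"
    (``inclusive=True``).
    """
    if not 0.0 <= min_breadth <= 1.0:
        raise ParameterError(f"min_breadth must be in [0, 1], got {min_breadth}")
    if inclusive:
        return {c.ref_id for c in coverage if c.breadth >= min_breadth}
    return {c.ref_id for c in coverage if c.breadth > min_breadth}


def scaffold_relative_abundance(
    alignments_by_sample: Mapping[str, Iterable[Alignment]],
    total_reads: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample normalized read counts on phage scaffolds plus the summed
    per-sample phage load (phage-scaffold reads / total reads)."""
    rows: dict[str, dict[str, float]] = {}
    load: dict[str, float] = {}
    for sample, alns in alignments_by_sample.items():
        total = total_reads.get(sample, 0)
        if total <= 0:
            raise DataError(f"total_reads must be > 0 for sample {sample!r}")
        counts: dict[str, int] = defaultdict(int)
        for aln in alns:
            counts[aln.ref_id] += 1
        rows[sample] = {sid: n / total for sid, n in counts.items()}
        load[sample] = sum(counts.values()) / total
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    df = df[sorted(df.columns)] if len(df.columns) else df
    return df, pd.Series(load, name="phage_load").sort_index()
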