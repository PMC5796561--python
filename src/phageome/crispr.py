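"""CRISPR array detection and spacer-to-protospacer matching.

Arrays are detected with a seed-and-extend heuristic in the spirit of CRT:
exact k-mers (k = 13 by default) recurring at regular spacing seed candidate
repeat sets, which are extended outward while all occurrences agree, then
validated against repeat-length, spacer-length and repeat-identity bounds.
Spacers are the inter-repeat intervals. Matching a spacer to a scaffold
implicates that scaffold as a (pro)phage and links it to the bacterial host
that carries the array; matching is strand-insensitive and tolerates a
configurable number of substitutions (default 1) found by a pigeonhole
split of the spacer into exact parts.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._kmers import INVALID, encode, revcomp, window_codes
from .seq_io import Scaffold, SeqRecord


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    scaffold_id: str
    repeat_consensus: str
    repeats: tuple[tuple[int, int], ...]
    spacers: tuple[tuple[str, int, int, str], ...]  # (spacer_id, start, end, seq)


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    target_id: str
    position: int
    strand: str
    mismatches: int
    same_sample: bool


@dataclass(frozen=True)
class Spacer:
    """A spacer queried against candidate protospacer targets."""

    spacer_id: str
    seq: str
    scaffold_id: str = ""
    sample_id: str = ""


# ---------------------------------------------------------------------------
# array detection


def _runs_with_regular_spacing(
    positions: np.ndarray, lo: int, hi: int, min_repeats: int
) -> list[np.ndarray]:
    """Maximal runs of positions whose consecutive gaps are all in [lo, hi]."""
    runs = []
    start = 0
    for i in range(1, len(positions) + 1):
        if i == len(positions) or not lo <= positions[i] - positions[i - 1] <= hi:
            if i - start >= min_repeats:
                runs.append(positions[start:i])
            start = i
    return runs


def detect_arrays(
    scaffold: Scaffold | SeqRecord,
    repeat_len: tuple[int, int] = (21, 48),
    spacer_len: tuple[int, int] = (18, 50),
    min_repeats: int = 3,
    min_repeat_identity: float = 0.9,
    k: int = 13,
) -> list[CrisprArray]:
    """Detect maximal non-overlapping CRISPR arrays on one scaffold."""
    seq = scaffold.seq.upper()
    L = len(seq)
    if L < 2 * repeat_len[0] + spacer_len[0]:
        return []
    codes = encode(seq)
    wc = window_codes(codes, k)
    valid = wc != INVALID
    order = np.argsort(wc, kind="stable")
    sw = wc[order]
    # boundaries of equal-code groups
    cut = np.flatnonzero(np.concatenate(([True], sw[1:] != sw[:-1], [True])))
    period_lo = repeat_len[0] + spacer_len[0]
    period_hi = repeat_len[1] + spacer_len[1]

    candidates: list[np.ndarray] = []
    for gi in range(len(cut) - 1):
        a, b = cut[gi], cut[gi + 1]
        if b - a < min_repeats or sw[a] == INVALID:
            continue
        positions = np.sort(order[a:b])
        for run in _runs_with_regular_spacing(
            positions, period_lo, period_hi, min_repeats
        ):
            candidates.append(run)
    candidates.sort(key=lambda r: (int(r[0]), -len(r)))

    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []
    n_found = 0
    for run in candidates:
        first, last = int(run[0]), int(run[-1]) + k
        if any(first < ce and last > cs for cs, ce in claimed):
            continue
        # extend outward while every occurrence agrees
        dl = 0
        while True:
            nxt = run - dl - 1
            if nxt[0] < 0:
                break
            col = {seq[int(p)] for p in nxt}
            if len(col) != 1:
                break
            dl += 1
            if dl + k > repeat_len[1]:
                break
        dr = 0
        while True:
            nxt = run + k + dr
            if nxt[-1] >= L:
                break
            col = {seq[int(p)] for p in nxt}
            if len(col) != 1:
                break
            dr += 1
            if dl + k + dr > repeat_len[1]:
                break
        rl = dl + k + dr
        starts = [int(p) - dl for p in run]
        if not repeat_len[0] <= rl <= repeat_len[1]:
            continue
        gaps = [starts[i + 1] - (starts[i] + rl) for i in range(len(starts) - 1)]
        if not all(spacer_len[0] <= g <= spacer_len[1] for g in gaps):
            continue
        instances = [seq[s : s + rl] for s in starts]
        consensus = instances[0]
        ident = np.mean(
            [
                sum(a == b for a, b in zip(inst, consensus)) / rl
                for inst in instances
            ]
        )
        if ident < min_repeat_identity or "N" in consensus:
            continue
        n_found += 1
        array_id = f"{scaffold.id}_crispr{n_found}"
        repeats = tuple((s, s + rl) for s in starts)
        spacers = tuple(
            (
                f"{array_id}_s{i + 1}",
                starts[i] + rl,
                starts[i + 1],
                seq[starts[i] + rl : starts[i + 1]],
            )
            for i in range(len(starts) - 1)
        )
        arrays.append(
            CrisprArray(array_id, scaffold.id, consensus, repeats, spacers)
        )
        claimed.append((starts[0], starts[-1] + rl))
    arrays.sort(key=lambda a: a.repeats[0][0])
    # renumber in positional order for deterministic ids
    out = []
    for i, arr in enumerate(arrays):
        array_id = f"{arr.scaffold_id}_crispr{i + 1}"
        out.append(
            CrisprArray(
                array_id,
                arr.scaffold_id,
                arr.repeat_consensus,
                arr.repeats,
                tuple(
                    (f"{array_id}_s{j + 1}", s, e, q)
                    for j, (_, s, e, q) in enumerate(arr.spacers)
                ),
            )
        )
    return out


def extract_spacers(
    arrays: Iterable[CrisprArray], sample_of_scaffold: dict[str, str] | None = None
) -> list[Spacer]:
    sample_of_scaffold = sample_of_scaffold or {}
    return [
        Spacer(sp_id, seq, arr.scaffold_id,
               sample_of_scaffold.get(arr.scaffold_id, ""))
        for arr in arrays
        for sp_id, _, _, seq in arr.spacers
    ]


# ---------------------------------------------------------------------------
# spacer matching


def _verify(target: str, probe: str, start: int, max_mm: int) -> int | None:
    if start < 0 or start + len(probe) > len(target):
        return None
    seg = target[start : start + len(probe)]
    if seg == probe:
        return 0
    mm = 0
    for a, b in zip(seg, probe):
        if a != b:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def match_spacers(
    spacers: Sequence[Spacer],
    targets: Sequence[Scaffold | SeqRecord],
    max_mismatch: int = 1,
    chunk: int = 4_000_000,
) -> list[SpacerMatch]:
    """All occurrences of each spacer on each target, either strand, with at
    most ``max_mismatch`` substitutions.

    Uses a pigeonhole split: each spacer is cut into ``max_mismatch + 1``
    exact parts; part occurrences are located by a vectorized scan of packed
    target windows and candidate placements are verified by direct
    comparison. ``same_sample`` compares the spacer's sample with the
    target's (empty sample ids compare unequal).
    """
    if not spacers or not targets:
        return []
    n_parts = max_mismatch + 1
    # spacers of different lengths split into different part lengths; the
    # scan below runs once per distinct part length
    by_plen: dict[int, dict[int, list[tuple[int, str, int, str]]]] = {}
    for si, sp in enumerate(spacers):
        for strand, probe in (("+", sp.seq), ("-", revcomp(sp.seq))):
            plen = len(probe) // n_parts
            if plen < 8:
                raise ValueError(
                    f"spacer {sp.spacer_id!r} too short to split into "
                    f"{n_parts} parts of >= 8 bp"
                )
            if plen > 31:
                plen = 31
            part_index = by_plen.setdefault(plen, defaultdict(list))
            for pi in range(n_parts):
                off = pi * (len(probe) // n_parts)
                part = probe[off : off + plen]
                code = _part_code(part)
                if code is not None:
                    part_index[code].append((si, strand, off, probe))

    keys_by_plen = {
        plen: np.array(sorted(idx), dtype=np.uint64)
        for plen, idx in by_plen.items()
    }
    found: set[tuple[int, str, int, str]] = set()
    out: list[SpacerMatch] = []
    for tgt in targets:
        tseq = tgt.seq.upper()
        tsample = getattr(tgt, "sample_id", "")
        codes = encode(tseq)
        for plen, part_index in by_plen.items():
            keys = keys_by_plen[plen]
            n = len(codes) - plen + 1
            for lo in range(0, max(n, 0), chunk):
                hi = min(lo + chunk, n)
                wc = window_codes(codes[lo : hi + plen - 1], plen)
                for rel in np.flatnonzero(np.isin(wc, keys)):
                    posn = lo + int(rel)
                    for si, strand, off, probe in part_index[int(wc[int(rel)])]:
                        start = posn - off
                        mm = _verify(tseq, probe, start, max_mismatch)
                        if mm is None:
                            continue
                        key = (si, tgt.id, start, strand)
                        if key in found:
                            continue
                        found.add(key)
                        sp = spacers[si]
                        out.append(
                            SpacerMatch(
                                sp.spacer_id,
                                tgt.id,
                                start,
                                strand,
                                mm,
                                bool(sp.sample_id)
                                and sp.sample_id == tsample,
                            )
                        )
    out.sort(key=lambda m: (m.spacer_id, m.target_id, m.position, m.strand))
    return out


def _part_code(part: str):
    from ._kmers import kmer_code

    code = kmer_code(part)
    return None if code == INVALID else int(code)
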