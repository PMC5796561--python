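"""Weighted-vote taxonomic assignment and terminase identification.

Phage scaffolds are assigned to a family through the phage family ratio
(PFR): every gene with homology hits contributes its top hit with weight 1
and its second-best hit with weight 0.5 to the hit's family; the PFR of a
family is its summed score over the scaffold total, and the scaffold is
assigned when the best family's PFR is strictly greater than 50% (otherwise
"unclassified"). Bacterial scaffolds are assigned a genus the same way with
the bacterial genus ratio (BGR) and an inclusive >= 70% threshold. Per-gene
hit ranking is by ascending e-value, ties by descending bit-score, then
subject id — a declared rule, since external search tools differ here.

Large-subunit terminases (LSTs) are recognized by one of four domains
(Terminase_1, Terminase_3, Terminase_6, Terminase_GpA), scored here with
ungapped motif matching; externally computed domain-hit tables can be
supplied for real data.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seq_io import Gene, HitRecord, SeqRecord

PFR_THRESHOLD = 0.5    # strict: assigned iff PFR > 0.5
BGR_THRESHOLD = 0.70   # inclusive: assigned iff BGR >= 0.70
TOP_HIT_WEIGHT = 1.0
SECOND_HIT_WEIGHT = 0.5

TERMINASE_DOMAINS = ("Terminase_1", "Terminase_3", "Terminase_6", "Terminase_GpA")


@dataclass(frozen=True)
class TaxAssignment:
    scaffold_id: str
    level: str            # 'family' | 'genus'
    label: str            # taxon name or 'unclassified'
    ratio: float
    gene_votes: int


@dataclass(frozen=True)
class LstCall:
    gene_id: str
    domain: str
    score: float


def weighted_votes(
    hits_by_gene: Mapping[str, Sequence[HitRecord]],
    label_of_subject: Mapping[str, str],
) -> tuple[dict[str, float], int]:
    """Summed label scores over genes: per gene the two best-ranked distinct
    subjects that carry a label vote 1.0 and 0.5. Returns (scores, n voting
    genes)."""
    scores: dict[str, float] = defaultdict(float)
    voting = 0
    for gene_id in sorted(hits_by_gene):
        ranked = sorted(
            (h for h in hits_by_gene[gene_id] if h.subject_id in label_of_subject),
            key=lambda h: (h.evalue, -h.bitscore, h.subject_id),
        )
        seen: set[str] = set()
        distinct: list[HitRecord] = []
        for h in ranked:
            if h.subject_id in seen:
                continue
            seen.add(h.subject_id)
            distinct.append(h)
            if len(distinct) == 2:
                break
        if not distinct:
            continue
        voting += 1
        scores[label_of_subject[distinct[0].subject_id]] += TOP_HIT_WEIGHT
        if len(distinct) > 1:
            scores[label_of_subject[distinct[1].subject_id]] += SECOND_HIT_WEIGHT
    return dict(scores), voting


def _assign(
    scaffold_id: str,
    level: str,
    genes: Iterable[Gene],
    hits: Iterable[HitRecord],
    label_of_subject: Mapping[str, str],
    max_evalue: float,
    threshold: float,
    inclusive: bool,
) -> TaxAssignment:
    gene_ids = {g.gene_id for g in genes}
    hits_by_gene: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        if h.evalue <= max_evalue and h.query_id in gene_ids:
            hits_by_gene[h.query_id].append(h)
    scores, voting = weighted_votes(hits_by_gene, label_of_subject)
    total = sum(scores.values())
    if total == 0:
        return TaxAssignment(scaffold_id, level, "unclassified", 0.0, 0)
    # deterministic argmax: highest score, then label
    label, score = min(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    ratio = score / total
    passed = ratio >= threshold if inclusive else ratio > threshold
    return TaxAssignment(
        scaffold_id, level, label if passed else "unclassified", ratio, voting
    )


def assign_phage_family(
    scaffold_id: str,
    genes: Iterable[Gene],
    hits: Iterable[HitRecord],
    family_of_subject: Mapping[str, str],
    max_evalue: float = 1e-5,
) -> TaxAssignment:
    """Family-level assignment by the PFR with the strict > 50% rule."""
    return _assign(
        scaffold_id, "family", genes, hits, family_of_subject, max_evalue,
        PFR_THRESHOLD, inclusive=False,
    )


def assign_bacterial_genus(
    scaffold_id: str,
    genes: Iterable[Gene],
    hits: Iterable[HitRecord],
    genus_of_subject: Mapping[str, str],
    max_evalue: float = 1e-5,
) -> TaxAssignment:
    """Genus-level assignment by the BGR with the inclusive >= 70% rule."""
    return _assign(
        scaffold_id, "genus", genes, hits, genus_of_subject, max_evalue,
        BGR_THRESHOLD, inclusive=True,
    )


# ---------------------------------------------------------------------------
# terminase identification


def _motif_best_score(protein: str, motif: str | np.ndarray, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> float:
    """Best ungapped window score of a motif on a protein, normalized to
    [0, 1]. String motifs score identity fraction; position-weight matrices
    (rows = positions, cols = alphabet) score the normalized path weight."""
    if isinstance(motif, str):
        m = len(motif)
        if m == 0 or len(protein) < m:
            return 0.0
        best = 0
        for i in range(len(protein) - m + 1):
            window = protein[i : i + m]
            score = sum(a == b for a, b in zip(window, motif))
            if score > best:
                best = score
        return best / m
    pwm = np.asarray(motif, dtype=float)
    m = pwm.shape[0]
    if len(protein) < m:
        return 0.0
    col = {aa: j for j, aa in enumerate(alphabet)}
    lo = pwm.min(axis=1).sum()
    hi = pwm.max(axis=1).sum()
    if hi <= lo:
        return 0.0
    best = -np.inf
    for i in range(len(protein) - m + 1):
        s = sum(
            pwm[j, col[aa]] for j, aa in enumerate(protein[i : i + m]) if aa in col
        )
        best = max(best, s)
    return float((best - lo) / (hi - lo))


def identify_lst(
    proteins: Sequence[SeqRecord | tuple[str, str]],
    motifs: Mapping[str, str | np.ndarray],
    min_score: float = 0.9,
) -> list[LstCall]:
    """Proteins matching >= 1 terminase domain motif at ``min_score``; one
    call per protein with the best-scoring domain (ties broken by domain
    name order)."""
    out = []
    for rec in proteins:
        pid, seq = (rec.id, rec.seq) if isinstance(rec, SeqRecord) else rec
        best: tuple[float, str] | None = None
        for domain in sorted(motifs):
            score = _motif_best_score(seq, motifs[domain])
            if score >= min_score and (best is None or score > best[0]):
                best = (score, domain)
        if best is not None:
            out.append(LstCall(pid, best[1], best[0]))
    return out


def lst_tree(lst_proteins: Sequence[SeqRecord]) -> "object":
    """Convenience neighbor-joining tree of LST proteins on pairwise
    p-distances from global alignments. Provided for exploratory use only;
    it stands in for the maximum-likelihood trees a full analysis would
    build with dedicated software."""
    from Bio import Align
    from skbio import DistanceMatrix
    from skbio.tree import nj

    n = len(lst_proteins)
    if n < 3:
        raise ValueError("need >= 3 proteins for a tree")
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-0.5,
    )
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = lst_proteins[i].seq, lst_proteins[j].seq
            ident = aligner.score(a, b) / max(len(a), len(b))
            dm[i, j] = dm[j, i] = 1.0 - min(ident, 1.0)
    ids = [r.id for r in lst_proteins]
    return nj(DistanceMatrix(dm, ids))
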