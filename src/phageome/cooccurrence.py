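"""Compositional co-occurrence/exclusion network between bacterial genera
and pOTUs.

Correlations are estimated in the SparCC manner: relative-abundance data
are compositional, so ordinary correlations of fractions are biased; the
basis (absolute-abundance) correlations are instead inferred from the
log-ratio variance matrix t_ij = Var[log(x_i / x_j)] by solving the linear
approximation that most pairs are uncorrelated, iteratively excluding the
most strongly correlated pairs from that assumption, and averaging over
Dirichlet resamplings of the observed counts. Significance comes from a
permutation null in which each taxon's samples are shuffled independently,
and the network keeps only edges with |r| strictly greater than 0.3 and
p strictly below 0.01, dropping unconnected nodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

R_THRESHOLD = 0.3
P_THRESHOLD = 0.01
DEFAULT_PREVALENCE_MIN_SAMPLES = 72   # strict >, per the cohort's 50% rule


@dataclass(frozen=True)
class CorrEdge:
    node_a: str
    node_b: str
    type_a: str
    type_b: str
    r: float
    p: float

    @property
    def sign(self) -> str:
        return "co-occurrence" if self.r > 0 else "exclusion"


def prevalence_filter(
    matrix: pd.DataFrame, min_samples: int = DEFAULT_PREVALENCE_MIN_SAMPLES
) -> pd.DataFrame:
    """Keep columns detected (value > 0) in strictly more than
    ``min_samples`` samples; an empty result is returned (not raised)."""
    detected = (matrix > 0).sum(axis=0)
    keep = detected[detected > min_samples].index
    return matrix[keep]


def _variation_matrix(logf: np.ndarray) -> np.ndarray:
    """t_ij = Var(log x_i - log x_j), sample variance with ddof=1."""
    n, d = logf.shape
    t = np.zeros((d, d))
    for i in range(d):
        diff = logf[:, i : i + 1] - logf
        t[i] = diff.var(axis=0, ddof=1)
    return t


def _basis_correlations(
    t: np.ndarray, excluded: set[tuple[int, int]]
) -> np.ndarray:
    """Solve for basis variances and correlations given excluded pairs."""
    d = t.shape[0]
    m = np.ones((d, d)) + np.diag([d - 2.0] * d)
    t_eff = t.copy()
    for i, j in excluded:
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
    w = np.linalg.solve(m, t_eff.sum(axis=1))
    w = np.maximum(w, 1e-12)
    sw = np.sqrt(w)
    corr = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sw, sw))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def _sparcc_single(
    fracs: np.ndarray, n_exclusion_rounds: int, exclusion_threshold: float
) -> np.ndarray:
    logf = np.log(fracs)
    t = _variation_matrix(logf)
    d = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    corr = _basis_correlations(t, excluded)
    for _ in range(n_exclusion_rounds):
        a = np.abs(corr)
        np.fill_diagonal(a, 0.0)
        for i, j in excluded:
            a[i, j] = a[j, i] = 0.0
        i, j = np.unravel_index(int(np.argmax(a)), a.shape)
        if a[i, j] <= exclusion_threshold:
            break
        excluded.add((min(i, j), max(i, j)))
        # keep every component in at least 3 unexcluded pairs
        per_comp = np.zeros(d, dtype=int)
        for x, y in excluded:
            per_comp[x] += 1
            per_comp[y] += 1
        if (per_comp > d - 4).any():
            excluded.discard((min(i, j), max(i, j)))
            break
        corr = _basis_correlations(t, excluded)
    return corr


def sparcc_corr(
    counts: pd.DataFrame | np.ndarray,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = 0.1,
    n_resamplings: int = 20,
    pseudocount: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC-style basis correlation matrix of a samples x taxa table.

    With ``n_resamplings=0`` the point estimate from pseudocounted
    fractions is returned (deterministic); otherwise correlations are
    averaged over Dirichlet resamplings of each sample's composition.
    Requires >= 4 taxa (the basis-variance system is unsolvable below
    that; use :func:`spearman_corr` instead).
    """
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    x = df.to_numpy(dtype=float)
    n, d = x.shape
    if d < 4:
        raise ParameterError(
            f"SparCC needs >= 4 taxa (got {d}); use the Spearman fallback "
            "(spearman_corr) for smaller tables"
        )
    if n < 3:
        raise ParameterError(f"need >= 3 samples, got {n}")
    if n_resamplings <= 0:
        z = x + pseudocount
        fracs = z / z.sum(axis=1, keepdims=True)
        corr = _sparcc_single(fracs, n_exclusion_rounds, exclusion_threshold)
    else:
        rng = np.random.default_rng(seed)
        acc = np.zeros((d, d))
        for _ in range(n_resamplings):
            fracs = np.empty_like(x)
            for i in range(n):
                fracs[i] = rng.dirichlet(x[i] + pseudocount)
            acc += _sparcc_single(fracs, n_exclusion_rounds, exclusion_threshold)
        corr = acc / n_resamplings
        np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def spearman_corr(counts: pd.DataFrame) -> pd.DataFrame:
    """Rank-correlation fallback behind the same interface (documented for
    tables too small for the basis-variance solve)."""
    rho = stats.spearmanr(counts.to_numpy(dtype=float), axis=0).statistic
    rho = np.atleast_2d(rho)
    return pd.DataFrame(rho, index=counts.columns, columns=counts.columns)


def permutation_p(
    counts: pd.DataFrame,
    r_obs: pd.DataFrame,
    n_perm: int = 200,
    seed: int | None = None,
    corr_func=None,
    **corr_kwargs,
) -> pd.DataFrame:
    """Two-sided permutation p-values: columns are permuted independently
    per round and p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100, got {n_perm}")
    if corr_func is None:
        corr_func = sparcc_corr
        corr_kwargs.setdefault("n_resamplings", 0)
        corr_kwargs.setdefault("n_exclusion_rounds", 10)
    rng = np.random.default_rng(seed)
    x = counts.to_numpy(dtype=float)
    n, d = x.shape
    obs = np.abs(r_obs.to_numpy(dtype=float))
    exceed = np.zeros((d, d))
    for _ in range(n_perm):
        perm = np.empty_like(x)
        for j in range(d):
            perm[:, j] = x[rng.permutation(n), j]
        r = corr_func(
            pd.DataFrame(perm, columns=counts.columns), **corr_kwargs
        ).to_numpy(dtype=float)
        exceed += np.abs(r) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=r_obs.index, columns=r_obs.columns)


def build_coocc_network(
    corr: pd.DataFrame,
    p: pd.DataFrame,
    node_types: Mapping[str, str] | None = None,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> tuple[list[CorrEdge], list[str]]:
    """Edges with |r| strictly > 0.3 and p strictly < 0.01; nodes not on
    any qualifying edge are omitted from the node list."""
    node_types = node_types or {}
    names = list(corr.columns)
    rm = corr.to_numpy(dtype=float)
    pm = p.to_numpy(dtype=float)
    edges: list[CorrEdge] = []
    connected: set[str] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(rm[i, j]) > r_threshold and pm[i, j] < p_threshold:
                a, b = names[i], names[j]
                edges.append(
                    CorrEdge(
                        a, b,
                        node_types.get(a, "taxon"), node_types.get(b, "taxon"),
                        float(rm[i, j]), float(pm[i, j]),
                    )
                )
                connected |= {a, b}
    return edges, [nm for nm in names if nm in connected]


def coocc_graph(
    edges: Iterable[CorrEdge], prevalence: Mapping[str, int] | None = None
) -> "nx.Graph":
    import networkx as nx

    prevalence = prevalence or {}
    g = nx.Graph()
    for e in edges:
        g.add_node(e.node_a, kind=e.type_a, prevalence=prevalence.get(e.node_a, 0))
        g.add_node(e.node_b, kind=e.type_b, prevalence=prevalence.get(e.node_b, 0))
        g.add_edge(e.node_a, e.node_b, r=e.r, p=e.p, sign=e.sign)
    return g


def write_coocc_graphml(
    edges: Iterable[CorrEdge], path: str | Path,
    prevalence: Mapping[str, int] | None = None,
) -> None:
    import networkx as nx

    nx.write_graphml(coocc_graph(edges, prevalence), str(path))


def write_coocc_edges(edges: Sequence[CorrEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\ttype_a\ttype_b\tr\tp\tsign\n")
        for e in edges:
            fh.write(
                f"{e.node_a}\t{e.node_b}\t{e.type_a}\t{e.type_b}\t"
                f"{e.r:.6g}\t{e.p:.6g}\t{e.sign}\n"
            )
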