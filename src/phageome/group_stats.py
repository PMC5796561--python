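"""Group-wise differential phageome statistics and richness estimation.

Differences between groups are assessed per feature with the two-sided
Mann-Whitney rank-sum test (exact permutation enumeration for small group
sizes, midrank normal approximation with tie and continuity corrections
otherwise), corrected with the Benjamini-Hochberg step-up procedure.
Features are flagged at p < 0.05 and FDR < 0.25; direction is reported
separately from the test. Richness uses the incidence-based Chao2
estimator and sample-based rarefaction.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

P_FLAG = 0.05
Q_FLAG = 0.25
EXACT_MAX_N = 12


@dataclass(frozen=True)
class DiffResult:
    feature_id: str
    level: str                 # 'pOTU' | 'family' | 'scaffold_load'
    u_statistic: float
    p: float
    q: float
    direction: str             # 'up_in_case' | 'up_in_control' | 'none'
    prevalence: int
    significant: bool


# ---------------------------------------------------------------------------
# Mann-Whitney


def _u_from_ranks(pooled_ranks: np.ndarray, idx_x: Sequence[int], n1: int) -> float:
    r1 = float(pooled_ranks[list(idx_x)].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U of the first sample, p). For combined sizes <= 12 the exact
    two-sided permutation distribution of U is enumerated (ties handled via
    midranks); larger samples use the normal approximation with tie and
    continuity corrections. Identical pooled values give p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_from_ranks(ranks, range(n1), n1)
    mu = n1 * n2 / 2.0
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    n = n1 + n2
    if n <= EXACT_MAX_N:
        dev_obs = abs(u_obs - mu)
        count = total = 0
        for combo in itertools.combinations(range(n), n1):
            u = _u_from_ranks(ranks, combo, n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return u_obs, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# prevalence / core selection


def core_selection(
    matrix: pd.DataFrame,
    mode: str,
    min_samples: int | None = None,
    detection_threshold: float = 0.0,
) -> list[str]:
    """Features passing a strict prevalence cutoff.

    ``core_2of3`` keeps features detected in strictly more than
    floor(2N/3) samples; ``prevalent_70pct`` in strictly more than
    floor(0.7 N). ``min_samples`` overrides the computed threshold (the
    cohort analyses this mirrors used explicit counts).
    """
    n = len(matrix.index)
    if mode == "core_2of3":
        thr = min_samples if min_samples is not None else (2 * n) // 3
    elif mode == "prevalent_70pct":
        thr = min_samples if min_samples is not None else int(0.7 * n)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    detected = (matrix > detection_threshold).sum(axis=0)
    return [c for c in matrix.columns if detected[c] > thr]


# ---------------------------------------------------------------------------
# differential analysis


def differential_phageome(
    abundances: pd.DataFrame,
    sample_groups: Mapping[str, str],
    level: str = "pOTU",
    p_flag: float = P_FLAG,
    q_flag: float = Q_FLAG,
) -> list[DiffResult]:
    """Per-feature Mann-Whitney (case vs control) with BH correction.

    ``abundances`` is samples x features; missing values are dropped per
    feature. FDR is computed within the supplied feature set, i.e. per
    reporting level.
    """
    groups = pd.Series({s: sample_groups[s] for s in abundances.index})
    labels = set(groups)
    if labels != {"control", "case"}:
        missing = {"control", "case"} - labels
        raise ParameterError(f"both groups must be present; missing {missing}")
    case_idx = groups[groups == "case"].index
    ctrl_idx = groups[groups == "control"].index
    feats = list(abundances.columns)
    stats_rows = []
    for f in feats:
        col = abundances[f]
        xc = col.loc[case_idx].dropna().to_numpy(dtype=float)
        xn = col.loc[ctrl_idx].dropna().to_numpy(dtype=float)
        u, p = mann_whitney(xc, xn)
        med_c, med_n = np.median(xc), np.median(xn)
        if med_c > med_n:
            direction = "up_in_case"
        elif med_c < med_n:
            direction = "up_in_control"
        else:
            mean_c, mean_n = xc.mean(), xn.mean()
            direction = (
                "up_in_case" if mean_c > mean_n
                else "up_in_control" if mean_c < mean_n else "none"
            )
        prevalence = int((col.fillna(0) > 0).sum())
        stats_rows.append((f, u, p, direction, prevalence))
    qs = bh_fdr([r[2] for r in stats_rows])
    return [
        DiffResult(
            f, level, u, p, float(q), direction, prev,
            bool(p < p_flag and q < q_flag),
        )
        for (f, u, p, direction, prev), q in zip(stats_rows, qs)
    ]


def phage_load_test(
    loads: pd.Series, sample_groups: Mapping[str, str]
) -> DiffResult:
    """Single test of the per-sample phage load (phage-scaffold reads over
    total reads) between groups."""
    df = pd.DataFrame({"phage_load": loads})
    return differential_phageome(df, sample_groups, level="scaffold_load")[0]


# ---------------------------------------------------------------------------
# richness


def chao2(incidence: pd.DataFrame | np.ndarray) -> float:
    """Incidence-based Chao2 richness: S_obs + ((m-1)/m) * Q1^2 / (2 Q2),
    with the bias-corrected form S_obs + ((m-1)/m) * Q1 (Q1 - 1) / 2 when
    no feature occurs in exactly two samples. Rows are features, columns
    samples; any positive value is an occurrence."""
    inc = (
        incidence.to_numpy() if isinstance(incidence, pd.DataFrame) else
        np.asarray(incidence)
    ) > 0
    if inc.ndim != 2 or inc.shape[1] < 1:
        raise ParameterError("incidence must be a features x samples matrix")
    m = inc.shape[1]
    occ = inc.sum(axis=1)
    s_obs = int((occ > 0).sum())
    q1 = int((occ == 1).sum())
    q2 = int((occ == 2).sum())
    factor = (m - 1) / m if m > 0 else 0.0
    if q2 > 0:
        return s_obs + factor * q1 * q1 / (2.0 * q2)
    return s_obs + factor * q1 * (q1 - 1) / 2.0


def rarefaction(
    incidence: pd.DataFrame | np.ndarray,
    n_permutations: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Sample-based rarefaction curve: mean distinct features contained in
    a random k-sample subset, for k = 1..m, averaged over permutations of
    the sample order. Monotone non-decreasing in k."""
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    inc = (
        incidence.to_numpy() if isinstance(incidence, pd.DataFrame) else
        np.asarray(incidence)
    ) > 0
    m = inc.shape[1]
    rng = np.random.default_rng(seed)
    acc = np.zeros(m)
    for _ in range(n_permutations):
        order = rng.permutation(m)
        seen = np.zeros(inc.shape[0], dtype=bool)
        for k, col in enumerate(order):
            seen |= inc[:, col]
            acc[k] += int(seen.sum())
    return acc / n_permutations


def rarefaction_by_group(
    incidence: pd.DataFrame,
    sample_groups: Mapping[str, str],
    n_permutations: int = 100,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """One rarefaction curve per group (columns are samples)."""
    out = {}
    for gi, group in enumerate(sorted(set(sample_groups.values()))):
        cols = [c for c in incidence.columns if sample_groups.get(c) == group]
        sub = incidence[cols]
        out[group] = rarefaction(
            sub, n_permutations, None if seed is None else seed + gi
        )
    return out
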