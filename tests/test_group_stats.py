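"""Rank-sum testing, FDR, prevalence selection, richness and rarefaction."""
import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from phageome.errors import DataError, ParameterError
from phageome.group_stats import (
    bh_fdr,
    chao2,
    core_selection,
    differential_phageome,
    mann_whitney,
    phage_load_test,
    rarefaction,
    rarefaction_by_group,
)


def _exact_two_sided_p(x, y):
    """Oracle: full enumeration of group assignments on midranks."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2.0

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    dev = abs(u_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(combo) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of the 20 arrangements are as extreme

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        _, p_xy = mann_whitney(x, y)
        _, p_yx = mann_whitney(y, x)
        assert p_xy == pytest.approx(p_yx)

    def test_constant_data_p_one(self):
        _, p = mann_whitney([2.0] * 5, [2.0] * 7)
        assert p == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 5), (6, 6)])
    def test_exact_p_equals_enumeration_with_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x = rng.integers(0, 4, n1).astype(float)   # heavy ties
            y = rng.integers(0, 4, n2).astype(float)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(_exact_two_sided_p(x, y), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0.4, 1.2, 18)
            _, p = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
            assert p == pytest.approx(ref, abs=1e-10)


class TestBhFdr:
    def test_hand_worked_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_raises(self):
        with pytest.raises(DataError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_statsmodels_and_preserves_order(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = bh_fdr(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, ref)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestCoreSelection:
    def _matrix(self, n_samples, detections):
        data = {
            f"f{i}": [1.0] * d + [0.0] * (n_samples - d)
            for i, d in enumerate(detections)
        }
        return pd.DataFrame(data)

    def test_core_two_thirds_boundary(self):
        m = self._matrix(145, [97, 96, 145])
        kept = core_selection(m, "core_2of3", min_samples=96)
        assert kept == ["f0", "f2"]

    def test_prevalent_70pct_explicit_count(self):
        m = self._matrix(145, [121, 120, 145])
        kept = core_selection(m, "prevalent_70pct", min_samples=120)
        assert kept == ["f0", "f2"]

    def test_defaults_computed_from_n(self):
        m = self._matrix(9, [7, 6, 9])   # floor(2*9/3)=6 -> need >6
        assert core_selection(m, "core_2of3") == ["f0", "f2"]
        m2 = self._matrix(10, [8, 7, 10])  # floor(0.7*10)=7 -> need >7
        assert core_selection(m2, "prevalent_70pct") == ["f0", "f2"]

    def test_unknown_mode_raises(self):
        with pytest.raises(ParameterError):
            core_selection(self._matrix(4, [4]), "bogus")


class TestDifferential:
    def test_obvious_effect_flagged_with_direction(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(20)]
        groups = {s: ("control" if i < 10 else "case") for i, s in enumerate(samples)}
        effect = np.concatenate([rng.normal(1, 0.1, 10), rng.normal(5, 0.1, 10)])
        null = rng.normal(1, 0.1, 20)
        ab = pd.DataFrame({"eff": effect, "null": null}, index=samples)
        res = {r.feature_id: r for r in differential_phageome(ab, groups)}
        assert res["eff"].significant
        assert res["eff"].direction == "up_in_case"
        assert not res["null"].significant

    def test_missing_group_raises(self):
        ab = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ParameterError):
            differential_phageome(ab, {"a": "control", "b": "control"})

    def test_phage_load_single_test(self):
        loads = pd.Series(
            [0.1] * 6 + [0.5] * 6, index=[f"S{i}" for i in range(12)]
        )
        groups = {f"S{i}": ("control" if i < 6 else "case") for i in range(12)}
        r = phage_load_test(loads, groups)
        assert r.level == "scaffold_load"
        assert r.direction == "up_in_case"
        assert r.p < 0.05


class TestChao2:
    def _incidence(self, m, q1, q2, shared):
        rows = []
        for _ in range(q1):
            row = np.zeros(m); row[0] = 1; rows.append(row)
        for _ in range(q2):
            row = np.zeros(m); row[:2] = 1; rows.append(row)
        for _ in range(shared):
            row = np.zeros(m); row[:3] = 1; rows.append(row)
        return np.array(rows)

    def test_closed_form(self):
        inc = self._incidence(30, q1=10, q2=5, shared=35)
        assert chao2(inc) == pytest.approx(50 + (29 / 30) * 100 / 10, abs=1e-9)

    def test_no_singletons_equals_observed(self):
        inc = self._incidence(10, q1=0, q2=4, shared=6)
        assert chao2(inc) == pytest.approx(10 + (9 / 10) * 0.0)

    def test_bias_corrected_form_when_no_doubletons(self):
        inc = self._incidence(10, q1=4, q2=0, shared=6)
        assert chao2(inc) == pytest.approx(10 + (9 / 10) * 4 * 3 / 2)

    def test_estimate_at_least_observed(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            inc = (rng.random((30, 12)) < 0.2).astype(int)
            s_obs = int((inc.sum(axis=1) > 0).sum())
            assert chao2(inc) >= s_obs

    def test_agrees_with_vegan_specpool(self):
        rng = np.random.default_rng(3)
        inc = (rng.random((40, 15)) < 0.15).astype(int)
        inc = inc[inc.sum(axis=1) > 0]
        csv = "\n".join(",".join(map(str, row)) for row in inc.T)
        script = (
            "suppressMessages(library(vegan));"
            "x <- as.matrix(read.csv(text=readLines('stdin'), header=FALSE));"
            "cat(specpool(x)$chao)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], input=csv, capture_output=True,
            text=True, check=True,
        )
        assert chao2(inc) == pytest.approx(float(out.stdout.strip()), rel=1e-6)


class TestRarefaction:
    def test_full_depth_equals_observed_richness(self):
        rng = np.random.default_rng(4)
        inc = (rng.random((25, 8)) < 0.3).astype(int)
        curve = rarefaction(inc, n_permutations=5, seed=1)
        assert curve[-1] == pytest.approx((inc.sum(axis=1) > 0).sum())

    def test_ubiquitous_single_feature_constant_curve(self):
        inc = np.ones((1, 6))
        curve = rarefaction(inc, n_permutations=3, seed=1)
        assert np.allclose(curve, 1.0)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        inc = (rng.random((40, 10)) < 0.2).astype(int)
        curve = rarefaction(inc, n_permutations=20, seed=2)
        assert (np.diff(curve) >= -1e-12).all()

    def test_matches_exhaustive_enumeration_m5(self):
        """Expected distinct features over all k-subsets of 5 samples."""
        rng = np.random.default_rng(6)
        inc = (rng.random((12, 5)) < 0.4).astype(int)
        curve = rarefaction(inc, n_permutations=4000, seed=3)
        for k in range(1, 6):
            vals = [
                len({f for c in combo for f in np.flatnonzero(inc[:, c])})
                for combo in itertools.combinations(range(5), k)
            ]
            assert curve[k - 1] == pytest.approx(np.mean(vals), abs=0.25)

    def test_by_group_returns_curve_per_group(self):
        rng = np.random.default_rng(7)
        inc = pd.DataFrame(
            (rng.random((20, 6)) < 0.3).astype(int),
            columns=[f"S{i}" for i in range(6)],
        )
        groups = {f"S{i}": ("control" if i < 3 else "case") for i in range(6)}
        curves = rarefaction_by_group(inc, groups, n_permutations=10, seed=1)
        assert set(curves) == {"control", "case"}
        assert len(curves["control"]) == 3
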