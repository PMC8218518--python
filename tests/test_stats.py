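"""Mann-Whitney and Fisher exact against enumeration oracles, plus
group summaries."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as ss

import esnvsig as es
from esnvsig.errors import InsufficientDataError


def mw_exact_oracle(x, y):
    """Independent exact two-sided p: enumerate every way the pooled
    ranks could be assigned to the first group (no ties assumed)."""
    pooled = sorted(x + y)
    ranks_x = [pooled.index(v) + 1 for v in x]
    nx, ny = len(x), len(y)
    u_obs = sum(ranks_x) - nx * (nx + 1) / 2
    us = [sum(c) - nx * (nx + 1) / 2 for c in combinations(range(1, nx + ny + 1), nx)]
    le = sum(u <= u_obs for u in us)
    ge = sum(u >= u_obs for u in us)
    return min(1.0, 2 * min(le, ge) / len(us))


def fisher_oracle(a, b, c, d):
    """Exact-rational hypergeometric enumeration (point-probability rule)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1)) for x in range(lo, hi + 1)
    }
    return float(sum(v for v in probs.values() if v <= probs[a]))


class TestMannWhitney:
    def test_small_exact_example(self):
        u, p = es.mann_whitney_two_sided([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        _, p = es.mann_whitney_two_sided([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            es.mann_whitney_two_sided([], [1.0])

    def test_exact_path_matches_oracles(self):
        """For every group-size split with pooled n <= 10 (tie-free
        values), the p-value matches both the enumeration oracle and an
        independent implementation (scipy exact)."""
        rng = np.random.default_rng(0)
        for n in range(2, 11):
            for nx in range(1, n):
                vals = rng.choice(10_000, size=n, replace=False).astype(float).tolist()
                x, y = vals[:nx], vals[nx:]
                u, p = es.mann_whitney_two_sided(x, y)
                assert p == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)
                ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="exact")
                assert u == ref.statistic and p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_tied_large_sample_matches_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.integers(0, 8, size=int(rng.integers(8, 40))).astype(float)
            y = rng.integers(0, 10, size=int(rng.integers(8, 40))).astype(float)
            u, p = es.mann_whitney_two_sided(x, y)
            ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @given(
        x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8),
        y=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=8),
    )
    @settings(max_examples=80, deadline=None)
    def test_u_statistics_partition(self, x, y):
        ux, _ = es.mann_whitney_two_sided(x, y)
        uy, _ = es.mann_whitney_two_sided(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(1, 1, size=20)
        u1, p1 = es.mann_whitney_two_sided(x, y)
        u2, p2 = es.mann_whitney_two_sided(np.exp(x), np.exp(y))
        assert u1 == u2 and p1 == pytest.approx(p2)


class TestFisherExact:
    def test_balanced_table(self):
        assert es.fisher_exact_two_sided([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_table(self):
        # P(x=2) + P(x=0) = 1/6 + 1/6
        assert es.fisher_exact_two_sided([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_extreme_one_sided_table(self):
        # the observed table is the most extreme with its margins, so the
        # two-sided sum reduces to a single tail
        p = es.fisher_exact_two_sided([[6, 0], [47, 142]])
        assert p == pytest.approx(fisher_oracle(6, 0, 47, 142), rel=1e-9)
        assert p == pytest.approx(3.25e-4, rel=0.01)

    def test_all_small_tables_match_oracle(self):
        """Every 2x2 table with total <= 10 agrees with the
        exact-rational enumeration oracle and with scipy."""
        from itertools import product

        for a, b, c, d in product(range(8), repeat=4):
            if not 1 <= a + b + c + d <= 10:
                continue
            p = es.fisher_exact_two_sided([[a, b], [c, d]])
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)
            assert p == pytest.approx(ss.fisher_exact([[a, b], [c, d]])[1], abs=1e-7)

    def test_transpose_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            p = es.fisher_exact_two_sided([[a, b], [c, d]])
            assert p == pytest.approx(es.fisher_exact_two_sided([[a, c], [b, d]]), rel=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            es.ContingencyTable2x2(-1, 1, 1, 1)


class TestSummarizeGroup:
    def test_six_case_ages(self):
        s = es.summarize_group([46, 49, 49, 46, 49, 51])
        assert s.mean == pytest.approx(48.33, abs=0.005)

    def test_six_case_tmb_median(self):
        s = es.summarize_group([75.2, 71.7, 64.1, 28.6, 21.6, 5.8])
        assert s.median == pytest.approx(46.35)

    def test_single_value(self):
        s = es.summarize_group([7.0])
        assert s.mean == s.median == s.q1 == s.q3 == 7.0

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            es.summarize_group([])


class TestCompareCohort:
    def test_joins_and_tests(self):
        import pandas as pd

        calls = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(10)],
                "pole_tmb": [50, 40, 1, 2, 1, 0.5, 2, 1, 0.2, 0.8],
                "outlier": [True, True] + [False] * 8,
            }
        )
        ann = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(10)],
                "age_years": [45, 50, 60, 62, 70, 58, 66, 71, 59, 64],
                "histology": ["endometrioid"] * 3 + ["serous"] * 7,
            }
        )
        out = es.compare_cohort(calls, ann)
        assert out["n_pole"] == 2
        assert out["histotype_fisher"]["table"] == [[2, 0], [1, 7]]
        assert 0 < out["histotype_fisher"]["p"] <= 1
        assert out["pole_frequency_in_histotype_pct"] == pytest.approx(100 * 2 / 3)
        assert out["age_mann_whitney"]["mean_age_pole"] == pytest.approx(47.5)
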