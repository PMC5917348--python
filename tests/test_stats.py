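"""Region assignment, classification, agreement statistics and the exact
tests, each checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.stats import hypergeom

from afconcord import stats as st
from afconcord import substrate, tissue
from afconcord.phase import PSPoint, PSTrajectory


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def fisher_exact_enum(k1, n1, k2, n2):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    K = k1 + k2
    N = n1 + n2
    p_obs = hypergeom.pmf(k1, N, K, n1)
    total = 0.0
    for x in range(max(0, K - n2), min(K, n1) + 1):
        p = hypergeom.pmf(x, N, K, n1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def wilcoxon_enum(x, y):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product((0, 1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    m = 2 ** n
    p_le = np.sum(ws <= w_obs + 1e-9) / m
    p_ge = np.sum(ws >= w_obs - 1e-9) / m
    return min(1.0, 2 * min(p_le, p_ge))


def kappa_direct(a, b, c, d):
    n = a + b + c + d
    po = (a + d) / n
    pe = ((a + b) / n) * ((a + c) / n) + ((c + d) / n) * ((b + d) / n)
    return (po - pe) / (1 - pe)


def kappa0_direct(a, b, c, d):
    n = a + b + c + d
    po = (a + d) / n
    pbar = ((a + b) / n + (a + c) / n) / 2
    pe = pbar ** 2 + (1 - pbar) ** 2
    return (po - pe) / (1 - pe)


# ---------------------------------------------------------------------------
# Region assignment and classification
# ---------------------------------------------------------------------------

def make_grid():
    g = tissue.TissueGrid.uniform(120, 120)
    g.region_id = substrate.partition_regions(g)
    return g


def traj_in_regions(grid, region_counts):
    """Trajectory with the requested number of points in each region."""
    pts = []
    t = 0.0
    for region, count in region_counts:
        iys, ixs = np.nonzero(grid.region_id == region)
        for k in range(count):
            pts.append(PSPoint(t=t, x=ixs[k] * grid.dx, y=iys[k] * grid.dx,
                               chirality=1))
            t += 1.0
    return PSTrajectory(points=pts)


class TestRegionAssignment:
    def test_plurality_wins(self):
        g = make_grid()
        traj = traj_in_regions(g, [(1, 4), (3, 6)])
        assert st.assign_rd_region(traj, g) == 3

    def test_all_in_one_region(self):
        g = make_grid()
        traj = traj_in_regions(g, [(5, 9)])
        assert st.assign_rd_region(traj, g) == 5

    def test_tie_broken_by_latest_point(self):
        g = make_grid()
        traj = traj_in_regions(g, [(1, 5), (2, 5)])  # last point in region 2
        assert st.assign_rd_region(traj, g) == 2

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            st.assign_rd_region(PSTrajectory(points=[]), make_grid())


class TestClassification:
    def test_example_sets(self):
        cl = st.classify_patient(sim_regions={1, 3}, ecgi_regions={1, 2})
        assert cl.labels[1] == "ECGI+/Sim+"
        assert cl.labels[2] == "ECGI+/Sim-"
        assert cl.labels[3] == "ECGI-/Sim+"
        for r in (4, 5, 6, 7):
            assert cl.labels[r] == "ECGI-/Sim-"

    def test_identical_sets_only_agreement(self):
        cl = st.classify_patient({2, 5}, {2, 5})
        assert set(cl.labels.values()) <= {"ECGI+/Sim+", "ECGI-/Sim-"}

    def test_both_empty_all_negative(self):
        cl = st.classify_patient(set(), set())
        assert all(v == "ECGI-/Sim-" for v in cl.labels.values())

    @given(hst.sets(hst.integers(1, 7)), hst.sets(hst.integers(1, 7)),
           hst.sets(hst.integers(1, 7)), hst.sets(hst.integers(1, 7)))
    def test_pooling_conserves_margins(self, s1, e1, s2, e2):
        cls = [st.classify_patient(s1, e1, "a"),
               st.classify_patient(s2, e2, "b")]
        table = st.pool_concordance(cls)
        assert table.n == 14
        assert table.a + table.b == len(e1) + len(e2)
        assert table.a + table.c == len(s1) + len(s2)

    def test_pooled_fixture_agreement(self):
        table = st.ConcordanceTable(19, 23, 9, 33)
        assert table.percent_agreement == pytest.approx(52 / 84)


class TestKappas:
    def test_perfect_agreement(self):
        t = st.ConcordanceTable(10, 0, 0, 20)
        assert st.cohen_kappa(t) == (pytest.approx(1.0), False)
        assert st.kraemer_kappa0(t) == (pytest.approx(1.0), False)

    def test_independence_table_zero(self):
        t = st.ConcordanceTable(10, 10, 10, 10)
        k, flag = st.cohen_kappa(t)
        assert k == pytest.approx(0.0, abs=1e-15)
        assert not flag

    def test_pooled_table_matches_direct_formula(self):
        t = st.ConcordanceTable(19, 23, 9, 33)
        k, _ = st.cohen_kappa(t)
        k0, _ = st.kraemer_kappa0(t)
        assert abs(k - kappa_direct(19, 23, 9, 33)) < 1e-12
        assert abs(k0 - kappa0_direct(19, 23, 9, 33)) < 1e-12

    def test_label_swap_invariance(self):
        # swapping the positive/negative labels of both raters maps
        # (a,b,c,d) -> (d,c,b,a) and must leave both kappas unchanged
        for (a, b, c, d) in [(19, 23, 9, 33), (5, 2, 7, 11), (1, 2, 3, 4)]:
            t1 = st.ConcordanceTable(a, b, c, d)
            t2 = st.ConcordanceTable(d, c, b, a)
            assert st.cohen_kappa(t1)[0] == pytest.approx(st.cohen_kappa(t2)[0])
            assert st.kraemer_kappa0(t1)[0] == pytest.approx(
                st.kraemer_kappa0(t2)[0])

    def test_degenerate_margin_flagged(self):
        k, flag = st.cohen_kappa(st.ConcordanceTable(0, 0, 5, 10))
        assert flag and k == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            st.cohen_kappa(st.ConcordanceTable(0, 0, 0, 0))


class TestFisher:
    def test_identical_proportions_p_one(self):
        assert st.fisher_exact(5, 10, 5, 10) == pytest.approx(1.0)

    def test_extreme_table_small_p(self):
        p = st.fisher_exact(10, 10, 0, 10)
        assert p == pytest.approx(fisher_exact_enum(10, 10, 0, 10), rel=1e-9)
        assert p < 1e-3

    def test_outcome_rates_not_significant(self):
        # 13/23 vs 9/22 positive responses
        p = st.fisher_exact(13, 23, 9, 22)
        assert p > 0.05
        assert p == pytest.approx(fisher_exact_enum(13, 23, 9, 22), rel=1e-9)

    @given(hst.integers(1, 12), hst.integers(1, 12),
           hst.integers(0, 12), hst.integers(0, 12))
    def test_matches_enumeration_small_n(self, n1, n2, k1_raw, k2_raw):
        k1, k2 = min(k1_raw, n1), min(k2_raw, n2)
        assert st.fisher_exact(k1, n1, k2, n2) == pytest.approx(
            fisher_exact_enum(k1, n1, k2, n2), rel=1e-9, abs=1e-12)


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert st.wilcoxon_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_three_positive_differences(self):
        # all ranks positive: W+ = 6, two-sided p = 2/8
        p = st.wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert p == pytest.approx(0.25)

    def test_table2_pre_vs_post1_not_significant(self):
        pre = [3, 3, 3, 3, 4, 2]
        post1 = [2, 5, 3, 1, 3, 2]
        p = st.wilcoxon_signed_rank(pre, post1)
        assert p > 0.05
        assert p == pytest.approx(wilcoxon_enum(pre, post1), rel=1e-12)

    @given(hst.lists(hst.integers(-4, 4), min_size=1, max_size=9),
           hst.lists(hst.integers(-4, 4), min_size=1, max_size=9))
    def test_matches_enumeration_small_n(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = xs[:n], ys[:n]
        assert st.wilcoxon_signed_rank(x, y) == pytest.approx(
            wilcoxon_enum(x, y), rel=1e-12, abs=1e-12)


class TestMedianIqr:
    @pytest.mark.parametrize("values,expected", [
        ([2, 3, 3, 3, 3, 4], (3.0, 2.8, 3.3)),
        ([1, 2, 2, 3, 3, 5], (2.5, 1.8, 3.5)),
        ([1, 2, 2, 3, 3, 4], (2.5, 1.8, 3.3)),
    ])
    def test_printed_iqr_convention(self, values, expected):
        assert st.median_iqr(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            st.median_iqr([])


class TestOutcomeTabulation:
    def test_fixture_counts_reproduce_rates(self):
        targets = []
        for _ in range(13):
            targets.append({"region_class": "ECGI+/Sim+", "terminated": False,
                            "positive_response": True, "delta_cl": 15.0})
        for _ in range(10):
            targets.append({"region_class": "ECGI+/Sim+", "terminated": False,
                            "positive_response": False, "delta_cl": 2.0})
        for _ in range(9):
            targets.append({"region_class": "ECGI+/Sim-", "terminated": False,
                            "positive_response": True, "delta_cl": 12.0})
        for _ in range(13):
            targets.append({"region_class": "ECGI+/Sim-", "terminated": False,
                            "positive_response": False, "delta_cl": 1.0})
        out = st.outcome_tabulation(targets)
        assert out["ECGI+/Sim+"].positive_rate_pct == 57
        assert out["ECGI+/Sim-"].positive_rate_pct == 41

    def test_empty_class_flagged(self):
        out = st.outcome_tabulation([])
        assert all(not s.defined for s in out.values())

    def test_all_terminated_hundred_percent(self):
        targets = [{"region_class": "ECGI+/Sim+", "terminated": True,
                    "positive_response": True, "delta_cl": None}] * 4
        out = st.outcome_tabulation(targets)
        s = out["ECGI+/Sim+"]
        assert s.positive_rate_pct == 100
        assert s.termination_rate_pct == 100
        assert s.delta_cl_median_iqr is None
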