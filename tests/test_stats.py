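import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from nasolab import stats
from nasolab.stats import (
    RatingRecord,
    composite_scores,
    kendall_tau_b,
    kruskal_wallis,
    reliability_tables,
    simulate_ratings,
    subjective_objective_correlation,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent enumeration oracles (pure python, no shared code paths)


def oracle_tau_b(x, y):
    n = len(x)
    num = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a = np.sign(x[i] - x[j])
        b = np.sign(y[i] - y[j])
        num += a * b
        tx += a != 0
        ty += b != 0
    return num / np.sqrt(tx * ty)


def oracle_tau_p(x, y):
    obs = abs(oracle_tau_b(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(oracle_tau_b(x, perm)) >= obs - 1e-9:
            hits += 1
    return hits / total


def oracle_wilcoxon_p(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    lo = hi = total = 0
    for signs in itertools.product([False, True], repeat=len(d)):
        w = ranks[list(signs)].sum()
        total += 1
        lo += w <= w_obs + 1e-9
        hi += w >= w_obs - 1e-9
    return min(1.0, 2 * min(lo / total, hi / total))


def oracle_kruskal_p(groups):
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_stat(vals_by_group):
        n = len(pooled)
        ranks = sps.rankdata(np.concatenate(vals_by_group))
        offs = np.cumsum([0] + [len(g) for g in vals_by_group])
        h = sum(
            len(g) * (ranks[offs[i]:offs[i + 1]].mean() - (n + 1) / 2) ** 2
            for i, g in enumerate(vals_by_group)
        ) * 12.0 / (n * (n + 1))
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1 - ((counts**3 - counts).sum()) / (len(pooled) ** 3 - len(pooled))
        return h / tie if tie > 0 else 0.0

    h_obs = h_stat(groups)
    hits = total = 0
    idx = list(range(len(pooled)))

    def assignments(remaining, szs):
        if not szs:
            yield []
            return
        for combo in itertools.combinations(remaining, szs[0]):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in assignments(rest, szs[1:]):
                yield [combo] + tail

    for lab in assignments(tuple(idx), sizes):
        total += 1
        if h_stat([pooled[list(ix)] for ix in lab]) >= h_obs - 1e-9:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------


class TestComposites:
    def test_worked_example(self):
        rec = RatingRecord("c1", "r1", "lay", 1, 2, 3, 1, 4, 5)
        assert composite_scores(rec) == (5, 10, 15)

    def test_all_ones(self):
        rec = RatingRecord("c1", "r1", "lay", 1, 1, 1, 1, 1, 1)
        assert composite_scores(rec) == (2, 3, 5)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="\\[1, 5\\]"):
            RatingRecord("c1", "r1", "lay", 1, 6, 3, 1, 4, 5)
        with pytest.raises(ValueError, match="missing"):
            RatingRecord("c1", "r1", "lay", 1, None, 3, 1, 4, 5)


class TestWilcoxon:
    def test_constant_shift_exact_p(self):
        x = np.arange(1, 7, dtype=float)
        r = wilcoxon_signed_rank(x, x + 1)
        assert r.statistic == 0.0
        assert r.p == 2 / 64

    def test_single_pair(self):
        assert wilcoxon_signed_rank([3.0], [4.0]).p == 1.0

    def test_identical_samples_noted(self):
        r = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert r.p == 1.0
        assert any("all-zero" in n for n in r.notes)

    @pytest.mark.parametrize("x, y", [
        ([5, 3, 8, 8, 2, 6, 4], [3, 3, 6, 10, 4, 6, 1]),
        ([1, 2, 3, 4, 5], [2, 2, 2, 5, 3]),
        ([1, 1, 1, 2], [2, 2, 2, 1]),
        ([10, 9, 8, 7, 6, 5], [9, 9, 9, 9, 9, 9]),
    ])
    def test_exact_p_matches_sign_flip_enumeration(self, x, y):
        r = wilcoxon_signed_rank(np.array(x, float), np.array(y, float))
        assert r.p == pytest.approx(oracle_wilcoxon_p(x, y), abs=1e-12)

    def test_untied_exact_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            mine = wilcoxon_signed_rank(x, y).p
            ref = float(sps.wilcoxon(x, y, method="exact").pvalue)
            assert mine == pytest.approx(ref, abs=1e-12)


class TestKendall:
    def test_perfect_concordance_and_reversal(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]).statistic == 1.0
        assert kendall_tau_b([1, 2, 3, 4], [4, 3, 2, 1]).statistic == -1.0

    def test_fully_tied_margin_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            kendall_tau_b([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("x, y", [
        ([1, 2, 2, 3], [1, 2, 3, 3]),
        ([1, 1, 2, 3, 3], [2, 1, 3, 1, 2]),
        ([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5]),
        ([1, 5, 2, 5, 3], [2, 2, 4, 4, 1]),
    ])
    def test_tau_and_exact_p_match_enumeration(self, x, y):
        r = kendall_tau_b(np.array(x, float), np.array(y, float))
        assert r.statistic == pytest.approx(oracle_tau_b(x, y), abs=1e-12)
        assert r.p == pytest.approx(oracle_tau_p(x, y), abs=1e-12)

    @given(st.lists(st.integers(1, 5), min_size=4, max_size=7),
           st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_tau_bounds_and_antisymmetry(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.array(xs, dtype=float)
        y = rng.permutation(np.arange(len(x), dtype=float))  # untied margin
        if len(np.unique(x)) < 2:
            return
        r = kendall_tau_b(x, y)
        assert -1.0 <= r.statistic <= 1.0
        r_neg = kendall_tau_b(x, -y)
        assert r_neg.statistic == pytest.approx(-r.statistic, abs=1e-12)


class TestKruskalWallis:
    def test_worked_example_exact(self):
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6]], exact=True)
        assert r.statistic == pytest.approx(12 / 42 * 13.5, abs=1e-12)
        assert r.p == pytest.approx(2 / 20, abs=1e-12)

    def test_identical_groups_h_zero(self):
        r = kruskal_wallis([[2, 2, 2], [2, 2, 2]])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            kruskal_wallis([[1, 2], []])

    @pytest.mark.parametrize("groups", [
        [[1, 3, 5], [2, 2, 6]],
        [[1, 2], [3, 4], [5, 1]],
        [[1, 1, 2, 2], [3, 3, 1]],
    ])
    def test_exact_p_matches_enumeration(self, groups):
        r = kruskal_wallis([np.array(g, float) for g in groups], exact=True)
        assert r.p == pytest.approx(oracle_kruskal_p(
            [np.array(g, float) for g in groups]), abs=1e-12)

    def test_h_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            groups = [rng.integers(1, 6, rng.integers(3, 8)).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            r = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=6) for _ in range(3)]
        h1 = kruskal_wallis(groups).statistic
        h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
        assert h1 == pytest.approx(h2, abs=1e-10)


class TestTypeIError:
    def test_all_three_tests_hold_nominal_level(self):
        """Simulated continuous null at n = 15: each test's rejection rate
        at alpha = 0.05 stays within +-0.015 of nominal (2000 reps)."""
        rng = np.random.default_rng(7)
        n_rep = 2000
        rej = {"w": 0, "k": 0, "kw": 0}
        for _ in range(n_rep):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            if wilcoxon_signed_rank(a, b).p <= 0.05:
                rej["w"] += 1
            if kendall_tau_b(a, b).p <= 0.05:
                rej["k"] += 1
            g = rng.normal(size=15)
            if kruskal_wallis([g[:5], g[5:10], g[10:]]).p <= 0.05:
                rej["kw"] += 1
        for key, count in rej.items():
            assert abs(count / n_rep - 0.05) <= 0.015, (key, count / n_rep)


# ---------------------------------------------------------------------------
# rating tables


def _measurements(n_cases=12, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "case": [f"c{i}" for i in range(n_cases)],
        "scar_area_mm2": rng.uniform(80, 220, n_cases),
        "mean_total_mm": rng.uniform(0.2, 1.4, n_cases),
    })


class TestReliabilityTables:
    def test_duplicated_occasion_gives_perfect_agreement(self):
        meas = _measurements()
        ratings = simulate_ratings(meas, seed=3)
        o1 = ratings[ratings["occasion"] == 1].copy()
        o2 = o1.copy()
        o2["occasion"] = 2
        dup = pd.concat([o1, o2], ignore_index=True)
        intra = stats.intra_rater_table(dup)
        np.testing.assert_allclose(intra["kendall_tau"], 1.0, atol=1e-12)
        np.testing.assert_allclose(intra["wilcoxon_p"], 1.0, atol=1e-12)

    def test_table_shape_and_row_labels(self):
        ratings = simulate_ratings(_measurements(), seed=1)
        tables = reliability_tables(ratings)
        intra, inter = tables["intra"], tables["inter"]
        assert len(intra) == 2 * 8  # 8 parameters per panel
        assert list(intra["parameter"].unique()) == list(stats.PARAMETERS)
        assert intra["parameter"].iloc[7] == "total_score"
        assert len(inter) == 2 * 8  # 8 parameters per occasion
        assert set(inter["occasion"]) == {1, 2}

    def test_missing_panel_rejected(self):
        ratings = simulate_ratings(_measurements(), seed=1)
        pro_only = ratings[ratings["panel"] == "professional"]
        with pytest.raises(ValueError, match="lay"):
            stats.inter_panel_table(pro_only)
        with pytest.raises(ValueError, match="lay"):
            stats.intra_rater_table(pro_only)

    def test_missing_occasion_rejected(self):
        ratings = simulate_ratings(_measurements(), seed=1)
        occ1 = ratings[ratings["occasion"] == 1]
        with pytest.raises(ValueError, match="occasion 2"):
            stats.intra_rater_table(occ1)


class TestSubjectiveObjective:
    def test_monotone_scores_give_tau_one(self):
        """Strictly increasing (untied) composites as a monotone function
        of the objective measure give tau-b exactly 1."""
        meas = _measurements(8, seed=2)
        rows = []
        order = meas["scar_area_mm2"].rank().astype(int) - 1
        asym_order = meas["mean_total_mm"].rank().astype(int) - 1
        for panel in ("professional", "lay"):
            for occ in (1, 2):
                for i, case in enumerate(meas["case"]):
                    r, a = int(order.iloc[i]), int(asym_order.iloc[i])
                    rows.append({
                        "case": case, "rater": f"{panel}_r", "panel": panel,
                        "occasion": occ,
                        # composites 2+r and 3+a: strictly increasing in rank
                        "scar_length": 1 + r // 2,
                        "scar_width": 1 + (r + 1) // 2,
                        "vb_disparity": 1 + a // 3,
                        "asym_y": 1 + (a + 1) // 3,
                        "asym_z": 1 + (a + 2) // 3,
                    })
        corr = subjective_objective_correlation(pd.DataFrame(rows), meas)
        np.testing.assert_allclose(corr["kendall_tau"], 1.0, atol=1e-12)

    def test_independent_scores_give_near_zero_tau(self):
        """With ratings independent of the measurements (200 cases), tau
        stays small — the null-distribution sanity check."""
        rng = np.random.default_rng(12)
        n = 200
        meas = _measurements(n, seed=5)
        rows = []
        for panel in ("professional", "lay"):
            for case in meas["case"]:
                rows.append({
                    "case": case, "rater": f"{panel}_r", "panel": panel,
                    "occasion": 1,
                    **{c: int(rng.integers(1, 6))
                       for c in stats.SCORE_COLUMNS},
                })
        corr = subjective_objective_correlation(pd.DataFrame(rows), meas)
        assert (corr["kendall_tau"].abs() < 0.15).all()

    def test_missing_measurement_rejected(self):
        meas = _measurements(6)
        ratings = simulate_ratings(meas, seed=1)
        with pytest.raises(ValueError, match="missing"):
            subjective_objective_correlation(ratings, meas.iloc[:-1])


class TestRatingsCsv:
    def test_round_trip_and_validation(self, tmp_path):
        ratings = simulate_ratings(_measurements(5), seed=6)
        path = tmp_path / "ratings.csv"
        ratings[["case", "rater", "panel", "occasion",
                 *stats.SCORE_COLUMNS]].to_csv(path, index=False)
        back = stats.read_ratings_csv(path)
        assert len(back) == len(ratings)
        assert "total_score" in back.columns

    def test_duplicate_rows_rejected(self):
        ratings = simulate_ratings(_measurements(4), seed=6)
        dup = pd.concat([ratings, ratings.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            stats.validate_ratings(dup[["case", "rater", "panel", "occasion",
                                        *stats.SCORE_COLUMNS]])
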