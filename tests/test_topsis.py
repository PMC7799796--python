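"""TOPSIS: the five-step chain, its invariants, and the group scores."""

import numpy as np
import pandas as pd
import pytest

from caregap.topsis import (
    DegenerateMatrixWarning,
    TopsisError,
    WeightScheme,
    apply_weights,
    closeness,
    distances,
    group_scores,
    ideal_base,
    mean_total,
    normalize,
    run_group_topsis,
    summarize_scores,
    topsis,
)


class TestSteps:
    def test_normalize_3_4_5(self):
        r = normalize(np.array([[3.0], [4.0]]))
        assert r[:, 0] == pytest.approx([0.6, 0.8])

    def test_normalize_unit_column_norms(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.1, 100, size=(4, 2))
        r = normalize(x)
        assert np.linalg.norm(r, axis=0) == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_single_alternative_rejected(self):
        with pytest.raises(TopsisError):
            normalize(np.array([[5.0]]))

    def test_all_zero_column_warns(self):
        with pytest.warns(DegenerateMatrixWarning):
            r = normalize(np.array([[0.0, 1.0], [0.0, 2.0]]))
        assert (r[:, 0] == 0).all()

    def test_apply_weights_scaling_and_identity(self):
        r = np.array([[0.6], [0.8]])
        assert apply_weights(r, [0.5])[:, 0] == pytest.approx([0.3, 0.4])
        assert (apply_weights(r, [1.0]) == r).all()
        with pytest.warns(DegenerateMatrixWarning):
            v = apply_weights(r, [0.0])
        assert (v == 0).all()

    def test_ideal_base_max_min(self):
        v = np.array([[0.3, 0.1], [0.4, 0.1]])
        h, d = ideal_base(v)
        assert h.tolist() == [0.4, 0.1]
        assert d.tolist() == [0.3, 0.1]

    def test_ideal_base_matches_column_scan(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=(5, 3))
        h, d = ideal_base(v)
        for j in range(3):
            col = [v[i, j] for i in range(5)]
            assert h[j] == max(col) and d[j] == min(col)

    def test_distances_at_the_poles(self):
        v = np.array([[0.1, 0.2], [0.4, 0.6]])
        h, d = ideal_base(v)
        d_plus, d_minus = distances(v, h, d)
        assert d_plus[1] == 0.0 and d_minus[0] == 0.0

    def test_distances_hand_case(self):
        v = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 0.0]])
        h, d = ideal_base(v)
        d_plus, d_minus = distances(v, h, d)
        assert d_plus.tolist() == [5.0, 0.0, 4.0]
        assert d_minus.tolist() == [0.0, 5.0, 3.0]

    def test_closeness_poles_and_degenerate(self):
        assert closeness([0.0], [2.0])[0] == 1.0
        assert closeness([2.0], [0.0])[0] == 0.0
        with pytest.warns(DegenerateMatrixWarning):
            assert closeness([0.0], [0.0])[0] == 0.5
        with pytest.raises(TopsisError):
            closeness([-1.0], [1.0])


class TestChain:
    def test_two_alternative_dominance_closed_form(self):
        m = pd.DataFrame([[100.0, 100.0], [40.0, 70.0]], index=["A", "B"])
        res = topsis(m, [0.6, 0.4])
        assert res.c["A"] == 1.0
        assert res.c["B"] == 0.0
        assert res.ranking() == ["A", "B"]

    def test_three_district_manual_oracle(self):
        """Full c vector equals an independently hand-executed chain."""
        raw = [[100.0, 100.0], [50.0, 100.0], [0.0, 0.0]]
        w = [0.6, 0.4]
        # independent step-by-step recomputation with plain loops
        norms = [sum(row[j] ** 2 for row in raw) ** 0.5 for j in range(2)]
        r = [[row[j] / norms[j] for j in range(2)] for row in raw]
        v = [[w[j] * r[i][j] for j in range(2)] for i in range(3)]
        h = [max(v[i][j] for i in range(3)) for j in range(2)]
        d = [min(v[i][j] for i in range(3)) for j in range(2)]
        dp = [sum((v[i][j] - h[j]) ** 2 for j in range(2)) ** 0.5 for i in range(3)]
        dm = [sum((v[i][j] - d[j]) ** 2 for j in range(2)) ** 0.5 for i in range(3)]
        expected = [dm[i] / (dm[i] + dp[i]) for i in range(3)]

        res = topsis(pd.DataFrame(raw, index=["A", "B", "C"]), w)
        assert res.c.tolist() == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(0, 100, size=(6, 2)), index=list("ABCDEF"))
        res = topsis(m, [0.6, 0.4])
        perm = m.sample(frac=1, random_state=1)
        res2 = topsis(perm, [0.6, 0.4])
        for a in m.index:
            assert res2.c[a] == pytest.approx(res.c[a], abs=1e-12)

    def test_range_and_tie_break(self):
        m = pd.DataFrame([[50.0, 50.0], [50.0, 50.0], [10.0, 10.0]],
                         index=["B", "A", "C"])
        res = topsis(m, [0.6, 0.4])
        assert ((res.c >= 0) & (res.c <= 1)).all()
        assert res.ranking() == ["A", "B", "C"]  # tie broken by id

    def test_scale_invariance_of_closeness(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = rng.uniform(0.1, 100, size=(5, 2))
            c1 = topsis(pd.DataFrame(m), [0.7, 0.3]).c
            scaled = m * np.array([13.7, 0.04])
            c2 = topsis(pd.DataFrame(scaled), [0.7, 0.3]).c
            assert c2.to_numpy() == pytest.approx(c1.to_numpy(), abs=1e-10)

    def test_dominance_monotonicity_random(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            m = rng.uniform(0, 100, size=(6, 2))
            c = topsis(pd.DataFrame(m), [0.6, 0.4]).c.to_numpy()
            for i in range(6):
                for k in range(6):
                    if (m[i] >= m[k]).all() and (m[i] > m[k]).any():
                        assert c[i] >= c[k] - 1e-12


class TestGroups:
    def test_group_topsis_on_indicator_table(self):
        table = pd.DataFrame(
            {
                "X1": [100, 200, 300],
                "X4a": [100.0, 50.0, 0.0],
                "X4b": [100.0, 100.0, 0.0],
            },
            index=["D1", "D2", "D3"],
        )
        res = run_group_topsis(table, "X4")
        assert res.c["D1"] == 1.0 and res.c["D3"] == 0.0

    def test_unknown_group_rejected(self):
        with pytest.raises(TopsisError):
            run_group_topsis(pd.DataFrame({"X4a": [1, 2], "X4b": [1, 2]}), "X9")

    def test_zero_recipient_districts_dropped_with_notice(self):
        table = pd.DataFrame(
            {
                "X1": [100, 0, 300],
                "X4a": [100.0, 50.0, 0.0],
                "X4b": [100.0, 100.0, 0.0],
            },
            index=["D1", "D2", "D3"],
        )
        with pytest.warns(DegenerateMatrixWarning, match="D2"):
            res = run_group_topsis(table, "X4")
        assert list(res.c.index) == ["D1", "D3"]

    def test_mean_total_forced_means(self):
        scores = pd.DataFrame(
            {
                "X4ci": [1.0, 0.8],
                "X5ci": [1.0, 0.6],
                "X6ci": [1.0, 0.4],
                "X7ci": [1.0, 0.2],
            },
            index=["D1", "D2"],
        )
        mt = mean_total(scores)
        assert mt["D1"] == 1.0
        assert mt["D2"] == pytest.approx(0.5)

    def test_mean_total_missing_group_named(self):
        scores = pd.DataFrame({"X4ci": [1.0, 0.5]}, index=["D1", "D2"])
        with pytest.raises(TopsisError, match="X5ci"):
            mean_total(scores)
        full = pd.DataFrame(
            {f"X{g}ci": [1.0, np.nan] for g in (4, 5, 6, 7)}, index=["D1", "D2"]
        )
        with pytest.raises(TopsisError, match="D2"):
            mean_total(full)

    def test_summary_matches_direct_recomputation(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        scores = pd.DataFrame(
            rng.uniform(size=(76, 4)),
            columns=[f"X{g}ci" for g in (4, 5, 6, 7)],
        )
        summary = summarize_scores(scores)
        for col in scores.columns:
            s = scores[col].to_numpy()
            assert summary.at[col, "mean"] == pytest.approx(s.mean())
            assert summary.at[col, "median"] == pytest.approx(np.median(s))
            assert summary.at[col, "sd"] == pytest.approx(s.std(ddof=1))
            assert summary.at[col, "min"] == s.min()
            assert summary.at[col, "max"] == s.max()
            assert summary.at[col, "skewness"] == pytest.approx(
                stats.skew(s, bias=False), abs=1e-10
            )
            assert summary.at[col, "kurtosis"] == pytest.approx(
                stats.kurtosis(s, bias=False), abs=1e-10
            )
        assert ((scores.ge(-1e-12)) & (scores.le(1 + 1e-12))).all().all()
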