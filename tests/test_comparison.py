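"""Contingency tables and chi-square tests against independent oracles."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from robdiv import (
    ScoreTable,
    StudyRecord,
    benjamini_hochberg,
    chi_square,
    compare_all,
    contingency,
)


def brute_force_pearson(obs: np.ndarray) -> float:
    """Independent Sum (O - E)^2 / E with explicit loops."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / n
            stat += (obs[i, j] - e) ** 2 / e
    return stat


class TestContingency:
    def test_toy_direct_count(self, mini_instrument):
        studies = [
            StudyRecord(f"a{i}", "m", "animal", "treatment") for i in range(4)
        ] + [StudyRecord(f"h{i}", "m", "human", "treatment") for i in range(4)]
        values = {"a0": "Y", "a1": "Y", "a2": "Y", "a3": "N",
                  "h0": "Y", "h1": "N", "h2": "N", "h3": "N"}
        rows = []
        for s in studies:
            rows.append({"study_id": s.study_id, "item_id": "A1",
                         "value": values[s.study_id]})
            rows.append({"study_id": s.study_id, "item_id": "A2", "value": "I"})
            rows.append({"study_id": s.study_id, "item_id": "S1", "value": "U"})
        table = ScoreTable(mini_instrument, studies, pd.DataFrame(rows))
        ct = contingency(table, "A1", "population")
        assert ct.table.to_numpy().tolist() == [[3, 1], [1, 3]]

    def test_irrelevant_excluded_and_empty_level_rejected(self, paper_table):
        # S4 is never scored for human studies: population split impossible
        with pytest.raises(ValueError, match="human"):
            contingency(paper_table, "S4", "population")
        # but the design split exists and I never enters the counts
        ct = contingency(paper_table, "S4", "design")
        assert ct.table.to_numpy().sum() == 78  # animal studies only

    def test_rob_item_gives_two_by_three(self, paper_table):
        ct = contingency(paper_table, "S2", "design")
        assert ct.table.shape == (2, 3)
        assert list(ct.table.columns) == ["L", "U", "H"]
        assert ct.table.to_numpy().sum() == 164


class TestChiSquare:
    def test_no_association(self):
        res = chi_square(np.array([[10, 10], [10, 10]]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_uncorrected_closed_form(self):
        # n(ad - bc)^2 / (r1 r2 c1 c2) = 60*300^2/30^4... = 20/3
        res = chi_square(np.array([[20, 10], [10, 20]]), correction="off")
        assert res.statistic == pytest.approx(20 / 3, abs=1e-10)
        assert res.df == 1

    def test_yates_closed_form(self):
        # n(|ad - bc| - n/2)^2 / (r1 r2 c1 c2) = 60*285^2/810000 = 5.4... no:
        # 60 * (300 - 30)^2 / 30^4 = 60*72900/810000 = 5.4
        res = chi_square(np.array([[20, 10], [10, 20]]), correction="on")
        assert res.statistic == pytest.approx(5.4, abs=1e-10)
        assert res.correction_applied

    def test_auto_corrects_only_2x2(self):
        assert chi_square(np.array([[20, 10], [10, 20]])).correction_applied
        assert not chi_square(
            np.array([[20, 10, 5], [10, 20, 5]])
        ).correction_applied

    def test_correction_shift_clamped(self):
        """|O - E| < 0.5 must clamp to a zero statistic, not overshoot."""
        obs = np.array([[10, 10], [10, 11]])
        res = chi_square(obs, correction="on")
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        shift = min(0.5, np.abs(obs - exp).min())
        manual = (((np.abs(obs - exp) - shift) ** 2) / exp).sum()
        assert res.statistic == pytest.approx(manual, abs=1e-12)
        assert res.statistic >= 0

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(11)
        shapes = [(2, 2), (2, 3), (3, 3), (2, 4)]
        for _ in range(1000):
            shape = shapes[rng.integers(len(shapes))]
            obs = rng.integers(1, 40, size=shape)
            res = chi_square(obs, correction="off")
            assert res.statistic == pytest.approx(
                brute_force_pearson(obs), abs=1e-10
            )

    def test_matches_scipy(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        for _ in range(50):
            obs = rng.integers(1, 30, size=(2, 3))
            mine = chi_square(obs, correction="off")
            ref = chi2_contingency(obs, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.df == ref.dof

    def test_matches_r_chisq_test(self):
        """Default behaviour replicates base R's chisq.test."""
        tables = {
            "2x2": [[20, 10], [10, 20]],
            "2x3": [[12, 30, 7], [5, 22, 16]],
        }
        script = (
            "a <- chisq.test(matrix(c(20,10,10,20), nrow=2, byrow=TRUE));"
            "b <- chisq.test(matrix(c(12,30,7,5,22,16), nrow=2, byrow=TRUE));"
            "cat(sprintf('%.10f %.10f %.10f %.10f', a$statistic, a$p.value,"
            " b$statistic, b$p.value))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        r_stat2, r_p2, r_stat3, r_p3 = map(float, out)
        mine2 = chi_square(np.array(tables["2x2"]))  # auto -> Yates
        mine3 = chi_square(np.array(tables["2x3"]))
        assert mine2.statistic == pytest.approx(r_stat2, abs=1e-8)
        assert mine2.p == pytest.approx(r_p2, abs=1e-8)
        assert mine3.statistic == pytest.approx(r_stat3, abs=1e-8)
        assert mine3.p == pytest.approx(r_p3, abs=1e-8)

    def test_permutation_invariance(self):
        obs = np.array([[12, 30, 7], [5, 22, 16]])
        base = chi_square(obs, correction="off")
        for perm in ([1, 0], [0, 1]):
            for cperm in ([2, 0, 1], [1, 2, 0]):
                res = chi_square(obs[perm][:, cperm], correction="off")
                assert res.statistic == pytest.approx(base.statistic, abs=1e-12)
                assert res.p == pytest.approx(base.p, abs=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="zero marginal"):
            chi_square(np.array([[0, 0], [3, 4]]))

    def test_small_expected_count_warning(self):
        res = chi_square(np.array([[2, 1], [1, 2]]), correction="off")
        assert res.warning and res.expected_min < 5


class TestTypeOneError:
    def test_null_calibration(self):
        """Uncorrected Pearson test holds its nominal 5% level under the null."""
        rng = np.random.default_rng(42)
        n1, n2, p = 100, 100, 0.5
        reps = 1000
        rejections = 0
        for _ in range(reps):
            y1 = rng.binomial(n1, p)
            y2 = rng.binomial(n2, p)
            obs = np.array([[y1, n1 - y1], [y2, n2 - y2]])
            if obs.sum(axis=0).min() == 0:
                continue
            if chi_square(obs, correction="off").p < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se


class TestCompareAll:
    def test_planted_effect_has_largest_statistic(self, strata_table):
        """C15 carries the planted animal/human split and dominates."""
        results = compare_all(strata_table, "population")
        tested = results[~results["skipped"]]
        rq = tested[tested["kind"] == "RQ"].set_index("item_id")
        assert rq["statistic"].idxmax() == "C15"
        assert rq.loc["C15", "p"] < 0.001

    def test_planted_design_effect(self, strata_table):
        results = compare_all(strata_table, "design")
        tested = results[~results["skipped"]].set_index("item_id")
        assert tested.loc["A16b", "p"] < 0.01  # adverse events split
        assert tested.loc["S5", "p"] < 0.001   # blinding split

    def test_skips_are_logged_not_fatal(self, paper_table):
        results = compare_all(paper_table, "population")
        skipped = results[results["skipped"]]
        assert "S4" in set(skipped["item_id"])
        assert (skipped["skip_reason"].str.len() > 0).all()

    def test_bh_adjustment_step_up(self):
        """Hand-worked 5-value Benjamini-Hochberg example."""
        p = [0.005, 0.009, 0.05, 0.5, 0.9]
        expected = [0.0225, 0.0225, 0.05 * 5 / 3, 0.625, 0.9]
        assert benjamini_hochberg(p) == pytest.approx(expected, abs=1e-12)

    def test_bh_column_present(self, paper_table):
        results = compare_all(paper_table, "design", adjust="BH")
        tested = results[~results["skipped"]]
        assert (tested["p_adjusted"] >= tested["p"] - 1e-12).all()
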