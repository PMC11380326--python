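"""Loading, harmonisation, validation and merging of score tables."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robdiv import (
    ScoreTable,
    StudyRecord,
    ValidationError,
    harmonise_tokens,
    load_scores,
    merge_projects,
)


class TestHarmonise:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (" Low ", "L"), ("YES", "Y"), ("yes", "Y"), ("Y", "Y"),
            ("not reported", "N"), ("No", "N"),
            ("Irrelevant", "I"), ("n/a", "I"), ("NA", "I"),
            ("UNCLEAR", "U"), ("high", "H"), ("  H ", "H"),
        ],
    )
    def test_synonyms(self, raw, expected):
        assert harmonise_tokens(raw) == expected

    def test_unmappable_token_carries_raw_string(self):
        with pytest.raises(ValueError, match="maybe"):
            harmonise_tokens("maybe")

    @given(
        st.sampled_from(
            ["y", "yes", "n", "no", "i", "irrelevant", "l", "low", "u",
             "unclear", "h", "high", "not reported", "n/a"]
        ),
        st.sampled_from([str.upper, str.lower, str.title]),
        st.text(alphabet=" \t", max_size=3),
    )
    @settings(deadline=None)
    def test_idempotent(self, token, case, pad):
        once = harmonise_tokens(pad + case(token) + pad)
        assert harmonise_tokens(once) == once


class TestLoadScores:
    def _write(self, tmp_path, scores_rows, studies_rows, delim=","):
        scores = tmp_path / "scores.csv"
        studies = tmp_path / "studies.csv"
        pd.DataFrame(scores_rows).to_csv(scores, index=False, sep=delim)
        pd.DataFrame(studies_rows).to_csv(studies, index=False, sep=delim)
        return scores, studies

    STUDIES = [
        {"study_id": "s1", "manuscript_id": "m1", "population": "animal",
         "design": "treatment", "year": 2001},
        {"study_id": "s2", "manuscript_id": "m1", "population": "human",
         "design": "treatment", "year": 2002},
    ]

    def _rows(self, values):
        rows = []
        for sid, trio in values.items():
            for iid, v in zip(("A1", "A2", "S1"), trio):
                rows.append({"study_id": sid, "item_id": iid, "value": v})
        return rows

    def test_toy_long_file(self, tmp_path, mini_instrument):
        scores, studies = self._write(
            tmp_path,
            self._rows({"s1": "YNL", "s2": "NYU"}),
            self.STUDIES,
        )
        table = load_scores(scores, studies, mini_instrument)
        assert table.n_assessments == 6
        assert table.n_studies == 2

    def test_semicolon_delimiter_autodetected(self, tmp_path, mini_instrument):
        scores, studies = self._write(
            tmp_path, self._rows({"s1": "YNL", "s2": "NYU"}), self.STUDIES,
            delim=";",
        )
        table = load_scores(scores, studies, mini_instrument)
        assert table.n_assessments == 6

    def test_rq_item_with_rob_value_rejected(self, tmp_path, mini_instrument):
        scores, studies = self._write(
            tmp_path, self._rows({"s1": "UNL", "s2": "NYU"}), self.STUDIES
        )
        with pytest.raises(ValidationError, match=r"\(s1, A1\)"):
            load_scores(scores, studies, mini_instrument)

    def test_missing_applicable_cell_is_an_error_not_I(
        self, tmp_path, mini_instrument
    ):
        rows = self._rows({"s1": "YNL", "s2": "NYU"})
        del rows[1]  # drop (s1, A2), an applicable cell
        scores, studies = self._write(tmp_path, rows, self.STUDIES)
        with pytest.raises(ValidationError, match="missing value .*s1, A2"):
            load_scores(scores, studies, mini_instrument)

    def test_unknown_item_listed(self, tmp_path, mini_instrument):
        rows = self._rows({"s1": "YNL", "s2": "NYU"})
        rows.append({"study_id": "s1", "item_id": "ZZ9", "value": "Y"})
        scores, studies = self._write(tmp_path, rows, self.STUDIES)
        with pytest.raises(ValidationError, match="ZZ9"):
            load_scores(scores, studies, mini_instrument)

    def test_conflicting_duplicates_rejected(self, tmp_path, mini_instrument):
        rows = self._rows({"s1": "YNL", "s2": "NYU"})
        rows.append({"study_id": "s1", "item_id": "A1", "value": "N"})
        scores, studies = self._write(tmp_path, rows, self.STUDIES)
        with pytest.raises(ValidationError, match="conflicting duplicate"):
            load_scores(scores, studies, mini_instrument)

    def test_wide_format_matches_long(self, tmp_path, mini_instrument):
        long_scores, studies = self._write(
            tmp_path, self._rows({"s1": "YNL", "s2": "NYU"}), self.STUDIES
        )
        wide = tmp_path / "wide.csv"
        pd.DataFrame(
            [
                {"study_id": "s1", "A1": "yes", "A2": "no", "S1": "Low"},
                {"study_id": "s2", "A1": "N", "A2": "Y", "S1": "unclear"},
            ]
        ).to_csv(wide, index=False)
        from_long = load_scores(long_scores, studies, mini_instrument)
        from_wide = load_scores(wide, studies, mini_instrument, wide=True)
        pd.testing.assert_frame_equal(from_long.assessments, from_wide.assessments)

    def test_wide_unmatched_column_reported(self, tmp_path, mini_instrument):
        wide = tmp_path / "wide.csv"
        pd.DataFrame(
            [{"study_id": "s1", "A1": "Y", "A2": "N", "S1": "L", "B9": "Y"}]
        ).to_csv(wide, index=False)
        _, studies = self._write(tmp_path, [], self.STUDIES[:1])
        with pytest.raises(ValidationError, match="B9"):
            load_scores(wide, studies, mini_instrument, wide=True)


class TestNormalisation:
    def test_inapplicable_cells_materialised_as_I(self, mini_instrument):
        # a baseline study never sees fewer rows than items
        studies = [StudyRecord("b1", "m", "animal", "baseline")]
        rows = pd.DataFrame(
            [
                {"study_id": "b1", "item_id": "A1", "value": "Y"},
                {"study_id": "b1", "item_id": "A2", "value": "N"},
                {"study_id": "b1", "item_id": "S1", "value": "U"},
            ]
        )
        table = ScoreTable(mini_instrument, studies, rows)
        assert table.n_assessments == 3

    def test_normalisation_idempotent(self, toy_table):
        again = ScoreTable(
            toy_table.instrument, toy_table.studies, toy_table.assessments
        )
        pd.testing.assert_frame_equal(again.assessments, toy_table.assessments)

    def test_round_trip(self, toy_table, tmp_path):
        sp, tp = tmp_path / "s.csv", tmp_path / "t.csv"
        toy_table.write(sp, tp)
        again = load_scores(sp, tp, toy_table.instrument)
        pd.testing.assert_frame_equal(again.assessments, toy_table.assessments)

    def test_dense_accounting(self, paper_table):
        """48 items x 164 studies, every cell exactly once."""
        assert paper_table.n_assessments == 48 * 164 == 7872
        counts = paper_table.assessments.groupby(["study_id", "item_id"]).size()
        assert (counts == 1).all()


class TestMerge:
    def test_merge_partitions(self, paper_table):
        baseline_ids = [s.study_id for s in paper_table.studies
                        if s.design == "baseline"]
        treatment_ids = [s.study_id for s in paper_table.studies
                         if s.design == "treatment"]
        a = paper_table.subset(baseline_ids)
        b = paper_table.subset(treatment_ids)
        assert (a.n_studies, b.n_studies) == (130, 34)
        merged = merge_projects(a, b)
        assert merged.n_studies == 164
        assert merged.n_assessments == paper_table.n_assessments

    def test_merge_with_empty_is_identity(self, toy_table, mini_instrument):
        empty = ScoreTable(mini_instrument, [], pd.DataFrame(
            columns=["study_id", "item_id", "value"]))
        merged = merge_projects(toy_table, empty)
        assert merged.n_studies == toy_table.n_studies
        pd.testing.assert_frame_equal(merged.assessments, toy_table.assessments)

    def test_shared_study_id_rejected(self, toy_table):
        with pytest.raises(ValueError, match="shared study_id"):
            merge_projects(toy_table, toy_table)

    def test_instrument_mismatch_rejected(self, toy_table, paper_table):
        with pytest.raises(ValueError, match="instruments differ"):
            merge_projects(toy_table, paper_table)
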