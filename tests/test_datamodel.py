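"""Cohort I/O, validation, BMI classification and covariate assembly."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cyclessm as c
from cyclessm.datamodel import (
    BMI_CATEGORIES,
    CohortValidationError,
    ConfigurationError,
    SchemaError,
)

CSV_ONE_WOMAN = """woman_id,cycle_index,length_days,age_years
a,1,27,30.0
a,2,28,30.08
a,3,26,30.15
"""


def test_read_simple_cohort():
    coh = c.read_cohort(io.StringIO(CSV_ONE_WOMAN))
    assert coh.I == 1
    s = coh.woman("a")
    assert s.n_cycles == 3
    assert list(s.lengths) == [27.0, 28.0, 26.0]


def test_plausibility_window():
    csv = CSV_ONE_WOMAN + "a,4,60,30.23\n"
    coh = c.read_cohort(io.StringIO(csv))  # default: drop
    assert coh.woman("a").n_cycles == 3
    coh_keep = c.read_cohort(io.StringIO(csv), on_implausible="keep")
    assert coh_keep.woman("a").n_cycles == 4
    with pytest.raises(CohortValidationError):
        c.read_cohort(io.StringIO(csv), on_implausible="error")
    # a wider configured window keeps the row
    coh_wide = c.read_cohort(io.StringIO(csv), plausibility_window=(10, 90))
    assert coh_wide.woman("a").n_cycles == 4


def test_interleaved_rows_sorted():
    csv = ("woman_id,cycle_index,length_days,age_years\n"
           "b,2,29,25.1\na,1,27,30.0\nb,1,31,25.0\na,2,28,30.08\n")
    coh = c.read_cohort(io.StringIO(csv))
    assert list(coh.woman("a").lengths) == [27.0, 28.0]
    assert list(coh.woman("b").lengths) == [31.0, 29.0]
    assert [r.cycle_index for r in coh.woman("b").records] == [1, 2]


def test_schema_and_parse_errors():
    with pytest.raises(SchemaError):
        c.read_cohort(io.StringIO("woman_id,length_days\na,27\n"))
    bad = "woman_id,cycle_index,length_days,age_years\na,1,27.5,30.0\n"
    with pytest.raises(CohortValidationError, match="row"):
        c.read_cohort(io.StringIO(bad))


def test_missing_covariate_cells_imputed_zero():
    csv = ("woman_id,cycle_index,length_days,age_years,cramps\n"
           "a,1,27,30.0,2\na,2,28,30.08,\n")
    coh = c.read_cohort(io.StringIO(csv))
    assert coh.woman("a").records[1].counts == (0,)


def test_roundtrip_identity(small_sim):
    cohort, _ = small_sim
    buf = io.StringIO()
    c.write_cohort(cohort, buf)
    buf.seek(0)
    back = c.read_cohort(buf, on_implausible="keep")
    assert cohort.to_frame().equals(back.to_frame())


class TestFirstSequenceFilter:
    def test_truncates_at_break(self, small_sim):
        cohort, _ = small_sim
        wid = cohort.series[0].woman_id
        out = c.first_sequence_filter(cohort, breaks={(wid, 4)})
        assert out.woman(wid).n_cycles == 3
        assert [r.cycle_index for r in out.woman(wid).records] == [1, 2, 3]

    def test_no_breaks_is_identity(self, small_sim):
        cohort, _ = small_sim
        assert c.first_sequence_filter(cohort) is cohort

    def test_break_at_first_cycle_keeps_single_record(self, small_sim):
        cohort, _ = small_sim
        wid = cohort.series[0].woman_id
        out = c.first_sequence_filter(cohort, breaks={(wid, 1)})
        assert out.woman(wid).n_cycles == 1


class TestBmi:
    @pytest.mark.parametrize("bmi,label", [
        (14.44, "Underweight II"),
        (22.85, "Normal"),
        (25.0, "Normal"),
        (25.0001, "Overweight"),
        (15.0, "Underweight II"),
        (54.25, "Obese Class III"),
    ])
    def test_examples(self, bmi, label):
        assert c.classify_bmi(bmi).label == label

    @pytest.mark.parametrize("bad", [0.0, -3.0, float("nan")])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            c.classify_bmi(bad)

    @given(st.floats(min_value=0.001, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_categories_tile_the_line(self, bmi):
        hits = [cat for cat in BMI_CATEGORIES if cat.contains(bmi)]
        assert len(hits) == 1
        assert c.classify_bmi(bmi) == hits[0]


class TestCovariateMatrix:
    def _series(self):
        recs = [
            c.CycleRecord("a", 1, 27, 30.0, (1, 0, 10)),
            c.CycleRecord("a", 2, 28, 30.08, (0, 2, 0)),
        ]
        return c.CycleSeries("a", recs), ["inj", "cramps", "tender"]

    def test_counts_enter_linear_predictor(self):
        s, names = self._series()
        M = c.covariate_matrix(s, ["tender"], names)
        assert M[0, 0] == 10  # a symptom reported 10 times contributes 10*alpha
        assert (-0.1540) * M[0, 0] == pytest.approx(-1.54)

    def test_empty_selection(self):
        s, names = self._series()
        M = c.covariate_matrix(s, [], names)
        assert M.shape == (2, 0)

    def test_direct_assembly_and_permutations(self):
        s, names = self._series()
        M = c.covariate_matrix(s, ["inj", "cramps"], names)
        assert M.tolist() == [[1, 0], [0, 2]]
        M2 = c.covariate_matrix(s, ["cramps", "inj"], names)
        assert np.array_equal(M2, M[:, ::-1])

    def test_unknown_name_errors(self):
        s, names = self._series()
        with pytest.raises(ConfigurationError):
            c.covariate_matrix(s, ["nope"], names)
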