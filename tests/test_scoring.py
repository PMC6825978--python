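"""DASI scoring: per-factor cutoffs, the score arithmetic, risk bands, and
their monotonicity/partition invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from dasikit.errors import SchemaError, ValidationError
from dasikit.scoring import (
    categorize_dasi,
    dasi_score,
    default_registry,
    score_deficits,
    score_patient,
)

REG = default_registry()
BY_NAME = {f.name: f for f in REG}


# (factor, value, expected deficit) — each threshold exercised at, just below
# and just above its boundary under the literal cutoff convention (strict
# inequalities everywhere except corrected calcium's inclusive >= 11).
BOUNDARY_CASES = [
    ("readmission", True, 1), ("readmission", False, 0), ("readmission", None, None),
    ("marital_support", "married", 0), ("marital_support", "single", 1),
    ("marital_support", "divorced", 1), ("marital_support", "widowed", 1),
    ("language", "english", 0), ("language", "not_english", 1),
    ("fall_risk", "high", 1), ("fall_risk", "moderate", 0),
    ("fall_risk", "low", 0), ("fall_risk", "universal", 0),
    ("healthcare_visits", 2, 0), ("healthcare_visits", 1, 0), ("healthcare_visits", 3, 1),
    ("bmi", 19.0, 0), ("bmi", 18.9, 1), ("bmi", 19.1, 0),
    ("corrected_calcium", 11.0, 1), ("corrected_calcium", 10.9, 0), ("corrected_calcium", 11.1, 1),
    ("creatinine", 1.3, 0), ("creatinine", 1.2, 0), ("creatinine", 1.4, 1),
    ("ecog", 0, 0), ("ecog", 1, 0), ("ecog", 2, 1), ("ecog", 3, 1), ("ecog", 4, 1),
    ("nlr", 5.0, 0), ("nlr", 4.9, 0), ("nlr", 5.1, 1),
    ("neutrophils", 1.8, 0), ("neutrophils", 1.7, 1), ("neutrophils", 1.9, 0),
    ("plr", 250.0, 0), ("plr", 249.0, 0), ("plr", 251.0, 1),
    ("platelets", 150.0, 0), ("platelets", 149.0, 1), ("platelets", 151.0, 0),
    ("platelets", 450.0, 0), ("platelets", 451.0, 1), ("platelets", 300.0, 0),
    ("hemoglobin", 12.0, 0), ("hemoglobin", 11.9, 1), ("hemoglobin", 12.1, 0),
    ("length_of_stay", 5.0, 0), ("length_of_stay", 4.0, 0), ("length_of_stay", 6.0, 1),
    ("lymphocytes", 1.1, 0), ("lymphocytes", 1.0, 1), ("lymphocytes", 1.2, 0),
    ("sii", 1600.0, 0), ("sii", 1599.0, 0), ("sii", 1601.0, 1),
    ("albumin", 3.5, 0), ("albumin", 3.4, 1), ("albumin", 3.6, 0),
    ("sodium", 135.0, 0), ("sodium", 134.0, 1), ("sodium", 136.0, 0),
    ("wbc", 11.0, 0), ("wbc", 10.9, 0), ("wbc", 11.1, 1),
    ("medications", 5, 0), ("medications", 4, 0), ("medications", 6, 1),
    ("pni", 45.0, 0), ("pni", 44.9, 1), ("pni", 45.1, 0),
    ("metastasis", True, 1), ("metastasis", False, 0), ("metastasis", None, None),
]


@pytest.mark.parametrize("factor,value,expected", BOUNDARY_CASES)
def test_factor_cutoff_boundaries(factor, value, expected):
    assert BY_NAME[factor].evaluate(value) == expected


def test_registry_has_23_unique_factors():
    assert len(REG) == 23
    assert len(set(REG.names)) == 23


def test_benign_record_scores_zero(benign_record):
    res = score_patient(benign_record)
    assert all(v == 0 for v in res.deficits.values())
    assert res.n_evaluable == 23
    assert res.score == 0.0
    assert res.category == "low"


def test_frail_record_scores_one(frail_record):
    res = score_patient(frail_record)
    assert all(v == 1 for v in res.deficits.values()), res.deficits
    assert res.score == 1.0
    assert res.category == "high"


def test_missing_inputs_yield_missing_deficits(record_factory):
    rec = record_factory(sodium=None, lymphocytes=None, ecog_ps=None, metastasis=None)
    deficits = score_deficits(rec)
    # lymphocytes feed four derived indices plus their own factor
    for name in ("sodium", "lymphocytes", "nlr", "plr", "sii", "pni", "ecog", "metastasis"):
        assert deficits[name] is None
    assert deficits["hemoglobin"] == 0


class TestScoreArithmetic:
    def _vector(self, ones=0, missing=0):
        names = REG.names
        vec = {}
        for i, n in enumerate(names):
            if i < ones:
                vec[n] = 1
            elif i >= len(names) - missing:
                vec[n] = None
            else:
                vec[n] = 0
        return vec

    def test_extremes(self):
        assert dasi_score(self._vector(ones=0)) == 0.0
        assert dasi_score(self._vector(ones=23)) == 1.0

    def test_fixed_denominator(self):
        assert dasi_score(self._vector(ones=2)) == pytest.approx(2 / 23)
        # 3 missing factors: the literal rule still divides by 23
        assert dasi_score(self._vector(ones=2, missing=3)) == pytest.approx(2 / 23)

    def test_evaluable_denominator(self):
        vec = self._vector(ones=2, missing=3)  # 20 evaluable
        assert dasi_score(vec, denominator_policy="evaluable") == pytest.approx(0.10)

    def test_completeness_floor(self):
        vec = self._vector(ones=2, missing=6)  # 17 evaluable < default floor 18
        assert dasi_score(vec) is None
        assert dasi_score(vec, completeness_floor=17) is not None

    def test_unknown_factor_rejected(self):
        vec = self._vector()
        vec["bogus"] = 1
        with pytest.raises(SchemaError):
            dasi_score(vec)
        del vec["bogus"]
        del vec["sodium"]
        with pytest.raises(SchemaError):
            dasi_score(vec)

    def test_missing_never_inflates_score(self):
        # fixed-23 policy: a missing factor can only lower the score relative
        # to assuming the deficit present
        vec = self._vector(ones=5, missing=4)
        imputed = {k: (1 if v is None else v) for k, v in vec.items()}
        assert dasi_score(vec) <= dasi_score(imputed)


class TestCategorization:
    @pytest.mark.parametrize("score,cat", [
        (0.10, "low"), (0.40, "moderate"), (0.49, "high"),
        (0.30, "low"), (0.48, "moderate"), (0.0, "low"), (1.0, "high"),
        (0.3000001, "moderate"), (0.4800001, "high"),
    ])
    def test_band_boundaries(self, score, cat):
        assert categorize_dasi(score) == cat

    @pytest.mark.parametrize("bad", [-0.01, 1.01, 2.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            categorize_dasi(bad)

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_total_contiguous_partition(self, score):
        assert categorize_dasi(score) in ("low", "moderate", "high")


_CAT_ORDER = {"low": 0, "moderate": 1, "high": 2}


@settings(derandomize=True, max_examples=200)
@given(
    bits=st.lists(st.sampled_from([0, 1, None]), min_size=23, max_size=23),
    flip=st.integers(min_value=0, max_value=22),
)
def test_flipping_a_deficit_never_lowers_score_or_category(bits, flip):
    names = REG.names
    vec = dict(zip(names, bits))
    vec[names[flip]] = 0
    up = dict(vec)
    up[names[flip]] = 1
    s0 = dasi_score(vec, completeness_floor=0)
    s1 = dasi_score(up, completeness_floor=0)
    assert 0.0 <= s0 <= 1.0 and 0.0 <= s1 <= 1.0
    assert s1 >= s0
    assert _CAT_ORDER[categorize_dasi(s1)] >= _CAT_ORDER[categorize_dasi(s0)]
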