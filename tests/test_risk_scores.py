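"""Risk scores: elective filter, MCRS, Wu score, category cutpoints and the
ordinal cutpoint search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcilos import registry, risk_scores
from pcilos.schema import SchemaError
from tests.conftest import make_cohort, make_record


class TestElectiveFilter:
    def test_shock_and_unstable_excluded(self):
        cohort = make_cohort(
            [
                make_record(hemodynamic_state="shock"),
                make_record(hemodynamic_state="unstable"),
                make_record(),
            ]
        )
        kept = risk_scores.elective_filter(cohort)
        assert len(kept) == 1
        assert (kept["hemodynamic_state"] == "stable").all()

    def test_recent_but_not_acute_mi_retained(self):
        cohort = make_cohort(
            [make_record(mi_timing="d1_14"), make_record(mi_timing="lt6h_no_st")]
        )
        kept, counts = risk_scores.elective_filter(cohort, return_counts=True)
        assert list(kept["mi_timing"]) == ["d1_14"]
        assert counts["mi_within_24h"] == 1

    def test_identity_on_stable_cohort_and_idempotent(self, small_cohort):
        once = risk_scores.elective_filter(small_cohort)
        assert len(once) == len(small_cohort)  # default generator is all-elective
        twice = risk_scores.elective_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_order_preserved(self):
        cohort = make_cohort(
            [make_record(age=a) for a in (40, 70, 50)]
            + [make_record(urgent_emergent=1)]
            + [make_record(age=60)]
        )
        kept = risk_scores.elective_filter(cohort)
        assert list(kept["age"]) == [40, 70, 50, 60]

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            risk_scores.elective_filter(pd.DataFrame({"age": [50]}))


class TestMCRS:
    def test_reference_record_scores_zero(self):
        ra = risk_scores.mcrs_score(make_record(age=30))
        assert ra.score == 0 and ra.category == "very_low"

    def test_hand_summed_example(self):
        # age 75 (4 decades past 30) + left main 5 + multivessel 2 + NYHA 2
        ra = risk_scores.mcrs_score(
            make_record(age=75, left_main_disease=1, multivessel_disease=1, nyha_class_3_4=1)
        )
        assert ra.score == 13
        assert ra.category == "high"
        assert ra.components["age"] == 4

    def test_elective_mode_drops_shock_and_urgent(self):
        rec = make_record(hemodynamic_state="shock", urgent_emergent=1)
        full = risk_scores.mcrs_score(rec)
        elec = risk_scores.mcrs_score(rec, elective_mode=True)
        assert full.score - elec.score == 7
        assert elec.components["shock"] == 0 and elec.components["urgent_emergent"] == 0

    def test_renal_criterion_counted_once(self):
        ra = risk_scores.mcrs_score(make_record(creatinine_gt_2_5=1, dialysis=1))
        assert ra.components["renal_failure"] == 3

    @pytest.mark.parametrize(
        "score,cat",
        [(0, "very_low"), (5, "very_low"), (6, "low"), (8, "low"), (9, "moderate"),
         (11, "moderate"), (12, "high"), (14, "high"), (15, "very_high"), (40, "very_high")],
    )
    def test_category_bounds(self, score, cat):
        assert risk_scores.mcrs_category(score) == cat

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            risk_scores.mcrs_category(-1)

    def test_frame_matches_per_record(self, small_cohort):
        sub = small_cohort.head(500)
        frame = risk_scores.mcrs_score_frame(sub, elective_mode=True)
        rec = [
            risk_scores.mcrs_score(r._asdict() if hasattr(r, "_asdict") else r, True).score
            for r in sub.to_dict(orient="records")
        ]
        assert list(frame) == rec


class TestWuScore:
    def test_reference_record_scores_zero(self):
        assert risk_scores.wu_score(make_record(age=40)).score == 0

    def test_maximum_is_forty(self):
        rec = make_record(
            age=80, sex="female", hemodynamic_state="shock", ejection_fraction=15.0,
            mi_timing="lt24h_stent_thrombosis", peripheral_arterial_disease=1,
            heart_failure="current", dialysis=1, left_main_disease=1,
        )
        assert risk_scores.wu_score(rec).score == 40

    def test_enumeration_bounds(self):
        totals = risk_scores.wu_enumerate()
        assert totals.min() == 0
        assert totals.max() == 40

    def test_elective_maximum_is_26(self):
        # brute force over level combinations admissible after the elective
        # filter (stable hemodynamics, no MI within 24 h)
        import itertools

        groups = [
            [0, 1, 3, 5], [0, 1], [0], [0, 2, 3], [0, 4, 2], [0, 2],
            [0, 3, 4], [0, 3, 4], [0, 3],
        ]
        best = max(sum(c) for c in itertools.product(*groups))
        assert best == 26

    @pytest.mark.parametrize(
        "overrides,expected",
        [
            (dict(dialysis=1), 4),
            (dict(creatinine_gt_2_5=1), 3),
            (dict(left_main_disease=1), 3),
            (dict(heart_failure="current"), 4),
            (dict(heart_failure="past"), 3),
            (dict(ejection_fraction=25.0), 2),
            (dict(ejection_fraction=15.0), 3),
            (dict(ejection_fraction=np.nan), 0),
            (dict(age=56), 1),
            (dict(age=65), 3),
            (dict(age=75), 5),
            (dict(mi_timing="gt14d"), 2),
            (dict(mi_timing="d1_14"), 4),
        ],
    )
    def test_single_factor_points(self, overrides, expected):
        rec = make_record(**{"age": 40, **overrides})
        assert risk_scores.wu_score(rec).score == expected

    def test_dialysis_takes_precedence_over_creatinine(self):
        ra = risk_scores.wu_score(make_record(age=40, dialysis=1, creatinine_gt_2_5=1))
        assert ra.components["renal_failure"] == 4

    @pytest.mark.parametrize("score,cat", [(0, "very_low"), (5, "very_low"), (6, "low"),
                                           (10, "low"), (11, "moderate"), (12, "moderate"),
                                           (13, "high"), (15, "high"), (16, "very_high")])
    def test_category_bounds(self, score, cat):
        assert risk_scores.wu_category(score) == cat

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            risk_scores.wu_category(41)

    def test_unknown_token_rejected(self):
        with pytest.raises(SchemaError):
            risk_scores.wu_score(make_record(heart_failure="chf"))

    def test_frame_matches_per_record(self, small_cohort):
        sub = small_cohort.head(500)
        frame = risk_scores.wu_score_frame(sub)
        rec = [risk_scores.wu_score(r).score for r in sub.to_dict(orient="records")]
        assert list(frame) == rec


@given(
    age=st.floats(18, 100),
    sex=st.sampled_from(["male", "female"]),
    hf=st.sampled_from(["none", "past", "current"]),
    mi=st.sampled_from(["none", "d1_14", "gt14d"]),
    flags=st.tuples(*[st.booleans()] * 6),
)
@settings(max_examples=200, derandomize=True)
def test_score_invariants(age, sex, hf, mi, flags):
    """Scores are non-negative integers; Wu in [0, 40]; score equals the
    component sum; categories are monotone in the score."""
    nyha, creat, dial, pad, lm, mv = flags
    rec = make_record(
        age=age, sex=sex, heart_failure=hf, mi_timing=mi, nyha_class_3_4=int(nyha),
        creatinine_gt_2_5=int(creat), dialysis=int(dial),
        peripheral_arterial_disease=int(pad), left_main_disease=int(lm),
        multivessel_disease=int(mv),
    )
    for scorer in (risk_scores.mcrs_score, risk_scores.wu_score):
        ra = scorer(rec)
        assert ra.score >= 0
        assert ra.score == sum(ra.components.values())
    assert 0 <= risk_scores.wu_score(rec).score <= 40


def test_categories_monotone_in_score():
    order = {c: i for i, c in enumerate(("very_low", "low", "moderate", "high", "very_high"))}
    mcrs = [order[risk_scores.mcrs_category(s)] for s in range(0, 30)]
    wu = [order[risk_scores.wu_category(s)] for s in range(0, 41)]
    assert mcrs == sorted(mcrs)
    assert wu == sorted(wu)


class TestCutpointSearch:
    def _planted(self, uppers=(3, 8, 12, 16), n_per=400, seed=0):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 20, size=n_per * 20)
        cuts = risk_scores.CutpointSet(uppers)
        codes = pd.Categorical(cuts.assign(scores)).codes
        mus = np.array([1.5, 2.5, 4.0, 6.5, 10.0])
        los = registry.draw_ztnb(mus[codes], 0.3, rng)
        return scores, los

    def test_recovers_planted_plateaus(self):
        scores, los = self._planted()
        for objective in ("ztnb", "logvar"):
            found = risk_scores.cutpoint_search(scores, los, objective=objective)
            assert found.uppers == (3, 8, 12, 16), objective

    def test_all_equal_scores_infeasible(self):
        with pytest.raises(risk_scores.SearchInfeasibleError):
            risk_scores.cutpoint_search(np.full(100, 7), np.ones(100, dtype=int) + 2)

    def test_min_fraction_infeasible(self):
        scores = np.repeat([0, 1, 2, 3, 4], [96, 1, 1, 1, 1])
        los = np.ones(100, dtype=int) * 3
        with pytest.raises(risk_scores.SearchInfeasibleError):
            risk_scores.cutpoint_search(scores, los, min_fraction=0.05)

    def test_returned_set_at_least_as_good_as_any_fixed_set(self):
        scores, los = self._planted(seed=5)
        found = risk_scores.cutpoint_search(scores, los, objective="logvar")
        obj_found = risk_scores.cutpoint_objective(scores, los, found, objective="logvar")
        obj_pub = risk_scores.cutpoint_objective(
            scores, los, risk_scores.CutpointSet((4, 9, 13, 17)), objective="logvar"
        )
        assert obj_found >= obj_pub - 1e-9
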