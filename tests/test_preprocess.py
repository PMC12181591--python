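import numpy as np
import pandas as pd
import pytest

from cogconnectome import (
    CognitiveDataset,
    GROUPS,
    eligibility_filter,
    invert_scores,
    module_composites,
    stratify,
    zscore_cohort,
)
from cogconnectome.preprocess import EligibilityError
from cogconnectome.roster import DEFAULT as ROSTER


def _cohort_with_demographics(rows: list[dict]) -> CognitiveDataset:
    """Tiny cohort with given demographic rows and random scores."""
    rng = np.random.default_rng(0)
    base = {
        "age": 45, "sex": "F", "education_level": 2, "mmse": 29,
        "bdrs_personality": 0.0, "bdrs_everyday": 0.0, "bdrs_habits": 0.0,
        "faq": 0, "wais_info": 18,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(base)
        rec.update(row)
        rec["participant_id"] = rec.get("participant_id", f"P{i:03d}")
        records.append(rec)
    df = pd.DataFrame(records)
    scores = rng.standard_normal((len(df), 47))
    return CognitiveDataset(
        pd.concat([df, pd.DataFrame(scores, columns=ROSTER.names)], axis=1)
    )


class TestEligibility:
    @pytest.mark.parametrize(
        "row, included, reason",
        [
            # BDRS total 4.0 but 75% from the personality subscale -> kept
            ({"mmse": 29, "faq": 0, "bdrs_personality": 3.0,
              "bdrs_everyday": 0.5, "bdrs_habits": 0.5}, True, None),
            ({"mmse": 23, "faq": 0}, False, "MMSE"),
            # fraction 0.5 < 0.70 and everyday 2.0 > 1.5 -> excluded
            ({"mmse": 29, "faq": 0, "bdrs_personality": 2.0,
              "bdrs_everyday": 2.0, "bdrs_habits": 0.0}, False, "BDRS"),
            ({"faq": 6}, False, "FAQ"),
            ({"mmse": 24, "faq": 5, "bdrs_personality": 1.5,
              "bdrs_everyday": 1.0, "bdrs_habits": 1.0}, True, None),
            # first failing criterion wins: MMSE checked before FAQ
            ({"mmse": 20, "faq": 10}, False, "MMSE"),
        ],
    )
    def test_screening_rules(self, row, included, reason):
        ds = _cohort_with_demographics([row])
        kept, excluded = eligibility_filter(ds)
        if included:
            assert len(kept) == 1 and not excluded
        else:
            assert len(kept) == 0
            assert excluded[0][1] == reason

    def test_missing_demographic_field_lists_ids(self):
        ds = _cohort_with_demographics([{}, {"mmse": np.nan}])
        with pytest.raises(EligibilityError, match="P001"):
            eligibility_filter(ds)

    def test_optional_boolean_screens_are_anded(self):
        ds = _cohort_with_demographics([{}, {}])
        ds.data["mci_free"] = [True, False]
        kept, excluded = eligibility_filter(ds)
        assert len(kept) == 1
        assert excluded == [("P001", "mci_free")]


class TestZScoring:
    def test_cohort_mean_zero_sd_one(self, null_cohort):
        z = zscore_cohort(null_cohort)
        m = z.score_matrix
        np.testing.assert_allclose(m.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(m.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_population_sd_convention_on_toy_column(self):
        ds = _cohort_with_demographics([{}, {}, {}])
        ds.data[ROSTER.names[0]] = [1.0, 2.0, 3.0]
        z = zscore_cohort(ds, ddof=0)
        np.testing.assert_allclose(
            z.scores[ROSTER.names[0]], [-1.224744871, 0.0, 1.224744871],
            atol=1e-8,
        )
        # sample-sd convention scales by sqrt(2/3)
        z1 = zscore_cohort(ds, ddof=1)
        np.testing.assert_allclose(z1.scores[ROSTER.names[0]], [-1.0, 0.0, 1.0])

    def test_rescoring_standardized_data_is_identity(self, null_cohort):
        z = zscore_cohort(null_cohort)
        z2 = zscore_cohort(z)
        np.testing.assert_allclose(z.score_matrix, z2.score_matrix, atol=1e-12)

    def test_zero_variance_variable_is_named(self):
        ds = _cohort_with_demographics([{}, {}])
        ds.data[ROSTER.names[3]] = 7.0
        with pytest.raises(ValueError, match=ROSTER.names[3]):
            zscore_cohort(ds)


class TestInversion:
    def test_processing_speed_flipped_verbal_memory_not(self, null_cohort):
        z = zscore_cohort(null_cohort)
        inv = invert_scores(z)
        np.testing.assert_allclose(
            inv.scores["ctt_part_a"], -z.scores["ctt_part_a"]
        )
        np.testing.assert_allclose(
            inv.scores["lm_a_immediate"], z.scores["lm_a_immediate"]
        )

    def test_involution(self, null_cohort):
        z = zscore_cohort(null_cohort)
        twice = invert_scores(invert_scores(z))
        np.testing.assert_allclose(twice.score_matrix, z.score_matrix)
        assert twice.inverted == z.inverted


class TestComposites:
    def test_module_means(self, null_cohort):
        z = invert_scores(zscore_cohort(null_cohort))
        comp = module_composites(z)
        pm = ROSTER.module_members("PM")
        np.testing.assert_allclose(comp["PM"], z.scores[pm].mean(axis=1))

    def test_constant_scores_give_constant_composites(self):
        ds = _cohort_with_demographics([{}, {}, {}])
        ds.data[ROSTER.names] = 0.7
        ds.z_units = True
        ds.inverted = True
        comp = module_composites(ds)
        for module in ("VM", "VMV", "EPF", "PM", "PS"):
            np.testing.assert_allclose(comp[module], 0.7)

    def test_shift_one_variable_shifts_composite_proportionally(self, null_cohort):
        z = invert_scores(zscore_cohort(null_cohort))
        comp = module_composites(z)
        shifted = z.scores.copy()
        name = ROSTER.module_members("EPF")[0]
        shifted[name] = shifted[name] + 0.6
        comp2 = module_composites(z.with_scores(shifted))
        delta = comp2["EPF"] - comp["EPF"]
        np.testing.assert_allclose(delta, 0.6 / len(ROSTER.module_members("EPF")))
        np.testing.assert_allclose(comp2["VM"], comp["VM"])


class TestStratification:
    def test_printed_rule_examples(self):
        ds = _cohort_with_demographics([
            {"age": 50, "wais_info": 16},
            {"age": 51, "wais_info": 15},
            {"age": 65, "wais_info": 20},
        ])
        strat = stratify(ds, threshold=15)
        assert strat.assignments["P000"] == ("EMA", "high")
        assert strat.assignments["P001"] == ("LMA", "low")
        assert strat.assignments["P002"] == ("ELD", "high")

    def test_median_threshold_default(self):
        ds = _cohort_with_demographics([
            {"wais_info": 10}, {"wais_info": 15}, {"wais_info": 20},
        ])
        strat = stratify(ds)
        assert strat.split_threshold == 15
        groups = [strat.assignments[f"P{i:03d}"][1] for i in range(3)]
        assert groups == ["low", "low", "high"]

    def test_age_outside_range_lists_ids(self):
        ds = _cohort_with_demographics([{"age": 36}, {"age": 45}])
        with pytest.raises(ValueError, match="P000"):
            stratify(ds)

    def test_partition_is_disjoint_and_complete(self, null_preprocessed):
        z, strat, _ = null_preprocessed
        assert set(strat.assignments) == set(z.ids)
        assert sum(strat.counts().values()) == len(z)
        assert set(strat.counts()) == set(GROUPS)

    def test_non_integer_ages_floored(self):
        ds = _cohort_with_demographics([{"age": 50.9}])
        strat = stratify(ds)
        assert strat.assignments["P000"][0] == "EMA"
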