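import numpy as np
import pandas as pd
import pytest

from msfrail import (
    build_transition_datasets,
    cohort_accounting,
    default_scenario,
    filter_providers,
    next_admissions,
    percentage,
    simulate_cohort,
    truncate_admissions,
    validate_episodes,
)
from msfrail.episodes import EpisodeValidationError

from conftest import flat_scenario, toy_episode_table


class TestValidation:
    def test_well_formed_table_returned_unchanged(self, toy_episodes):
        out, diags = validate_episodes(toy_episodes)
        assert diags == {}
        pd.testing.assert_frame_equal(out, toy_episodes)

    def test_discharge_before_admission_rejected(self, toy_episodes):
        bad = toy_episodes.copy()
        bad.loc[1, "discharge_day"] = -1.0
        with pytest.raises(EpisodeValidationError) as err:
            validate_episodes(bad)
        assert err.value.rule == "discharge-after-admission"
        assert 2 in err.value.patient_ids

    def test_multi_provider_patient_rejected(self, toy_episodes):
        bad = pd.concat(
            [toy_episodes, toy_episodes.assign(admission_index=2, admission_day=20.0,
                                               discharge_day=[np.nan, 30.0])],
            ignore_index=True,
        )
        bad = bad[bad["patient_id"] == 2].reset_index(drop=True)
        bad.loc[1, "provider_id"] = "B"
        bad.loc[0, "death_day"] = np.nan
        bad.loc[0, "in_hospital_death"] = 0
        with pytest.raises(EpisodeValidationError) as err:
            validate_episodes(bad)
        assert err.value.rule == "same-institution"

    def test_excess_procedures_rejected(self, toy_episodes):
        bad = toy_episodes.copy()
        bad.loc[0, "n_procedures"] = 7
        with pytest.raises(EpisodeValidationError) as err:
            validate_episodes(bad)
        assert err.value.rule == "n-procedures-range"

    def test_same_day_readmission_merged_into_one_stay(self):
        df = toy_episode_table()
        df = df[df["patient_id"] == 2].reset_index(drop=True)
        second = df.copy()
        second["admission_index"] = 2
        second["admission_day"] = 10.0  # readmitted on the discharge day
        second["discharge_day"] = 25.0
        merged, diags = validate_episodes(pd.concat([df, second], ignore_index=True))
        assert diags == {"merged_same_day": 1}
        assert len(merged) == 1
        assert merged.loc[0, "discharge_day"] == 25.0


class TestProviderFilter:
    def test_threshold_boundary(self):
        rows = []
        for prov, n in (("A", 25), ("B", 20), ("C", 19)):
            for i in range(n):
                r = toy_episode_table().iloc[[1]].copy()
                r["patient_id"] = f"{prov}{i}"
                r["provider_id"] = prov
                rows.append(r)
        table = pd.concat(rows, ignore_index=True)
        kept, excluded = filter_providers(table, min_patients=20)
        assert excluded == ["C"]
        assert set(kept["provider_id"]) == {"A", "B"}

    def test_min_patients_one_never_excludes(self, small_cohort):
        kept, excluded = filter_providers(small_cohort.episodes, min_patients=1)
        assert excluded == []
        assert len(kept) == len(small_cohort.episodes)

    def test_empty_result_raises(self, toy_episodes):
        with pytest.raises(ValueError, match="lower min_patients"):
            filter_providers(toy_episodes, min_patients=100)


class TestTruncation:
    def test_three_admissions_unchanged(self, small_cohort):
        eps = small_cohort.episodes
        keep = eps.groupby("patient_id")["admission_index"].transform("max") <= 3
        sub = eps[keep].reset_index(drop=True)
        out = truncate_admissions(sub, max_admissions=5)
        pd.testing.assert_frame_equal(out, sub)

    def test_truncation_matches_simulator_bookkeeping(self):
        # high readmission pressure so a few percent exceed five admissions
        scen = flat_scenario(J=30, sizes=(30, 60), rates=(0.1, 0.005, 0.01, 0.001),
                             max_admissions=9)
        cohort = simulate_cohort(scen, seed=42)
        eps = cohort.episodes
        n_over = int((cohort.n_admissions > 5).sum())
        assert n_over > 0
        out = truncate_admissions(eps, max_admissions=5)
        assert out["admission_index"].max() <= 5
        removed = len(eps) - len(out)
        assert removed == int(np.maximum(cohort.n_admissions - 5, 0).sum())
        # follow-up of affected patients is capped at their fifth discharge
        over_ids = np.where(cohort.n_admissions > 5)[0]
        fifth = eps[(eps["patient_id"].isin(over_ids)) & (eps["admission_index"] == 5)]
        capped = out[out["patient_id"].isin(over_ids)]
        cap = fifth.set_index("patient_id")["discharge_day"]
        assert np.allclose(
            capped["followup_end_day"], capped["patient_id"].map(cap)
        )

    def test_invalid_max_admissions(self, toy_episodes):
        with pytest.raises(ValueError):
            truncate_admissions(toy_episodes, max_admissions=0)


class TestTransitionDatasets:
    def test_clock_reset_rows_for_readmission_then_death(self):
        df = pd.DataFrame(
            {
                "patient_id": [1, 1],
                "provider_id": ["A", "A"],
                "admission_index": [1, 2],
                "admission_day": [0.0, 40.0],
                "discharge_day": [10.0, np.nan],
                "in_hospital_death": [0, 1],
                "death_day": [np.nan, 45.0],
                "followup_end_day": [1826.0, 1826.0],
                "age": [70.0, 70.0],
                "sex": [0, 0],
                "comorb3": [0, 0],
                "n_procedures": [0, 0],
            }
        )
        ds = build_transition_datasets(df)
        assert list(zip(ds[1].time, ds[1].event)) == [(10.0, 1), (5.0, 0)]
        assert list(zip(ds[2].time, ds[2].event)) == [(10.0, 0), (5.0, 1)]
        assert list(zip(ds[3].time, ds[3].event)) == [(30.0, 1)]
        assert list(zip(ds[4].time, ds[4].event)) == [(30.0, 0)]

    def test_censored_out_of_hospital_spell(self):
        df = toy_episode_table()
        df = df[df["patient_id"] == 2].reset_index(drop=True)
        ds = build_transition_datasets(df)
        assert list(zip(ds[3].time, ds[3].event)) == [(1816.0, 0)]
        assert list(zip(ds[4].time, ds[4].event)) == [(1816.0, 0)]

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_event_counts_match_simulator_tallies(self, seed):
        scen = default_scenario(J=25, provider_size_range=(20, 40))
        cohort = simulate_cohort(scen, seed=seed)
        ds = build_transition_datasets(cohort.episodes)
        for l in (1, 2, 3, 4):
            assert ds[l].n_events == cohort.event_counts[l]

    def test_competing_rows_share_times_within_origin_state(self, small_cohort):
        ds = build_transition_datasets(small_cohort.episodes)
        for a, b in ((1, 2), (3, 4)):
            fa, fb = ds[a].frame, ds[b].frame
            assert len(fa) == len(fb)
            assert np.array_equal(fa["time"], fb["time"])
            assert np.array_equal(fa["patient_id"], fb["patient_id"])
            # at most one of the competing events fires per spell
            assert int(((fa["event"] == 1) & (fb["event"] == 1)).sum()) == 0


class TestCohortAccounting:
    def test_flow_identity_on_margins(self):
        assert next_admissions(42_871, 4_766, 14_569, 12_231) == 11_305

    def test_percentage_rule(self):
        assert percentage(7_015, 42_871) == 16.36

    def test_two_patient_toy_cohort(self, toy_episodes):
        summary = cohort_accounting(toy_episodes)
        col = summary[1]
        assert col["n_admitted"] == 2
        assert col["n_in_hospital_death"] == 1
        assert col["n_censored_after_discharge"] == 1
        assert 2 not in summary.columns  # nobody admitted a second time

    @pytest.mark.parametrize("seed", [1, 5, 11, 23])
    def test_flow_identity_holds_exactly_on_simulated_cohorts(self, seed):
        scen = default_scenario(J=20, provider_size_range=(20, 40))
        cohort = simulate_cohort(scen, seed=seed)
        summary = cohort_accounting(cohort.episodes)
        for k in summary.columns:
            col = summary[k]
            assert col["n_admitted"] == col["n_discharged"] + col["n_in_hospital_death"]
            if k + 1 in summary.columns:
                assert summary[k + 1]["n_admitted"] == next_admissions(
                    col["n_admitted"],
                    col["n_in_hospital_death"],
                    col["n_death_after_discharge"],
                    col["n_censored_after_discharge"],
                )
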