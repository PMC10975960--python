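"""Trial simulator and event-table I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bepopk as bp
from bepopk.simulate import (
    ADULT_NOMINAL_TIMES,
    EVENT_COLUMNS,
    apply_lloq_filter,
    adult_design,
    pediatric_design,
    read_event_table,
    simulate_demographics,
    simulate_study,
    validate_event_table,
    write_event_table,
)


class TestDemographics:
    def test_adult_bounds_and_mean(self):
        covs = simulate_demographics("adult", 10_000, np.random.default_rng(0))
        wt = np.array([c.wt for c in covs])
        assert wt.min() >= 56.8 and wt.max() <= 89.6
        assert abs(wt.mean() - 70.95) < 0.5
        assert all(c.sex == "male" for c in covs)

    def test_pediatric_bounds(self):
        covs = simulate_demographics("pediatric", 5_000, np.random.default_rng(1))
        wt = np.array([c.wt for c in covs])
        age = np.array([c.age for c in covs])
        assert wt.min() >= 13.0 and wt.max() <= 26.0
        assert set(age) <= {2.0, 3.0, 4.0, 5.0, 6.0}
        frac_male = np.mean([c.sex == "male" for c in covs])
        assert frac_male == pytest.approx(19 / 30, abs=0.03)

    def test_pediatric_weight_tracks_age_group_medians(self):
        covs = simulate_demographics("pediatric", 20_000, np.random.default_rng(2))
        wt = np.array([c.wt for c in covs])
        age = np.array([c.age for c in covs])
        assert np.median(wt[age == 2]) == pytest.approx(14.0, abs=0.35)
        assert np.median(wt[age == 6]) == pytest.approx(19.6, abs=0.35)


class TestSimulateStudy:
    def test_zero_variability_reproduces_typical_curve(self, no_variability_pop):
        tbl = simulate_study(adult_design(5), no_variability_pop, np.random.default_rng(3))
        obs = tbl[tbl["EVID"] == 0]
        for sid, grp in obs.groupby("ID"):
            p = bp.allometric_scale(
                no_variability_pop, bp.Covariates(wt=grp["WT"].iloc[0])
            )
            expected = bp.pk_core.conc_single_dose(p, 10.0, grp["TIME"].to_numpy())
            np.testing.assert_allclose(grp["DV"].to_numpy(), expected, atol=1e-5)

    def test_adult_design_times_and_dose(self, pop):
        tbl = simulate_study(adult_design(4), pop, np.random.default_rng(4))
        for _, grp in tbl.groupby("ID"):
            doses = grp[grp["EVID"] == 1]
            assert len(doses) == 1 and doses["AMT"].iloc[0] == 10.0
            times = grp.loc[grp["EVID"] == 0, "TIME"].tolist()
            assert times == sorted(ADULT_NOMINAL_TIMES)

    def test_pediatric_two_samples_one_per_window(self, pop):
        tbl = simulate_study(pediatric_design(10), pop, np.random.default_rng(5))
        t_dose = 8 * 12.0  # sampling follows the 9th dose
        for _, grp in tbl.groupby("ID"):
            doses = grp[grp["EVID"] == 1]
            assert len(doses) == 9 and set(doses["AMT"]) == {3.0}
            tad = grp.loc[grp["EVID"] == 0, "TIME"].to_numpy() - t_dose
            assert tad.shape == (2,)
            assert 0.5 <= tad[0] <= 2.0
            assert 6.0 <= tad[1] <= 12.0

    def test_fixed_seed_is_byte_identical(self, pop, tmp_path):
        a = simulate_study(adult_design(6), pop, np.random.default_rng(42))
        b = simulate_study(adult_design(6), pop, np.random.default_rng(42))
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_event_table(a, pa)
        write_event_table(b, pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestLloqFilter:
    def test_typical_adult_retains_11_of_13(self, no_variability_pop):
        tbl = simulate_study(adult_design(3), no_variability_pop, np.random.default_rng(6))
        out = apply_lloq_filter(tbl)
        # pre-dose (0 h) and the 24 h sample fall below 1 ng/mL
        assert (out["EVID"] == 0).sum() == 3 * 11
        assert out.attrs["n_blq_removed"] == 3 * 2
        assert 24.0 not in out.loc[out["EVID"] == 0, "TIME"].values

    def test_all_above_lloq_unchanged(self):
        tbl = pd.DataFrame(
            {
                "ID": [1, 1], "TIME": [0.0, 1.0], "EVID": [1, 0], "AMT": [10.0, np.nan],
                "DV": [np.nan, 5.0], "BLQ": [0, 0], "WT": 70.0, "AGE": 25.0,
                "SCR": 0.9, "EGFR": 110.0, "SEX": 0,
            }
        )
        out = apply_lloq_filter(tbl)
        assert len(out) == 2 and out.attrs["n_blq_removed"] == 0

    def test_empty_table(self):
        tbl = pd.DataFrame(columns=EVENT_COLUMNS)
        assert len(apply_lloq_filter(tbl)) == 0

    def test_pediatric_blq_fraction_is_small(self, pop):
        # informative design: few observations fall below quantification
        rng = np.random.default_rng(7)
        removed = total = 0
        for _ in range(20):
            tbl = simulate_study(pediatric_design(30), pop, rng)
            out = apply_lloq_filter(tbl)
            removed += out.attrs["n_blq_removed"]
            total += (tbl["EVID"] == 0).sum()
        assert removed / total < 0.05


class TestEventTableIO:
    def test_round_trip(self, pop, tmp_path):
        tbl = simulate_study(pediatric_design(5), pop, np.random.default_rng(8))
        path = tmp_path / "events.csv"
        write_event_table(tbl, path)
        back = read_event_table(path)
        pd.testing.assert_frame_equal(tbl, back, check_dtype=False)

    def test_blq_flag_survives_round_trip(self, pop, tmp_path):
        tbl = simulate_study(adult_design(4), pop, np.random.default_rng(9))
        path = tmp_path / "events.csv"
        write_event_table(tbl, path)
        back = read_event_table(path)
        assert back["BLQ"].tolist() == tbl["BLQ"].tolist()
        assert back["BLQ"].sum() > 0  # pre-dose rows are flagged

    def test_missing_column_is_named(self, pop, tmp_path):
        tbl = simulate_study(adult_design(2), pop, np.random.default_rng(10))
        path = tmp_path / "bad.csv"
        tbl.drop(columns=["WT"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="WT"):
            read_event_table(path)

    def test_subject_without_dose_rows_rejected(self, pop):
        tbl = simulate_study(adult_design(2), pop, np.random.default_rng(11))
        no_dose = tbl[~((tbl["ID"] == 1) & (tbl["EVID"] == 1))]
        with pytest.raises(ValueError, match="no dose rows"):
            validate_event_table(no_dose)
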