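"""Quality filters, detrending, and lag-table construction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emanet as e
from emanet.preprocess import _term_pvalues

from conftest import homogeneous_population


def make_beep_frame(answered_mask, person_id="P001", scores=None):
    """Beep-level frame for one person from a (day, occasion) answered mask."""
    rows = []
    n_days, n_occ = answered_mask.shape
    rng = np.random.default_rng(0)
    for d in range(n_days):
        for o in range(n_occ):
            t = pd.Timestamp("2023-01-01") + pd.Timedelta(days=d, hours=9 + 3 * o)
            if answered_mask[d, o]:
                vals = (scores[d, o] if scores is not None
                        else rng.uniform(0, 100, 6))
                rows.append((person_id, d + 1, o + 1, t, t, 200.0, *vals))
            else:
                rows.append((person_id, d + 1, o + 1, t, pd.NaT, np.nan,
                             *[np.nan] * 6))
    cols = ["person_id", "day", "occasion", "scheduled_time", "response_time",
            "completion_seconds", *e.NODE_NAMES]
    return pd.DataFrame(rows, columns=cols)


class TestCompliance:
    @pytest.mark.parametrize("n_answered, expected", [(73, 73 / 105), (105, 1.0), (0, 0.0)])
    def test_answered_fraction(self, n_answered, expected):
        mask = np.zeros((21, 5), dtype=bool)
        mask.flat[:n_answered] = True
        ds = make_beep_frame(mask)
        assert e.compute_compliance(ds)["P001"] == pytest.approx(expected)

    def test_count_rule_governs(self):
        # 73 of 105 is only 69.5% but satisfies the >= 73 count criterion
        mask = np.zeros((21, 5), dtype=bool)
        mask.flat[:73] = True
        ds = make_beep_frame(mask)
        filtered, audit = e.apply_inclusion_filters(
            pd.concat([ds, make_beep_frame(np.ones((21, 5), bool), "P002")]),
            min_count=73)
        assert audit["persons_low_compliance"] == 0
        assert set(filtered["person_id"]) == {"P001", "P002"}

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError):
            e.compute_compliance(make_beep_frame(np.ones((1, 1), bool)).iloc[:0])


class TestRsi:
    def _frame(self, durations):
        mask = np.ones((1, len(durations)), dtype=bool)
        ds = make_beep_frame(mask)
        ds["completion_seconds"] = durations
        return ds

    def test_median_duration_gives_unit_rsi(self):
        q = e.compute_rsi(self._frame([100.0, 100.0, 100.0]))
        assert (q["rsi"] == 1.0).all() and q["retained"].all()

    def test_boundary_exactly_two_retained(self):
        q = e.compute_rsi(self._frame([100.0, 100.0, 50.0]))
        assert q.loc[2, "rsi"] == 2.0 and bool(q.loc[2, "retained"])

    def test_speeder_excluded(self):
        # durations [100, 100, 100, 20] s, speed convention: rsi = median / duration
        q = e.compute_rsi(self._frame([100.0, 100.0, 100.0, 20.0]))
        assert q.loc[3, "rsi"] == pytest.approx(5.0)
        assert not q.loc[3, "retained"]

    def test_literal_convention(self):
        q = e.compute_rsi(self._frame([100.0, 100.0, 100.0, 250.0]),
                          convention="literal")
        assert q.loc[3, "rsi"] == pytest.approx(2.5)
        assert not q.loc[3, "retained"]

    def test_non_positive_duration_errors(self):
        with pytest.raises(ValueError, match="P001"):
            e.compute_rsi(self._frame([100.0, 0.0]))


class TestInclusionFilters:
    def test_clean_data_unchanged(self):
        ds = make_beep_frame(np.ones((21, 5), bool))
        ds2 = make_beep_frame(np.ones((21, 5), bool), "P002")
        both = pd.concat([ds, ds2], ignore_index=True)
        filtered, audit = e.apply_inclusion_filters(both)
        pd.testing.assert_frame_equal(filtered, both)
        assert audit["prompts_rsi_excluded"] == 0

    def test_low_compliance_person_removed_and_logged(self):
        mask60 = np.zeros((21, 5), dtype=bool)
        mask60.flat[:63] = True  # 60%
        both = pd.concat([make_beep_frame(mask60, "P001"),
                          make_beep_frame(np.ones((21, 5), bool), "P002")],
                         ignore_index=True)
        filtered, audit = e.apply_inclusion_filters(both)
        assert set(filtered["person_id"]) == {"P002"}
        assert audit["persons_low_compliance"] == 1

    def test_flagged_persons_removed_by_reason(self):
        frames = [make_beep_frame(np.ones((21, 5), bool), f"P{i:03d}")
                  for i in range(1, 7)]
        ds = pd.concat(frames, ignore_index=True)
        flags = {"P001": "careless", "P002": "careless",
                 "P003": "failed_verification"}
        filtered, audit = e.apply_inclusion_filters(ds, exclusion_flags=flags)
        assert audit["persons_flagged"] == 3
        assert audit["flag_reasons"] == {"careless": 2, "failed_verification": 1}
        assert filtered["person_id"].nunique() == 3

    def test_cohort_reduction_to_target_count(self):
        # 125 simulated persons, 6 flagged + low-compliance ones -> analysis cohort
        pop = e.default_population_model()
        pop.compliance_mean, pop.compliance_sd = 0.93, 0.10
        ds = e.simulate_study(e.StudyDesign(n_participants=125, n_days=21),
                              pop=pop, seed=10, clip=True)
        persons = sorted(ds["person_id"].unique())
        flags = {p: "careless" for p in persons[:4]}
        flags.update({p: "failed_verification" for p in persons[4:6]})
        filtered, audit = e.apply_inclusion_filters(ds, exclusion_flags=flags)
        n_kept = audit["persons_retained"]
        assert n_kept == 125 - 6 - audit["persons_low_compliance"]
        assert 100 <= n_kept <= 119

    def test_filtering_idempotent(self, small_realistic_ds):
        once, _ = e.apply_inclusion_filters(small_realistic_ds, min_count=20)
        twice, audit2 = e.apply_inclusion_filters(once, min_count=20)
        pd.testing.assert_frame_equal(once, twice)
        assert audit2["prompts_rsi_excluded"] == 0


class TestDetrend:
    def test_noise_free_trend_removed_exactly(self):
        mask = np.ones((21, 5), dtype=bool)
        day = np.arange(1, 22)[:, None, None]
        scores = np.broadcast_to(30.0 + 2.0 * day, (21, 5, 6)).copy()
        ds = make_beep_frame(mask, scores=scores)
        ds2 = pd.concat([ds, make_beep_frame(mask, "P002", scores=scores)],
                        ignore_index=True)
        out, report = e.detrend(ds2)
        assert report["removed_day"].all()
        # refit: remaining slope must vanish
        for pid, sub in out.groupby("person_id"):
            slope = np.polyfit(sub["day"], sub["rigidity"], 1)[0]
            assert abs(slope) < 1e-8
            # grand mean preserved
            assert sub["rigidity"].mean() == pytest.approx(
                ds2[ds2.person_id == pid]["rigidity"].mean())

    def test_occasion_effects_removed_exactly(self):
        mask = np.ones((21, 5), dtype=bool)
        occ_fx = np.array([5.0, 0.0, -3.0, 0.0, 2.0])
        scores = np.broadcast_to(50.0 + occ_fx[None, :, None], (21, 5, 6)).copy()
        ds = make_beep_frame(mask, scores=scores)
        out, report = e.detrend(ds)
        assert report["removed_occasion"].all()
        assert not report["removed_day"].any()
        # occasion component is removed mean-centred: grand mean is preserved
        assert np.allclose(out[e.NODE_NAMES].to_numpy(), 50.0 + occ_fx.mean())

    def test_white_noise_type_one_rate(self):
        # term-wise test keeps ~95% of null series untouched
        pop = homogeneous_population()
        ds = e.simulate_study(e.StudyDesign(n_participants=170, n_days=21),
                              pop=pop, seed=12, clip=False)
        _, report = e.detrend(ds)
        n_series = len(report)
        assert n_series >= 1000
        for term in ("removed_day", "removed_occasion"):
            rate = report[term].mean()
            assert 0.03 < rate < 0.07, f"{term} rate {rate}"

    def test_constant_series_unchanged(self):
        mask = np.ones((21, 5), dtype=bool)
        scores = np.full((21, 5, 6), 40.0)
        ds = make_beep_frame(mask, scores=scores)
        out, report = e.detrend(ds)
        assert np.allclose(out[e.NODE_NAMES].to_numpy(), 40.0)
        assert not report[["removed_day", "removed_occasion"]].any().any()

    def test_short_series_skipped_with_warning(self):
        mask = np.zeros((21, 5), dtype=bool)
        mask.flat[:5] = True
        ds = make_beep_frame(mask)
        with pytest.warns(UserWarning, match="skipped"):
            out, report = e.detrend(ds)
        assert report["skipped"].all()
        pd.testing.assert_frame_equal(out, ds)

    def test_detrend_idempotent_on_noise_free_fixture(self):
        mask = np.ones((21, 5), dtype=bool)
        day = np.arange(1, 22)[:, None, None]
        occ_fx = np.array([3.0, 0.0, -1.0, 0.0, 1.0])[None, :, None]
        scores = np.broadcast_to(30.0 + 1.5 * day + occ_fx, (21, 5, 6)).copy()
        ds = make_beep_frame(mask, scores=scores)
        once, _ = e.detrend(ds)
        twice, _ = e.detrend(once)
        assert np.max(np.abs(once[e.NODE_NAMES].to_numpy()
                             - twice[e.NODE_NAMES].to_numpy())) < 1e-6

    def test_degenerate_exact_trend_pvalue(self):
        day = np.repeat(np.arange(1.0, 11.0), 5)
        occ = np.tile(np.arange(1, 6), 10)
        slope, day_p, occ_p, _, _ = _term_pvalues(10 + 2 * day, day, occ)
        assert slope == pytest.approx(2.0) and day_p == 0.0 and occ_p == 1.0


def brute_force_lag_pairs(answered_mask):
    """Independent enumerator of within-day adjacent answered pairs."""
    count = 0
    for day_row in answered_mask:
        for o in range(1, len(day_row)):
            if day_row[o] and day_row[o - 1]:
                count += 1
    return count


class TestLaggedTable:
    def test_full_day_gives_four_pairs(self):
        ds = make_beep_frame(np.ones((1, 5), bool))
        assert len(e.build_lagged_table(ds)) == 4

    def test_missed_prompt_breaks_chain(self):
        mask = np.array([[True, True, False, True, True]])
        lag = e.build_lagged_table(make_beep_frame(mask))
        assert list(lag["occasion"]) == [2, 5]

    def test_no_overnight_pairs(self):
        lag = e.build_lagged_table(make_beep_frame(np.ones((2, 5), bool)))
        assert len(lag) == 8
        assert (lag["occasion"] > 1).all()

    def test_lag_values_align(self):
        scores = np.arange(1 * 5 * 6, dtype=float).reshape(1, 5, 6)
        lag = e.build_lagged_table(make_beep_frame(np.ones((1, 5), bool),
                                                   scores=scores))
        row = lag.iloc[0]
        assert row["occasion"] == 2
        assert np.allclose([row["lag_" + n] for n in e.NODE_NAMES], scores[0, 0])
        assert np.allclose([row[n] for n in e.NODE_NAMES], scores[0, 1])

    @given(st.lists(st.lists(st.booleans(), min_size=5, max_size=5),
                    min_size=1, max_size=8))
    @settings(max_examples=200)
    def test_row_count_matches_brute_force(self, mask_rows):
        mask = np.array(mask_rows, dtype=bool)
        ds = make_beep_frame(mask)
        assert len(e.build_lagged_table(ds)) == brute_force_lag_pairs(mask)
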