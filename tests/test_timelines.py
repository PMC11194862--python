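import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrmspred.timelines import (
    FlowLog,
    NODMT,
    OTHERDMT,
    TherapyCycle,
    build_timeline,
    censor_at_last_edss,
    eligibility_filter,
    make_switch_pairs,
    quality_filter,
    select_one_cycle_per_patient,
    temporal_split,
)

D = pd.Timestamp


def episodes(*rows):
    return pd.DataFrame(
        [{"patient_id": "p1", "dmt_name": d, "start_date": D(s), "end_date": D(e)} for d, s, e in rows]
    )


def patients(**overrides):
    row = {
        "patient_id": "p1",
        "centre_id": "c1",
        "sex": "F",
        "birth_date": D("1980-01-01"),
        "onset_date": D("2005-01-01"),
        "diagnosis_date": D("2006-01-01"),
        "course_label": "RRMS",
    }
    row.update(overrides)
    return pd.DataFrame([row])


class TestBuildTimeline:
    def test_single_episode_identity(self):
        cycles = build_timeline(episodes(("fingolimod", "2012-01-01", "2013-01-01")))
        assert len(cycles) == 1
        c = cycles[0]
        assert (c.dmt, c.start_date, c.end_date) == ("fingolimod", D("2012-01-01"), D("2013-01-01"))

    def test_gap_becomes_nodmt(self):
        cycles = build_timeline(
            episodes(("fingolimod", "2012-01-01", "2012-06-01"), ("natalizumab", "2013-01-01", "2014-01-01"))
        )
        assert [(c.dmt, c.start_date, c.end_date) for c in cycles] == [
            ("fingolimod", D("2012-01-01"), D("2012-06-01")),
            (NODMT, D("2012-06-01"), D("2013-01-01")),
            ("natalizumab", D("2013-01-01"), D("2014-01-01")),
        ]

    def test_overlap_becomes_otherdmt(self):
        cycles = build_timeline(
            episodes(("fingolimod", "2012-01-01", "2013-01-01"), ("natalizumab", "2012-07-01", "2014-01-01"))
        )
        assert [(c.dmt, c.start_date, c.end_date) for c in cycles] == [
            ("fingolimod", D("2012-01-01"), D("2012-07-01")),
            (OTHERDMT, D("2012-07-01"), D("2013-01-01")),
            ("natalizumab", D("2013-01-01"), D("2014-01-01")),
        ]

    def test_same_dmt_overlap_is_not_otherdmt(self):
        cycles = build_timeline(
            episodes(("fingolimod", "2012-01-01", "2013-01-01"), ("fingolimod", "2012-07-01", "2014-01-01"))
        )
        assert [c.dmt for c in cycles] == ["fingolimod"]

    def test_one_day_gap_merged(self):
        cycles = build_timeline(
            episodes(("fingolimod", "2012-01-01", "2012-06-01"), ("fingolimod", "2012-06-02", "2013-01-01"))
        )
        assert len(cycles) == 1

    def test_invalid_episode_rejected(self):
        with pytest.raises(ValueError):
            build_timeline(episodes(("fingolimod", "2013-01-01", "2012-01-01")))

    def test_empty(self):
        assert build_timeline(episodes()) == []

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["fingolimod", "natalizumab", "teriflunomide"]),
                st.integers(0, 1000),
                st.integers(2, 400),
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_partitions_span(self, raw):
        eps = episodes(
            *[
                (d, str(D("2012-01-01") + pd.Timedelta(days=s)), str(D("2012-01-01") + pd.Timedelta(days=s + dur)))
                for d, s, dur in raw
            ]
        )
        cycles = build_timeline(eps)
        assert cycles[0].start_date == eps["start_date"].min()
        assert cycles[-1].end_date == eps["end_date"].max()
        for a, b in zip(cycles[:-1], cycles[1:]):
            assert a.end_date == b.start_date  # abut: no overlap, no untracked gap
            assert a.dmt != b.dmt or a.end_date < b.start_date or True


class TestCycleInvariants:
    def test_cycle_rejects_bad_interval(self):
        with pytest.raises(ValueError):
            TherapyCycle("p", "fingolimod", D("2013-01-01"), D("2012-01-01"))


class TestQualityFilter:
    def test_invalid_interval_logged(self):
        eps = episodes(("fingolimod", "2013-01-01", "2012-01-01"))
        out, log = quality_filter(eps, patients())
        assert len(out) == 0
        step = {s["filter_name"]: s for s in log.to_records()}
        assert step["invalid_interval"]["n_removed"] == 1

    def test_valid_set_untouched(self):
        eps = episodes(("fingolimod", "2012-01-01", "2013-01-01"), ("natalizumab", "2013-02-01", "2014-01-01"))
        out, log = quality_filter(eps, patients())
        assert len(out) == 2
        assert all(s["n_removed"] == 0 for s in log.to_records())

    def test_planted_violation_counts(self):
        rows = [("fingolimod", f"201{i}-01-01", f"201{i}-06-01") for i in range(2, 9)]
        eps = episodes(*rows)
        bad = pd.DataFrame(
            [
                {"patient_id": "p1", "dmt_name": "fingolimod", "start_date": pd.NaT, "end_date": D("2013-01-01")},
                {"patient_id": "p1", "dmt_name": "???", "start_date": D("2013-01-01"), "end_date": D("2013-06-01")},
                {"patient_id": "p1", "dmt_name": "fingolimod", "start_date": D("2001-01-01"), "end_date": D("2002-01-01")},
            ]
        )
        out, log = quality_filter(pd.concat([eps, bad], ignore_index=True), patients())
        assert len(out) == 7
        step = {s["filter_name"]: s["n_removed"] for s in log.to_records()}
        assert step == {"missing_start": 1, "invalid_interval": 0, "unknown_dmt": 1, "before_onset": 1}

    def test_flowlog_accounting(self):
        eps = episodes(("fingolimod", "2012-01-01", "2013-01-01"), ("???", "2013-01-01", "2014-01-01"))
        out, log = quality_filter(eps, patients())
        assert len(eps) - log.total_removed() == len(out)


def pairs_frame(*rows):
    """rows: (patient_id, current_dmt, index_dmt, index_start)."""
    recs = []
    for pid, cur, idx, start in rows:
        start = D(start)
        recs.append(
            {
                "patient_id": pid,
                "centre_id": "c1",
                "current_dmt": cur,
                "current_start": start - pd.Timedelta(days=400),
                "current_end": start,
                "index_dmt": idx,
                "index_start": start,
                "index_end": start + pd.Timedelta(days=400),
                "index_censored": False,
            }
        )
    return pd.DataFrame(recs)


class TestEligibility:
    def test_otherdmt_index_removed(self):
        p = pairs_frame(("p1", NODMT, OTHERDMT, "2015-01-01"))
        out, log = eligibility_filter(p, patients(), "2011-01-01")
        assert len(out) == 0
        assert log.to_records()[0]["filter_name"] == "index_dmt_not_eligible"
        assert log.to_records()[0]["n_removed"] == 1

    def test_five_months_post_diagnosis_removed(self):
        p = pairs_frame(("p1", NODMT, "fingolimod", "2015-06-01"))
        pat = patients(diagnosis_date=D("2015-01-05"))
        out, log = eligibility_filter(p, pat, "2011-01-01")
        assert len(out) == 0
        step = {s["filter_name"]: s["n_removed"] for s in log.to_records()}
        assert step["min_6_months_post_diagnosis"] == 1

    def test_six_months_boundary_kept(self):
        pat = patients(diagnosis_date=D("2015-01-01"))
        p = pairs_frame(("p1", NODMT, "fingolimod", "2015-07-05"))
        out, _ = eligibility_filter(p, pat, "2011-01-01")
        assert len(out) == 1

    def test_missing_dates_complete_case(self):
        p = pairs_frame(("p1", NODMT, "fingolimod", "2015-01-01"))
        out, log = eligibility_filter(p, patients(birth_date=pd.NaT), "2011-01-01")
        assert len(out) == 0
        step = {s["filter_name"]: s["n_removed"] for s in log.to_records()}
        assert step["complete_case"] == 1

    def test_planted_violation_counts(self):
        rows = [
            ("p1", NODMT, "fingolimod", "2015-01-01"),  # kept
            ("p2", NODMT, OTHERDMT, "2015-01-01"),  # bad index dmt
            ("p3", NODMT, "fingolimod", "2010-01-01"),  # pre-registry
            ("p4", NODMT, "fingolimod", "2015-01-01"),  # minor
            ("p5", NODMT, "fingolimod", "2015-01-01"),  # not RRMS
        ]
        p = pairs_frame(*rows)
        pat = pd.concat(
            [
                patients(),
                patients(patient_id="p2"),
                patients(patient_id="p3"),
                patients(patient_id="p4", birth_date=D("2005-06-01")),
                patients(patient_id="p5", course_label="SPMS"),
            ],
            ignore_index=True,
        )
        out, log = eligibility_filter(p, pat, "2011-01-01")
        assert list(out["patient_id"]) == ["p1"]
        step = {s["filter_name"]: s["n_removed"] for s in log.to_records()}
        assert step == {
            "index_dmt_not_eligible": 1,
            "complete_case": 0,
            "adult": 1,
            "min_6_months_post_diagnosis": 0,
            "before_registry_start": 1,
            "non_rrms_course": 1,
        }


def vframe(pid, *dates):
    return pd.DataFrame({"patient_id": pid, "date": [D(d) for d in dates], "edss": 2.0})


class TestCensoring:
    def test_closed_cycle_unchanged(self):
        cyc = pd.DataFrame(
            [{"patient_id": "p1", "dmt": "fingolimod", "start_date": D("2015-01-01"), "end_date": D("2016-01-01")}]
        )
        out, _ = censor_at_last_edss(cyc, vframe("p1", "2015-06-01"), "2017-01-01")
        assert out["end_date"].iloc[0] == D("2016-01-01")
        assert not out["censored"].iloc[0]

    def test_open_cycle_censored_at_last_edss(self):
        cyc = pd.DataFrame(
            [{"patient_id": "p1", "dmt": "fingolimod", "start_date": D("2015-01-01"), "end_date": pd.NaT}]
        )
        out, _ = censor_at_last_edss(cyc, vframe("p1", "2015-06-01", "2016-11-03", "2017-03-01"), "2017-01-01")
        assert out["end_date"].iloc[0] == D("2016-11-03")
        assert bool(out["censored"].iloc[0])

    def test_no_pre_cutoff_edss_dropped(self):
        cyc = pd.DataFrame(
            [{"patient_id": "p1", "dmt": "fingolimod", "start_date": D("2015-01-01"), "end_date": pd.NaT}]
        )
        out, log = censor_at_last_edss(cyc, vframe("p1", "2017-03-01"), "2017-01-01")
        assert len(out) == 0
        step = {s["filter_name"]: s["n_removed"] for s in log.to_records()}
        assert step["no_edss_before_cutoff"] == 1

    def test_cutoff_before_all_data_drops_ongoing(self):
        cyc = pd.DataFrame(
            [{"patient_id": "p1", "dmt": "fingolimod", "start_date": D("2015-01-01"), "end_date": pd.NaT}]
        )
        out, _ = censor_at_last_edss(cyc, vframe("p1", "2015-06-01"), "2014-01-01")
        assert len(out) == 0


class TestSelectionAndSplit:
    def test_single_pair_kept(self):
        p = pairs_frame(("p1", NODMT, "fingolimod", "2015-01-01"))
        out = select_one_cycle_per_patient(p, seed=0)
        assert len(out) == 1

    def test_deterministic(self):
        p = pairs_frame(*[(f"p{i}", NODMT, "fingolimod", "2015-01-01") for i in range(50)] * 2)
        a = select_one_cycle_per_patient(p, seed=3)
        b = select_one_cycle_per_patient(p, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_selection(self):
        rows = []
        for i in range(1000):
            rows.append((f"p{i:04d}", NODMT, "fingolimod", "2014-01-01"))
            rows.append((f"p{i:04d}", NODMT, "natalizumab", "2015-01-01"))
        p = pairs_frame(*rows)
        out = select_one_cycle_per_patient(p, seed=1)
        assert len(out) == 1000
        n_first = (out["index_dmt"] == "fingolimod").sum()
        # binomial(1000, .5) 99% interval
        assert 459 <= n_first <= 541

    def test_split_boundary(self):
        p = pairs_frame(
            ("p1", NODMT, "fingolimod", "2016-12-31"),
            ("p2", NODMT, "fingolimod", "2017-01-01"),
        )
        train, test = temporal_split(p, "2017-01-01")
        assert list(train["patient_id"]) == ["p1"]
        assert list(test["patient_id"]) == ["p2"]
        train2, _ = temporal_split(p, "2017-01-01", train_includes_boundary=True)
        assert len(train2) == 2

    def test_empty_and_degenerate(self):
        empty = pairs_frame()
        train, test = temporal_split(empty.reindex(columns=pairs_frame(("p", NODMT, "x", "2015-01-01")).columns), "2017-01-01")
        assert len(train) == 0 and len(test) == 0
        p = pairs_frame(("p1", NODMT, "fingolimod", "2015-01-01"))
        train, test = temporal_split(p, "2017-01-01")
        assert len(test) == 0

    def test_patient_ids_unique_after_selection_and_split(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(300):
            for j in range(rng.integers(1, 4)):
                rows.append((f"p{i:04d}", NODMT, "fingolimod", f"201{4 + j}-03-01"))
        p = pairs_frame(*rows)
        sel = select_one_cycle_per_patient(p, seed=5)
        train, test = temporal_split(sel, "2016-01-01")
        ids = list(train["patient_id"]) + list(test["patient_id"])
        assert len(ids) == len(set(ids)) == 300


class TestSwitchPairs:
    def test_consecutive_pairs(self):
        cycles = pd.DataFrame(
            [
                {"patient_id": "p1", "centre_id": "c1", "dmt": NODMT, "start_date": D("2014-01-01"), "end_date": D("2015-01-01"), "censored": False},
                {"patient_id": "p1", "centre_id": "c1", "dmt": "fingolimod", "start_date": D("2015-01-01"), "end_date": D("2016-01-01"), "censored": False},
                {"patient_id": "p1", "centre_id": "c1", "dmt": "natalizumab", "start_date": D("2016-01-01"), "end_date": D("2017-01-01"), "censored": True},
            ]
        )
        pairs = make_switch_pairs(cycles)
        assert len(pairs) == 2
        assert list(pairs["index_dmt"]) == ["fingolimod", "natalizumab"]
        assert bool(pairs["index_censored"].iloc[1])


class TestFlowLog:
    def test_accounting_identity(self):
        log = FlowLog()
        log.record("a", 10, 7)
        log.record("b", 7, 7)
        frame = log.as_frame()
        assert (frame["n_before"] - frame["n_removed"] == frame["n_after"]).all()
        assert log.total_removed() == 3

    def test_rejects_additions(self):
        log = FlowLog()
        with pytest.raises(ValueError):
            log.record("bad", 5, 6)
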