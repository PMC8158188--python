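"""Group assignment, cumulative steps, review adjustment, event matching."""

import pytest
from hypothesis import given, strategies as st

from dislokit import (
    Cohort,
    DislokitError,
    assign_group,
    build_cohort,
    classify_events,
    classify_patients,
    review_adjust,
    window_contacts,
)
from util import contact, event, tha


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        # correct dx + correct proc, laterality matches -> group 1
        (dict(dx=["DT840A"], procs=["KNFH20"]), 1),
        # correct proc with any random diagnosis -> group 2
        (dict(dx=["DS320"], procs=["KNFH20"]), 2),
        # alternative dx alone -> group 3
        (dict(dx=["DS730"]), 3),
        # alternative proc with random dx -> group 3
        (dict(dx=["DS320"], procs=["KNFH22"]), 3),
        # group 1-3 codes with unknown laterality -> group 4
        (dict(dx=["DS730"], side="unknown"), 4),
        (dict(dx=["DS320"], procs=["KNFH20"], side="unknown"), 4),
        # correct dx alone, acute -> group 5
        (dict(dx=["DT840"]), 5),
        (dict(dx=["DT840A"], admission_type="elective", setting="outpatient_er"), 5),
        # correct dx alone at an elective clinic visit -> no group
        (dict(dx=["DT840"], admission_type="elective", setting="outpatient_clinic"), None),
        # correct dx alone with unknown laterality is not a group 1-3 criterion
        (dict(dx=["DT840"], side="unknown"), None),
        # opposite side never qualifies
        (dict(dx=["DT840"], procs=["KNFH20"], side="right"), None),
        # no qualifying codes
        (dict(dx=["DM160"], procs=["KZZX00"]), None),
        (dict(), None),
    ],
)
def test_assign_group(codes, kwargs, expected):
    assert assign_group(contact(**kwargs), tha(side="left"), codes) == expected


def test_lowest_group_wins(codes):
    c = contact(dx=["DT840", "DS730"], procs=["KNFH20", "KNFH00"])
    assert assign_group(c, tha(), codes) == 1


def test_group5_requires_absent_correct_proc(codes):
    # with KNFH20 present the contact is group 1/2 territory, never group 5
    c = contact(dx=["DT840"], procs=["KNFH20"])
    assert assign_group(c, tha(), codes) == 1


def _classify(contacts, records=None, truth=()):
    cohort = build_cohort(records or [tha()])
    windowed = window_contacts(cohort, contacts)
    return cohort, windowed, classify_patients(cohort, windowed)


class TestClassifyPatients:
    def test_single_group3_contact(self):
        _, _, cls = _classify([contact(dx=["DS730"])])
        det = cls[0].detected_at_step
        assert [det[k] for k in (1, 2, 3, 4, 5)] == [False, False, True, True, True]

    def test_no_contacts(self):
        _, _, cls = _classify([])
        assert not any(cls[0].detected_at_step.values())

    def test_group1_detected_everywhere(self):
        _, _, cls = _classify([contact(dx=["DT840"], procs=["KNFH20"])])
        assert all(cls[0].detected_at_step[k] for k in (1, 2, 3, 4, 5, "4A", "5A"))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["DT840", "DS730", "DS320", "DM160"]),
                st.booleans(),  # carries KNFH20?
                st.sampled_from(["left", "right", "unknown"]),
                st.booleans(),  # acute?
            ),
            max_size=6,
        )
    )
    def test_detection_monotone_over_steps(self, specs):
        contacts = [
            contact(
                cid=f"C{i}",
                dx=[dx],
                procs=["KNFH20"] if proc else [],
                side=side,
                admission_type="acute" if acute else "elective",
                setting="inpatient" if acute else "outpatient_clinic",
            )
            for i, (dx, proc, side, acute) in enumerate(specs)
        ]
        _, _, cls = _classify(contacts)
        det = cls[0].detected_at_step
        for a, b in zip((1, 2, 3, 4), (2, 3, 4, 5)):
            assert det[b] or not det[a]


class TestReviewAdjust:
    def test_group4_false_positive_removed_at_4a(self):
        _, _, cls = _classify([contact(dx=["DS730"], side="unknown")])
        review_adjust(cls, [], "4A")
        det = cls[0].detected_at_step
        assert det[4] and not det["4A"]

    def test_group4_true_positive_kept(self):
        _, _, cls = _classify([contact(dx=["DS730"], side="unknown")])
        review_adjust(cls, [event(day=10)], "4A")
        assert cls[0].detected_at_step["4A"]

    def test_group2_false_positive_untouched(self):
        _, _, cls = _classify([contact(dx=["DS320"], procs=["KNFH20"])])
        review_adjust(cls, [], "4A")
        review_adjust(cls, [], "5A")
        det = cls[0].detected_at_step
        assert det["4A"] and det["5A"]

    def test_group5_false_positive_removed_at_5a_only(self):
        _, _, cls = _classify([contact(dx=["DT840"])])
        review_adjust(cls, [], "4A")
        review_adjust(cls, [], "5A")
        det = cls[0].detected_at_step
        assert det[5] and det["4A"] == det[4] and not det["5A"]

    def test_5a_requires_4a_first(self):
        _, _, cls = _classify([contact(dx=["DT840"])])
        with pytest.raises(DislokitError):
            review_adjust(cls, [], "5A")

    @given(st.data())
    def test_review_never_changes_true_positives(self, data):
        n = data.draw(st.integers(1, 5))
        records, contacts, truth = [], [], []
        for i in range(n):
            pid = f"P{i}"
            records.append(tha(pid=pid))
            group_dx = data.draw(
                st.sampled_from([["DT840"], ["DS730"], ["DM160"], []]), label=pid
            )
            side = data.draw(st.sampled_from(["left", "unknown"]))
            if group_dx:
                contacts.append(contact(pid=pid, cid=f"C{i}", dx=group_dx, side=side))
            if data.draw(st.booleans()):
                truth.append(event(pid=pid, eid=f"E{i}", day=10))
        cohort = build_cohort(records)
        windowed = window_contacts(cohort, contacts)
        cls = classify_patients(cohort, windowed)
        before = {c.patient_id: dict(c.detected_at_step) for c in cls}
        review_adjust(cls, truth, "4A")
        review_adjust(cls, truth, "5A")
        positives = {e.patient_id for e in truth}
        for c in cls:
            # sensitivity unchanged: positives keep their status at 4A/5A
            if c.patient_id in positives:
                assert c.detected_at_step["4A"] == before[c.patient_id][4]
                assert c.detected_at_step["5A"] == before[c.patient_id][5]
            # review only ever turns a positive call off, never on
            assert c.detected_at_step["4A"] <= before[c.patient_id][4]
            assert c.detected_at_step["5A"] <= before[c.patient_id][5]


class TestClassifyEvents:
    def test_one_of_two_events_detected(self):
        truth = [event(eid="E1", day=10), event(eid="E2", day=100)]
        cohort, windowed, cls = _classify([contact(dx=["DT840"], procs=["KNFH20"], day=10)])
        dets = classify_events(truth, cls, windowed)
        by_id = {d.event_id: d for d in dets}
        assert by_id["E1"].detected_at_step[1]
        assert not by_id["E2"].detected_at_step[5]

    def test_contact_ten_days_away_does_not_match(self):
        truth = [event(day=10)]
        _, windowed, cls = _classify([contact(dx=["DT840"], procs=["KNFH20"], day=20)])
        dets = classify_events(truth, cls, windowed)
        assert not dets[0].detected_at_step[1]

    @pytest.mark.parametrize("offset,detected", [(-1, True), (1, True), (2, False)])
    def test_match_window_is_one_day(self, offset, detected):
        truth = [event(day=10)]
        _, windowed, cls = _classify(
            [contact(dx=["DT840"], procs=["KNFH20"], day=10 + offset)]
        )
        dets = classify_events(truth, cls, windowed)
        assert dets[0].detected_at_step[1] is detected

    def test_tie_breaks_to_earlier_event(self):
        truth = [event(eid="E1", day=9), event(eid="E2", day=11)]
        _, windowed, cls = _classify([contact(dx=["DT840"], procs=["KNFH20"], day=10)])
        dets = {d.event_id: d for d in classify_events(truth, cls, windowed)}
        assert dets["E1"].detected_at_step[1]
        assert not dets["E2"].detected_at_step[1]

    def test_contact_matches_at_most_one_event(self):
        # one qualifying contact, two same-window events: only one detected
        truth = [event(eid="E1", day=10), event(eid="E2", day=10)]
        _, windowed, cls = _classify([contact(dx=["DT840"], procs=["KNFH20"], day=10)])
        dets = classify_events(truth, cls, windowed)
        assert sum(d.detected_at_step[1] for d in dets) == 1

    def test_patient_detection_implies_event_detection_for_same_day_contacts(self):
        # generator-style data: every event has a same-day coded contact
        truth = [event(eid="E1", day=10), event(eid="E2", day=50)]
        contacts = [
            contact(cid="C1", dx=["DS730"], day=10),
            contact(cid="C2", dx=["DS730"], day=50),
        ]
        _, windowed, cls = _classify(contacts)
        dets = classify_events(truth, cls, windowed)
        for k in (3, 4, 5):
            assert cls[0].detected_at_step[k]
            assert any(d.detected_at_step[k] for d in dets)
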