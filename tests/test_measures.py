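"""Dyadic rate measures, sequence assembly, repertoire filter, kappa."""

import datetime as dt
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chimpnet as cn
from chimpnet.measures import (
    DyadCounts,
    MAX_SEQUENCE_GAP_S,
    assemble_sequences,
    cohens_kappa,
    count_sequences,
    dyadic_association,
    dyadic_communication,
    dyadic_grooming,
    repertoire_filter,
)
from chimpnet.records import CommEvent, ScanRecord

T0 = dt.datetime(2008, 3, 1, 7, 0)


def scan(focal, party, within10, grooming="none", partner=None, idx=1, minutes=0):
    return ScanRecord(
        focal_id=focal,
        follow_id=f"{focal}-f1",
        scan_index=idx,
        timestamp=T0 + dt.timedelta(minutes=minutes),
        party_ids=frozenset(party),
        within10_ids=frozenset(within10),
        grooming=grooming,
        grooming_partner=partner,
    )


def gesture(eid, sec, signaller="A", recipient="B", goal="g", context="c",
            category="Greeting", gtype=None, flags=(True, False, False, False, False)):
    return CommEvent(
        event_id=eid,
        timestamp=T0 + dt.timedelta(seconds=sec),
        signaller_id=signaller,
        recipient_ids=frozenset({recipient}),
        category=category,
        gesture_type=gtype,
        goal=goal,
        context=context,
        intentionality_flags=flags,
    )


class TestCountDyads:
    def test_single_scan_party_and_proximity(self):
        counts = cn.count_dyads([scan("A", {"B"}, {"B"})])
        assert counts.p10[("A", "B")] == 1 and counts.psp[("A", "B")] == 1

    def test_single_scan_party_only(self):
        counts = cn.count_dyads([scan("A", {"B"}, set())])
        assert counts.p10[("A", "B")] == 0 and counts.psp[("A", "B")] == 1

    def test_nine_scan_follow_counts(self):
        scans = [
            scan("A", {"B"}, {"B"} if i < 5 else set(), idx=i + 1, minutes=2 * i)
            for i in range(9)
        ]
        counts = cn.count_dyads(scans)
        assert counts.p10[("A", "B")] == 5 and counts.psp[("A", "B")] == 9

    def test_grooming_counts_split_by_category(self):
        scans = [
            scan("A", {"B"}, {"B"}, "given", "B", idx=1),
            scan("A", {"B"}, {"B"}, "mutual", "B", idx=2, minutes=2),
        ]
        counts = cn.count_dyads(scans)
        assert counts.grooming["given"][("A", "B")] == 1
        assert counts.grooming["mutual"][("A", "B")] == 1
        assert counts.grooming["received"][("A", "B")] == 0


class TestAssociation:
    def test_maximum_sixty_minutes_per_hour(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.p10[("A", "B")] = 9
        c.psp[("A", "B")] = 9
        assert dyadic_association(c, "A", "B") == 60.0

    def test_zero_proximity_gives_zero(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.psp[("A", "B")] = 9
        assert dyadic_association(c, "A", "B") == 0.0

    def test_hand_computed_value(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.p10[("A", "B")] = 5
        c.psp[("A", "B")] = 12
        assert dyadic_association(c, "A", "B") == 25.0

    def test_never_co_present_is_missing_not_zero(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        assert math.isnan(dyadic_association(c, "A", "B"))

    def test_kin_restriction_and_oestrus_restriction(self):
        c = DyadCounts(ids=("A", "B", "C"), focal_ids=("A",))
        for b in ("B", "C"):
            c.p10[("A", b)] = 3
            c.psp[("A", b)] = 6
        kin = {frozenset({"A", "B"})}
        assert dyadic_association(c, "A", "B", kin_pairs=kin) == 30.0
        assert math.isnan(dyadic_association(c, "A", "C", kin_pairs=kin))
        assert math.isnan(dyadic_association(c, "A", "B", oestrous_ids={"C"}))
        assert dyadic_association(c, "A", "B", oestrous_ids={"A"}) == 30.0

    @given(st.integers(1, 50), st.integers(0, 50), st.integers(2, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_duplicating_every_scan(self, psp, p10_raw, k):
        p10 = min(p10_raw, psp)
        c1 = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c1.p10[("A", "B")] = p10
        c1.psp[("A", "B")] = psp
        ck = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        ck.p10[("A", "B")] = p10 * k
        ck.psp[("A", "B")] = psp * k
        assert dyadic_association(c1, "A", "B") == pytest.approx(
            dyadic_association(ck, "A", "B")
        )
        assert 0.0 <= dyadic_association(c1, "A", "B") <= 60.0


class TestGrooming:
    def test_bound_and_zero(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.p10[("A", "B")] = 4
        c.psp[("A", "B")] = 4
        c.grooming["mutual"][("A", "B")] = 4
        assert dyadic_grooming(c, "A", "B", "mutual") == 60.0
        assert dyadic_grooming(c, "A", "B", "given") == 0.0

    def test_hand_computed_value(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.p10[("A", "B")] = 6
        c.psp[("A", "B")] = 6
        c.grooming["given"][("A", "B")] = 2
        assert dyadic_grooming(c, "A", "B", "given") == 20.0

    def test_no_proximity_is_missing(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.psp[("A", "B")] = 3
        assert math.isnan(dyadic_grooming(c, "A", "B", "given"))

    def test_unknown_category_rejected(self):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        with pytest.raises(ValueError):
            dyadic_grooming(c, "A", "B", "tickling")


class TestSequences:
    def test_gaps_within_30s_join_one_sequence(self):
        events = [gesture("e1", 0), gesture("e2", 10), gesture("e3", 30)]
        seqs = assemble_sequences(events)
        assert len(seqs) == 1 and len(seqs[0]) == 3

    def test_gap_of_exactly_30s_joins_but_31_splits(self):
        assert len(assemble_sequences([gesture("e1", 0), gesture("e2", 30)])) == 1
        assert len(assemble_sequences([gesture("e1", 0), gesture("e2", 31)])) == 2

    def test_alternating_recipients_split_every_time(self):
        events = [
            gesture("e1", 0, recipient="B"),
            gesture("e2", 5, recipient="C"),
            gesture("e3", 10, recipient="B"),
            gesture("e4", 15, recipient="C"),
        ]
        assert len(assemble_sequences(events)) == 4

    def test_goal_or_context_change_splits(self):
        assert len(assemble_sequences([gesture("e1", 0, goal="g1"),
                                       gesture("e2", 5, goal="g2")])) == 2
        assert len(assemble_sequences([gesture("e1", 0, context="c1"),
                                       gesture("e2", 5, context="c2")])) == 2

    def test_partition_property_on_generated_data(self, default_dataset):
        _attrs, _model, _scans, events = default_dataset
        gestures = [e for e in events if e.is_gesture]
        seqs = assemble_sequences(events)
        assert sum(len(s) for s in seqs) == len(gestures)
        ids = [eid for s in seqs for eid in s.event_ids]
        assert len(ids) == len(set(ids))

    def test_assembly_is_idempotent_under_reordering(self, default_dataset):
        _attrs, _model, _scans, events = default_dataset
        seqs1 = assemble_sequences(events[:500])
        seqs2 = assemble_sequences(list(reversed(events[:500])))
        key = lambda s: (s.signaller_id, s.start, tuple(s.event_ids))
        assert sorted(map(key, seqs1)) == sorted(map(key, seqs2))


class TestCommunication:
    def _counts(self, p10):
        c = DyadCounts(ids=("A", "B"), focal_ids=("A",))
        c.p10[("A", "B")] = p10
        c.psp[("A", "B")] = p10
        return c

    def test_unit_check_one_sequence_per_proximity_hour(self):
        comm = {"Greeting": Counter({("A", "B"): 1})}
        assert dyadic_communication(comm, self._counts(30), "A", "B", "Greeting") == 1.0

    def test_zero_sequences(self):
        assert dyadic_communication({}, self._counts(30), "A", "B", "Greeting") == 0.0

    def test_hand_computed_value(self):
        comm = {"Greeting": Counter({("A", "B"): 4})}
        assert dyadic_communication(comm, self._counts(6), "A", "B", "Greeting") == 20.0

    def test_missing_when_no_proximity(self):
        assert math.isnan(
            dyadic_communication({}, self._counts(0), "A", "B", "Greeting")
        )

    def test_pant_hoot_counts_each_co_recipient_once_per_event(self):
        hoot = CommEvent(
            event_id="h1",
            timestamp=T0,
            signaller_id="A",
            recipient_ids=frozenset({"B", "C", "D"}),
            category="Synchronized high-intensity pant-hoot",
        )
        comm = count_sequences([], [hoot])
        ctr = comm["Synchronized high-intensity pant-hoot"]
        assert ctr[("A", "B")] == ctr[("A", "C")] == ctr[("A", "D")] == 1


class TestRepertoireFilter:
    def _cases(self, gtype, n, n_flagged):
        return [
            gesture(f"e{i}", i * 60, gtype=gtype,
                    flags=(i < n_flagged, False, False, False, False))
            for i in range(n)
        ]

    def test_sixty_percent_boundary_inclusive(self):
        assert repertoire_filter(self._cases("t", 10, 6)) == {"t"}
        assert repertoire_filter(self._cases("t", 10, 5)) == set()

    def test_two_thirds_admitted(self):
        assert repertoire_filter(self._cases("t", 3, 2)) == {"t"}

    def test_type_without_cases_warns_and_is_excluded(self):
        cases = self._cases("seen", 3, 3)
        with pytest.warns(UserWarning, match="unseen"):
            admitted = repertoire_filter(cases, candidate_types={"seen", "unseen"})
        assert admitted == {"seen"}


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(list("aabb"), list("aabb")) == 1.0

    def test_chance_level_agreement_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.choice(["x", "y"], size=20000).tolist()
        b = rng.choice(["x", "y"], size=20000).tolist()
        assert abs(cohens_kappa(a, b)) < 0.03

    def test_hand_computed_from_confusion_counts(self):
        # confusion [[20, 5], [10, 15]]: p_o=0.7, p_e=0.5 -> kappa=0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.4)

    def test_matches_reference_implementation(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(1)
        a = rng.choice(["x", "y", "z"], size=200, p=[0.5, 0.3, 0.2]).tolist()
        b = [v if rng.random() < 0.7 else rng.choice(["x", "y", "z"]) for v in a]
        assert cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_undefined_when_both_coders_constant(self):
        assert math.isnan(cohens_kappa(["a", "a"], ["a", "a"]))

    def test_length_mismatch_and_short_input_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            cohens_kappa(["a"], ["a"])


def test_rates_bounded_on_generated_data(default_counts):
    counts = default_counts
    prox = cn.association_matrix(counts)
    vals = prox.offdiag_values()
    assert vals.min() >= 0.0 and vals.max() <= 60.0
    for cat in ("given", "received", "mutual"):
        gv = cn.grooming_matrix(counts, cat).offdiag_values()
        assert gv.min() >= 0.0 and gv.max() <= 60.0
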