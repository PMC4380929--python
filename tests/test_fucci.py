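"""Fucci track classification, event calling and population statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hepg1s.fucci import (
    PHASES,
    PhaseThresholds,
    classify_phase,
    cumulative_transition_curve,
    derive_thresholds,
    detect_transitions,
    filter_fields,
    snapshot_fractions,
)
from hepg1s.synth import HillSpec, TrackGeneratorSpec, generate_tracks

THR = PhaseThresholds(rfp=50.0, yfp=40.0)


def _track(rfp, yfp, dt=0.25, cell=0):
    n = len(rfp)
    return pd.DataFrame(
        {"cell_id": cell, "field_id": 0, "time_h": np.arange(n) * dt,
         "rfp": rfp, "yfp": yfp}
    )


class TestThresholds:
    def test_identical_intensities_collapse_both_thresholds(self):
        t = _track([3.0] * 10, [3.0] * 10)
        thr = derive_thresholds(t)
        assert thr.rfp == thr.yfp == 3.0

    def test_known_mixture_percentiles(self):
        rfp = np.arange(1.0, 101.0)
        yfp = np.arange(1.0, 101.0)
        t = _track(rfp, yfp)
        thr = derive_thresholds(t, rfp_percentile=10, yfp_percentile=95)
        assert thr.rfp == pytest.approx(np.percentile(rfp, 10))
        assert thr.yfp == pytest.approx(np.percentile(yfp, 95))

    def test_unstimulated_reference_classifies_mostly_g1(self):
        ref = generate_tracks(
            TrackGeneratorSpec(n_cells=60, dose=0.0, responder_hill=HillSpec(amp=0.0),
                               seed=31)
        )
        thr = derive_thresholds(ref)
        fractions = snapshot_fractions(ref, thr, window=(0.0, 60.0))
        assert fractions["G1"] >= 90.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            derive_thresholds(pd.DataFrame(columns=["rfp", "yfp"]))


class TestClassification:
    @pytest.mark.parametrize(
        "rfp,yfp,phase",
        [
            (90.0, 5.0, "G1"),
            (90.0, 90.0, "G1/S"),
            (5.0, 90.0, "S/G2/M"),
            (5.0, 5.0, "earlyG1"),
            (50.0, 40.0, "G1/S"),  # at-threshold counts as high on both axes
        ],
    )
    def test_quadrant_rule(self, rfp, yfp, phase):
        t = _track([rfp], [yfp])
        assert classify_phase(t, THR)[0] == phase

    def test_every_point_gets_exactly_one_phase(self):
        rng = np.random.default_rng(0)
        t = _track(rng.uniform(0, 100, 200), rng.uniform(0, 100, 200))
        phases = classify_phase(t, THR)
        assert set(phases) <= set(PHASES)
        assert phases.size == 200


class TestTransitionCaller:
    def test_all_g1_has_no_events(self):
        assert detect_transitions(np.array(["G1"] * 20, dtype=object)) == []

    def test_minimal_four_plus_four_pattern(self):
        phases = np.array(["G1/S"] * 4 + ["S/G2/M"] * 4, dtype=object)
        assert detect_transitions(phases) == [4]

    def test_short_excursion_not_called(self):
        phases = np.array(
            ["G1"] * 4 + ["G1/S"] * 3 + ["G1"] * 5 + ["G1/S"] * 4 + ["S/G2/M"] * 3,
            dtype=object,
        )
        assert detect_transitions(phases) == []

    def test_exhaustive_agreement_with_bruteforce_oracle(self):
        """Compare against direct enumeration over every phase string of
        length 8 (the 4+4 window size)."""

        def oracle(phases, r=4):
            events = []
            n = len(phases)
            for i in range(n):
                ok = (
                    i - r >= 0
                    and i + r <= n
                    and all(p == "G1/S" for p in phases[i - r:i])
                    and all(p == "S/G2/M" for p in phases[i:i + r])
                )
                if ok:
                    events.append(i)
            return events

        for combo in itertools.product(PHASES, repeat=8):
            phases = np.array(combo, dtype=object)
            assert detect_transitions(phases) == oracle(list(combo)), combo


class TestCumulativeCurves:
    def test_no_events_flat_zero(self):
        t = _track([90.0] * 30, [5.0] * 30)
        curve = cumulative_transition_curve(t, THR)
        assert (curve["cumulative_events"] == 0).all()
        assert (curve["cells_transitioned"] == 0).all()

    def test_hand_built_three_track_fixture(self):
        def phases_to_track(phases, cell):
            rfp = [90.0 if p in ("G1", "G1/S") else 5.0 for p in phases]
            yfp = [90.0 if p in ("G1/S", "S/G2/M") else 5.0 for p in phases]
            return _track(rfp, yfp, cell=cell)

        a = phases_to_track(["G1"] * 2 + ["G1/S"] * 4 + ["S/G2/M"] * 6, cell=0)  # event @ t=1.5h
        b = phases_to_track(["G1"] * 12, cell=1)  # no event
        c = phases_to_track(["G1/S"] * 4 + ["S/G2/M"] * 4 + ["G1/S"] * 4, cell=2)  # event @ t=1h
        tracks = pd.concat([a, b, c], ignore_index=True)
        curve = cumulative_transition_curve(tracks, THR)
        at = lambda t: curve[curve["time_h"] == t].iloc[0]  # noqa: E731
        assert at(0.75)["cumulative_events"] == 0
        assert at(1.0)["cumulative_events"] == 1
        assert at(1.5)["cumulative_events"] == 2
        assert at(2.75)["cells_transitioned"] == 2

    def test_all_responders_plateau_at_n_cells(self):
        spec = TrackGeneratorSpec(
            n_cells=12, dose=40.0, responder_hill=HillSpec(base=1.0, amp=0.0),
            channel_noise_sd=0.0, seed=17,
        )
        tracks = generate_tracks(spec)
        curve = cumulative_transition_curve(tracks, THR)
        assert curve["cells_transitioned"].iloc[-1] == 12

    def test_curves_non_decreasing(self):
        spec = TrackGeneratorSpec(n_cells=25, dose=40.0, seed=19)
        curve = cumulative_transition_curve(generate_tracks(spec), THR)
        assert (curve["cumulative_events"].diff().dropna() >= 0).all()
        assert (curve["cells_transitioned"].diff().dropna() >= 0).all()
        assert curve["cells_transitioned"].iloc[-1] <= 25


class TestSnapshot:
    def test_pure_sgm_window_is_hundred_percent(self):
        t = _track([5.0] * 300, [90.0] * 300, dt=0.25)
        out = snapshot_fractions(t, THR, window=(42.0, 54.0))
        assert out["S/G2/M"] == pytest.approx(100.0)

    def test_counting_fixture_three_of_twelve(self):
        rfp = [5.0] * 3 + [90.0] * 9
        yfp = [90.0] * 3 + [5.0] * 9
        t = _track(rfp, yfp, dt=1.0)
        out = snapshot_fractions(t, THR, window=(0.0, 11.0))
        assert out["S/G2/M"] == pytest.approx(25.0)
        assert out["G1"] == pytest.approx(75.0)

    def test_percentages_partition(self):
        rng = np.random.default_rng(23)
        t = _track(rng.uniform(0, 100, 400), rng.uniform(0, 100, 400))
        out = snapshot_fractions(t, THR, window=(0.0, 100.0))
        assert sum(out.values()) == pytest.approx(100.0)

    def test_empty_window_rejected(self):
        t = _track([1.0] * 10, [1.0] * 10)
        with pytest.raises(ValueError):
            snapshot_fractions(t, THR, window=(500.0, 600.0))


class TestFieldFilter:
    @pytest.mark.parametrize(
        "seeded,infected,included",
        [
            (9, 5, False),   # below seeding range
            (10, 5, True),   # boundaries inclusive
            (50, 5, True),
            (51, 5, False),  # above seeding range
            (30, 4, False),  # too few infected
            (30, 5, True),
        ],
    )
    def test_inclusion_rules(self, seeded, infected, included):
        df = pd.DataFrame({"field_id": [1], "seeded": [seeded], "infected": [infected]})
        assert (filter_fields(df) == [1]) is included

    def test_negative_counts_rejected(self):
        df = pd.DataFrame({"field_id": [1], "seeded": [-1], "infected": [5]})
        with pytest.raises(ValueError):
            filter_fields(df)
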