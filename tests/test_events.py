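"""Event classification, artifact flagging and per-frame statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from recascan.events import (
    FrameOutcome,
    JointMeasurement,
    SamplingEvent,
    classify_event,
    events_from_tsv,
    events_to_tsv,
    flag_dislocations,
    joint_stats,
    joints_from_tsv,
    joints_to_tsv,
    outcome_proportions,
    outcomes_from_tsv,
    outcomes_to_tsv,
    position_histogram,
)


class TestClassification:
    def test_short_dwell_is_transient(self):
        assert classify_event(3.0) == "transient"

    def test_boundary_dwell_is_stable(self):
        # "no more than 10 s" is ambiguous at the boundary; strict-less chosen
        assert classify_event(10.0) == "stable"
        assert classify_event(9.999) == "transient"

    def test_threshold_configurable(self):
        assert classify_event(10.0, threshold=20.0) == "transient"

    def test_negative_dwell_raises(self):
        with pytest.raises(ValueError):
            classify_event(-1.0)

    def test_exponential_transient_fraction_matches_cdf(self):
        # dwell ~ Exp(mean 4 s): P(transient) = 1 - exp(-10/4)
        rng = np.random.default_rng(0)
        n = 1000
        dwells = rng.exponential(4.0, size=n)
        frac = np.mean([classify_event(d) == "transient" for d in dwells])
        p = 1.0 - math.exp(-10.0 / 4.0)
        assert abs(frac - p) <= 4.0 * math.sqrt(p * (1 - p) / n)

    def test_event_kind_derived_and_exclusive(self):
        ev = SamplingEvent(frame_id=0, onset_s=0, dwell_s=3.0, position_nm=10.0)
        assert ev.kind == "transient"
        ev2 = SamplingEvent(frame_id=0, onset_s=0, dwell_s=30.0, position_nm=10.0)
        assert ev2.kind == "stable"


class TestDislocationFlags:
    def test_constructed_spike_flagged(self):
        track = [20.0] * 5 + [35.0] + [20.0] * 5
        flags = flag_dislocations(track, jump_threshold=8.0)
        assert flags.sum() == 1 and flags[5]

    def test_monotone_drift_not_flagged(self):
        track = [10.0 + 0.5 * i for i in range(30)]
        assert not flag_dislocations(track, jump_threshold=8.0).any()

    def test_planted_spikes_recovered_exactly(self):
        # 100 noisy tracks with one planted 15 nm spike each: every spike
        # found, nothing else flagged (sensitivity 1, FPR 0 at 1 nm noise)
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = 40
            track = 19.0 + rng.normal(0, 1.0, size=n)
            k = int(rng.integers(1, n - 1))
            track[k] += 15.0
            flags = flag_dislocations(track, jump_threshold=8.0)
            assert flags[k]
            assert flags.sum() == 1

    def test_idempotent_and_time_reversal_invariant(self):
        rng = np.random.default_rng(1)
        track = 19.0 + rng.normal(0, 1.0, size=25)
        track[7] += 20.0
        f = flag_dislocations(track)
        assert np.array_equal(f, flag_dislocations(track))  # pure function
        assert np.array_equal(f[::-1], flag_dislocations(track[::-1]))

    def test_short_track_raises(self):
        with pytest.raises(ValueError):
            flag_dislocations([1.0, 2.0])


def _events_at(positions_nt, dwell=1.0):
    return [
        SamplingEvent(frame_id=i, onset_s=0.0, dwell_s=dwell, position_nm=0.0,
                      position_nt=int(p))
        for i, p in enumerate(positions_nt)
    ]


class TestHistogram:
    def test_empty_all_zero(self):
        h = position_histogram([], bin_width=1)
        assert (h["count"] == 0).all()
        assert len(h) == 128

    def test_peak_recovered(self):
        rng = np.random.default_rng(5)
        nts = np.clip(np.round(rng.normal(55, 2, size=300)), 1, 128).astype(int)
        h = position_histogram(_events_at(nts), bin_width=3)
        top = h.loc[h["count"].idxmax()]
        assert top.bin_start <= 55 <= top.bin_end

    @pytest.mark.parametrize("bin_width", [1, 2, 5, 7])
    def test_count_conservation(self, bin_width):
        rng = np.random.default_rng(9)
        nts = rng.integers(1, 129, size=137)
        h = position_histogram(_events_at(nts), bin_width=bin_width)
        assert h["count"].sum() == 137

    def test_out_of_range_clipped_with_warning(self, caplog):
        evs = _events_at([200])
        with caplog.at_level("WARNING"):
            h = position_histogram(evs)
        assert h["count"].sum() == 1
        assert h.loc[h["bin_start"] == 128, "count"].iloc[0] == 1
        assert "clipped" in caplog.text

    def test_nm_positions_mapped_via_geometry(self):
        # 18.7 nm along the strand lies in nt 55
        ev = SamplingEvent(frame_id=0, onset_s=0, dwell_s=1.0, position_nm=18.7)
        h = position_histogram([ev])
        assert h.loc[h["bin_start"] == 55, "count"].iloc[0] == 1


class TestJointStats:
    def test_single_boundary_joint(self):
        j = JointMeasurement(frame_id=0, timepoint_s=0, length_nm=10.2,
                             position_nm=18.0)
        s = joint_stats([j], bounds=(10.2, 15.3))
        assert s["mean"] == pytest.approx(10.2)
        assert s["fraction_in_range"] == 1.0
        assert s["fraction_below_lower"] == 0.0

    def test_all_below_lower(self):
        joints = [JointMeasurement(i, 0, 5.0, 18.0) for i in range(10)]
        s = joint_stats(joints, bounds=(10.2, 15.3))
        assert s["fraction_below_lower"] == 1.0
        assert s["fraction_in_range"] == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            joint_stats([])

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            JointMeasurement(0, 0, -1.0, 0.0)


class TestOutcomeProportions:
    def test_reported_population_split(self):
        # counts reproducing the published percentages at n=514
        counts = {"homologous": 270, "heterologous": 38, "none": 24,
                  "unclassified": 182}
        assert sum(counts.values()) == 514
        outcomes = []
        i = 0
        for cat, k in counts.items():
            for _ in range(k):
                outcomes.append(FrameOutcome(frame_id=i, category=cat))
                i += 1
        df = outcome_proportions(outcomes).set_index("category")
        assert df.loc["homologous", "proportion"] * 100 == pytest.approx(52.5, abs=0.1)
        assert df.loc["heterologous", "proportion"] * 100 == pytest.approx(7.4, abs=0.1)
        assert df.loc["none", "proportion"] * 100 == pytest.approx(4.6, abs=0.1)
        assert df.loc["unclassified", "proportion"] * 100 == pytest.approx(35.5, abs=0.1)
        assert df["proportion"].sum() == pytest.approx(1.0)
        # pooled binomial SE for the homologous class ~ 2.2 points
        assert df.loc["homologous", "se_binomial"] == pytest.approx(
            math.sqrt(0.525 * 0.475 / 514), rel=0.05)

    def test_single_category(self):
        outcomes = [FrameOutcome(i, "homologous") for i in range(20)]
        df = outcome_proportions(outcomes).set_index("category")
        assert df.loc["homologous", "proportion"] == 1.0
        assert df.loc["homologous", "se_binomial"] == 0.0

    def test_monte_carlo_sd_matches_binomial_se(self):
        # multinomial at the reported rates: across replicate draws of
        # n=514 the spread of the homologous proportion is the binomial SE
        rng = np.random.default_rng(7)
        probs = (0.525, 0.074, 0.046, 0.355)
        phats = []
        for _ in range(200):
            draw = rng.multinomial(514, probs)
            phats.append(draw[0] / 514)
        se_emp = float(np.std(phats, ddof=1))
        se_theory = math.sqrt(probs[0] * (1 - probs[0]) / 514)
        assert abs(se_emp - se_theory) / se_theory <= 0.15

    def test_replicate_sd_reported(self):
        rng = np.random.default_rng(3)
        outcomes = [
            FrameOutcome(i, rng.choice(["homologous", "none"]),
                         replicate=f"rep{i % 3}")
            for i in range(90)
        ]
        df = outcome_proportions(outcomes).set_index("category")
        assert np.isfinite(df.loc["homologous", "sd_replicates"])

    def test_exclude_unclassified_convention(self):
        outcomes = (
            [FrameOutcome(i, "homologous") for i in range(50)]
            + [FrameOutcome(100 + i, "unclassified") for i in range(50)]
        )
        incl = outcome_proportions(outcomes).set_index("category")
        excl = outcome_proportions(outcomes, exclude_unclassified=True
                                   ).set_index("category")
        assert incl.loc["homologous", "proportion"] == 0.5
        assert excl.loc["homologous", "proportion"] == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            outcome_proportions([])


class TestTablesIO:
    def test_event_table_round_trip(self, tmp_path):
        evs = [
            SamplingEvent(1, 0.0, 3.0, 18.7).with_position_nt(),
            SamplingEvent(2, 5.0, 30.0, 5.1, target_label="Control"),
        ]
        path = tmp_path / "events.tsv"
        events_to_tsv(evs, path)
        back = events_from_tsv(path)
        assert back == [evs[0], evs[1]]

    def test_joint_table_round_trip(self, tmp_path):
        joints = [JointMeasurement(0, 1.0, 11.1, 18.0)]
        path = tmp_path / "joints.tsv"
        joints_to_tsv(joints, path)
        assert joints_from_tsv(path) == joints

    def test_outcome_table_round_trip(self, tmp_path):
        outcomes = [FrameOutcome(0, "homologous", replicate="a"),
                    FrameOutcome(1, "none")]
        path = tmp_path / "outcomes.tsv"
        outcomes_to_tsv(outcomes, path)
        assert outcomes_from_tsv(path) == outcomes

    def test_unit_header_validated(self, tmp_path):
        path = tmp_path / "events.tsv"
        events_to_tsv([SamplingEvent(0, 0.0, 1.0, 2.0)], path)
        text = path.read_text().replace("position_nm=nm", "position_nm=um")
        path.write_text(text)
        with pytest.raises(ValueError, match="unit"):
            events_from_tsv(path)
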