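"""Quality filter, repeat removal and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanocoloc.exceptions import ConfigurationError
from nanocoloc.filtering import (
    QualityThresholds,
    apply_quality_filter,
    remove_repeated_localizations,
)

from _oracles import brute_chain_removal
from conftest import make_table, random_table

THRESHOLDS = QualityThresholds()


class TestQualityFilter:
    @pytest.mark.parametrize(
        "channel, precision, photons, kept",
        [
            ("GluA1", 31.0, 1000, False),  # precision strictly above 30
            ("GluA1", 30.0, 1000, True),  # boundary retained
            ("PSD95", 26.0, 1000, False),  # scaffold channel cut at 25
            ("PSD95", 25.0, 1000, True),
            ("GluA1", 20.0, 299, False),  # photons strictly below 300
            ("GluA1", 20.0, 300, True),
            ("GluA1", 20.0, 30_000, True),
            ("GluA1", 20.0, 30_001, False),
        ],
    )
    def test_strict_boundaries(self, channel, precision, photons, kept):
        table = make_table([[0, 0]], precision=precision, photons=photons, channel=channel)
        out, report = apply_quality_filter(table, THRESHOLDS)
        assert (len(out) == 1) is kept
        assert report.n_in == report.n_out + report.removed

    def test_empty_table(self):
        out, report = apply_quality_filter(make_table(np.zeros((0, 2))), THRESHOLDS)
        assert len(out) == 0
        assert report.as_dict() == {
            "n_in": 0,
            "removed_precision": 0,
            "removed_photons": 0,
            "removed_repeat": 0,
            "n_out": 0,
        }

    def test_channel_without_threshold_errors(self):
        table = make_table([[0, 0]], channel="Homer1")
        with pytest.raises(ConfigurationError, match="Homer1"):
            apply_quality_filter(table, THRESHOLDS)

    def test_order_preserved_and_report_balances(self, rng):
        table = random_table(rng, 500)
        out, report = apply_quality_filter(table, THRESHOLDS)
        report.check()
        assert report.n_in == 500
        # retained records appear in their original relative order
        kept_x = out.records["x_nm"].to_numpy()
        orig_x = table.records["x_nm"].to_numpy()
        assert np.array_equal(kept_x, orig_x[np.isin(orig_x, kept_x)])

    @given(pmax=st.floats(min_value=1, max_value=40))
    @settings(max_examples=25, deadline=None)
    def test_monotonic_in_precision_threshold(self, pmax):
        rng = np.random.default_rng(7)
        table = random_table(rng, 300, channels=("GluA1",))
        loose = QualityThresholds(precision_max_nm={"GluA1": 40.0})
        tight = QualityThresholds(precision_max_nm={"GluA1": float(pmax)})
        n_loose = apply_quality_filter(table, loose)[1].n_out
        n_tight = apply_quality_filter(table, tight)[1].n_out
        assert n_tight <= n_loose

    def test_idempotent(self, rng):
        table = random_table(rng, 400)
        once, _ = apply_quality_filter(table, THRESHOLDS)
        twice, report = apply_quality_filter(once, THRESHOLDS)
        assert report.removed == 0
        pd.testing.assert_frame_equal(twice.records, once.records)


def chain_table(n, dx=0.0, start_frame=1, channel="GluA1"):
    """n localizations in consecutive frames, stepping dx nm along x."""
    xy = np.column_stack([np.arange(n) * dx, np.zeros(n)])
    return make_table(xy, frames=np.arange(start_frame, start_frame + n), channel=channel)


class TestRepeatRemoval:
    def test_consecutive_pair_within_radius(self):
        table = make_table([[0, 0], [50, 0]], frames=[5, 6])
        out, report = remove_repeated_localizations(table)
        assert len(out) == 1
        assert out.records["frame"].tolist() == [5]
        assert report.removed_repeat == 1

    def test_long_chain_removes_initial_too(self):
        out, _ = remove_repeated_localizations(chain_table(12, dx=5.0))
        assert len(out) == 0  # >10 frames: even the seed goes

    def test_ten_frame_chain_keeps_initial(self):
        out, _ = remove_repeated_localizations(chain_table(10, dx=5.0))
        assert len(out) == 1

    def test_eleven_frame_chain_removes_all(self):
        out, _ = remove_repeated_localizations(chain_table(11, dx=5.0))
        assert len(out) == 0

    def test_non_consecutive_frames_kept(self):
        table = make_table([[0, 0], [0, 0]], frames=[5, 8])
        out, _ = remove_repeated_localizations(table, frame_gap=1)
        assert len(out) == 2

    def test_outside_radius_kept(self):
        table = make_table([[0, 0], [70, 0]], frames=[5, 6])
        out, _ = remove_repeated_localizations(table)
        assert len(out) == 2

    def test_channels_are_scanned_independently(self):
        # same positions/frames in two channels never chain across channels
        a = make_table([[0, 0]], frames=5, channel="PSD95")
        b = make_table([[10, 0]], frames=6, channel="GluA1")
        table = make_table(
            np.vstack([a.coords(), b.coords()]),
            frames=[5, 6],
            channel=np.array(["PSD95", "GluA1"], dtype=object),
        )
        out, _ = remove_repeated_localizations(table)
        assert len(out) == 2

    def test_chain_follows_most_recent_member(self):
        # drifting emitter: each step 50 nm, total drift 150 nm from seed
        out, _ = remove_repeated_localizations(chain_table(4, dx=50.0))
        assert len(out) == 1

    def test_idempotent_seed_linking(self, rng):
        # seed-anchored chaining is exactly idempotent on any input
        table = make_table(
            rng.uniform(0, 400, size=(300, 2)),
            frames=rng.integers(0, 40, size=300),
            channel="GluA1",
        )
        once, _ = remove_repeated_localizations(table, link_to="seed")
        twice, report = remove_repeated_localizations(once, link_to="seed")
        assert report.removed_repeat == 0
        pd.testing.assert_frame_equal(twice.records, once.records)

    def test_idempotent_default_on_separated_emitters(self, rng):
        # most-recent-member chaining: idempotent whenever emitters are
        # farther apart than the chaining radius
        xy, frames = [], []
        for i in range(40):
            pos = np.array([(i % 8) * 200.0, (i // 8) * 200.0])
            run = int(rng.integers(1, 15))
            start = int(rng.integers(0, 100))
            for k in range(run):
                xy.append(pos + rng.normal(0, 8, 2))
                frames.append(start + k)
        table = make_table(np.array(xy), frames=np.array(frames), channel="GluA1")
        once, _ = remove_repeated_localizations(table)
        twice, report = remove_repeated_localizations(once)
        assert report.removed_repeat == 0
        pd.testing.assert_frame_equal(twice.records, once.records)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        xy = rng.uniform(0, 600, size=(n, 2))
        frames = rng.integers(0, 60, size=n)
        table = make_table(xy, frames=frames, channel="GluA1")
        out, _ = remove_repeated_localizations(table, radius_nm=60, max_frames=10)
        keep = brute_chain_removal(xy, frames, 60.0, 10, 1)
        expected = table.records[keep].reset_index(drop=True)
        pd.testing.assert_frame_equal(out.records.reset_index(drop=True), expected)
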