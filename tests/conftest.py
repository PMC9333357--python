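"""Shared fixtures and table-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nanocoloc.localization_io import LocalizationTable


def make_table(
    xy: np.ndarray,
    frames=None,
    photons=1000.0,
    precision=10.0,
    channel="PSD95",
    metadata=None,
) -> LocalizationTable:
    """Build a LocalizationTable from coordinates plus broadcastable extras."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    df = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "frame": np.broadcast_to(np.asarray(frames if frames is not None else 0), n).astype(np.int64),
            "photons": np.broadcast_to(np.asarray(photons, dtype=float), n),
            "precision_nm": np.broadcast_to(np.asarray(precision, dtype=float), n),
            "channel": np.broadcast_to(np.asarray(channel, dtype=object), n),
        }
    )
    return LocalizationTable(df, dict(metadata or {}))


def random_table(rng: np.random.Generator, n: int, extent=1000.0, channels=("PSD95", "GluA1")):
    """A random two-channel table for property tests."""
    return make_table(
        rng.uniform(0, extent, size=(n, 2)),
        frames=rng.integers(0, 100, size=n),
        photons=rng.uniform(100, 40_000, size=n),
        precision=rng.uniform(1, 40, size=n),
        channel=rng.choice(list(channels), size=n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
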