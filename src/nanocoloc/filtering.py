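"""Localization quality filters and consecutive-localization (blink) removal.

Two filters are applied to drift-corrected localization tables before any
spatial analysis:

* a quality filter that removes localizations whose fitted precision exceeds
  a per-channel maximum (30 nm for the receptor channel, 25 nm for the
  scaffold channel in the defaults) or whose photon count falls outside
  300–30,000 photons — all with *strict* inequalities, so boundary values
  are retained;
* a repeat filter that removes re-blinking of the same emitter: consecutive
  localizations within 60 nm of each other are chained and all chain members
  after the first are removed; if a chain persists for more than 10 frames
  the initial localization is removed as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .localization_io import LocalizationTable

#: Default precision ceilings for the two endogenous channels.
DEFAULT_PRECISION_MAX = {"GluA1": 30.0, "PSD95": 25.0}


@dataclass(frozen=True)
class QualityThresholds:
    """Thresholds of the localization quality and repeat filters.

    ``precision_max_nm`` maps each channel label to its maximum admissible
    localization precision.  Records are removed only when a threshold is
    *strictly* violated (precision > max, photons < min or > max).
    """

    precision_max_nm: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRECISION_MAX)
    )
    photons_min: float = 300.0
    photons_max: float = 30_000.0
    repeat_radius_nm: float = 60.0
    repeat_max_frames: int = 10
    frame_gap: int = 1

    def __post_init__(self) -> None:
        if not self.photons_min < self.photons_max:
            raise ConfigurationError("photons_min must be < photons_max")
        positive = (
            self.photons_min,
            self.photons_max,
            self.repeat_radius_nm,
            self.repeat_max_frames,
            self.frame_gap,
            *self.precision_max_nm.values(),
        )
        if any(not v > 0 for v in positive):
            raise ConfigurationError("all thresholds must be strictly positive")


@dataclass
class FilterReport:
    """Bookkeeping of one filter pass; ``n_in = n_out + removed``."""

    n_in: int = 0
    removed_precision: int = 0
    removed_photons: int = 0
    removed_repeat: int = 0
    n_out: int = 0

    @property
    def removed(self) -> int:
        return self.removed_precision + self.removed_photons + self.removed_repeat

    def check(self) -> None:
        assert self.n_in == self.n_out + self.removed, "filter report does not balance"

    def as_dict(self) -> dict[str, int]:
        return {
            "n_in": self.n_in,
            "removed_precision": self.removed_precision,
            "removed_photons": self.removed_photons,
            "removed_repeat": self.removed_repeat,
            "n_out": self.n_out,
        }


def apply_quality_filter(
    table: LocalizationTable, thresholds: QualityThresholds
) -> tuple[LocalizationTable, FilterReport]:
    """Remove localizations with too-poor precision or out-of-range photons.

    A record is retained iff ``precision <= precision_max(channel)`` and
    ``photons_min <= photons <= photons_max``.  Record order is preserved.
    A record violating both rules is counted once, under precision.

    Raises
    ------
    ConfigurationError
        If a channel present in the table has no precision threshold.
    """
    df = table.records
    report = FilterReport(n_in=len(df))
    if len(df) == 0:
        return LocalizationTable(df.copy(), dict(table.metadata)), report

    channels = pd.unique(df["channel"])
    missing = [c for c in channels if c not in thresholds.precision_max_nm]
    if missing:
        raise ConfigurationError(
            f"no precision_max threshold for channel(s) {missing}"
        )
    pmax = df["channel"].map(thresholds.precision_max_nm).to_numpy(dtype=float)
    precision_bad = df["precision_nm"].to_numpy(dtype=float) > pmax
    photons = df["photons"].to_numpy(dtype=float)
    photons_bad = (photons < thresholds.photons_min) | (photons > thresholds.photons_max)

    report.removed_precision = int(precision_bad.sum())
    report.removed_photons = int((photons_bad & ~precision_bad).sum())
    keep = ~(precision_bad | photons_bad)
    report.n_out = int(keep.sum())
    report.check()
    return LocalizationTable(df[keep].copy(), dict(table.metadata)), report


def _chain_scan(
    xy: np.ndarray,
    frames: np.ndarray,
    radius: float,
    max_frames: int,
    frame_gap: int,
    link_to: str = "last",
) -> np.ndarray:
    """Boolean keep-mask of the repeat filter for one channel.

    Records are iterated in (frame, original order).  A record joins the
    nearest active chain whose anchor lies within ``radius`` and whose last
    member is within ``frame_gap`` frames, otherwise it seeds a new chain.
    The anchor is the chain's most recent member (``link_to="last"``, the
    default: tracks a slowly wobbling emitter) or its first member
    (``link_to="seed"``: makes the filter exactly idempotent).  Chain
    members after the first are always removed; the first is removed too
    when the chain spans more than ``max_frames`` distinct frames.
    """
    n = len(frames)
    keep = np.ones(n, dtype=bool)
    order = np.lexsort((np.arange(n), frames))

    # active chains: parallel lists of anchor position, last frame, first
    # index, set of distinct frames spanned
    last_xy: list[np.ndarray] = []
    last_frame: list[int] = []
    first_idx: list[int] = []
    frames_spanned: list[set[int]] = []

    for idx in order:
        f = int(frames[idx])
        p = xy[idx]
        # drop expired chains, finalizing their verdicts
        alive = []
        for c in range(len(last_xy)):
            if f - last_frame[c] <= frame_gap:
                alive.append(c)
            else:
                if len(frames_spanned[c]) > max_frames:
                    keep[first_idx[c]] = False
        if len(alive) < len(last_xy):
            last_xy = [last_xy[c] for c in alive]
            last_frame = [last_frame[c] for c in alive]
            first_idx = [first_idx[c] for c in alive]
            frames_spanned = [frames_spanned[c] for c in alive]

        joined = -1
        if last_xy:
            d = np.linalg.norm(np.asarray(last_xy) - p, axis=1)
            within = np.flatnonzero(d <= radius)
            if within.size:
                joined = int(within[np.argmin(d[within])])
        if joined >= 0:
            keep[idx] = False
            if link_to == "last":
                last_xy[joined] = p
            last_frame[joined] = f
            frames_spanned[joined].add(f)
        else:
            last_xy.append(p)
            last_frame.append(f)
            first_idx.append(idx)
            frames_spanned.append({f})

    for c in range(len(last_xy)):
        if len(frames_spanned[c]) > max_frames:
            keep[first_idx[c]] = False
    return keep


def remove_repeated_localizations(
    table: LocalizationTable,
    radius_nm: float = 60.0,
    max_frames: int = 10,
    frame_gap: int = 1,
    link_to: str = "last",
) -> tuple[LocalizationTable, FilterReport]:
    """Remove consecutive re-localizations of the same blinking emitter.

    Chains are built per channel: a localization joins an existing chain when
    it appears within ``radius_nm`` of the chain's anchor (its most recent
    member by default, see ``link_to``) and at most ``frame_gap`` frames
    after the chain's last member.  All chain members after the first are
    removed; when the chain spans more than ``max_frames`` distinct frames,
    the initial localization is removed as well.  Non-chained records pass
    through untouched, in their original order.
    """
    if not (radius_nm > 0 and max_frames >= 1 and frame_gap >= 1):
        raise ConfigurationError("invalid repeat-filter parameters")
    if link_to not in ("last", "seed"):
        raise ConfigurationError("link_to must be 'last' or 'seed'")
    df = table.records
    report = FilterReport(n_in=len(df))
    if len(df) == 0:
        report.n_out = 0
        return LocalizationTable(df.copy(), dict(table.metadata)), report

    keep = np.ones(len(df), dtype=bool)
    for _, sub in df.groupby("channel", sort=False):
        pos = sub.index.to_numpy()
        xy = sub[["x_nm", "y_nm"]].to_numpy(dtype=float)
        frames = sub["frame"].to_numpy(dtype=np.int64)
        keep[pos] = _chain_scan(xy, frames, radius_nm, max_frames, frame_gap, link_to)

    report.removed_repeat = int((~keep).sum())
    report.n_out = int(keep.sum())
    report.check()
    return LocalizationTable(df[keep].copy(), dict(table.metadata)), report


def filter_table(
    table: LocalizationTable, thresholds: QualityThresholds
) -> tuple[LocalizationTable, FilterReport]:
    """Quality filter followed by repeat removal, with a merged report."""
    filtered, rep_q = apply_quality_filter(table, thresholds)
    filtered, rep_r = remove_repeated_localizations(
        filtered,
        radius_nm=thresholds.repeat_radius_nm,
        max_frames=thresholds.repeat_max_frames,
        frame_gap=thresholds.frame_gap,
    )
    merged = FilterReport(
        n_in=rep_q.n_in,
        removed_precision=rep_q.removed_precision,
        removed_photons=rep_q.removed_photons,
        removed_repeat=rep_r.removed_repeat,
        n_out=rep_r.n_out,
    )
    merged.check()
    return filtered, merged
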