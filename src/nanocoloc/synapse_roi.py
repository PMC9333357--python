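"""Synapse ROI segmentation, localization assignment and inclusion filtering.

Synapse regions of interest are outlined on a widefield reference image of
the scaffold channel: around every intensity peak, the ROI is the connected
region above the full-width-half-maximum level (background plus half the
peak's height over background), extracted as a sub-pixel marching-squares
contour and converted to a polygon in nm.  Localizations are then assigned
to ROIs by point-in-polygon membership, and synapses are kept for analysis
only when they carry enough localizations in both channels and their PSD
area falls inside a plausibility window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage import measure
from skimage.feature import peak_local_max

from .exceptions import ConfigurationError
from .localization_io import LocalizationTable, WidefieldImage

log = logging.getLogger(__name__)


@dataclass
class SynapseROI:
    """A synapse outline in nm coordinates."""

    id: int
    boundary: Polygon
    peak_xy_nm: tuple[float, float]
    peak_height: float = 0.0

    @property
    def area_um2(self) -> float:
        return self.boundary.area * 1e-6

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise ValueError(f"ROI {self.id}: boundary polygon invalid or empty")


@dataclass
class SynapseRecord:
    """A synapse ROI with its per-channel localization subsets.

    ``psd_center_nm`` / ``psd_area_um2`` are filled by the nanodomain stage
    (DBSCAN on the scaffold channel); until then they are ``None`` and the
    ROI area acts as the size fallback.
    """

    roi: SynapseROI
    channels: dict[str, LocalizationTable] = field(default_factory=dict)
    psd_center_nm: tuple[float, float] | None = None
    psd_area_um2: float | None = None
    flags: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {name: len(t) for name, t in self.channels.items()}

    @property
    def area_um2(self) -> float:
        """PSD area when computed, else the ROI polygon area."""
        return self.psd_area_um2 if self.psd_area_um2 is not None else self.roi.area_um2


@dataclass(frozen=True)
class InclusionCriteria:
    """Per-synapse inclusion thresholds (strict inequalities throughout)."""

    min_locs: dict[str, int] = field(
        default_factory=lambda: {"PSD95": 800, "GluA1": 400}
    )
    area_min_um2: float = 0.02
    area_max_um2: float = 0.3

    def __post_init__(self) -> None:
        if not self.area_min_um2 < self.area_max_um2:
            raise ConfigurationError("area_min must be < area_max")


def segment_widefield(
    image: WidefieldImage,
    smoothing_nm: float = 0.0,
    min_peak_height: float | None = None,
    min_peak_distance_px: int = 3,
) -> list[SynapseROI]:
    """Segment synapse ROIs from a widefield image at the FWHM level.

    The image is optionally Gaussian-smoothed; the background is the median
    of the (smoothed) image; peaks are local maxima strictly higher than
    ``background + min_peak_height``.  For each peak the ROI boundary is the
    marching-squares contour at ``background + (peak - background) / 2``
    that encloses the peak, in nm (pixel centers at ``(k + 0.5) * p``).

    ``min_peak_height`` defaults to 20% of the image's dynamic range above
    background.  A flat image yields an empty list (with a warning), never
    an error.
    """
    if smoothing_nm < 0:
        raise ConfigurationError("smoothing must be >= 0")
    p = image.pixel_size_nm
    img = np.asarray(image.data, dtype=float)
    sigma_px = smoothing_nm / p
    sm = ndimage.gaussian_filter(img, sigma_px) if sigma_px > 0 else img

    background = float(np.median(sm))
    if min_peak_height is None:
        min_peak_height = 0.2 * (float(sm.max()) - background)
    if not sm.max() > background + min_peak_height:
        warnings.warn("no peak above background + min_peak_height; returning no ROIs")
        return []

    peaks = peak_local_max(
        sm,
        min_distance=min_peak_distance_px,
        threshold_abs=background + min_peak_height,
        exclude_border=False,
    )
    # threshold_abs is >=; enforce the strict inequality
    peaks = [tuple(pk) for pk in peaks if sm[tuple(pk)] > background + min_peak_height]

    # pad with background so every half-max contour closes inside the array
    padded = np.pad(sm, 1, mode="constant", constant_values=background)

    rois: list[SynapseROI] = []
    used_contours: list[Polygon] = []
    for row, col in peaks:
        level = background + (sm[row, col] - background) / 2.0
        peak_pt = Point((col + 0.5) * p, (row + 0.5) * p)
        if any(poly.covers(peak_pt) for poly in used_contours):
            continue  # a previous (higher) peak already claimed this region
        contours = measure.find_contours(padded, level)
        chosen = None
        for contour in contours:
            # padded indices -> nm at pixel centers
            xy = np.column_stack(((contour[:, 1] - 1 + 0.5) * p, (contour[:, 0] - 1 + 0.5) * p))
            if len(xy) < 4:
                continue
            poly = Polygon(xy)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.is_empty or poly.area <= 0:
                continue
            if poly.covers(peak_pt) and (chosen is None or poly.area < chosen.area):
                chosen = poly  # innermost contour enclosing the peak
        if chosen is None:
            log.warning("peak at (%d, %d) has no closed half-max contour; skipped", row, col)
            continue
        used_contours.append(chosen)
        rois.append(
            SynapseROI(
                id=len(rois),
                boundary=chosen,
                peak_xy_nm=((col + 0.5) * p, (row + 0.5) * p),
                peak_height=float(sm[row, col] - background),
            )
        )
    return rois


def assign_localizations(
    table: LocalizationTable, rois: list[SynapseROI]
) -> list[SynapseRecord]:
    """Assign localizations to synapse ROIs by point-in-polygon membership.

    Boundary points count as inside (closed polygons).  Localizations in no
    ROI are dropped from synapse analysis.  Where ROIs overlap, a
    localization goes to the ROI with the nearest peak; the overlap is
    logged on the affected records' flags.
    """
    records = [SynapseRecord(roi=roi) for roi in rois]
    if not rois or len(table) == 0:
        for rec, roi in zip(records, rois):
            for name in table.channels:
                rec.channels[name] = LocalizationTable(
                    table.records.iloc[0:0].copy(), dict(table.metadata)
                )
        return records

    xy = table.coords()
    pts = shapely.points(xy)
    membership = np.full(len(table), -1, dtype=int)
    overlap = 0
    for i, roi in enumerate(rois):
        inside = shapely.covers(roi.boundary, pts)
        both = inside & (membership >= 0)
        if both.any():
            overlap += int(both.sum())
            for j in np.flatnonzero(both):
                prev = rois[membership[j]]
                d_prev = np.hypot(*(xy[j] - np.asarray(prev.peak_xy_nm)))
                d_new = np.hypot(*(xy[j] - np.asarray(roi.peak_xy_nm)))
                if d_new < d_prev:
                    membership[j] = i
            inside = inside & (membership < 0)
        membership[np.flatnonzero(inside)] = i
    if overlap:
        frac = overlap / len(table)
        log.warning("ROIs overlap: %d localizations (%.1f%%) resolved by nearest peak", overlap, 100 * frac)
        for rec in records:
            rec.flags.append(f"roi_overlap:{overlap}")

    channel_names = table.channels
    chan_values = table.records["channel"].to_numpy()
    for i, rec in enumerate(records):
        mask = membership == i
        for name in channel_names:
            sel = mask & (chan_values == name)
            rec.channels[name] = LocalizationTable(
                table.records[sel].copy(), dict(table.metadata)
            )
    return records


def select_synapses(
    records: list[SynapseRecord], criteria: InclusionCriteria
) -> list[SynapseRecord]:
    """Apply the synapse inclusion criteria (all inequalities strict).

    A synapse is retained iff every channel's localization count strictly
    exceeds its minimum and ``area_min < area < area_max`` (PSD area when
    available, otherwise the ROI area — logged as a fallback).
    """
    kept = []
    for rec in records:
        counts = rec.counts()
        ok = all(
            counts.get(name, 0) > minimum for name, minimum in criteria.min_locs.items()
        )
        if rec.psd_area_um2 is None:
            log.info("synapse %d: PSD area not computed; using ROI area", rec.roi.id)
        area = rec.area_um2
        ok = ok and (criteria.area_min_um2 < area < criteria.area_max_um2)
        if ok:
            kept.append(rec)
    return kept
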