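"""FRAP trace processing: correction, normalization, mobile fraction.

A FRAP (fluorescence recovery after photobleaching) trace is a time series
of mean ROI intensities sampled every few minutes, together with a
background trace and a bleach-reference trace from an unbleached region.
Processing proceeds raw -> corrected -> normalized:

* correction subtracts background and divides out acquisition bleaching by
  ratio to the (background-subtracted) reference, anchored at the
  reference's pre-bleach mean;
* normalization maps the pre-bleach mean to 1 and the first post-bleach
  frame to 0;
* the mobile fraction is the mean of the last four normalized frames — the
  plateau of the recovery curve, the fraction of fluorophores free to
  exchange on the experiment's time scale.

A synaptic enrichment helper reports the ratio of synapse over dendritic
shaft intensity from small disc ROIs on an image.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, TraceError
from .localization_io import WidefieldImage


@dataclass
class FrapTrace:
    """One ROI's FRAP time series through its processing stages.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    before it are pre-bleach.  ``stage`` is ``raw``, ``corrected`` or
    ``normalized``; correction metadata survive in ``background`` /
    ``reference`` so the pipeline can be audited.
    """

    times_min: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    reference: np.ndarray
    bleach_index: int
    stage: str = "raw"
    roi_id: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        n = len(self.times_min)
        if not (len(self.roi) == len(self.background) == len(self.reference) == n):
            raise TraceError("trace arrays must share one length")
        if n < 2 or np.any(np.diff(self.times_min) <= 0):
            raise TraceError("times must be strictly increasing")
        if not (0 < self.bleach_index < n):
            raise TraceError("bleach_index must leave >= 1 pre-bleach frame")

    @property
    def n_pre(self) -> int:
        return self.bleach_index

    @property
    def n_post(self) -> int:
        return len(self.times_min) - self.bleach_index


@dataclass
class FrapSummary:
    """Per-ROI mobile fractions plus per-cell means."""

    per_roi: pd.DataFrame  # columns: roi_id, cell_id, mobile_fraction
    per_cell: pd.DataFrame  # columns: cell_id, mobile_fraction, n_rois
    n_last: int = 4


def correct_trace(trace: FrapTrace) -> FrapTrace:
    """Background-subtract and bleach-correct a raw trace.

    ``corrected(t) = (roi(t) - bg(t)) * refPre / (ref(t) - bg(t))`` with
    ``refPre`` the pre-bleach mean of the background-subtracted reference
    (ratio bleaching correction against an unbleached region).
    """
    if trace.stage != "raw":
        raise TraceError(f"correct_trace expects a raw trace, got {trace.stage!r}")
    ref = trace.reference - trace.background
    if np.any(ref <= 0):
        bad = int(np.flatnonzero(ref <= 0)[0])
        raise TraceError(
            f"bleach reference at or below background at frame {bad}"
        )
    ref_pre = float(ref[: trace.bleach_index].mean())
    corrected = (trace.roi - trace.background) * (ref_pre / ref)
    return replace(trace, roi=corrected, stage="corrected")


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Two-point normalization: pre-bleach mean -> 1, first post-bleach -> 0."""
    if trace.stage != "corrected":
        raise TraceError(f"normalize_trace expects a corrected trace, got {trace.stage!r}")
    f_pre = float(trace.roi[: trace.bleach_index].mean())
    f0 = float(trace.roi[trace.bleach_index])
    if f_pre == f0:
        raise TraceError("no bleach depth: pre-bleach mean equals first post-bleach frame")
    normalized = (trace.roi - f0) / (f_pre - f0)
    return replace(trace, roi=normalized, stage="normalized")


def mobile_fraction(trace: FrapTrace, n_last: int = 4) -> float:
    """Mean of the final ``n_last`` normalized frames (the recovery plateau)."""
    if trace.stage != "normalized":
        raise TraceError(f"mobile_fraction expects a normalized trace, got {trace.stage!r}")
    if not 1 <= n_last <= trace.n_post:
        raise TraceError(
            f"need >= {n_last} post-bleach frames, trace has {trace.n_post}"
        )
    return float(trace.roi[-n_last:].mean())


def process_trace(trace: FrapTrace, n_last: int = 4) -> tuple[FrapTrace, float]:
    """raw -> corrected -> normalized -> mobile fraction, in one call."""
    normalized = normalize_trace(correct_trace(trace))
    return normalized, mobile_fraction(normalized, n_last)


def summarize(traces: list[FrapTrace], n_last: int = 4) -> FrapSummary:
    """Process a batch of raw traces into per-ROI and per-cell summaries."""
    rows = []
    for trace in traces:
        _, m = process_trace(trace, n_last)
        rows.append({"roi_id": trace.roi_id, "cell_id": trace.cell_id, "mobile_fraction": m})
    per_roi = pd.DataFrame(rows)
    per_cell = (
        per_roi.groupby("cell_id", sort=True)["mobile_fraction"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mobile_fraction", "size": "n_rois"})
    )
    return FrapSummary(per_roi=per_roi, per_cell=per_cell, n_last=n_last)


def read_traces(path) -> list[FrapTrace]:
    """Read long-format trace CSV with columns
    roi_id, cell_id (optional), t_min, roi_mean, bg_mean, ref_mean, bleach_index."""
    df = pd.read_csv(path)
    required = {"roi_id", "t_min", "roi_mean", "bg_mean", "ref_mean", "bleach_index"}
    missing = required - set(df.columns)
    if missing:
        raise TraceError(f"trace file lacks column(s) {sorted(missing)}")
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=False):
        sub = sub.sort_values("t_min")
        traces.append(
            FrapTrace(
                times_min=sub["t_min"].to_numpy(),
                roi=sub["roi_mean"].to_numpy(),
                background=sub["bg_mean"].to_numpy(),
                reference=sub["ref_mean"].to_numpy(),
                bleach_index=int(sub["bleach_index"].iloc[0]),
                roi_id=str(roi_id),
                cell_id=str(sub["cell_id"].iloc[0]) if "cell_id" in sub else "",
            )
        )
    return traces


def _disc_mean(image: WidefieldImage, center_nm: tuple[float, float], diameter_nm: float) -> float:
    p = image.pixel_size_nm
    ny, nx = image.data.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = center_nm
    r = diameter_nm / 2.0
    mask = ((xx + 0.5) * p - cx) ** 2 + ((yy + 0.5) * p - cy) ** 2 <= r**2
    if not mask.any():
        raise ConfigurationError(f"ROI at {center_nm} nm covers no pixel")
    return float(np.asarray(image.data, dtype=float)[mask].mean())


def synaptic_enrichment(
    image: WidefieldImage,
    synapse_centers_nm: list[tuple[float, float]],
    shaft_centers_nm: list[tuple[float, float]],
    roi_diameter_nm: float = 250.0,
    background: float = 0.0,
) -> float:
    """Ratio of mean synapse over mean dendritic-shaft intensity.

    Measured from small disc ROIs (default 250 nm diameter, 10 per
    compartment in the original protocol), background-subtracted.
    """
    if not synapse_centers_nm or not shaft_centers_nm:
        raise ConfigurationError("need >= 1 ROI per compartment")
    syn = np.mean([_disc_mean(image, c, roi_diameter_nm) for c in synapse_centers_nm]) - background
    shaft = np.mean([_disc_mean(image, c, roi_diameter_nm) for c in shaft_centers_nm]) - background
    if shaft <= 0:
        raise TraceError("shaft intensity at or below background; ratio undefined")
    return float(syn / shaft)
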