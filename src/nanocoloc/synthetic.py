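"""Ground-truth-labeled synthetic data for every pipeline stage.

The generator emulates the data regime of a dual-color dSTORM experiment on
synapses: a postsynaptic density (PSD) modeled as a disc of baseline
localizations with Gaussian nanodomains superimposed, imaged over a
20,000-frame acquisition at 50 Hz.  Emitters blink in geometric-length runs
of consecutive frames; every localization carries a fitted precision
(truncated-normal, in the <=25-30 nm filter regime) and a photon count
(log-normal, mostly inside the 300-30,000 filter window), and is jittered
around its emitter by its own precision.  Matched widefield images are
rendered by convolving the localization density with a Gaussian PSF, and
FRAP traces follow a single-exponential recovery with configurable mobile
fraction, plus the background/bleaching distortions the correction pipeline
is expected to undo.

What this emulates — and what it does not — is documented in the methods
note; in short, it reproduces point statistics, blinking chains and filter
regimes, not photophysics or sample drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .frap import FrapTrace
from .localization_io import LocalizationTable, WidefieldImage, render_reconstruction


@dataclass(frozen=True)
class ChannelGroundTruth:
    """Ground truth of one channel within a synapse.

    ``baseline_density_um2`` fills the PSD disc with diffuse localizations
    (the non-nanodomain PSD pool); nanodomains add ``locs_per_domain``
    localizations each, Gaussian with ``sigma_nm`` around their centers.
    """

    name: str
    n_domains: int = 2
    sigma_nm: float = 25.0
    locs_per_domain: int = 300
    baseline_density_um2: float = 3000.0
    precision_mean_nm: float = 12.0
    precision_sd_nm: float = 4.0
    photons_meanlog: float = 7.6  # log-normal; median ~2000 photons
    photons_sdlog: float = 0.6

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.baseline_density_um2 < 0 or self.n_domains < 0:
            raise ValueError("invalid channel ground truth")


@dataclass(frozen=True)
class SynapseGroundTruth:
    """Ground truth of one simulated two-channel synapse.

    The PSD is a disc of radius ``psd_radius_nm`` centered at
    ``center_nm``.  With ``shared_centers`` the second channel reuses the
    first channel's nanodomain centers (displaced by ``center_offset_nm``
    in a random direction per domain); otherwise its centers are placed
    independently.  Acquisition defaults match a 20,000-frame, 50 Hz run.
    """

    channel_a: ChannelGroundTruth = field(
        default_factory=lambda: ChannelGroundTruth(name="PSD95")
    )
    channel_b: ChannelGroundTruth = field(
        default_factory=lambda: ChannelGroundTruth(
            name="GluA1",
            n_domains=1,
            baseline_density_um2=2000.0,
            precision_mean_nm=15.0,
            precision_sd_nm=5.0,
        )
    )
    psd_radius_nm: float = 220.0
    center_nm: tuple[float, float] = (0.0, 0.0)
    shared_centers: bool = True
    center_offset_nm: float = 0.0
    domain_centers_a: tuple[tuple[float, float], ...] | None = None
    n_frames: int = 20_000
    frame_rate_hz: float = 50.0
    mean_blink_frames: float = 2.0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.psd_radius_nm <= 0 or self.mean_blink_frames < 1:
            raise ValueError("invalid synapse ground truth")


@dataclass(frozen=True)
class FrapGroundTruth:
    """Ground truth of one simulated FRAP trace.

    The corrected-domain truth is 1 before bleaching and
    ``M * (1 - exp(-t/tau))`` after, with ``t`` minutes since the first
    post-bleach frame.  The raw trace re-applies background, reference
    bleaching decay and Gaussian noise, i.e. everything the correction and
    normalization pipeline must undo.
    """

    mobile_fraction: float = 0.31
    tau_min: float = 8.0
    n_pre: int = 3
    post_duration_min: float = 30.0
    dt_min: float = 5.0
    noise_sd: float = 0.02
    ref_decay_per_min: float = 0.004
    background: float = 20.0
    baseline: float = 30.0  # residual (immobile-bound) corrected intensity
    amplitude: float = 70.0  # corrected-domain bleach depth
    ref_amplitude: float = 150.0

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile fraction must be in [0, 1]")
        if self.tau_min <= 0 or self.n_pre < 1 or self.dt_min <= 0:
            raise ValueError("invalid FRAP ground truth")


def _sample_domain_centers(
    gt: SynapseGroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Well-spread nanodomain centers inside the inner half of the PSD."""
    if gt.domain_centers_a is not None:
        return np.asarray(gt.domain_centers_a, dtype=float)
    k = gt.channel_a.n_domains
    c = np.asarray(gt.center_nm)
    if k == 0:
        return np.zeros((0, 2))
    if k == 1:
        return c[None, :] + rng.normal(0, gt.psd_radius_nm / 8, size=(1, 2))
    # evenly spaced on a ring at ~55% of the PSD radius, random phase
    phase = rng.uniform(0, 2 * np.pi)
    ang = phase + np.arange(k) * 2 * np.pi / k
    r = 0.55 * gt.psd_radius_nm
    return c[None, :] + r * np.column_stack([np.cos(ang), np.sin(ang)])


def _emit(
    emitters: np.ndarray,
    channel: ChannelGroundTruth,
    gt: SynapseGroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Blinking model: one geometric-length run of consecutive frames per
    emitter appearance; per-localization precision jitter and photons."""
    p_stop = 1.0 / gt.mean_blink_frames
    rows_pos = []
    rows_frame = []
    for xy in emitters:
        run = int(rng.geometric(p_stop))
        run = min(run, gt.n_frames)
        start = int(rng.integers(0, gt.n_frames - run + 1))
        for k in range(run):
            rows_pos.append(xy)
            rows_frame.append(start + k)
    n = len(rows_frame)
    pos = np.asarray(rows_pos, dtype=float).reshape(n, 2)
    precision = rng.normal(channel.precision_mean_nm, channel.precision_sd_nm, size=n)
    precision = np.clip(precision, 1.0, None)
    jitter = rng.normal(0.0, 1.0, size=(n, 2)) * precision[:, None]
    photons = rng.lognormal(channel.photons_meanlog, channel.photons_sdlog, size=n)
    df = pd.DataFrame(
        {
            "x_nm": pos[:, 0] + jitter[:, 0],
            "y_nm": pos[:, 1] + jitter[:, 1],
            "frame": np.asarray(rows_frame, dtype=np.int64),
            "photons": photons,
            "precision_nm": precision,
            "channel": channel.name,
        }
    )
    return df.sort_values(["frame"], kind="stable").reset_index(drop=True)


def _channel_emitters(
    channel: ChannelGroundTruth,
    centers: np.ndarray,
    gt: SynapseGroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emitter positions: Gaussian mixture over nanodomains + uniform disc."""
    parts = []
    for c in centers:
        parts.append(rng.normal(0, channel.sigma_nm, size=(channel.locs_per_domain, 2)) + c)
    area_um2 = np.pi * (gt.psd_radius_nm * 1e-3) ** 2
    n_bg = rng.poisson(channel.baseline_density_um2 * area_um2)
    if n_bg > 0:
        r = gt.psd_radius_nm * np.sqrt(rng.uniform(0, 1, size=n_bg))
        ang = rng.uniform(0, 2 * np.pi, size=n_bg)
        parts.append(
            np.asarray(gt.center_nm)[None, :]
            + np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        )
    if not parts:
        return np.zeros((0, 2))
    return np.vstack(parts)


def simulate_synapse_pair(
    gt: SynapseGroundTruth, seed: int | np.random.Generator
) -> tuple[LocalizationTable, LocalizationTable, dict]:
    """Simulate one two-channel synapse.

    Returns the two channels' localization tables plus a ground-truth echo
    holding the request parameters and the realized nanodomain centers.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers_a = _sample_domain_centers(gt, rng)
    kb = gt.channel_b.n_domains
    if gt.shared_centers and len(centers_a) > 0 and kb > 0:
        base = centers_a[np.arange(kb) % len(centers_a)]
        if gt.center_offset_nm > 0:
            ang = rng.uniform(0, 2 * np.pi, size=kb)
            base = base + gt.center_offset_nm * np.column_stack([np.cos(ang), np.sin(ang)])
        centers_b = base
    else:
        centers_b = _sample_domain_centers(
            replace(gt, channel_a=gt.channel_b, domain_centers_a=None), rng
        )[:kb]

    meta = {
        "n_frames": gt.n_frames,
        "frame_rate_hz": gt.frame_rate_hz,
    }
    emitters_a = _channel_emitters(gt.channel_a, centers_a, gt, rng)
    emitters_b = _channel_emitters(gt.channel_b, centers_b, gt, rng)
    table_a = LocalizationTable(_emit(emitters_a, gt.channel_a, gt, rng), dict(meta))
    table_b = LocalizationTable(_emit(emitters_b, gt.channel_b, gt, rng), dict(meta))
    echo = {
        "ground_truth": gt,
        "domain_centers": {
            gt.channel_a.name: centers_a.tolist(),
            gt.channel_b.name: centers_b.tolist(),
        },
    }
    return table_a, table_b, echo


def simulate_dataset(
    n_synapses: int,
    gt: SynapseGroundTruth,
    seed: int,
    spacing_nm: float = 2000.0,
    n_cols: int = 4,
    margin_nm: float = 1200.0,
) -> tuple[LocalizationTable, dict]:
    """Lay ``n_synapses`` simulated synapses on a grid in one field of view.

    Returns a single two-channel localization table (both channels merged,
    distinguished by the channel column) with the field extent in its
    metadata, plus a ground-truth echo per synapse.
    """
    rng = np.random.default_rng(seed)
    frames = []
    echoes = []
    for i in range(n_synapses):
        row, col = divmod(i, n_cols)
        center = (margin_nm + col * spacing_nm, margin_nm + row * spacing_nm)
        sub = replace(gt, center_nm=center, domain_centers_a=None)
        ta, tb, echo = simulate_synapse_pair(sub, rng)
        frames.extend([ta.records, tb.records])
        echoes.append(echo)
    records = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["frame"], kind="stable")
        .reset_index(drop=True)
    )
    n_rows = int(np.ceil(n_synapses / n_cols))
    extent = (
        margin_nm * 2 + (min(n_synapses, n_cols) - 1) * spacing_nm,
        margin_nm * 2 + max(n_rows - 1, 0) * spacing_nm,
    )
    meta = {
        "n_frames": gt.n_frames,
        "frame_rate_hz": gt.frame_rate_hz,
        "extent_nm": extent,
    }
    return LocalizationTable(records, meta), {"synapses": echoes, "extent_nm": extent}


def simulate_widefield(
    table: LocalizationTable, psf_sigma_nm: float = 150.0, pixel_size_nm: float = 100.0
) -> WidefieldImage:
    """Diffraction-limited image: localization density blurred by a Gaussian
    PSF and sampled on the camera grid (total intensity proportional to the
    localization count)."""
    if psf_sigma_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("psf_sigma_nm and pixel_size_nm must be > 0")
    hist = render_reconstruction(table, pixel_size_nm)
    blurred = ndimage.gaussian_filter(
        np.asarray(hist.data, dtype=float), psf_sigma_nm / pixel_size_nm, mode="constant"
    )
    return WidefieldImage(blurred, pixel_size_nm)


def frap_truth_normalized(gt: FrapGroundTruth, times_post_min: np.ndarray) -> np.ndarray:
    """Noiseless normalized recovery at given minutes after bleaching."""
    t = np.asarray(times_post_min, dtype=float)
    return gt.mobile_fraction * (1.0 - np.exp(-t / gt.tau_min))


def expected_mobile_fraction(gt: FrapGroundTruth, n_last: int = 4) -> float:
    """Closed-form expectation of the last-``n_last``-frame mean under the
    exponential-recovery model at the sampled time points."""
    n_post = int(round(gt.post_duration_min / gt.dt_min)) + 1
    t_post = np.arange(n_post) * gt.dt_min
    return float(frap_truth_normalized(gt, t_post)[-n_last:].mean())


def simulate_frap_trace(
    gt: FrapGroundTruth, seed: int | np.random.Generator, roi_id: str = "", cell_id: str = ""
) -> tuple[FrapTrace, dict]:
    """Simulate one raw FRAP trace plus its ground truth.

    The corrected-domain truth (baseline + amplitude pre-bleach; baseline +
    amplitude * recovery post-bleach) is noised, then pushed backwards
    through the correction model: multiplied by the decaying reference ratio
    and offset by the background.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_post = int(round(gt.post_duration_min / gt.dt_min)) + 1
    t_pre = -gt.dt_min * np.arange(gt.n_pre, 0, -1)
    t_post = gt.dt_min * np.arange(n_post)
    times = np.concatenate([t_pre, t_post])

    truth_norm = np.concatenate(
        [np.ones(gt.n_pre), frap_truth_normalized(gt, t_post)]
    )
    corrected = gt.baseline + gt.amplitude * truth_norm
    corrected = corrected + rng.normal(0.0, gt.noise_sd * gt.amplitude, size=len(times))

    elapsed = times - times[0]
    ref_minus_bg = gt.ref_amplitude * np.exp(-gt.ref_decay_per_min * elapsed)
    ref_pre = float(ref_minus_bg[: gt.n_pre].mean())
    raw_roi = corrected * (ref_minus_bg / ref_pre) + gt.background
    trace = FrapTrace(
        times_min=times,
        roi=raw_roi,
        background=np.full(len(times), gt.background),
        reference=ref_minus_bg + gt.background,
        bleach_index=gt.n_pre,
        roi_id=roi_id,
        cell_id=cell_id,
    )
    truth = {
        "ground_truth": gt,
        "normalized": truth_norm,
        "expected_mobile_fraction": expected_mobile_fraction(gt),
    }
    return trace, truth


def write_traces_csv(traces: Sequence[FrapTrace], path) -> None:
    """Write traces in the long-format CSV the FRAP reader consumes."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "roi_id": tr.roi_id,
                    "cell_id": tr.cell_id,
                    "t_min": tr.times_min,
                    "roi_mean": tr.roi,
                    "bg_mean": tr.background,
                    "ref_mean": tr.reference,
                    "bleach_index": tr.bleach_index,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
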