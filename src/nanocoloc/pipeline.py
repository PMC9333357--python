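"""End-to-end orchestration: filter -> segment -> assign -> select ->
nanodomains -> co-localization (+ optional FRAP), from one config.

The pipeline runs the stages in their canonical order, logs every threshold
actually applied and every stage's record counts (input = output + removed,
checkable post hoc), and writes tidy per-synapse and per-nanodomain tables
plus a JSON summary with the standard ordinary-least-squares regressions of
PSD size against nanodomain distance and against the mean co-localization
index.  Given the same config and seed, outputs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import synthetic
from .colocalization import (
    ColocParams,
    colocalization_index,
    nanodomain_enrichment,
    nanodomain_membership,
)
from .exceptions import ConfigurationError, DegenerateInputError, NanocolocError
from .filtering import QualityThresholds, filter_table
from .localization_io import (
    read_localizations,
    read_widefield,
    write_localizations,
    write_widefield,
)
from .nanodomain import (
    NanodomainParams,
    detect_nanodomains,
    psd_centroid,
    topology_metrics,
)
from .synapse_roi import (
    InclusionCriteria,
    SynapseRecord,
    assign_localizations,
    segment_widefield,
    select_synapses,
)

log = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    smoothing_nm: float = 100.0
    min_peak_height: float | None = None  # None -> auto (20% of dynamic range)
    min_peak_distance_px: int = 3
    pixel_size_nm: float = 100.0


@dataclass
class SimulateConfig:
    n_synapses: int = 12
    spacing_nm: float = 2000.0
    ground_truth: synthetic.SynapseGroundTruth = field(
        default_factory=synthetic.SynapseGroundTruth
    )
    psf_sigma_nm: float = 150.0


@dataclass
class PipelineConfig:
    """Everything one run needs; every threshold defaults to the values
    documented in docs/methods.md."""

    outdir: str = "nanocoloc_out"
    seed: int = 0
    scaffold_channel: str = "PSD95"
    receptor_channel: str = "GluA1"
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    criteria: InclusionCriteria = field(default_factory=InclusionCriteria)
    nanodomain: NanodomainParams = field(default_factory=NanodomainParams)
    dbscan_min_pts: int = 5
    # input mode A: simulate
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    # input mode B: files
    localizations_path: str | None = None
    localizations_dialect: str = "canonical"
    widefield_path: str | None = None
    frap_traces_path: str | None = None


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    """Build a config from a YAML file; omitted fields keep their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    nested = {
        "thresholds": QualityThresholds,
        "segmentation": SegmentationConfig,
        "criteria": InclusionCriteria,
        "nanodomain": NanodomainParams,
    }
    for key, value in raw.items():
        if key in nested and isinstance(value, dict):
            setattr(cfg, key, nested[key](**value))
        elif key == "simulate":
            if value is None:
                cfg.simulate = None
            else:
                gt_raw = value.pop("ground_truth", None)
                sim = SimulateConfig(**value)
                if gt_raw:
                    for chan_key in ("channel_a", "channel_b"):
                        if chan_key in gt_raw:
                            gt_raw[chan_key] = synthetic.ChannelGroundTruth(**gt_raw[chan_key])
                    sim.ground_truth = synthetic.SynapseGroundTruth(**gt_raw)
                cfg.simulate = sim
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ConfigurationError(f"unknown config key {key!r}")
    return cfg


@dataclass
class RunResult:
    per_synapse: pd.DataFrame
    per_nanodomain: pd.DataFrame
    summary: dict
    stage_counts: dict
    outdir: Path


def _analyze_synapse(
    rec: SynapseRecord,
    scaffold: str,
    receptor: str,
    nd_params: NanodomainParams,
    dbscan_min_pts: int,
) -> tuple[dict, list[dict]] | None:
    """Per-synapse analysis; returns (synapse row, nanodomain rows) or None
    when the PSD cluster cannot be formed."""
    pts = {name: t.coords() for name, t in rec.channels.items()}
    try:
        center, area_um2, _ = psd_centroid(pts[scaffold], min_pts=dbscan_min_pts)
    except DegenerateInputError:
        rec.flags.append("no_psd_cluster")
        return None
    rec.psd_center_nm = (float(center[0]), float(center[1]))
    rec.psd_area_um2 = area_um2

    nds = {
        name: detect_nanodomains(pts[name], nd_params, roi=rec.roi.boundary, channel=name)
        for name in (scaffold, receptor)
    }
    topo = topology_metrics(nds, center, area_um2)

    eps = {
        name: float(rec.channels[name].records["precision_nm"].mean())
        for name in (scaffold, receptor)
    }
    coloc = colocalization_index(
        pts[scaffold], pts[receptor], ColocParams(eps[scaffold], eps[receptor])
    )
    inside_a = nanodomain_membership(pts[scaffold], nds[receptor])
    inside_b = nanodomain_membership(pts[receptor], nds[scaffold])
    enrich_a, fl_a = nanodomain_enrichment(coloc.ci_a, inside_a)
    enrich_b, fl_b = nanodomain_enrichment(coloc.ci_b, inside_b)
    coloc.enrichment = {scaffold: enrich_a, receptor: enrich_b}
    rec.flags.extend(coloc.flags + fl_a + fl_b + topo.flags)

    cross = np.concatenate(
        [topo.cross_channel_dist[scaffold], topo.cross_channel_dist[receptor]]
    )
    cross = cross[np.isfinite(cross)]
    row = {
        "synapse_id": rec.roi.id,
        "psd_area_um2": area_um2,
        "psd_center_x_nm": center[0],
        "psd_center_y_nm": center[1],
        f"n_locs_{scaffold}": len(pts[scaffold]),
        f"n_locs_{receptor}": len(pts[receptor]),
        f"n_nanodomains_{scaffold}": len(nds[scaffold]),
        f"n_nanodomains_{receptor}": len(nds[receptor]),
        "mean_cross_channel_dist_nm": float(cross.mean()) if cross.size else np.nan,
        f"mean_ci_{scaffold}": coloc.mean_ci_a,
        f"mean_ci_{receptor}": coloc.mean_ci_b,
        f"d_{scaffold}_nm": coloc.d_a_nm,
        f"d_{receptor}_nm": coloc.d_b_nm,
        f"enrichment_{scaffold}": enrich_a,
        f"enrichment_{receptor}": enrich_b,
        "flags": ";".join(rec.flags),
    }
    nd_rows = []
    for name in (scaffold, receptor):
        for j, nd in enumerate(nds[name]):
            nd_rows.append(
                {
                    "synapse_id": rec.roi.id,
                    "channel": name,
                    "nanodomain_id": j,
                    "center_x_nm": nd.center_nm[0],
                    "center_y_nm": nd.center_nm[1],
                    "diameter_nm": nd.diameter_nm,
                    "n_members": len(nd.members),
                    "member_fraction": nd.member_fraction,
                    "dist_to_psd_center_nm": topo.dist_to_psd[name][j],
                    "cross_channel_dist_nm": topo.cross_channel_dist[name][j],
                }
            )
    return row, nd_rows


def _regress(x: np.ndarray, y: np.ndarray) -> dict:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan, "p_value": np.nan, "n": int(mask.sum())}
    fit = stats.linregress(x[mask], y[mask])
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue**2,
        "p_value": fit.pvalue,
        "n": int(mask.sum()),
    }


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run the full SMLM analysis described by ``config``.

    Outputs written to ``config.outdir``: the filtered localization table,
    ROI polygons (GeoJSON), per-synapse and per-nanodomain CSVs, a FRAP
    summary when traces are provided, and ``summary.json`` with stage
    counts, the effective config and the OLS regression report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, dict] = {}

    # ---- inputs -----------------------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        table, echo = synthetic.simulate_dataset(
            sim.n_synapses, sim.ground_truth, config.seed, spacing_nm=sim.spacing_nm
        )
        scaffold_table = table.channel(config.scaffold_channel)
        image = synthetic.simulate_widefield(
            scaffold_table, sim.psf_sigma_nm, config.segmentation.pixel_size_nm
        )
        write_localizations(table, outdir / "localizations_raw.csv")
        write_widefield(image, outdir / "widefield.tif")
    elif config.localizations_path and config.widefield_path:
        table = read_localizations(
            config.localizations_path, dialect=config.localizations_dialect
        )
        image = read_widefield(config.widefield_path, config.segmentation.pixel_size_nm)
    else:
        raise ConfigurationError(
            "config must either enable simulation or point at localization and widefield files"
        )
    table.validate()

    # ---- stage 1: filtering ----------------------------------------------
    filtered, report = filter_table(table, config.thresholds)
    stage_counts["filter"] = report.as_dict()
    write_localizations(filtered, outdir / "localizations_filtered.csv")

    # ---- stage 2: segmentation -------------------------------------------
    rois = segment_widefield(
        image,
        smoothing_nm=config.segmentation.smoothing_nm,
        min_peak_height=config.segmentation.min_peak_height,
        min_peak_distance_px=config.segmentation.min_peak_distance_px,
    )
    stage_counts["segment"] = {"n_rois": len(rois)}
    _write_rois_geojson(rois, outdir / "rois.geojson")

    # ---- stage 3: assignment ---------------------------------------------
    records = assign_localizations(filtered, rois)
    assigned = sum(sum(rec.counts().values()) for rec in records)
    stage_counts["assign"] = {
        "n_in": len(filtered),
        "n_assigned": assigned,
        "n_unassigned": len(filtered) - assigned,
    }

    # ---- stage 4+5: PSD centroid, inclusion, nanodomains, coloc ----------
    syn_rows: list[dict] = []
    nd_rows: list[dict] = []
    analyzed = []
    for rec in records:
        try:
            out = _analyze_synapse(
                rec,
                config.scaffold_channel,
                config.receptor_channel,
                config.nanodomain,
                config.dbscan_min_pts,
            )
        except (DegenerateInputError, NanocolocError) as exc:
            log.warning("synapse %d skipped: %s", rec.roi.id, exc)
            rec.flags.append(f"error:{exc}")
            continue
        if out is not None:
            analyzed.append((rec, out))
    selected = select_synapses([rec for rec, _ in analyzed], config.criteria)
    selected_ids = {rec.roi.id for rec in selected}
    for rec, (row, rows_nd) in analyzed:
        if rec.roi.id in selected_ids:
            syn_rows.append(row)
            nd_rows.extend(rows_nd)
    stage_counts["select"] = {
        "n_in": len(records),
        "n_out": len(syn_rows),
        "n_removed": len(records) - len(syn_rows),
    }

    per_synapse = pd.DataFrame(syn_rows)
    per_nanodomain = pd.DataFrame(nd_rows)
    per_synapse.to_csv(outdir / "per_synapse.csv", index=False, float_format="%.6f")
    per_nanodomain.to_csv(outdir / "per_nanodomain.csv", index=False, float_format="%.6f")

    # ---- regression report -----------------------------------------------
    summary: dict = {"seed": config.seed, "config": _asdict(config)}
    if len(per_synapse):
        area = per_synapse["psd_area_um2"].to_numpy(dtype=float)
        summary["regressions"] = {
            "psd_size_vs_cross_channel_distance": _regress(
                area, per_synapse["mean_cross_channel_dist_nm"].to_numpy(dtype=float)
            ),
            "psd_size_vs_mean_ci_receptor": _regress(
                area,
                per_synapse[f"mean_ci_{config.receptor_channel}"].to_numpy(dtype=float),
            ),
        }
    else:
        log.warning("no synapse passed the inclusion criteria")
        summary["regressions"] = {}

    # ---- optional FRAP ----------------------------------------------------
    if config.frap_traces_path:
        from .frap import read_traces, summarize

        frap_summary = summarize(read_traces(config.frap_traces_path))
        frap_summary.per_roi.to_csv(outdir / "frap_per_roi.csv", index=False, float_format="%.6f")
        frap_summary.per_cell.to_csv(outdir / "frap_per_cell.csv", index=False, float_format="%.6f")
        summary["frap"] = {
            "mean_mobile_fraction": float(frap_summary.per_roi["mobile_fraction"].mean()),
            "n_rois": int(len(frap_summary.per_roi)),
        }

    summary["stage_counts"] = stage_counts
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_asdict(summary), fh, indent=2, sort_keys=True)

    return RunResult(per_synapse, per_nanodomain, summary, stage_counts, outdir)


def _write_rois_geojson(rois, path: Path) -> None:
    features = []
    for roi in rois:
        coords = [[list(xy) for xy in roi.boundary.exterior.coords]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": {
                    "id": roi.id,
                    "area_um2": roi.area_um2,
                    "peak_xy_nm": list(roi.peak_xy_nm),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
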