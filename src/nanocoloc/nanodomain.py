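"""Local-density nanodomain detection and subsynaptic topology metrics.

Within a synapse, each localization's *local density* (LD) is the number of
other same-channel localizations within a radius of five times the channel's
mean nearest-neighbor distance (MNND), both computed inside the PSD.
Localizations with LD > 40 are nanodomain material; they are grouped by
single-linkage clustering cut at the LD radius, candidate groups holding
several distinct density peaks are subclustered by an 80% / 80 nm / 30%
peak-and-valley rule, and each retained group is bounded by the union of its
members' Voronoi cells clipped to the synapse ROI.  Groups holding fewer
than 5% of the synapse's localizations in that channel, or with an
equal-area-circle diameter below 30 nm, are excluded.

The PSD itself (center and area) is defined by the largest DBSCAN cluster of
scaffold-channel localizations; topology metrics report every nanodomain's
distance to the PSD center and the center-to-center distance to its closest
nanodomain in the other channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError, Voronoi, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN

from .exceptions import ConfigurationError, DegenerateInputError


@dataclass(frozen=True)
class NanodomainParams:
    """Tunable parameters of nanodomain detection.

    Defaults are the standard regime for synaptic dSTORM data: LD
    radius factor 5, LD
    threshold 40 neighbors, subcluster rule 80% / 80 nm / 30%, exclusion of
    groups below 5% membership or 30 nm diameter.  All comparisons are
    strict, mirroring the stated inequalities.
    """

    density_radius_factor: float = 5.0
    ld_threshold: float = 40.0
    peak_fraction: float = 0.80
    peak_min_separation_nm: float = 80.0
    valley_fraction: float = 0.30
    valley_corridor_width_nm: float = 40.0
    min_member_fraction: float = 0.05
    min_diameter_nm: float = 30.0
    linkage_cut_nm: float | None = None  # None -> cut at the LD radius
    diameter_mode: str = "equal_area"  # or "max_extent"

    def __post_init__(self) -> None:
        fracs = (self.peak_fraction, self.valley_fraction, self.min_member_fraction)
        if any(not (0 < f < 1) for f in fracs):
            raise ConfigurationError("fractions must lie in (0, 1)")
        dists = (
            self.density_radius_factor,
            self.peak_min_separation_nm,
            self.valley_corridor_width_nm,
            self.min_diameter_nm,
        )
        if any(not d > 0 for d in dists):
            raise ConfigurationError("distances must be > 0")
        if self.diameter_mode not in ("equal_area", "max_extent"):
            raise ConfigurationError("diameter_mode must be equal_area or max_extent")


@dataclass
class DensityField:
    """Per-localization local densities of one channel within a synapse."""

    ld: np.ndarray  # integer neighbor counts (self excluded)
    radius_nm: float
    mnnd_nm: float
    channel: str = ""


@dataclass
class Nanodomain:
    """A detected subsynaptic cluster of one channel."""

    members: np.ndarray  # indices into the synapse's channel point array
    center_nm: np.ndarray  # (2,) arithmetic centroid of members
    boundary: Polygon  # Voronoi-cell union, clipped to the synapse ROI
    diameter_nm: float  # equal-area-circle diameter of the boundary
    max_extent_nm: float  # largest pairwise member distance
    member_fraction: float
    channel: str = ""


@dataclass
class TopologyMetrics:
    """Per-nanodomain topology of a synapse (NaN = undefined, flagged)."""

    psd_center_nm: np.ndarray
    psd_area_um2: float
    dist_to_psd: dict[str, np.ndarray]
    cross_channel_dist: dict[str, np.ndarray]
    flags: list[str] = field(default_factory=list)


def mean_nearest_neighbor_distance(points: np.ndarray) -> float:
    """Arithmetic mean of each point's distance to its nearest other point.

    Raises :class:`DegenerateInputError` for fewer than two points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise DegenerateInputError("MNND requires at least 2 points")
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.mean(d[:, 1]))


def local_density(points: np.ndarray, radius_nm: float) -> np.ndarray:
    """Number of *other* points within ``radius_nm`` of each point (<=)."""
    if not radius_nm > 0:
        raise ConfigurationError("radius must be > 0")
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(points)
    counts = tree.query_ball_point(points, r=radius_nm, return_length=True)
    return np.asarray(counts, dtype=np.int64) - 1


def density_field(
    points: np.ndarray, params: NanodomainParams, channel: str = ""
) -> DensityField:
    """LD of every point at radius ``density_radius_factor x MNND``."""
    mnnd = mean_nearest_neighbor_distance(points)
    radius = params.density_radius_factor * mnnd
    return DensityField(local_density(points, radius), radius, mnnd, channel)


def _voronoi_cell_polygons(points: np.ndarray, clip: Polygon) -> list[Polygon | None]:
    """Voronoi cell of every point, clipped to ``clip``.

    Far-away ghost points bound the outer cells so every real cell is a
    finite polygon before clipping.  Duplicate positions share a cell.
    """
    pts = np.asarray(points, dtype=float)
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    minx, miny, maxx, maxy = clip.bounds
    span = max(maxx - minx, maxy - miny, 1.0)
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    r = 10 * span
    ghosts = np.array(
        [[cx + r * np.cos(a), cy + r * np.sin(a)] for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)]
    )
    if len(uniq) == 1:
        return [clip] * len(pts)
    vor = Voronoi(np.vstack([uniq, ghosts]))
    cells: list[Polygon | None] = []
    for i in range(len(uniq)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            cells.append(None)
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        cell = poly.intersection(clip)
        cells.append(cell if not cell.is_empty else None)
    return [cells[inverse[i]] for i in range(len(pts))]


def split_nanodomain(
    points: np.ndarray, ld: np.ndarray, params: NanodomainParams
) -> list[np.ndarray]:
    """Subcluster a candidate nanodomain on the peak-and-valley rule.

    Density peaks are members whose LD is maximal among members within half
    the minimum peak separation of themselves.  Two retained peaks (LD
    strictly above ``peak_fraction`` of the group maximum) are split apart
    iff they lie strictly more than ``peak_min_separation_nm`` apart *and*
    the minimum LD among members inside a straight corridor of width
    ``valley_corridor_width_nm`` joining them is strictly below
    ``valley_fraction`` of the maximum.  Members are then reassigned to
    their nearest retained peak.  Returns index arrays into ``points``.
    """
    points = np.asarray(points, dtype=float)
    ld = np.asarray(ld, dtype=float)
    n = len(points)
    if n == 0:
        return []
    all_idx = np.arange(n)
    if n == 1:
        return [all_idx]
    max_ld = float(ld.max())
    tree = cKDTree(points)
    half_sep = params.peak_min_separation_nm / 2.0

    peaks = []
    for i in range(n):
        neigh = tree.query_ball_point(points[i], r=half_sep)
        if ld[i] >= ld[neigh].max():
            peaks.append(i)
    retained = [i for i in peaks if ld[i] > params.peak_fraction * max_ld]
    if len(retained) < 2:
        return [all_idx]

    # graph among retained peaks: an edge keeps two peaks together
    k = len(retained)
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    half_w = params.valley_corridor_width_nm / 2.0
    for a in range(k):
        for b in range(a + 1, k):
            pa, pb = points[retained[a]], points[retained[b]]
            sep = float(np.linalg.norm(pb - pa))
            split = False
            if sep > params.peak_min_separation_nm:
                axis = (pb - pa) / sep
                rel = points - pa
                t = rel @ axis
                perp = np.abs(rel @ np.array([-axis[1], axis[0]]))
                corridor = (t >= 0) & (t <= sep) & (perp <= half_w)
                if corridor.any():
                    valley = float(ld[corridor].min())
                    split = valley < params.valley_fraction * max_ld
            if not split:
                union(a, b)

    comps = [find(a) for a in range(k)]
    if len(set(comps)) < 2:
        return [all_idx]
    peak_pts = points[retained]
    nearest_peak = np.argmin(
        np.linalg.norm(points[:, None, :] - peak_pts[None, :, :], axis=2), axis=1
    )
    groups = []
    for comp in sorted(set(comps)):
        sel = np.isin(nearest_peak, [a for a in range(k) if comps[a] == comp])
        if sel.any():
            groups.append(all_idx[sel])
    return groups


def detect_nanodomains(
    points: np.ndarray,
    params: NanodomainParams = NanodomainParams(),
    roi: Polygon | None = None,
    channel: str = "",
) -> list[Nanodomain]:
    """Detect nanodomains of one channel within one synapse.

    Pipeline: LD at radius 5xMNND; keep points with LD strictly above the
    threshold; single-linkage clustering of kept points cut at the LD
    radius; subcluster split attempt on each group; Voronoi-cell-union
    boundary clipped to the synapse ROI; exclusion of groups below the
    membership-fraction or diameter minima.

    ``roi`` clips the Voronoi cells; when omitted, the bounding box of the
    points padded by the LD radius is used.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise DegenerateInputError("nanodomain detection requires >= 2 points")
    fieldv = density_field(points, params, channel)
    keep = np.flatnonzero(fieldv.ld > params.ld_threshold)
    if keep.size == 0:
        return []
    cut = params.linkage_cut_nm if params.linkage_cut_nm is not None else fieldv.radius_nm

    if keep.size == 1:
        groups = [keep]
    else:
        Z = linkage(points[keep], method="single")
        labels = fcluster(Z, t=cut, criterion="distance")
        groups = [keep[labels == lab] for lab in np.unique(labels)]

    # subcluster pass
    final_groups: list[np.ndarray] = []
    for g in groups:
        for sub in split_nanodomain(points[g], fieldv.ld[g], params):
            final_groups.append(g[sub])

    if roi is None:
        pad = fieldv.radius_nm
        minx, miny = points.min(axis=0) - pad
        maxx, maxy = points.max(axis=0) + pad
        roi = Polygon([(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)])

    cells = _voronoi_cell_polygons(points, roi)
    out: list[Nanodomain] = []
    n_total = len(points)
    for g in final_groups:
        member_cells = [cells[i] for i in g if cells[i] is not None]
        if not member_cells:
            continue
        boundary = unary_union(member_cells)
        if boundary.is_empty or boundary.area <= 0:
            continue
        if params.diameter_mode == "equal_area":
            diameter = 2.0 * np.sqrt(boundary.area / np.pi)
        else:
            diameter = _max_extent(points[g])
        fraction = len(g) / n_total
        if fraction < params.min_member_fraction or diameter < params.min_diameter_nm:
            continue
        out.append(
            Nanodomain(
                members=np.sort(g),
                center_nm=points[g].mean(axis=0),
                boundary=boundary,
                diameter_nm=float(diameter),
                max_extent_nm=float(_max_extent(points[g])),
                member_fraction=float(fraction),
                channel=channel,
            )
        )
    return out


def _max_extent(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 3:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    return float(d.max())


def psd_centroid(
    points: np.ndarray, eps_nm: float | None = None, min_pts: int = 5
) -> tuple[np.ndarray, float, np.ndarray]:
    """PSD center and area from the largest DBSCAN cluster.

    ``eps`` defaults to five times the point set's MNND.  Returns
    ``(center_nm, area_um2, member_indices)`` where the center is the
    arithmetic centroid and the area is the convex hull of the cluster.

    Raises :class:`DegenerateInputError` when DBSCAN finds no cluster; the
    caller flags and excludes the synapse.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < max(2, min_pts):
        raise DegenerateInputError("too few points for a PSD cluster")
    if eps_nm is None:
        eps_nm = 5.0 * mean_nearest_neighbor_distance(points)
    labels = DBSCAN(eps=eps_nm, min_samples=min_pts).fit_predict(points)
    valid = labels[labels >= 0]
    if valid.size == 0:
        raise DegenerateInputError("DBSCAN found no PSD cluster")
    largest = np.bincount(valid).argmax()
    members = np.flatnonzero(labels == largest)
    cluster = points[members]
    center = cluster.mean(axis=0)
    try:
        area_um2 = ConvexHull(cluster).volume * 1e-6  # 2-D hull "volume" = area
    except QhullError:
        area_um2 = 0.0
    return center, float(area_um2), members


def topology_metrics(
    nd_by_channel: dict[str, list[Nanodomain]],
    psd_center_nm: np.ndarray,
    psd_area_um2: float = float("nan"),
) -> TopologyMetrics:
    """Distances of every nanodomain to the PSD center and to the closest
    nanodomain of the other channel (NaN + flag when the other channel has
    none).  Supports exactly two channels for the cross-channel metric.
    """
    psd_center_nm = np.asarray(psd_center_nm, dtype=float)
    names = list(nd_by_channel)
    dist_to_psd: dict[str, np.ndarray] = {}
    cross: dict[str, np.ndarray] = {}
    flags: list[str] = []
    for name in names:
        centers = np.array([nd.center_nm for nd in nd_by_channel[name]]).reshape(-1, 2)
        dist_to_psd[name] = np.linalg.norm(centers - psd_center_nm, axis=1)
        others = [n for n in names if n != name]
        other_centers = (
            np.array([nd.center_nm for o in others for nd in nd_by_channel[o]]).reshape(-1, 2)
        )
        if len(other_centers) == 0:
            cross[name] = np.full(len(centers), np.nan)
            if len(centers):
                flags.append(f"{name}:no_other_channel_nanodomain")
        else:
            d = np.linalg.norm(centers[:, None, :] - other_centers[None, :, :], axis=2)
            cross[name] = d.min(axis=1) if d.size else np.zeros(0)
    return TopologyMetrics(
        psd_center_nm=psd_center_nm,
        psd_area_um2=psd_area_um2,
        dist_to_psd=dist_to_psd,
        cross_channel_dist=cross,
        flags=flags,
    )
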