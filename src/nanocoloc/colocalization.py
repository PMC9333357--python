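"""Coordinate-based co-localization index between two SMLM channels.

For two channels A and B inside one synapse, the co-localization index of
localization ``A_i`` is the number of channel-B localizations within the
effective resolution ``d_B`` of ``A_i``, normalized by channel B's mean
local density at that same radius:

    CI_i^A(d_B) = N_{A_i}^B(d_B) / mean(LD_B),   d_B = sqrt(MNND_B^2 + eps_B^2)

and symmetrically for channel B against A.  ``eps`` summarizes the
localization error of a channel (here: the mean fitted precision within the
synapse).  A CI of 1 means B is locally as dense around A as B is around
itself — the no-association baseline; per-synapse means of the
per-localization values are the reported statistics.

Self-handling: within-channel LD counts exclude the point itself.  When A
and B are literally the same point set (a channel against itself), the
cross-channel count excludes the index-identical point too, which makes the
mean CI exactly 1 — the self-normalization identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree

from .exceptions import ConfigurationError, DegenerateInputError
from .nanodomain import Nanodomain, mean_nearest_neighbor_distance


@dataclass(frozen=True)
class ColocParams:
    """Localization-error summaries (nm) of the two channels.

    ``epsilon_a`` / ``epsilon_b`` are typically the mean fitted precision of
    each channel's localizations within the synapse.  ``self_exclusion``
    controls whether a point is its own neighbor in within-channel counts
    (the identity-preserving convention excludes it).
    """

    epsilon_a: float
    epsilon_b: float
    self_exclusion: bool = True

    def __post_init__(self) -> None:
        if not (self.epsilon_a > 0 and self.epsilon_b > 0):
            raise ConfigurationError("epsilon must be > 0")


@dataclass
class ColocResult:
    """Per-localization and per-synapse co-localization summaries."""

    ci_a: np.ndarray  # CI_i^A, one per A localization
    ci_b: np.ndarray
    d_a_nm: float  # effective resolution of channel A
    d_b_nm: float
    mean_ld_a: float
    mean_ld_b: float
    mean_ci_a: float
    mean_ci_b: float
    enrichment: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def effective_resolution(mnnd_nm: float, epsilon_nm: float) -> float:
    """sqrt(MNND^2 + eps^2); the counting radius of the CI."""
    if mnnd_nm < 0 or epsilon_nm < 0:
        raise ConfigurationError("MNND and epsilon must be >= 0")
    if mnnd_nm == 0 and epsilon_nm == 0:
        raise DegenerateInputError("MNND and epsilon cannot both be zero")
    return float(np.hypot(mnnd_nm, epsilon_nm))


def _ld_counts(points: np.ndarray, radius: float, self_excluded: bool) -> np.ndarray:
    tree = cKDTree(points)
    counts = np.asarray(
        tree.query_ball_point(points, r=radius, return_length=True), dtype=float
    )
    return counts - 1.0 if self_excluded else counts


def colocalization_index(
    A: np.ndarray, B: np.ndarray, params: ColocParams
) -> ColocResult:
    """Compute CI in both channel directions for one synapse.

    Counting is boundary-inclusive (distance <= d is a neighbor).  When the
    mean LD of a channel is zero (every point isolated at its effective
    resolution) the CI in that direction is undefined: NaN plus a flag.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) < 2 or len(B) < 2:
        raise DegenerateInputError("each channel needs >= 2 points for CI")
    same = A is B or (A.shape == B.shape and np.array_equal(A, B))

    d_a = effective_resolution(mean_nearest_neighbor_distance(A), params.epsilon_a)
    d_b = effective_resolution(mean_nearest_neighbor_distance(B), params.epsilon_b)

    ld_a = _ld_counts(A, d_a, params.self_exclusion)
    ld_b = _ld_counts(B, d_b, params.self_exclusion)
    mean_ld_a = float(ld_a.mean())
    mean_ld_b = float(ld_b.mean())

    tree_a = cKDTree(A)
    tree_b = cKDTree(B)
    n_ab = np.asarray(tree_b.query_ball_point(A, r=d_b, return_length=True), dtype=float)
    n_ba = np.asarray(tree_a.query_ball_point(B, r=d_a, return_length=True), dtype=float)
    if same and params.self_exclusion:
        n_ab = n_ab - 1.0
        n_ba = n_ba - 1.0

    flags: list[str] = []
    if mean_ld_b > 0:
        ci_a = n_ab / mean_ld_b
        mean_ci_a = float(n_ab.mean() / mean_ld_b)
    else:
        ci_a = np.full(len(A), np.nan)
        mean_ci_a = float("nan")
        flags.append("mean_ld_b_zero")
    if mean_ld_a > 0:
        ci_b = n_ba / mean_ld_a
        mean_ci_b = float(n_ba.mean() / mean_ld_a)
    else:
        ci_b = np.full(len(B), np.nan)
        mean_ci_b = float("nan")
        flags.append("mean_ld_a_zero")

    return ColocResult(
        ci_a=ci_a,
        ci_b=ci_b,
        d_a_nm=d_a,
        d_b_nm=d_b,
        mean_ld_a=mean_ld_a,
        mean_ld_b=mean_ld_b,
        mean_ci_a=mean_ci_a,
        mean_ci_b=mean_ci_b,
        flags=flags,
    )


def nanodomain_membership(
    points: np.ndarray, nanodomains: list[Nanodomain]
) -> np.ndarray:
    """Boolean mask: point lies inside (or on) any nanodomain boundary."""
    points = np.asarray(points, dtype=float)
    mask = np.zeros(len(points), dtype=bool)
    if len(points) == 0 or not nanodomains:
        return mask
    pts = shapely.points(points)
    for nd in nanodomains:
        mask |= shapely.covers(nd.boundary, pts)
    return mask


def nanodomain_enrichment(
    ci: np.ndarray, inside_other_channel_nd: np.ndarray
) -> tuple[float, list[str]]:
    """Ratio of mean CI inside vs outside the other channel's nanodomains.

    A ratio of 1 is the no-enrichment null.  When either group is empty the
    ratio is undefined (NaN) and flagged.
    """
    ci = np.asarray(ci, dtype=float)
    inside = np.asarray(inside_other_channel_nd, dtype=bool)
    if inside.shape != ci.shape:
        raise ConfigurationError("membership mask must align with CI values")
    flags: list[str] = []
    valid = np.isfinite(ci)
    n_in = int((inside & valid).sum())
    n_out = int((~inside & valid).sum())
    if n_in == 0 or n_out == 0:
        flags.append("enrichment_undefined")
        return float("nan"), flags
    mean_out = float(ci[~inside & valid].mean())
    if mean_out == 0:
        flags.append("enrichment_outside_zero")
        return float("nan"), flags
    return float(ci[inside & valid].mean() / mean_out), flags
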