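"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain O(n^2) loops over explicit pairs — no
KD-trees, no vectorized shortcuts shared with the package code — so that an
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def brute_mnnd(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    total = 0.0
    for i in range(len(points)):
        best = math.inf
        for j in range(len(points)):
            if i == j:
                continue
            d = math.dist(points[i], points[j])
            best = min(best, d)
        total += best
    return total / len(points)


def brute_local_density(points: np.ndarray, radius: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    out = np.zeros(len(points), dtype=np.int64)
    for i in range(len(points)):
        for j in range(len(points)):
            if i != j and math.dist(points[i], points[j]) <= radius:
                out[i] += 1
    return out


def brute_cross_counts(A: np.ndarray, B: np.ndarray, radius: float) -> np.ndarray:
    """Number of B points within ``radius`` of each A point (<= inclusive)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    out = np.zeros(len(A), dtype=np.int64)
    for i in range(len(A)):
        for j in range(len(B)):
            if math.dist(A[i], B[j]) <= radius:
                out[i] += 1
    return out


def brute_chain_removal(
    xy: np.ndarray,
    frames: np.ndarray,
    radius: float,
    max_frames: int,
    frame_gap: int,
) -> np.ndarray:
    """Keep-mask of the consecutive-localization filter, restated naively.

    Chains are grown record by record in (frame, input-order); a record
    joins the chain whose most recent member is nearest among those within
    ``radius`` and at most ``frame_gap`` frames back, else starts a chain.
    All non-initial chain members are removed; the initial member is also
    removed when the chain covers more than ``max_frames`` distinct frames.
    """
    n = len(frames)
    order = sorted(range(n), key=lambda i: (frames[i], i))
    chains: list[dict] = []  # each: first, members, last_xy, last_frame, frames(set)
    for i in order:
        candidates = []
        for c in chains:
            if 0 <= frames[i] - c["last_frame"] <= frame_gap:
                d = math.dist(xy[i], c["last_xy"])
                if d <= radius:
                    candidates.append((d, c))
        if candidates:
            c = min(candidates, key=lambda t: t[0])[1]
            c["members"].append(i)
            c["last_xy"] = xy[i]
            c["last_frame"] = frames[i]
            c["frames"].add(int(frames[i]))
        else:
            chains.append(
                {
                    "first": i,
                    "members": [i],
                    "last_xy": xy[i],
                    "last_frame": frames[i],
                    "frames": {int(frames[i])},
                }
            )
    keep = np.ones(n, dtype=bool)
    for c in chains:
        for m in c["members"][1:]:
            keep[m] = False
        if len(c["frames"]) > max_frames:
            keep[c["first"]] = False
    return keep
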