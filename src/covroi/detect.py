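"""Clustering of threshold-crossing bases into regions of interest.

A double-threshold (hysteresis) scan turns the per-base z-scores into
events: a cluster opens when z crosses the inner threshold m = alpha*n,
extends while z stays beyond m, and is reported as an ROI only if it
reaches the outer threshold n somewhere. High (over-covered) and low
(under-covered) sides are scanned independently. On circular molecules
the scan starts from a quiet position so an event spanning the origin is
reported once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detrend import DetrendedTrack
from .mixture import ThresholdSpec
from .track import CoverageTrack

__all__ = [
    "ROI",
    "cluster_rois",
    "annotate_roi",
    "merge_close_rois",
    "filter_rois",
    "find_rois",
]


@dataclass
class ROI:
    """One clustered under- or over-covered region.

    Coordinates are 1-based inclusive. ``max_zscore`` is the signed
    extremum on the ROI's side (most negative for low-side events);
    z statistics are computed over unmasked bases and are NaN for a
    region whose running median is zero throughout (reported as "NA").
    ``cn_ratio`` (mean coverage / mean running median) estimates the copy
    number of the region relative to its local baseline; ``log2_ratio``
    is its log2 (-inf for a fully deleted region, reported as "NA").
    """

    chrom: str
    start: int
    end: int
    size: int
    side: str  # "high" or "low"
    mean_cov: float
    max_cov: float
    mean_rm: float
    mean_zscore: float
    max_zscore: float
    cn_ratio: float
    log2_ratio: float


def _scan(values: np.ndarray, m: float, n: float) -> list[tuple[int, int]]:
    """Left-to-right hysteresis scan on one side.

    ``values`` must already be oriented so that "beyond the threshold"
    means ``>=``. Returns 0-based half-open intervals of maximal runs
    with values >= m whose maximum reaches n.
    """
    above = values >= m
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    return [(int(s), int(e)) for s, e in zip(starts, ends) if values[s:e].max() >= n]


def cluster_rois(
    z: np.ndarray, spec: ThresholdSpec, side: str
) -> list[tuple[int, int]]:
    """Cluster threshold-crossing bases on one side of the z-score track.

    High side: runs with ``z >= m_high`` containing a base with
    ``z >= n_high``. Low side symmetric (masked-base sentinels, being
    -inf, always satisfy the low-side test). Returns 0-based half-open
    ``(start, end)`` intervals in scan order. Ties at exactly m belong to
    the cluster.
    """
    z = np.asarray(z, dtype=np.float64)
    if side == "high":
        return _scan(z, spec.m_high, spec.n_high)
    if side == "low":
        return _scan(-z, -spec.m_low, -spec.n_low)
    raise ValueError("side must be 'high' or 'low'")


def annotate_roi(
    interval: tuple[int, int],
    track: CoverageTrack,
    detrended: DetrendedTrack,
    z: np.ndarray,
    side: str,
) -> ROI:
    """Fill all ROI statistics for one 0-based half-open interval."""
    s, e = interval
    if e <= s:
        raise ValueError("zero-length interval")
    n = len(track.coverage)
    if s < 0 or e > n:
        raise ValueError("interval outside track bounds")
    cov = track.coverage[s:e]
    rm = detrended.rm[s:e]
    zi = z[s:e]
    finite = np.isfinite(zi)
    if finite.any():
        mean_z = float(zi[finite].mean())
        max_z = float(zi[finite].max() if side == "high" else zi[finite].min())
    else:
        mean_z = math.nan
        max_z = math.nan
    mean_cov = float(cov.mean())
    mean_rm = float(rm.mean())
    cn_ratio = mean_cov / mean_rm if mean_rm > 0 else math.nan
    if cn_ratio > 0:
        log2_ratio = math.log2(cn_ratio)
    elif cn_ratio == 0:
        log2_ratio = -math.inf
    else:
        log2_ratio = math.nan
    start1 = s + track.positions_start
    end1 = e - 1 + track.positions_start
    return ROI(
        chrom=track.chrom,
        start=start1,
        end=end1,
        size=e - s,
        side=side,
        mean_cov=mean_cov,
        max_cov=float(cov.max()),
        mean_rm=mean_rm,
        mean_zscore=mean_z,
        max_zscore=max_z,
        cn_ratio=cn_ratio,
        log2_ratio=log2_ratio,
    )


def merge_close_rois(
    rois: list[ROI],
    max_gap: int,
    track: CoverageTrack | None = None,
    detrended: DetrendedTrack | None = None,
    z: np.ndarray | None = None,
) -> list[ROI]:
    """Merge same-side ROIs separated by at most ``max_gap`` bases.

    Opposite sides never merge; ``max_gap=0`` is the identity. Merged
    spans are re-annotated from the underlying track (which must then be
    supplied).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if max_gap == 0 or len(rois) < 2:
        return list(rois)
    if track is None or detrended is None or z is None:
        raise ValueError("merging requires track, detrended and z context")
    out: list[ROI] = []
    for side in ("high", "low"):
        group = sorted((r for r in rois if r.side == side), key=lambda r: r.start)
        i = 0
        while i < len(group):
            j = i
            end = group[i].end
            while j + 1 < len(group) and group[j + 1].start - end - 1 <= max_gap:
                j += 1
                end = max(end, group[j].end)
            if j == i:
                out.append(group[i])
            else:
                s0 = group[i].start - track.positions_start
                e0 = end - track.positions_start + 1
                out.append(annotate_roi((s0, e0), track, detrended, z, side))
            i = j + 1
    return sorted(out, key=lambda r: (r.start, r.side))


def filter_rois(
    rois: list[ROI], min_mean_z: float = 0.0, min_size: int = 1
) -> list[ROI]:
    """Keep ROIs with |mean z| >= min_mean_z and size >= min_size.

    Copy-number calling uses (5, 100) to suppress the short, weak events
    that pure counting noise produces; the plain defaults (0, 1) keep
    everything. A fully masked (deleted) region has no finite mean z and
    is treated as maximally significant.
    """
    kept = []
    for r in rois:
        zval = math.inf if math.isnan(r.mean_zscore) else abs(r.mean_zscore)
        if zval >= min_mean_z and r.size >= min_size:
            kept.append(r)
    return kept


def _quiet_rotation(z: np.ndarray, spec: ThresholdSpec) -> int:
    """Offset of a position quiet on both sides, or 0 if none exists."""
    quiet = (z < spec.m_high) & (z > spec.m_low)
    idx = np.flatnonzero(quiet)
    return int(idx[0]) if idx.size else 0


def find_rois(
    track: CoverageTrack,
    detrended: DetrendedTrack,
    z: np.ndarray,
    spec: ThresholdSpec | None = None,
) -> list[ROI]:
    """Run the double-threshold scan on both sides and annotate.

    On circular tracks the series is rotated to start at a quiet
    position (|z| below the inner threshold on both sides) before
    scanning, so an event spanning the origin is reported as a single
    ROI; reported coordinates are mapped back and an origin-spanning
    ROI keeps ``start > end`` semantics collapsed to the full span
    annotation computed on the rotated series.
    """
    spec = spec or ThresholdSpec()
    n = len(track.coverage)
    offset = _quiet_rotation(z, spec) if track.circular else 0
    if offset:
        z_s = np.roll(z, -offset)
        cov_s = np.roll(track.coverage, -offset)
        rm_s = np.roll(detrended.rm, -offset)
        norm_s = np.roll(detrended.normalized, -offset)
        mask_s = np.roll(detrended.undefined_mask, -offset)
        track_s = CoverageTrack(
            chrom=track.chrom,
            coverage=cov_s,
            positions_start=track.positions_start,
            circular=True,
        )
        det_s = DetrendedTrack(
            track=track_s, rm=rm_s, normalized=norm_s, undefined_mask=mask_s
        )
    else:
        z_s, track_s, det_s = z, track, detrended

    rois: list[ROI] = []
    for side in ("high", "low"):
        for interval in cluster_rois(z_s, spec, side):
            roi = annotate_roi(interval, track_s, det_s, z_s, side)
            if offset:
                s0 = (roi.start - track.positions_start + offset) % n
                e0 = (roi.end - track.positions_start + offset) % n
                roi.start = s0 + track.positions_start
                roi.end = e0 + track.positions_start
            rois.append(roi)
    return sorted(rois, key=lambda r: (r.start, r.side))
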