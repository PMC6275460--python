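"""Detrending of coverage tracks.

A slowly varying trend (origin-of-replication bow shape, GC waves, ...)
is estimated with a running median (robust to deleted/duplicated
regions, unlike a moving average) and divided out, so that the
normalized coverage is centred on 1 wherever the track follows its
local trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track import CoverageTrack

__all__ = [
    "DetrendConfig",
    "DetrendedTrack",
    "default_window",
    "moving_average",
    "running_median",
    "normalize",
    "bin_track",
    "BinnedTrack",
]


def default_window(genome_length: int) -> int:
    """Default running-median window for a chromosome of a given length.

    20,001 bases for chromosomes longer than 100,000 bases, otherwise a
    fifth of the chromosome length, forced odd.
    """
    if genome_length > 100_000:
        return 20_001
    w = max(genome_length // 5, 1)
    return w if w % 2 == 1 else w + 1


@dataclass
class DetrendConfig:
    """Window configuration for moving average / running median.

    ``W`` is the full window length in bases (odd); ``V = (W - 1) // 2``
    is the half width. Even windows are incremented to the next odd value
    with a warning.
    """

    W: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.W < 1:
            raise ValueError("window length W must be >= 1")
        if self.W % 2 == 0:
            warnings.warn(
                f"window length must be odd; using W={self.W + 1} instead of {self.W}",
                stacklevel=3,
            )
            self.W += 1

    @property
    def V(self) -> int:
        return (self.W - 1) // 2

    def validate_for(self, n: int) -> None:
        if self.circular and self.W > n:
            raise ValueError(
                f"window W={self.W} exceeds track length {n} on a circular track"
            )


@dataclass
class DetrendedTrack:
    """A coverage track together with its running median and normalized series.

    ``normalized[b] = coverage[b] / rm[b]`` where the running median is
    positive; bases where the running median is zero are flagged in
    ``undefined_mask`` (normalized set to 0 there) and are excluded from
    model fitting downstream.
    """

    track: CoverageTrack
    rm: np.ndarray
    normalized: np.ndarray
    undefined_mask: np.ndarray


def _rolling(values: np.ndarray, cfg: DetrendConfig, stat: str) -> np.ndarray:
    """Centered rolling statistic, linear (truncated edges) or circular (wrapped)."""
    n = values.size
    cfg.validate_for(n)
    if cfg.circular:
        v = cfg.V
        padded = np.concatenate([values[n - v:], values, values[:v]])
        ser = pd.Series(padded).rolling(cfg.W, center=True)
        out = getattr(ser, stat)().to_numpy()
        return out[v:v + n] if v else out
    ser = pd.Series(values).rolling(cfg.W, center=True, min_periods=1)
    return getattr(ser, stat)().to_numpy()


def moving_average(track: CoverageTrack, cfg: DetrendConfig) -> np.ndarray:
    """Centered moving average of the coverage over a window of W bases.

    Linear tracks use truncated windows at both ends so the output covers
    the full chromosome; circular tracks wrap around the origin.
    """
    return _rolling(track.coverage.astype(np.float64), cfg, "mean")


def running_median(track: CoverageTrack, cfg: DetrendConfig) -> np.ndarray:
    """Centered running median of the coverage over a window of W bases.

    The value at every position equals the median of the (possibly
    wrapped or truncated) window, bit-identical to a naive per-window
    sort; windows with an even number of points (truncated edges) average
    the two central order statistics. Total cost is O(N log W) through an
    incremental sorted-window structure.
    """
    return _rolling(track.coverage.astype(np.float64), cfg, "median")


def normalize(track: CoverageTrack, rm: np.ndarray) -> DetrendedTrack:
    """Divide coverage by its running median.

    Where the running median is zero (long fully deleted stretches) the
    ratio is undefined: normalized coverage is set to 0 and the base is
    flagged in ``undefined_mask``. Those bases are excluded from mixture
    fitting and force-classified as low-side candidates downstream.
    """
    rm = np.asarray(rm, dtype=np.float64)
    if rm.shape != track.coverage.shape:
        raise ValueError("running median length does not match track length")
    mask = rm == 0
    normalized = np.zeros_like(rm)
    np.divide(track.coverage, rm, out=normalized, where=~mask)
    return DetrendedTrack(track=track, rm=rm, normalized=normalized, undefined_mask=mask)


@dataclass
class BinnedTrack:
    """A coverage track reduced to non-overlapping k-base bin means.

    Quacks like :class:`~covroi.track.CoverageTrack` for the detrending
    and detection machinery (``chrom``, ``coverage``, ``circular``) but
    holds real-valued bin means plus the mapping back to base
    coordinates.
    """

    chrom: str
    coverage: np.ndarray  # float bin means
    bin_size: int
    n_original: int
    positions_start: int = 1
    circular: bool = False

    def __len__(self) -> int:
        return self.coverage.size

    def bin_to_base(self, i: int) -> tuple[int, int]:
        """1-based inclusive base interval covered by bin ``i`` (0-based)."""
        start = i * self.bin_size + self.positions_start
        end = min((i + 1) * self.bin_size, self.n_original) + self.positions_start - 1
        return start, end


def bin_track(track: CoverageTrack, k: int) -> BinnedTrack:
    """Merge consecutive k-base bins into their mean coverage.

    Intended for very long chromosomes where per-base analysis is not
    needed; bin ``i`` (0-based) maps back to original 1-based coordinates
    ``[i*k + 1, min((i+1)*k, N)]``. The trailing partial bin is the mean
    of its members; ``k=1`` returns the identical series.
    """
    if k < 1:
        raise ValueError("bin size k must be >= 1")
    cov = track.coverage.astype(np.float64)
    n_full = len(cov) // k
    means = cov[: n_full * k].reshape(n_full, k).mean(axis=1) if n_full else np.empty(0)
    if len(cov) % k:
        means = np.append(means, cov[n_full * k:].mean())
    return BinnedTrack(
        chrom=track.chrom,
        coverage=means,
        bin_size=k,
        n_original=len(cov),
        positions_start=track.positions_start,
        circular=track.circular,
    )
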