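"""Whole-track summary metrics and the GC-vs-coverage summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track import CoverageTrack

__all__ = ["SummaryStats", "summary_stats", "gc_coverage_histogram"]


@dataclass
class SummaryStats:
    """Descriptive metrics of one chromosome's coverage.

    ``doc_mean`` is the sequencing depth (mean of the genome coverage,
    unit X), ``boc`` the breadth of coverage (fraction of bases covered
    by at least one read), ``sigma`` the population standard deviation of
    the coverage and ``cv = sigma / doc_mean`` its coefficient of
    variation. ``centralness`` and ``W_used`` are filled once the
    normalized-coverage model has been fitted.
    """

    chrom: str
    G: int
    doc_mean: float
    doc_median: float
    sigma: float
    cv: float
    boc: float
    centralness: float = float("nan")
    W_used: int = 0


def summary_stats(track: CoverageTrack) -> SummaryStats:
    """Compute depth/breadth/variation metrics for one track.

    The standard deviation is the population (divide-by-N) estimate:
    these are descriptive statistics of the full per-base series, not a
    sample estimate.
    """
    cov = track.coverage
    if cov.size == 0:
        raise ValueError("empty track")
    doc = float(cov.mean())
    sigma = float(cov.std())
    return SummaryStats(
        chrom=track.chrom,
        G=cov.size,
        doc_mean=doc,
        doc_median=float(np.median(cov)),
        sigma=sigma,
        cv=sigma / doc if doc > 0 else float("nan"),
        boc=float(np.count_nonzero(cov >= 1)) / cov.size,
    )


_GC_BASES = frozenset("GCgcSs")
_AT_BASES = frozenset("ATatWw")


def gc_coverage_histogram(
    track: CoverageTrack,
    reference: str,
    gc_window: int = 101,
    gc_bins: int = 100,
    coverage_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint histogram of local GC fraction vs per-base coverage.

    The GC fraction at each base is computed over a centered window of
    ``gc_window`` bases (odd), truncated at the chromosome ends;
    ambiguous IUPAC bases are excluded from both numerator and
    denominator. Bases whose whole window is ambiguous have undefined GC
    and are left out; the histogram counts therefore sum to the number of
    bases with defined GC.

    Returns ``(hist, gc_edges, cov_edges)`` with ``hist[i, j]`` the
    number of bases in GC bin i and coverage bin j.
    """
    if len(reference) != len(track.coverage):
        raise ValueError(
            f"reference length {len(reference)} does not match track length "
            f"{len(track.coverage)}"
        )
    if gc_window % 2 == 0 or gc_window < 1:
        raise ValueError("gc_window must be a positive odd integer")
    seq = np.frombuffer(reference.upper().encode("ascii"), dtype="S1")
    is_gc = np.isin(seq, [b"G", b"C", b"S"]).astype(np.float64)
    is_known = (is_gc > 0) | np.isin(seq, [b"A", b"T", b"W"])
    kernel = np.ones(gc_window)
    gc_counts = np.convolve(is_gc, kernel, mode="same")
    known_counts = np.convolve(is_known.astype(np.float64), kernel, mode="same")
    defined = known_counts > 0
    gc_frac = np.full(len(seq), np.nan)
    gc_frac[defined] = 100.0 * gc_counts[defined] / known_counts[defined]

    cov = track.coverage[defined].astype(np.float64)
    if cov.size == 0:
        gc_edges = np.linspace(0.0, 100.0, gc_bins + 1)
        cov_edges = np.linspace(0.0, 1.0, coverage_bins + 1)
        return np.zeros((gc_bins, coverage_bins)), gc_edges, cov_edges
    hist, gc_edges, cov_edges = np.histogram2d(
        gc_frac[defined],
        cov,
        bins=[gc_bins, coverage_bins],
        range=[[0.0, 100.0], [0.0, max(float(cov.max()), 1.0)]],
    )
    return hist, gc_edges, cov_edges
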