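"""Model/Results interface tying the pipeline stages together.

``CoverageModel`` holds one chromosome's coverage track and the analysis
configuration; ``fit()`` detrends the track, fits the normalized-coverage
mixture and returns a ``CoverageResults`` carrying the estimates, the
per-base z-scores, the adaptive thresholds, the detected ROIs and a
summary table.
"""

from __future__ import annotations


from pathlib import Path

import numpy as np

from . import detect, io as _io
from .detrend import (
    BinnedTrack,
    DetrendConfig,
    bin_track,
    default_window,
    normalize,
    running_median,
)
from .mixture import (
    MixtureFit,
    ThresholdSpec,
    adaptive_thresholds,
    centralness,
    fit_em,
    zscores,
)
from .stats import SummaryStats, summary_stats
from .track import CoverageTrack

__all__ = ["CoverageModel", "CoverageResults"]


class CoverageModel:
    """Normalized-coverage mixture model for one chromosome.

    Parameters
    ----------
    track : CoverageTrack
        Per-base coverage of one chromosome.
    window : int or "auto"
        Running-median window W (odd). "auto" resolves to 20,001 bases
        for chromosomes longer than 100 kb, else a fifth of the length.
    circular : bool, optional
        Overrides the track's circularity flag.
    thresholds : ThresholdSpec, optional
        Outer/inner z thresholds (defaults n = +/-4, alpha = 1/2).
    binning : int, optional
        Analyze k-base bin means instead of single bases (large genomes);
        reported ROI coordinates are mapped back to base space.
    """

    def __init__(
        self,
        track: CoverageTrack,
        window: int | str = "auto",
        circular: bool | None = None,
        thresholds: ThresholdSpec | None = None,
        binning: int | None = None,
    ) -> None:
        self.track = track
        if circular is not None:
            track.circular = circular
        self.thresholds = thresholds or ThresholdSpec()
        self.binning = binning
        work = bin_track(track, binning) if binning and binning > 1 else track
        self._work = work
        # window is expressed in bases; under binning it is rescaled to bins
        w = default_window(len(track.coverage)) if window == "auto" else int(window)
        if binning and binning > 1:
            w = max(w // binning, 1)
            w += w % 2 == 0
        self.config = DetrendConfig(W=w, circular=track.circular)
        self.config.validate_for(len(work.coverage))

    @classmethod
    def from_bed(
        cls, path: str | Path, chromosome: str | None = None, **kwargs
    ) -> "CoverageModel":
        """Build a model from the first (or a named) chromosome of a BED file."""
        circular = kwargs.pop("circular", None)
        tracks = _io.read_bed(path, circular=bool(circular))
        if chromosome is not None:
            names = [t.chrom for t in tracks]
            if chromosome not in names:
                raise ValueError(
                    f"chromosome {chromosome!r} not in input; available: {names}"
                )
            track = tracks[names.index(chromosome)]
        else:
            track = tracks[0]
        return cls(track, circular=circular, **kwargs)

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> "CoverageResults":
        """Detrend, fit the mixture by EM and score every base."""
        work = self._work
        rm = running_median(work, self.config)
        detrended = normalize(work, rm)
        fit = fit_em(
            detrended.normalized,
            detrended.undefined_mask,
            max_iter=max_iter,
            tol=tol,
        )
        z = zscores(detrended, fit)
        return CoverageResults(self, detrended, fit, z)


class CoverageResults:
    """Fitted model: estimates, per-base scores, ROIs and summaries."""

    def __init__(self, model, detrended, mixture: MixtureFit, z: np.ndarray) -> None:
        self.model = model
        self.track = model.track
        self.detrended = detrended
        self.mixture = mixture
        self.z = z
        self._stats: SummaryStats | None = None

    # -- scores and thresholds ------------------------------------------------
    def thresholds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) per-base coverage thresholds in the original space."""
        return adaptive_thresholds(self.detrended.rm, self.mixture, self.model.thresholds)

    def centralness(self, n: float | None = None) -> float:
        n = n if n is not None else self.model.thresholds.n_high
        return centralness(self.z, n)

    # -- ROIs -----------------------------------------------------------------
    def rois(
        self,
        cnv_mode: bool = False,
        merge_gap: int = 0,
        min_mean_z: float | None = None,
        min_size: int | None = None,
    ) -> list[detect.ROI]:
        """Detect and annotate ROIs with the double-threshold scan.

        ``cnv_mode`` applies the copy-number filter defaults (|mean z| >=
        5, size >= 100) that remove the short weak events counting noise
        produces. When the model was built with binning, coordinates are
        mapped back to base space.
        """
        work = self.model._work
        rois = detect.find_rois(work, self.detrended, self.z, self.model.thresholds)
        if merge_gap:
            rois = detect.merge_close_rois(
                rois, merge_gap, work, self.detrended, self.z
            )
        if min_mean_z is None:
            min_mean_z = 5.0 if cnv_mode else 0.0
        if min_size is None:
            min_size = 100 if cnv_mode else 1
        rois = detect.filter_rois(rois, min_mean_z=min_mean_z, min_size=min_size)
        if isinstance(work, BinnedTrack):
            k = work.bin_size
            for r in rois:
                s_bin = r.start - work.positions_start
                e_bin = r.end - work.positions_start
                r.start = work.bin_to_base(s_bin)[0]
                r.end = work.bin_to_base(e_bin)[1]
                r.size = r.end - r.start + 1
        return rois

    def roi_frame(self, **kwargs):
        """ROIs as a pandas DataFrame (columns as in the CSV output)."""
        import pandas as pd

        rois = self.rois(**kwargs)
        return pd.DataFrame(
            [[getattr(r, c) for c in _io.ROI_COLUMNS] for r in rois],
            columns=_io.ROI_COLUMNS,
        )

    # -- summaries ------------------------------------------------------------
    @property
    def stats(self) -> SummaryStats:
        if self._stats is None:
            st = summary_stats(self.track)
            st.centralness = self.centralness()
            st.W_used = self.model.config.W
            self._stats = st
        return self._stats

    def summary(self) -> str:
        """Human-readable summary table."""
        st = self.stats
        mx = self.mixture
        spec = self.model.thresholds
        rois = self.rois()
        n_low = sum(r.side == "low" for r in rois)
        n_high = len(rois) - n_low
        lines = [
            f"Coverage model: {st.chrom} ({st.G:,} bases, "
            f"{'circular' if self.track.circular else 'linear'})",
            "-" * 58,
            f"  sequencing depth (mean/median)  {st.doc_mean:10.3f} / {st.doc_median:.1f}",
            f"  breadth of coverage (BOC)       {st.boc:10.4f}",
            f"  coefficient of variation        {st.cv:10.4f}",
            f"  running-median window W         {st.W_used:10d}",
            f"  central component mu0           {mx.mu0:10.4f}",
            f"  central component sigma0        {mx.sigma0:10.4f}",
            f"  central weight pi0              {mx.pi0:10.4f}",
            f"  EM iterations (converged)       {mx.n_iter:10d} ({mx.converged})",
            f"  centralness (n={spec.n_high:g})              {st.centralness:10.4f}",
            f"  ROIs (low / high)               {n_low:6d} / {n_high:d}",
        ]
        if mx.single_population:
            lines.append("  note: no separated outlier class; central = whole data")
        return "\n".join(lines)

    # -- output files ---------------------------------------------------------
    def to_csv(self, path, **kwargs) -> None:
        _io.write_roi_csv(self.rois(**kwargs), path)

    def to_json(self, path, **kwargs) -> None:
        rois = self.rois(**kwargs)
        n_low = sum(r.side == "low" for r in rois)
        _io.write_summary_json(
            self.stats,
            self.mixture,
            path,
            thresholds=self.model.thresholds,
            n_rois_low=n_low,
            n_rois_high=len(rois) - n_low,
        )

    # -- plotting -------------------------------------------------------------
    def plot(self, ax=None, max_points: int = 100_000):
        """Coverage with running median and adaptive thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        work = self.model._work
        n = len(work.coverage)
        step = max(n // max_points, 1)
        x = np.arange(n)[::step]
        lower, upper = self.thresholds()
        ax.plot(x, work.coverage[::step], color="k", lw=0.3, label="coverage")
        ax.plot(x, self.detrended.rm[::step], color="r", lw=1, label="running median")
        ax.plot(x, upper[::step], "r--", lw=0.8, label="thresholds")
        ax.plot(x, lower[::step], "r--", lw=0.8)
        ax.set_xlabel("position (b)")
        ax.set_ylabel("coverage (X)")
        ax.legend(loc="upper right", fontsize=8)
        return ax
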