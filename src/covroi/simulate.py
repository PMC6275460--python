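"""Synthetic coverage tracks with known structure.

Two noise models are provided. ``poisson`` draws each base
independently (the Lander-Waterman idealization); ``read_placement``
drops reads of fixed length uniformly on the genome and accumulates
per-base depth, which reproduces the short-range autocorrelation of real
coverage (adjacent bases share reads). Paired mode places two reads per
fragment with a fragment length of N(200, 10) bases clipped at the read
length, the standard short-read simulator default for 2x100 bp
libraries; overlapping mates double-count, as per-read coverage counters
do.

An optional low-frequency "bow" trend emulates the origin-of-replication
shape of rapidly growing bacteria: expected depth varies smoothly from
``depth * endpoints_factor`` at the ends of the sequence to ``depth`` in
the middle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track import CoverageTrack

__all__ = [
    "BowTrend",
    "SimulationSpec",
    "simulate_coverage",
    "inject_events",
    "sample_event_positions",
    "null_experiment",
    "recovery_experiment",
    "EventRecovery",
]


@dataclass
class BowTrend:
    """Smooth multiplicative trend from ``endpoints_factor`` at both ends to 1 mid-genome."""

    endpoints_factor: float = 1.25

    def __call__(self, G: int) -> np.ndarray:
        b = np.arange(G)
        f = self.endpoints_factor
        return f + (1.0 - f) * np.sin(np.pi * b / max(G - 1, 1))


@dataclass
class SimulationSpec:
    """Recipe for one synthetic coverage track.

    ``events`` holds 1-based inclusive ``(start, end, cn)`` triplets with
    ``cn >= 0`` the region's copy number relative to baseline (``cn=1``
    is a no-op, ``cn=0`` a homozygous deletion).
    """

    G: int
    depth: float = 100.0
    noise: str = "poisson"  # or "read_placement" / "none"
    read_len: int = 100
    paired: bool = True
    frag_mean: float = 200.0
    frag_sd: float = 10.0
    trend: BowTrend | None = None
    events: list[tuple[int, int, float]] = field(default_factory=list)
    circular: bool = True
    seed: int = 0
    chrom: str = "sim"

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("genome length G must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.noise not in ("poisson", "read_placement", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.noise == "read_placement" and not 1 <= self.read_len <= self.G:
            raise ValueError("read_len must be in [1, G]")
        _check_events(self.events, self.G)


def _check_events(events, G) -> None:
    prev_end = 0
    for start, end, cn in sorted(events):
        if not 1 <= start <= end <= G:
            raise ValueError(f"event ({start}, {end}) outside [1, {G}]")
        if cn < 0:
            raise ValueError("event copy number must be >= 0")
        if start <= prev_end:
            raise ValueError("events must be pairwise non-overlapping")
        prev_end = end


def _read_placement_coverage(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    G, L = spec.G, spec.read_len
    n_reads = int(round(G * spec.depth / L))
    if spec.trend is not None:
        weights = spec.trend(G)
        p = weights / weights.sum()
    else:
        p = None
    if spec.paired:
        n_frag = n_reads // 2
        if p is None:
            s1 = rng.integers(0, G, n_frag)
        else:
            s1 = rng.choice(G, size=n_frag, p=p)
        frag = np.rint(rng.normal(spec.frag_mean, spec.frag_sd, n_frag)).astype(np.int64)
        frag = np.maximum(frag, L)
        s2 = s1 + frag - L
        starts = np.concatenate([s1, s2])
    else:
        if p is None:
            starts = rng.integers(0, G, n_reads)
        else:
            starts = rng.choice(G, size=n_reads, p=p)
    if spec.circular:
        starts %= G
    else:
        starts = np.clip(starts, 0, G - L)
    counts = np.bincount(starts, minlength=G)
    diff = np.zeros(G + L, dtype=np.int64)
    diff[:G] += counts
    diff[L:G + L] -= counts
    cov = np.cumsum(diff)
    if spec.circular:
        cov[:L] += cov[G:G + L]
    return cov[:G]


def simulate_coverage(spec: SimulationSpec, rng: np.random.Generator | None = None) -> CoverageTrack:
    """Generate a seeded, reproducible coverage track from a spec.

    The spec's ``seed`` is used unless an explicit generator is passed.
    Events listed in the spec are injected after the baseline noise is
    drawn (same generator stream).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if spec.noise in ("poisson", "none"):
        lam = np.full(spec.G, float(spec.depth))
        if spec.trend is not None:
            lam *= spec.trend(spec.G)
        # "none" is the noise-free limit used to test trend shapes
        cov = rng.poisson(lam) if spec.noise == "poisson" else np.rint(lam).astype(np.int64)
    else:
        cov = _read_placement_coverage(spec, rng)
    track = CoverageTrack(
        chrom=spec.chrom, coverage=cov, positions_start=1, circular=spec.circular
    )
    if spec.events:
        track = inject_events(track, spec.events, rng=rng)
    return track


def inject_events(
    track: CoverageTrack,
    events: list[tuple[int, int, float]],
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CoverageTrack:
    """Multiply regions of a track by known copy numbers.

    ``cn = 0`` zeroes the region exactly; ``cn < 1`` thins every count
    independently (binomial with probability cn); ``cn > 1`` adds
    independent Poisson counts with mean ``(cn - 1)`` times the region's
    local expectation (its mean coverage), so the region mean becomes
    approximately ``cn`` times baseline.
    """
    _check_events(events, len(track.coverage))
    rng = rng if rng is not None else np.random.default_rng(seed)
    cov = track.coverage.copy()
    for start, end, cn in events:
        s, e = start - 1, end  # to 0-based half-open
        if cn == 1:
            continue
        if cn == 0:
            cov[s:e] = 0
        elif cn < 1:
            cov[s:e] = rng.binomial(cov[s:e], cn)
        else:
            lam = (cn - 1.0) * cov[s:e].mean()
            cov[s:e] += rng.poisson(lam, e - s)
    return CoverageTrack(
        chrom=track.chrom,
        coverage=cov,
        positions_start=track.positions_start,
        circular=track.circular,
    )


def sample_event_positions(
    G: int,
    n_events: int,
    min_len: int,
    max_len: int,
    rng: np.random.Generator,
    cn: float | list[float] = 0.0,
    min_gap: int = 1,
) -> list[tuple[int, int, float]]:
    """Draw non-overlapping event intervals uniformly, with rejection.

    Lengths are uniform in [min_len, max_len]; events keep at least
    ``min_gap`` bases between each other. Returns 1-based inclusive
    ``(start, end, cn)`` triplets sorted by start.
    """
    cns = list(cn) if isinstance(cn, (list, tuple, np.ndarray)) else [cn] * n_events
    if len(cns) != n_events:
        raise ValueError("one copy number per event required")
    chosen: list[tuple[int, int]] = []
    attempts = 0
    while len(chosen) < n_events:
        attempts += 1
        if attempts > 1000 * n_events:
            raise RuntimeError("could not place events without overlap")
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(1, G - length + 1))
        end = start + length - 1
        if all(end + min_gap < s or e + min_gap < start for s, e in chosen):
            chosen.append((start, end))
    chosen.sort()
    return [(s, e, c) for (s, e), c in zip(chosen, cns)]


@dataclass
class EventRecovery:
    """Outcome of one injected-event recovery experiment.

    ``matches[i]`` holds every same-side detected ROI overlapping
    injected event i (empty if the event was missed). The event's copy
    number is estimated over the union span of its matching ROIs -- mean
    coverage over mean running median -- so that an event shattered into
    several reported pieces (its interior dipping below the inner
    threshold here and there) is still measured over its full extent.
    Breakpoint errors compare the union span's boundaries with the
    injected ones.
    """

    events: list[tuple[int, int, float]]
    rois: list
    matches: list[list]
    cn_estimates: np.ndarray

    @property
    def n_detected(self) -> int:
        return sum(bool(m) for m in self.matches)

    @property
    def sensitivity(self) -> float:
        return self.n_detected / len(self.events) if self.events else float("nan")

    @property
    def breakpoint_errors(self) -> np.ndarray:
        errs = []
        for (s, e, _), group in zip(self.events, self.matches):
            if group:
                start = min(r.start for r in group)
                end = max(r.end for r in group)
                errs.append(max(abs(start - s), abs(end - e)))
        return np.asarray(errs)

    def cn_ratios(self, cn: float | None = None) -> np.ndarray:
        """Copy-number estimates of detected events, optionally for one true CN."""
        out = [
            est
            for (_, _, c), est, group in zip(self.events, self.cn_estimates, self.matches)
            if group and (cn is None or c == cn)
        ]
        return np.asarray(out)


def match_events(events, rois) -> list[list]:
    """All same-side ROIs overlapping each event."""
    matches = []
    for s, e, cn in events:
        side = "low" if cn < 1 else "high"
        matches.append(
            [r for r in rois if r.side == side and r.start <= e and r.end >= s]
        )
    return matches


def recovery_experiment(
    spec: SimulationSpec,
    events: list[tuple[int, int, float]],
    window: int | str = "auto",
    thresholds=None,
    cnv_mode: bool = False,
) -> EventRecovery:
    """Inject events into a simulated track and measure their recovery.

    Simulates the baseline from ``spec`` (which must be event-free),
    injects ``events``, runs the full detection pipeline and matches
    every event to the reported ROIs overlapping it.
    """
    from .model import CoverageModel

    if spec.events:
        raise ValueError("pass events separately, not inside the spec")
    rng = np.random.default_rng(spec.seed)
    track = simulate_coverage(spec, rng=rng)
    track = inject_events(track, events, rng=rng)
    res = CoverageModel(track, window=window, thresholds=thresholds).fit()
    rois = res.rois(cnv_mode=cnv_mode)
    matches = match_events(events, rois)
    rm = res.detrended.rm
    cov = track.coverage
    cn_est = np.full(len(events), np.nan)
    for i, group in enumerate(matches):
        if group:
            s = min(r.start for r in group) - track.positions_start
            e = max(r.end for r in group) - track.positions_start + 1
            denom = rm[s:e].mean()
            cn_est[i] = cov[s:e].mean() / denom if denom > 0 else np.nan
    return EventRecovery(events=events, rois=rois, matches=matches, cn_estimates=cn_est)


def null_experiment(
    n_replicates: int,
    spec: SimulationSpec,
    window: int | str = "auto",
    thresholds=None,
    seed: int = 0,
):
    """Run the full detection pipeline on event-free replicates.

    Returns a dict with per-replicate ROI counts and the size and |mean
    z| extrema over all replicates' ROIs, characterizing the method's
    false-positive behaviour under pure counting noise.
    """
    from .model import CoverageModel

    if spec.events:
        raise ValueError("null experiment requires a spec without events")
    ss = np.random.SeedSequence(seed)
    counts = []
    max_size = 0
    max_abs_mean_z = 0.0
    sizes: list[int] = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        track = simulate_coverage(spec, rng=rng)
        res = CoverageModel(track, window=window, thresholds=thresholds).fit()
        rois = res.rois()
        counts.append(len(rois))
        for r in rois:
            sizes.append(r.size)
            max_size = max(max_size, r.size)
            if not np.isnan(r.mean_zscore):
                max_abs_mean_z = max(max_abs_mean_z, abs(r.mean_zscore))
    return {
        "counts": np.asarray(counts),
        "mean_count": float(np.mean(counts)),
        "sd_count": float(np.std(counts)),
        "sizes": np.asarray(sizes),
        "max_size": max_size,
        "max_abs_mean_z": max_abs_mean_z,
    }
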