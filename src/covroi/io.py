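"""Reading per-base coverage BED files and writing result files.

The input dialect is the three-column tab-delimited output of
``bedtools genomecov -d``: chromosome, 1-based position, integer depth.
Four-column bedGraph interval files are rejected explicitly. BAM/CRAM
are not parsed; convert externally, e.g.::

    bedtools genomecov -d -ibam sample.bam > sample.bed
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np

from .detect import ROI
from .mixture import MixtureFit, ThresholdSpec
from .track import CoverageTrack, MAX_COVERAGE

__all__ = [
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_roi_csv",
    "read_roi_csv",
    "write_summary_json",
    "BedParseError",
]

ROI_COLUMNS = [
    "chrom",
    "start",
    "end",
    "size",
    "mean_cov",
    "max_cov",
    "mean_rm",
    "mean_zscore",
    "max_zscore",
    "log2_ratio",
]


class BedParseError(ValueError):
    """Malformed coverage BED input."""


def read_bed(path: str | Path, circular: bool = False) -> list[CoverageTrack]:
    """Read a 3-column per-base coverage file into per-chromosome tracks.

    One track per distinct chromosome, in file order. Positions within a
    chromosome must be contiguous and strictly increasing by 1; the
    coverage vector is indexed from the first observed position.
    """
    path = Path(path)
    tracks: list[CoverageTrack] = []
    chrom = None
    start_pos = None
    last_pos = None
    values: list[int] = []
    seen: set[str] = set()

    def flush() -> None:
        if chrom is not None:
            tracks.append(
                CoverageTrack(
                    chrom=chrom,
                    coverage=np.asarray(values, dtype=np.int64),
                    positions_start=start_pos,
                    circular=circular,
                )
            )

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 4:
                raise BedParseError(
                    f"line {lineno}: 4 fields found; interval bedGraph input is "
                    "not supported, use per-base 'genomecov -d' output"
                )
            if len(fields) != 3:
                raise BedParseError(
                    f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            name, pos_s, cov_s = fields
            try:
                pos = int(pos_s)
                cov = int(cov_s)
            except ValueError as exc:
                raise BedParseError(
                    f"line {lineno}: non-integer position or coverage: {line!r}"
                ) from exc
            if cov < 0 or cov > MAX_COVERAGE:
                raise BedParseError(f"line {lineno}: coverage {cov} out of range")
            if name != chrom:
                if name in seen:
                    raise BedParseError(
                        f"line {lineno}: chromosome {name!r} appears in two blocks"
                    )
                flush()
                chrom = name
                seen.add(name)
                start_pos = pos
                last_pos = pos
                values = [cov]
            else:
                if pos != last_pos + 1:
                    raise BedParseError(
                        f"line {lineno}: position {pos} not contiguous with "
                        f"{last_pos} on {name}"
                    )
                last_pos = pos
                values.append(cov)
    if chrom is None:
        raise BedParseError(f"{path}: empty coverage file")
    flush()
    return tracks


def read_fasta(path: str | Path) -> dict[str, str]:
    """Reference sequences by record name (for the GC-vs-coverage summary)."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(rec[:]) for name, rec in fa.items()}


def write_bed(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write tracks back to the 3-column per-base dialect."""
    with open(path, "w") as fh:
        for track in tracks:
            for pos, cov in zip(track.positions, track.coverage):
                fh.write(f"{track.chrom}\t{pos}\t{cov}\n")


def _fmt(value: float) -> str:
    if isinstance(value, float):
        if math.isnan(value) or math.isinf(value):
            return "NA"
        return f"{value:.6f}"
    return str(value)


def write_roi_csv(rois: Iterable[ROI], path: str | Path) -> None:
    """Write one ROI per row; columns fixed, floats to 6 decimals, NA for
    undefined statistics (fully deleted regions)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROI_COLUMNS)
        for roi in rois:
            writer.writerow([_fmt(getattr(roi, col)) for col in ROI_COLUMNS])


def read_roi_csv(path: str | Path) -> list[ROI]:
    """Re-parse a ROI CSV written by :func:`write_roi_csv`.

    The side is reconstructed from the sign of the extreme z-score (low
    when negative or NA). Used for round-trip checks and downstream
    scripting.
    """

    def _f(s: str) -> float:
        return math.nan if s == "NA" else float(s)

    rois = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            max_z = _f(row["max_zscore"])
            log2_ratio = _f(row["log2_ratio"])
            cn = 2.0 ** log2_ratio if not math.isnan(log2_ratio) else math.nan
            rois.append(
                ROI(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    size=int(row["size"]),
                    side="high" if max_z > 0 else "low",
                    mean_cov=_f(row["mean_cov"]),
                    max_cov=_f(row["max_cov"]),
                    mean_rm=_f(row["mean_rm"]),
                    mean_zscore=_f(row["mean_zscore"]),
                    max_zscore=max_z,
                    cn_ratio=cn,
                    log2_ratio=log2_ratio,
                )
            )
    return rois


def write_summary_json(stats, fit: MixtureFit, path: str | Path, *,
                       thresholds: ThresholdSpec | None = None,
                       n_rois_low: int = 0, n_rois_high: int = 0) -> None:
    """Write the per-chromosome summary (depth, BOC, CV, fit, centralness, ROI counts)."""
    thresholds = thresholds or ThresholdSpec()
    payload = {
        "chrom": stats.chrom,
        "length": stats.G,
        "DOC_mean": stats.doc_mean,
        "DOC_median": stats.doc_median,
        "BOC": stats.boc,
        "sigma": stats.sigma,
        "CV": stats.cv,
        "centralness": stats.centralness,
        "W": stats.W_used,
        "thresholds": {
            "n_high": thresholds.n_high,
            "n_low": thresholds.n_low,
            "alpha": thresholds.alpha,
        },
        "mu0": fit.mu0,
        "sigma0": fit.sigma0,
        "pi0": fit.pi0,
        "n_rois_low": n_rois_low,
        "n_rois_high": n_rois_high,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
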