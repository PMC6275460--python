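"""Per-chromosome coverage containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_COVERAGE = 2**31 - 1


@dataclass
class CoverageTrack:
    """Per-base genome coverage of one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name as given in the input.
    coverage : ndarray of int
        Number of reads covering each base, one entry per base.
    positions_start : int
        1-based position of the first entry of ``coverage``.
    circular : bool
        Whether the molecule is circular (windows and events may wrap
        around the origin).
    """

    chrom: str
    coverage: np.ndarray
    positions_start: int = 1
    circular: bool = False

    def __post_init__(self) -> None:
        cov = np.asarray(self.coverage)
        if cov.ndim != 1 or cov.size == 0:
            raise ValueError("coverage must be a non-empty 1-D array")
        if not np.issubdtype(cov.dtype, np.integer):
            as_int = cov.astype(np.int64)
            if not np.array_equal(as_int, cov):
                raise ValueError("coverage values must be integers")
            cov = as_int
        else:
            cov = cov.astype(np.int64)
        if cov.min() < 0:
            raise ValueError("coverage values must be >= 0")
        if cov.max() > MAX_COVERAGE:
            raise ValueError(f"coverage values above {MAX_COVERAGE} are rejected")
        self.coverage = cov

    def __len__(self) -> int:
        return self.coverage.size

    @property
    def positions(self) -> np.ndarray:
        """1-based base positions of the track."""
        return np.arange(self.positions_start, self.positions_start + len(self))
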