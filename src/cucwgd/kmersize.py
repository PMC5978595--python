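"""Genome-size estimation from a k-mer depth histogram.

Given the histogram of k-mer multiplicities (depth d -> number of distinct
k-mers k_d), the genome size is estimated as

    G = sum_{d > valley} d * k_d / D

where D is the modal depth of the genomic component.  The leftmost part of
the histogram, up to the first valley of the smoothed counts, is discarded:
it is dominated by k-mers created by sequencing errors, which appear at
depths far below the sequencing coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KmerHistogram",
    "GenomeSizeEstimate",
    "find_error_valley",
    "estimate_genome_size",
    "coverage_fraction",
]


@dataclass
class KmerHistogram:
    """Depth -> count table (jellyfish ``histo`` dialect)."""

    depths: np.ndarray
    counts: np.ndarray
    k: int | None = None

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.depths.size != self.counts.size:
            raise ValueError("depths and counts differ in length")
        if self.depths.size == 0:
            raise ValueError("empty histogram")
        if np.any(self.depths <= 0):
            raise ValueError("depths must be positive")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_mapping(cls, mapping: dict[int, int], k: int | None = None) -> "KmerHistogram":
        items = sorted(mapping.items())
        return cls(np.array([d for d, _ in items]), np.array([c for _, c in items]), k)

    @classmethod
    def from_tsv(cls, path, k: int | None = None) -> "KmerHistogram":
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None, names=["depth", "count"]
        )
        return cls(df["depth"].to_numpy(), df["count"].to_numpy(), k)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.k is not None:
                fh.write(f"# k={self.k}\n")
            for d, c in zip(self.depths, self.counts):
                fh.write(f"{d}\t{c}\n")

    @property
    def total_mass(self) -> int:
        """Total k-mer mass sum(d * k_d)."""
        return int(np.sum(self.depths * self.counts))

    def dense(self) -> tuple[np.ndarray, np.ndarray]:
        """Contiguous depth grid 1..max with zero-filled counts."""
        grid = np.arange(1, self.depths.max() + 1)
        counts = np.zeros(grid.size, dtype=np.int64)
        counts[self.depths - 1] = self.counts
        return grid, counts


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    if window == 1:
        return counts.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def _first_valley(grid: np.ndarray, sm: np.ndarray) -> int | None:
    for i in range(1, sm.size - 1):
        if sm[i] <= sm[i - 1] and sm[i] < sm[i + 1]:
            return int(grid[i])
    return None


def find_error_valley(hist: KmerHistogram, smooth_window: int = 3) -> int | None:
    """First local minimum of the smoothed counts, scanning from depth 1.

    Returns the depth of the valley separating the low-depth error component
    from the genomic peak, or None when the smoothed counts never rise again
    (monotone decreasing histogram: no genomic peak is detectable).
    """
    if hist.depths.size < 3:
        raise ValueError("histogram needs at least 3 distinct depths")
    grid, counts = hist.dense()
    return _first_valley(grid, _smooth(counts, smooth_window))


@dataclass
class GenomeSizeEstimate:
    estimate: float
    modal_depth: int
    valley: int
    discarded_mass: int
    used_mass: int
    full_sum: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def estimate_genome_size(
    hist: KmerHistogram,
    smooth_window: int = 3,
    full_sum: bool = False,
    peak_depth: int | None = None,
) -> GenomeSizeEstimate:
    """Estimate genome size as sum(d * k_d) / D over post-valley depths.

    D is the depth at which the smoothed, error-truncated histogram attains
    its maximum count (the modal depth of the genomic component), detected
    automatically unless ``peak_depth`` is supplied.  With ``full_sum`` the
    numerator runs over all depths instead of only d > valley.

    Raises when no valley exists or when the detected peak sits at the edge
    of the histogram (truncated peak); in both cases a manual ``peak_depth``
    is the documented way out.
    """
    grid, counts = hist.dense()
    sm = _smooth(counts, smooth_window)

    valley = _first_valley(grid, sm)
    if valley is None:
        if peak_depth is None:
            raise ValueError(
                "no error valley detected (counts monotone decreasing); "
                "supply peak_depth manually if the modal depth is known"
            )
        valley = 0

    if peak_depth is not None:
        modal = int(peak_depth)
        if modal <= 0:
            raise ValueError("peak_depth must be positive")
    else:
        mask = grid > valley
        if not mask.any():
            raise ValueError("valley at histogram edge; supply peak_depth manually")
        sub_sm = sm[mask]
        sub_grid = grid[mask]
        sub_raw = counts[mask]
        best = np.flatnonzero(sub_sm == sub_sm.max())
        # ties on smoothed counts: prefer the depth with the larger raw
        # count, then the smaller depth
        best = best[np.lexsort((sub_grid[best], -sub_raw[best]))]
        modal = int(sub_grid[best[0]])
        if modal == valley + 1:
            raise ValueError(
                f"modal depth {modal} sits directly at the valley ({valley}); "
                "peak may be truncated - supply peak_depth manually"
            )
        raw_peak = int(sub_grid[np.argmax(sub_raw)])
        last = counts[-3:]
        if raw_peak == int(grid[-1]) and last.size == 3 and last[0] < last[1] < last[2]:
            raise ValueError(
                "counts still rising at the largest depth; histogram peak "
                "appears truncated - supply peak_depth manually"
            )

    keep = np.ones(grid.size, dtype=bool) if full_sum else grid > valley
    used_mass = int(np.sum(grid[keep] * counts[keep]))
    discarded = int(np.sum(grid[~keep] * counts[~keep]))
    return GenomeSizeEstimate(
        estimate=used_mass / modal,
        modal_depth=modal,
        valley=int(valley),
        discarded_mass=discarded,
        used_mass=used_mass,
        full_sum=full_sum,
    )


def coverage_fraction(assembly_bp: float, genome_size_bp: float) -> float:
    """Assembly span as a percentage of the estimated genome size (1 dp)."""
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    if assembly_bp < 0:
        raise ValueError("assembly length must be nonnegative")
    return round(100.0 * assembly_bp / genome_size_bp, 1)
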