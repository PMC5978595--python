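"""Mate-pair chimera classification from alignment coordinates.

Long-insert (mate-pair) libraries are prone to chimeric pairs that join
unrelated loci; left in, they wreck scaffolding.  Given read-pair alignment
coordinates against a draft assembly and a library specification (expected
relative orientation plus an accepted insert-distance window), each pair is
classified:

* ``keep``        -- both ends on one scaffold, expected orientation,
                     distance inside the window;
* ``chimeric``    -- both ends on one scaffold but orientation or distance
                     violated;
* ``unresolved``  -- an end unmapped, or ends on different scaffolds
                     (cannot be adjudicated against a draft assembly and is
                     excluded from the chimera denominator).

The per-library chimera fraction is n_chimeric / (n_keep + n_chimeric).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatePairRecord",
    "LibrarySpec",
    "pair_orientation",
    "outer_distance",
    "estimate_insert_window",
    "classify_pair",
    "filter_library",
    "records_to_frame",
    "records_from_frame",
]

KEEP = "keep"
CHIMERIC = "chimeric"
UNRESOLVED = "unresolved"


@dataclass
class MatePairRecord:
    """One aligned read pair (1-based leftmost positions)."""

    pair_id: str
    scaffold_a: str
    pos_a: int
    strand_a: str
    scaffold_b: str
    pos_b: int
    strand_b: str
    mapped_a: bool = True
    mapped_b: bool = True

    def __post_init__(self) -> None:
        for strand in (self.strand_a, self.strand_b):
            if strand not in ("+", "-"):
                raise ValueError(f"strand must be + or -, got {strand!r}")
        if self.mapped_a and self.pos_a < 1:
            raise ValueError("mapped positions are 1-based (>= 1)")
        if self.mapped_b and self.pos_b < 1:
            raise ValueError("mapped positions are 1-based (>= 1)")

    def swapped(self) -> "MatePairRecord":
        """The same pair with ends a and b exchanged."""
        return replace(
            self,
            scaffold_a=self.scaffold_b, pos_a=self.pos_b, strand_a=self.strand_b,
            mapped_a=self.mapped_b,
            scaffold_b=self.scaffold_a, pos_b=self.pos_a, strand_b=self.strand_a,
            mapped_b=self.mapped_a,
        )


@dataclass
class LibrarySpec:
    """Expected geometry of a sequencing library.

    ``expected_orientation`` is FR (reads pointing inwards, the paired-end
    convention) or RF (outwards, the pre-Nextera mate-pair convention).
    When ``window`` is None it defaults to [0.5, 2] x nominal_insert; use
    :func:`estimate_insert_window` for a data-driven window.
    """

    nominal_insert: float
    expected_orientation: str = "RF"
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.expected_orientation not in ("FR", "RF"):
            raise ValueError("expected_orientation must be FR or RF")
        if self.nominal_insert <= 0:
            raise ValueError("nominal_insert must be positive")
        if self.window is not None:
            low, high = self.window
            if not 0 < low < high:
                raise ValueError("window must satisfy 0 < low < high")

    def effective_window(self) -> tuple[float, float]:
        if self.window is not None:
            return self.window
        return (0.5 * self.nominal_insert, 2.0 * self.nominal_insert)


def pair_orientation(record: MatePairRecord) -> str | None:
    """Relative orientation FR / RF, or None for tandem (same-strand) pairs.

    Determined from the strand of the leftmost vs the rightmost read, so it
    is invariant under swapping the two ends.
    """
    if record.strand_a == record.strand_b:
        return None
    if (record.pos_a, record.strand_a) <= (record.pos_b, record.strand_b):
        left, right = record.strand_a, record.strand_b
    else:
        left, right = record.strand_b, record.strand_a
    return "FR" if left == "+" else "RF"


def outer_distance(record: MatePairRecord) -> int:
    """Distance between the two leftmost alignment coordinates."""
    return abs(record.pos_b - record.pos_a)


def estimate_insert_window(
    records: Iterable[MatePairRecord],
    lib: LibrarySpec,
    percentiles: tuple[float, float] = (1.0, 99.0),
    min_pairs: int = 100,
) -> tuple[float, float]:
    """Data-driven accepted-distance window.

    Takes the chosen percentiles of outer distances over pairs that map to
    a single scaffold with the expected orientation.  Fails when fewer than
    ``min_pairs`` qualifying pairs exist, in which case a manual window
    must be supplied on the LibrarySpec.
    """
    dists = [
        outer_distance(r)
        for r in records
        if r.mapped_a and r.mapped_b and r.scaffold_a == r.scaffold_b
        and pair_orientation(r) == lib.expected_orientation
    ]
    if len(dists) < min_pairs:
        raise ValueError(
            f"only {len(dists)} qualifying pairs (< {min_pairs}); "
            "supply a manual window on the LibrarySpec"
        )
    low, high = np.percentile(dists, percentiles)
    return float(low), float(high)


def classify_pair(record: MatePairRecord, lib: LibrarySpec) -> str:
    """Classify one pair as keep / chimeric / unresolved (total function)."""
    if not (record.mapped_a and record.mapped_b):
        return UNRESOLVED
    if record.scaffold_a != record.scaffold_b:
        return UNRESOLVED
    low, high = lib.effective_window()
    orient_ok = pair_orientation(record) == lib.expected_orientation
    dist_ok = low <= outer_distance(record) <= high
    return KEEP if (orient_ok and dist_ok) else CHIMERIC


def filter_library(
    records: Sequence[MatePairRecord], lib: LibrarySpec
) -> tuple[list[MatePairRecord], dict]:
    """Kept pairs plus the per-library summary.

    chimera_fraction = n_chimeric / (n_keep + n_chimeric); undefined (error)
    when every pair is unresolved.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    kept, counts = [], {KEEP: 0, CHIMERIC: 0, UNRESOLVED: 0}
    for rec in records:
        cls = classify_pair(rec, lib)
        counts[cls] += 1
        if cls == KEEP:
            kept.append(rec)
    denom = counts[KEEP] + counts[CHIMERIC]
    if denom == 0:
        raise ValueError("all pairs unresolved; chimera fraction undefined")
    summary = {
        "n_keep": counts[KEEP],
        "n_chimeric": counts[CHIMERIC],
        "n_unresolved": counts[UNRESOLVED],
        "chimera_fraction": counts[CHIMERIC] / denom,
    }
    return kept, summary


# ---------------------------------------------------------------------------
# I/O (TSV dialect shared with the simulator)
# ---------------------------------------------------------------------------

_COLUMNS = [
    "pair_id", "scaffold_a", "pos_a", "strand_a",
    "scaffold_b", "pos_b", "strand_b", "mapped_a", "mapped_b",
]


def records_to_frame(records: Iterable[MatePairRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])


def records_from_frame(df: pd.DataFrame) -> list[MatePairRecord]:
    return [
        MatePairRecord(
            str(row.pair_id), str(row.scaffold_a), int(row.pos_a), str(row.strand_a),
            str(row.scaffold_b), int(row.pos_b), str(row.strand_b),
            bool(row.mapped_a), bool(row.mapped_b),
        )
        for row in df.itertuples(index=False)
    ]
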