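"""Fourfold-degenerate transversion (4DTv) divergence on aligned coding pairs.

The 4DTv distance is the proportion of fourfold-degenerate third codon
positions at which two aligned coding sequences differ by a transversion
(purine <-> pyrimidine change).  Because such sites are synonymous under the
standard code, 4DTv behaves as a neutral divergence proxy and the relative
ages of duplication and speciation events can be read off the modes of its
distribution among paralog and ortholog pairs.

Raw proportions are corrected for multiple substitutions with the
two-parameter closed form d = -1/2 * ln(1 - 2p), which inverts the expected
observable transversion fraction of a Kimura-type process with cumulative
transversion distance d per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "CodonPair",
    "DivergenceRecord",
    "FOURFOLD_PREFIXES",
    "find_fourfold_sites",
    "raw_4dtv",
    "correct_4dtv",
    "distribution_mode",
    "paralog_ortholog_summary",
    "records_to_frame",
    "pairs_from_fasta",
]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_BASES = "ACGT"


def _fourfold_prefixes() -> frozenset[str]:
    """Dinucleotide prefixes whose four codons encode one amino acid."""
    table = standard_dna_table.forward_table
    out = set()
    for b1 in _BASES:
        for b2 in _BASES:
            aas = {table.get(b1 + b2 + b3) for b3 in _BASES}
            if len(aas) == 1 and None not in aas:
                out.add(b1 + b2)
    return frozenset(out)


#: The 8 fourfold-degenerate codon families of the standard code
#: (GCN, GGN, CCN, CGN, CTN, GTN, TCN, ACN).
FOURFOLD_PREFIXES = _fourfold_prefixes()

#: Default minimum number of qualifying sites below which a record is
#: flagged low-confidence (and excluded from distributions by default).
DEFAULT_MIN_SITES = 10


@dataclass
class CodonPair:
    """An aligned, in-frame pair of coding sequences."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str
    class_label: str = "unknown"
    species_pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length for pair "
                f"({self.id_a}, {self.id_b}): {len(self.seq_a)} vs {len(self.seq_b)}"
            )
        if len(self.seq_a) % 3 != 0:
            raise ValueError(
                f"alignment length {len(self.seq_a)} not divisible by 3 "
                f"for pair ({self.id_a}, {self.id_b})"
            )
        allowed = set("ACGTN-")
        bad = (set(self.seq_a) | set(self.seq_b)) - allowed
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass
class DivergenceRecord:
    """4DTv summary for one codon pair.

    ``p_raw`` is NaN when no qualifying site exists; ``d_corrected`` is NaN
    when undefined (no sites, or saturation at p_raw >= 0.5).
    """

    id_a: str
    id_b: str
    n_4d_sites: int
    n_transversions: int
    p_raw: float
    d_corrected: float
    low_confidence: bool
    class_label: str = "unknown"
    species_pair: tuple[str, str] = ("", "")


def find_fourfold_sites(pair: CodonPair) -> list[int]:
    """Alignment columns (0-based, third codon positions) usable for 4DTv.

    A column qualifies iff both codons are complete (no gap or N), both
    codons belong to a fourfold-degenerate family, and the first two codon
    nucleotides are identical across the pair -- which guarantees that any
    third-position difference is synonymous in both sequences.
    """
    sites = []
    a, b = pair.seq_a, pair.seq_b
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ("-" in ca or "N" in ca) or ("-" in cb or "N" in cb):
            continue
        if ca[:2] != cb[:2]:
            continue
        if ca[:2] in FOURFOLD_PREFIXES:
            sites.append(i + 2)
    return sites


def _is_transversion(x: str, y: str) -> bool:
    return (x in PURINES) != (y in PURINES)


def raw_4dtv(pair: CodonPair, min_sites: int = DEFAULT_MIN_SITES) -> DivergenceRecord:
    """Raw and corrected 4DTv for one pair.

    p_raw = (# qualifying sites differing by a transversion) / (# qualifying
    sites).  Records with fewer than ``min_sites`` qualifying sites are
    flagged ``low_confidence``.
    """
    sites = find_fourfold_sites(pair)
    n = len(sites)
    if n == 0:
        return DivergenceRecord(
            pair.id_a, pair.id_b, 0, 0, math.nan, math.nan, True,
            pair.class_label, pair.species_pair,
        )
    ntv = sum(
        1 for i in sites
        if pair.seq_a[i] != pair.seq_b[i] and _is_transversion(pair.seq_a[i], pair.seq_b[i])
    )
    p = ntv / n
    return DivergenceRecord(
        pair.id_a, pair.id_b, n, ntv, p, correct_4dtv(p), n < min_sites,
        pair.class_label, pair.species_pair,
    )


def correct_4dtv(p_raw: float) -> float:
    """Multiple-substitution correction d = -1/2 * ln(1 - 2 p).

    Monotone increasing and >= p_raw on [0, 0.5).  Saturated inputs
    (p_raw >= 0.5) yield NaN rather than an exception; negative inputs are
    rejected.
    """
    if math.isnan(p_raw):
        return math.nan
    if p_raw < 0:
        raise ValueError(f"p_raw must be nonnegative, got {p_raw}")
    if p_raw >= 0.5:
        return math.nan
    return -0.5 * math.log1p(-2.0 * p_raw)


# ---------------------------------------------------------------------------
# Distribution summaries (the Figure-2d-style analysis)
# ---------------------------------------------------------------------------

#: KDE evaluation grid for corrected 4DTv values.
KDE_GRID = np.arange(0.0, 1.5 + 1e-9, 0.001)
#: Local maxima below this fraction of the global density maximum are not
#: reported as secondary peaks.
PEAK_PROMINENCE_FRACTION = 0.05


def _finite(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    return arr[np.isfinite(arr)]


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Bandwidth actually used by the Silverman-rule Gaussian KDE."""
    arr = _finite(values)
    sd = arr.std(ddof=1) if arr.size > 1 else 0.0
    if sd == 0.0:
        return 0.0
    kde = gaussian_kde(arr, bw_method="silverman")
    return float(kde.factor * sd)


def distribution_mode(
    values: Sequence[float],
    grid: np.ndarray = KDE_GRID,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> list[float]:
    """Peak positions of the corrected-4DTv distribution, primary mode first.

    A Gaussian KDE with Silverman bandwidth is evaluated on a fixed grid
    (default [0, 1.5], step 0.001); the primary mode is the density argmax
    and further local maxima are reported when their prominence exceeds
    ``prominence_fraction`` of the maximum density.  Degenerate inputs
    (a single value, or zero variance) return that value directly.
    """
    arr = _finite(values)
    if arr.size == 0:
        raise ValueError("distribution_mode needs at least one finite value")
    if arr.size == 1 or arr.std(ddof=1) == 0.0:
        return [float(arr[0])]
    kde = gaussian_kde(arr, bw_method="silverman")
    dens = kde(grid)
    prominence = prominence_fraction * dens.max()
    idx, _ = find_peaks(dens, prominence=prominence)
    if idx.size == 0:  # plateau or boundary-only maximum
        return [float(grid[np.argmax(dens)])]
    order = np.argsort(dens[idx])[::-1]
    return [float(grid[i]) for i in idx[order]]


#: Verdict strings of the relative-timing comparison.
SIMULTANEOUS = "simultaneous"
DUP_MORE_RECENT = "duplication more recent"
DUP_OLDER = "duplication older"


def paralog_ortholog_summary(
    records: Iterable[DivergenceRecord],
    drop_flagged: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-group peak table and duplication-vs-speciation timing verdicts.

    Records are grouped by (class_label, species_pair); flagged records are
    dropped by default.  For each group the table reports the primary KDE
    mode and quartiles.  For every ortholog group, the paralog peak is
    compared with the ortholog peak using the larger KDE bandwidth as the
    simultaneity tolerance: peaks closer than the bandwidth cannot be
    ordered in time.
    """
    groups: dict[tuple[str, tuple[str, str]], list[float]] = {}
    for rec in records:
        if drop_flagged and rec.low_confidence:
            continue
        if not math.isfinite(rec.d_corrected):
            continue
        groups.setdefault((rec.class_label, tuple(rec.species_pair)), []).append(
            rec.d_corrected
        )
    if not groups:
        raise ValueError("no usable records after filtering")

    rows = []
    peaks: dict[tuple[str, tuple[str, str]], float] = {}
    bandwidths: dict[tuple[str, tuple[str, str]], float] = {}
    for key, vals in sorted(groups.items()):
        if not vals:
            raise ValueError(f"group {key} is empty after filtering")
        arr = np.asarray(vals)
        modes = distribution_mode(arr)
        peaks[key] = modes[0]
        bandwidths[key] = silverman_bandwidth(arr)
        q1, q2, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {
                "class_label": key[0],
                "species_pair": "-".join(key[1]) if any(key[1]) else "",
                "n": arr.size,
                "peak": modes[0],
                "secondary_peaks": ";".join(f"{m:.3f}" for m in modes[1:]),
                "q25": q1,
                "median": q2,
                "q75": q3,
                "bandwidth": bandwidths[key],
            }
        )
    table = pd.DataFrame(rows)

    verdicts: dict[str, str] = {}
    par_keys = [k for k in peaks if k[0] == "paralog"]
    ort_keys = [k for k in peaks if k[0] == "ortholog"]
    for pk in par_keys:
        for ok in ort_keys:
            tol = max(bandwidths[pk], bandwidths[ok])
            delta = peaks[ok] - peaks[pk]
            if abs(delta) <= tol:
                verdict = SIMULTANEOUS
            elif delta > 0:
                verdict = DUP_MORE_RECENT
            else:
                verdict = DUP_OLDER
            label = "-".join(ok[1]) if any(ok[1]) else "ortholog"
            verdicts[label] = verdict
    return table, verdicts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[DivergenceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id_a": r.id_a,
                "id_b": r.id_b,
                "n_4d_sites": r.n_4d_sites,
                "n_transversions": r.n_transversions,
                "p_raw": r.p_raw,
                "d_corrected": r.d_corrected,
                "low_confidence": r.low_confidence,
                "class_label": r.class_label,
                "species_pair": "-".join(r.species_pair) if any(r.species_pair) else "",
            }
        )
    return pd.DataFrame(rows)


def pairs_from_fasta(fasta_path, pair_table: pd.DataFrame) -> list[CodonPair]:
    """Build CodonPairs from a multi-FASTA and a pair table.

    The table needs columns id_a, id_b and optionally class_label and
    species_pair ("SP1-SP2").
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    pairs = []
    for row in pair_table.itertuples(index=False):
        label = getattr(row, "class_label", "unknown")
        sp = getattr(row, "species_pair", "")
        sp_pair = tuple(sp.split("-", 1)) if sp else ("", "")
        if len(sp_pair) == 1:
            sp_pair = (sp_pair[0], "")
        pairs.append(
            CodonPair(row.id_a, row.id_b, seqs[row.id_a], seqs[row.id_b], label, sp_pair)
        )
    return pairs
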