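"""Assembly and annotation summary statistics.

Conventions: Nx is the length of the sequence at which the cumulative
length, taken in descending length order, first reaches x% of the total;
Lx is that sequence's 1-based rank.  Percentages and means are reported to
one decimal, matching the usual presentation of assembly reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssemblyStats",
    "AnnotationSummary",
    "nx_lx",
    "gc_percent",
    "assembly_stats",
    "annotation_stats",
    "completeness_summary",
    "markers_per_group",
    "percent",
]


def nx_lx(lengths: Sequence[int], x: float) -> tuple[int, int]:
    """(Nx, Lx) of a length list by the cumulative-sum-reaches-x% rule."""
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("need at least one sequence of positive length")
    target = x / 100.0 * arr.sum()
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(arr[idx]), idx + 1


def gc_percent(sequences: Iterable[str]) -> float:
    """GC percentage over unambiguous bases, to two decimals."""
    gc = at = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases")
    return round(100.0 * gc / (gc + at), 2)


@dataclass
class AssemblyStats:
    n_sequences: dict[int, int]
    total_bases: dict[int, int]
    largest: int
    n50: int
    n75: int
    l50: int
    l75: int
    gc_percent: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for thr in sorted(self.n_sequences):
            rows.append({"statistic": f"n_sequences_ge_{thr}", "value": self.n_sequences[thr]})
            rows.append({"statistic": f"total_bases_ge_{thr}", "value": self.total_bases[thr]})
        rows += [
            {"statistic": "largest", "value": self.largest},
            {"statistic": "N50", "value": self.n50},
            {"statistic": "N75", "value": self.n75},
            {"statistic": "L50", "value": self.l50},
            {"statistic": "L75", "value": self.l75},
        ]
        if self.gc_percent is not None:
            rows.append({"statistic": "GC_percent", "value": self.gc_percent})
        return pd.DataFrame(rows)


def assembly_stats(
    lengths: Sequence[int] | None = None,
    sequences: Mapping[str, str] | None = None,
    thresholds: Sequence[int] = (0, 500, 1000),
) -> AssemblyStats:
    """Standard assembly report from a length list or sequence dict."""
    gc = None
    if lengths is None:
        if sequences is None:
            raise ValueError("supply lengths or sequences")
        lengths = [len(s) for s in sequences.values()]
        gc = gc_percent(sequences.values())
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty assembly")
    n50, l50 = nx_lx(arr, 50)
    n75, l75 = nx_lx(arr, 75)
    return AssemblyStats(
        n_sequences={t: int((arr >= t).sum()) for t in thresholds},
        total_bases={t: int(arr[arr >= t].sum()) for t in thresholds},
        largest=int(arr.max()),
        n50=n50, n75=n75, l50=l50, l75=l75,
        gc_percent=gc,
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSummary:
    n_genes: int
    n_exons: int
    n_introns: int
    n_cds: int
    mean_exons_per_gene: float
    pct_genes_with_introns: float
    mean_gene_length: float
    mean_exon_length: float
    mean_intron_length: float
    pct_genome_in_genes: float | None = None
    pct_genome_in_cds: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"statistic": k, "value": v} for k, v in self.__dict__.items()]
        )


def _union_length(intervals: list[tuple[str, int, int]]) -> int:
    """Total length covered by 1-based inclusive (seqid, start, end) spans."""
    total = 0
    current_seq, end = None, 0
    for seqid, start, stop in sorted(intervals):
        if seqid != current_seq:
            current_seq, end = seqid, 0
        if start > end:
            total += stop - start + 1
            end = stop
        elif stop > end:
            total += stop - end
            end = stop
    return total


def mean_exons_per_gene(n_exons: int, n_genes: int) -> float:
    """Average exon count per gene, one decimal."""
    if n_genes <= 0:
        raise ValueError("need at least one gene")
    return round(n_exons / n_genes, 1)


def annotation_stats(
    gff3: str, genome_length: int | None = None
) -> AnnotationSummary:
    """Annotation summary from GFF3 text or a GFF3 file path.

    Exons are tied to genes through their Parent chain (gene -> mRNA ->
    exon, or exon directly under gene); an exon whose parentage cannot be
    resolved to a gene is an error.  Introns are the per-gene gaps between
    exons (exon count - 1 per gene).
    """
    import gffutils

    from_string = "\n" in gff3 or "\t" in gff3
    db = gffutils.create_db(
        gff3, ":memory:", from_string=from_string,
        merge_strategy="create_unique", keep_order=True,
    )
    gene_of: dict[str, str] = {}
    gene_span: dict[str, tuple[str, int, int]] = {}
    for gene in db.features_of_type("gene"):
        gene_of[gene.id] = gene.id
        gene_span[gene.id] = (gene.seqid, gene.start, gene.end)
    for feat in db.all_features():
        if feat.featuretype == "gene":
            continue
        parents = feat.attributes.get("Parent", [])
        for p in parents:
            if p in gene_of and feat.id not in gene_of:
                gene_of[feat.id] = gene_of[p]
    # second pass for grandchildren declared before parents resolved
    changed = True
    while changed:
        changed = False
        for feat in db.all_features():
            if feat.id in gene_of:
                continue
            for p in feat.attributes.get("Parent", []):
                if p in gene_of:
                    gene_of[feat.id] = gene_of[p]
                    changed = True

    exons_by_gene: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_span}
    cds_intervals: list[tuple[str, int, int]] = []
    n_cds = 0
    for feat in db.all_features():
        if feat.featuretype == "exon":
            owner = None
            for p in feat.attributes.get("Parent", []):
                owner = gene_of.get(p)
                if owner:
                    break
            if owner is None:
                raise ValueError(f"orphan exon {feat.id or feat.attributes}")
            exons_by_gene[owner].append((feat.start, feat.end))
        elif feat.featuretype == "CDS":
            n_cds += 1
            cds_intervals.append((feat.seqid, feat.start, feat.end))

    n_genes = len(gene_span)
    if n_genes == 0:
        raise ValueError("no gene features in annotation")
    n_exons = sum(len(v) for v in exons_by_gene.values())
    exon_lengths = [e - s + 1 for v in exons_by_gene.values() for s, e in v]
    intron_lengths = []
    genes_with_introns = 0
    for g, exons in exons_by_gene.items():
        if len(exons) >= 2:
            genes_with_introns += 1
            ordered = sorted(exons)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                intron_lengths.append(max(0, s2 - e1 - 1))
    gene_lengths = [e - s + 1 for _, s, e in gene_span.values()]

    pct_genes = pct_cds = None
    if genome_length:
        pct_genes = round(100.0 * _union_length(list(gene_span.values())) / genome_length, 1)
        pct_cds = round(100.0 * _union_length(cds_intervals) / genome_length, 1)
    return AnnotationSummary(
        n_genes=n_genes,
        n_exons=n_exons,
        n_introns=len(intron_lengths),
        n_cds=n_cds,
        mean_exons_per_gene=mean_exons_per_gene(n_exons, n_genes),
        pct_genes_with_introns=round(100.0 * genes_with_introns / n_genes, 1),
        mean_gene_length=round(float(np.mean(gene_lengths)), 1),
        mean_exon_length=round(float(np.mean(exon_lengths)), 1) if exon_lengths else 0.0,
        mean_intron_length=round(float(np.mean(intron_lengths)), 1) if intron_lengths else 0.0,
        pct_genome_in_genes=pct_genes,
        pct_genome_in_cds=pct_cds,
    )


# ---------------------------------------------------------------------------
# Completeness / map arithmetic
# ---------------------------------------------------------------------------

def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """100 * part / whole, rounded."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be nonnegative")
    return round(100.0 * part / whole, ndigits)


def completeness_summary(
    single_pct: float, duplicated_pct: float, fragmented_pct: float | None = None
) -> dict[str, float]:
    """Aggregate single/duplicated/fragmented percentages (BUSCO-style)."""
    vals = [single_pct, duplicated_pct] + (
        [fragmented_pct] if fragmented_pct is not None else []
    )
    if any(v < 0 for v in vals):
        raise ValueError("percentages must be nonnegative")
    if sum(vals) > 100 + 1e-9:
        raise ValueError("percentages sum to more than 100")
    out = {"complete_pct": round(single_pct + duplicated_pct, 1)}
    if fragmented_pct is not None:
        out["fragmented_pct"] = round(fragmented_pct, 1)
        out["missing_pct"] = round(100.0 - out["complete_pct"] - fragmented_pct, 1)
    return out


def markers_per_group(n_markers: int, n_groups: int) -> int:
    """Average marker count per linkage group, nearest integer."""
    if n_markers < 0 or n_groups <= 0:
        raise ValueError("need nonnegative markers and positive groups")
    return round(n_markers / n_groups)
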