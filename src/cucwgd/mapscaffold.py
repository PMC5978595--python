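"""Genetic-map scaffold QC and pseudomolecule construction.

A high-density genetic map serves two purposes during genome integration:
scaffolds whose markers land on more than one linkage group are assembly
chimeras and must be split, and the surviving scaffolds are anchored,
ordered by mean genetic position and oriented by the sign of the
physical-vs-genetic rank correlation, then concatenated into
chromosome-scale pseudomolecules separated by fixed-length N spacers
(1000 N by default).  An AGP v2.1 table records the layout so the
pseudomolecules can be regenerated exactly.

Map tables are 1-based (marker_id, linkage_group, position_cM, scaffold_id,
position_bp); AGP coordinates are 1-based inclusive per the AGP standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "MAP_COLUMNS",
    "ChimeraCall",
    "PseudomoleculeLayout",
    "validate_map",
    "detect_chimeric_scaffolds",
    "split_scaffold",
    "split_all_chimeras",
    "anchor_order_orient",
    "build_pseudomolecules",
    "write_agp",
    "read_agp",
    "assemble_from_agp",
    "physical_genetic_correlation",
    "anchored_fraction",
]

MAP_COLUMNS = ["marker_id", "linkage_group", "position_cM", "scaffold_id", "position_bp"]
DEFAULT_SPACER = 1000
AGP_COLUMNS = [
    "object", "object_beg", "object_end", "part_number", "component_type",
    "component_id", "component_beg", "component_end", "orientation",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_map(map_df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MAP_COLUMNS if c not in map_df.columns]
    if missing:
        raise ValueError(f"map table missing columns: {missing}")
    if map_df["marker_id"].duplicated().any():
        dups = map_df.loc[map_df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ValueError(f"duplicate marker ids: {dups[:5]}")
    if (map_df["position_cM"] < 0).any() or not np.isfinite(map_df["position_cM"]).all():
        raise ValueError("genetic positions must be finite and >= 0")
    if (map_df["position_bp"] < 1).any():
        raise ValueError("physical positions are 1-based (>= 1)")
    return map_df


@dataclass
class ChimeraCall:
    scaffold_id: str
    linkage_groups: list[str]
    breakpoints: list[int]
    status: str  # "chimeric" or "warning"
    detail: str = ""


def detect_chimeric_scaffolds(
    map_df: pd.DataFrame, min_support: int = 2
) -> list[ChimeraCall]:
    """Flag scaffolds whose markers map to more than one linkage group.

    A scaffold is chimeric iff at least ``min_support`` markers map to each
    of >= 2 linkage groups; a candidate breakpoint is placed at the midpoint
    between the innermost markers of adjacent LG blocks along the scaffold.
    Scaffolds with stray markers (another LG, but below min_support) are
    reported as warnings only.
    """
    validate_map(map_df)
    calls = []
    for scaffold_id, sub in map_df.groupby("scaffold_id", sort=True):
        lg_counts = sub["linkage_group"].value_counts()
        if len(lg_counts) < 2:
            continue
        supported = sorted(str(lg) for lg in lg_counts[lg_counts >= min_support].index)
        strays = sorted(str(lg) for lg in lg_counts[lg_counts < min_support].index)
        if len(supported) < 2:
            calls.append(
                ChimeraCall(
                    str(scaffold_id), sorted(str(l) for l in lg_counts.index), [],
                    "warning",
                    f"stray markers on {strays} below min_support={min_support}",
                )
            )
            continue
        core = sub[sub["linkage_group"].astype(str).isin(supported)]
        core = core.sort_values("position_bp")
        lgs = core["linkage_group"].astype(str).to_numpy()
        pos = core["position_bp"].to_numpy()
        breakpoints = [
            int((pos[i] + pos[i + 1]) // 2)
            for i in range(len(lgs) - 1)
            if lgs[i] != lgs[i + 1]
        ]
        detail = f"stray markers on {strays}" if strays else ""
        calls.append(
            ChimeraCall(str(scaffold_id), supported, breakpoints, "chimeric", detail)
        )
    return calls


def split_scaffold(
    scaffold_id: str,
    length: int,
    breakpoint_bp: int,
    map_df: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, int]], pd.DataFrame | None]:
    """Split a scaffold at ``breakpoint_bp`` into two children.

    Child lengths are breakpoint and length - breakpoint (conserving the
    parent length); markers at positions <= breakpoint stay on the first
    child, the rest move to the second with positions re-based.
    """
    if not 0 < breakpoint_bp < length:
        raise ValueError(
            f"breakpoint {breakpoint_bp} outside (0, {length}) for {scaffold_id}"
        )
    children = [(f"{scaffold_id}.1", breakpoint_bp), (f"{scaffold_id}.2", length - breakpoint_bp)]
    new_map = None
    if map_df is not None:
        new_map = map_df.copy()
        on_scaffold = new_map["scaffold_id"] == scaffold_id
        first = on_scaffold & (new_map["position_bp"] <= breakpoint_bp)
        second = on_scaffold & (new_map["position_bp"] > breakpoint_bp)
        new_map.loc[first, "scaffold_id"] = children[0][0]
        new_map.loc[second, "scaffold_id"] = children[1][0]
        new_map.loc[second, "position_bp"] -= breakpoint_bp
    return children, new_map


def split_all_chimeras(
    map_df: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    min_support: int = 2,
) -> tuple[pd.DataFrame, dict[str, int], list[ChimeraCall]]:
    """Detect and split every chimeric scaffold (first breakpoint each pass).

    Scaffolds with multiple breakpoints are split iteratively.  Returns the
    updated map, updated length table and the original calls.
    """
    calls = detect_chimeric_scaffolds(map_df, min_support)
    lengths = dict(scaffold_lengths)
    work = [c for c in calls if c.status == "chimeric"]
    while work:
        current = map_df
        for call in work:
            sid = call.scaffold_id
            bp = call.breakpoints[0]
            children, current = split_scaffold(sid, lengths[sid], bp, current)
            del lengths[sid]
            lengths.update(dict(children))
        map_df = current
        work = [c for c in detect_chimeric_scaffolds(map_df, min_support)
                if c.status == "chimeric"]
    return map_df, lengths, calls


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

def anchor_order_orient(
    map_df: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
) -> tuple[pd.DataFrame, list[str]]:
    """Assign, order and orient scaffolds within linkage groups.

    Each mapped scaffold goes to the linkage group holding the majority of
    its markers, ordered by mean cM (ties: descending length, then id).
    Orientation is the sign of the Spearman correlation between position_bp
    and position_cM; scaffolds with < 2 informative markers (distinct bp
    and distinct cM) get '?'.  Scaffolds without mapped markers are
    returned as the unanchored list.
    """
    validate_map(map_df)
    rows = []
    for scaffold_id, sub in map_df.groupby("scaffold_id", sort=True):
        counts = sub["linkage_group"].value_counts()
        top = counts.max()
        lg = sorted(str(l) for l, c in counts.items() if c == top)[0]
        sub_lg = sub[sub["linkage_group"].astype(str) == lg]
        mean_cm = float(sub_lg["position_cM"].mean())
        bp = sub_lg["position_bp"].to_numpy(dtype=float)
        cm = sub_lg["position_cM"].to_numpy(dtype=float)
        informative = len(np.unique(bp)) >= 2 and len(np.unique(cm)) >= 2
        if informative:
            rho = spearmanr(bp, cm).statistic
            orientation = "+" if rho > 0 else "-" if rho < 0 else "?"
        else:
            orientation = "?"
        rows.append(
            {
                "scaffold_id": str(scaffold_id),
                "linkage_group": lg,
                "mean_cM": mean_cm,
                "orientation": orientation,
                "n_markers": len(sub_lg),
                "length": int(scaffold_lengths[str(scaffold_id)]),
            }
        )
    anchored = pd.DataFrame(rows)
    if not anchored.empty:
        anchored["_neg_len"] = -anchored["length"]
        anchored = (
            anchored.sort_values(["linkage_group", "mean_cM", "_neg_len", "scaffold_id"])
            .drop(columns="_neg_len")
            .reset_index(drop=True)
        )
        anchored["order_index"] = anchored.groupby("linkage_group").cumcount()
    unanchored = sorted(set(map(str, scaffold_lengths)) - set(anchored.get("scaffold_id", [])))
    return anchored, unanchored


@dataclass
class PseudomoleculeLayout:
    linkage_group: str
    scaffolds: pd.DataFrame  # anchored rows of this LG, in order
    spacer_length: int
    total_length: int
    length_without_spacers: int

    def __post_init__(self) -> None:
        n = len(self.scaffolds)
        expected = self.length_without_spacers + max(0, n - 1) * self.spacer_length
        if self.total_length != expected:
            raise ValueError(
                f"layout invariant violated for {self.linkage_group}: "
                f"{self.total_length} != {expected}"
            )


def build_pseudomolecules(
    anchored: pd.DataFrame,
    sequences: Mapping[str, str] | None,
    spacer_length: int = DEFAULT_SPACER,
) -> tuple[dict[str, str], pd.DataFrame, list[PseudomoleculeLayout]]:
    """Concatenate ordered scaffolds into per-LG pseudomolecules + AGP.

    '-' scaffolds are reverse-complemented; '?' scaffolds are emitted in
    forward orientation but written as '?' in the AGP.  Gap rows carry
    gap_type "scaffold", linkage "yes", evidence "map" (AGP v2.1).  With
    ``sequences`` None only the AGP and layouts are built.
    """
    pseudos: dict[str, str] = {}
    agp_rows = []
    layouts = []
    for lg, sub in anchored.sort_values(["linkage_group", "order_index"]).groupby(
        "linkage_group", sort=True
    ):
        obj = str(lg)
        parts = []
        pos = 0
        part_number = 0
        for i, row in enumerate(sub.itertuples(index=False)):
            if i > 0:
                part_number += 1
                agp_rows.append(
                    {
                        "object": obj,
                        "object_beg": pos + 1,
                        "object_end": pos + spacer_length,
                        "part_number": part_number,
                        "component_type": "N",
                        "component_id": spacer_length,
                        "component_beg": "scaffold",
                        "component_end": "yes",
                        "orientation": "map",
                    }
                )
                parts.append("N" * spacer_length)
                pos += spacer_length
            length = int(row.length)
            if sequences is not None:
                if row.scaffold_id not in sequences:
                    raise KeyError(f"no sequence for anchored scaffold {row.scaffold_id}")
                seq = sequences[row.scaffold_id]
                if len(seq) != length:
                    raise ValueError(
                        f"sequence length {len(seq)} != map length {length} "
                        f"for {row.scaffold_id}"
                    )
                parts.append(_revcomp(seq) if row.orientation == "-" else seq)
            part_number += 1
            agp_rows.append(
                {
                    "object": obj,
                    "object_beg": pos + 1,
                    "object_end": pos + length,
                    "part_number": part_number,
                    "component_type": "W",
                    "component_id": row.scaffold_id,
                    "component_beg": 1,
                    "component_end": length,
                    "orientation": row.orientation,
                }
            )
            pos += length
        if sequences is not None:
            pseudos[obj] = "".join(parts)
        n = len(sub)
        without = int(sub["length"].sum())
        layouts.append(
            PseudomoleculeLayout(
                obj, sub.reset_index(drop=True), spacer_length,
                without + (n - 1) * spacer_length, without,
            )
        )
    return pseudos, pd.DataFrame(agp_rows, columns=AGP_COLUMNS), layouts


def write_agp(agp: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        agp.to_csv(fh, sep="\t", header=False, index=False)


def read_agp(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=None, names=AGP_COLUMNS)


def assemble_from_agp(
    agp: pd.DataFrame, sequences: Mapping[str, str]
) -> dict[str, str]:
    """Regenerate pseudomolecule sequences from an AGP table (round trip)."""
    out: dict[str, str] = {}
    for obj, sub in agp.groupby("object", sort=True):
        parts = []
        for row in sub.sort_values("part_number").itertuples(index=False):
            if row.component_type == "N":
                parts.append("N" * int(row.component_id))
            else:
                seq = sequences[str(row.component_id)]
                seq = seq[int(row.component_beg) - 1 : int(row.component_end)]
                parts.append(_revcomp(seq) if row.orientation == "-" else seq)
        out[str(obj)] = "".join(parts)
    return out


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def physical_genetic_correlation(
    anchored: pd.DataFrame,
    map_df: pd.DataFrame,
    spacer_length: int = DEFAULT_SPACER,
) -> pd.DataFrame:
    """Rank correlation between pseudomolecule coordinate and cM per LG.

    Marker coordinates are projected through the layout (offsets plus
    orientation flips).  Linkage groups with < 3 projected markers are
    flagged and get a NaN correlation.  The mean over unflagged groups is
    appended as row "mean".
    """
    offsets: dict[str, tuple[str, int, int, str]] = {}
    for lg, sub in anchored.sort_values(["linkage_group", "order_index"]).groupby(
        "linkage_group", sort=True
    ):
        pos = 0
        for i, row in enumerate(sub.itertuples(index=False)):
            if i > 0:
                pos += spacer_length
            offsets[row.scaffold_id] = (str(lg), pos, int(row.length), row.orientation)
            pos += int(row.length)

    per_lg: dict[str, list[tuple[float, float]]] = {}
    for row in map_df.itertuples(index=False):
        info = offsets.get(str(row.scaffold_id))
        if info is None:
            continue
        lg, off, length, orientation = info
        if str(row.linkage_group) != lg:
            continue  # stray marker of another LG
        if orientation == "-":
            coord = off + (length - int(row.position_bp) + 1)
        else:
            coord = off + int(row.position_bp)
        per_lg.setdefault(lg, []).append((coord, float(row.position_cM)))

    rows = []
    for lg in sorted(per_lg):
        pts = per_lg[lg]
        if len(pts) < 3:
            rows.append({"linkage_group": lg, "n_markers": len(pts),
                         "spearman_rho": np.nan, "flagged": True})
            continue
        coords, cms = zip(*pts)
        rho = spearmanr(coords, cms).statistic
        rows.append({"linkage_group": lg, "n_markers": len(pts),
                     "spearman_rho": float(rho), "flagged": False})
    table = pd.DataFrame(rows)
    ok = table[~table["flagged"]]
    mean_rho = float(ok["spearman_rho"].mean()) if not ok.empty else np.nan
    table = pd.concat(
        [table, pd.DataFrame([{"linkage_group": "mean",
                               "n_markers": int(table["n_markers"].sum()),
                               "spearman_rho": mean_rho, "flagged": ok.empty}])],
        ignore_index=True,
    )
    return table


def anchored_fraction(
    anchored: pd.DataFrame, scaffold_lengths: Mapping[str, int]
) -> float:
    """Percentage of total assembly length placed in pseudomolecules (1 dp)."""
    total = sum(scaffold_lengths.values())
    if total <= 0:
        raise ValueError("total scaffold length must be positive")
    placed = int(anchored["length"].sum()) if not anchored.empty else 0
    return round(100.0 * placed / total, 1)
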