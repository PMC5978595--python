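"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes, and returns a :class:`SimTruth` sidecar so parameter recovery can
be tested without real data:

* CDS families evolving on a species tree with a whole-genome duplication
  planted on a chosen branch (for the 4DTv and reconciliation analyses);
* unimodal k-mer depth histograms with a low-depth error component (for
  genome-size estimation);
* genetic maps with planted chimeric scaffolds (for map QC / anchoring);
* mate-pair alignment records with a planted chimera fraction;
* expression tables with transcripts planted below the relative floor.

Sequence evolution uses a two-parameter equal-frequency substitution
process (separate transition and transversion components per branch, no
indels), chosen because the 4DTv multiple-substitution correction
-1/2*ln(1-2p) is exactly the inversion of this process's observable
transversion fraction: a branch with cumulative transversion distance tau
per site shows a transversion at a 4D site with probability
(1 - exp(-2*tau))/2.  Branch lengths in the scenario's newick are the
transversion component; the transition component is ts_tv_ratio times it.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .kmersize import KmerHistogram
from .matepair_qc import MatePairRecord

__all__ = [
    "WgdScenario",
    "SimTruth",
    "sim_cds_families",
    "sim_kmer_histogram",
    "sim_map_scaffolds",
    "sim_matepairs",
    "sim_expression_components",
    "write_families_fasta",
]

# base encoding: A=0, G=1, C=2, T=3 -> transition partner is base XOR 1,
# the two transversion partners are base XOR 2 and base XOR 3
_BASES = np.array(list("AGCT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = np.array(
    [
        [i, j, k]
        for i in range(4)
        for j in range(4)
        for k in range(4)
        if _BASES[i] + _BASES[j] + _BASES[k] not in _STOPS
    ],
    dtype=np.int8,
)


@dataclass
class SimTruth:
    """Ground-truth sidecar; only the fields the generator fills are set."""

    seed: int | None = None
    scenario: dict | None = None
    gene_trees: dict[str, str] | None = None
    dup_families: list[str] | None = None
    pair_tv: dict[str, dict[str, float]] | None = None
    pair_class: dict[str, dict[str, str]] | None = None
    genome_size: int | None = None
    peak_depth: float | None = None
    chimeric_scaffolds: dict[str, int] | None = None
    scaffold_lg: dict[str, object] | None = None
    inverted_scaffolds: list[str] | None = None
    pair_labels: dict[str, str] | None = None
    below_threshold_ids: list[str] | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {k: v for k, v in asdict(self).items() if v is not None},
                fh, indent=1, default=str,
            )


# ---------------------------------------------------------------------------
# CDS families with a planted WGD
# ---------------------------------------------------------------------------

@dataclass
class WgdScenario:
    """A species tree with a duplication planted on one branch.

    ``species_tree`` is newick with branch lengths equal to the expected
    number of transversions per (4D) site on that branch; ``wgd_branch``
    names the branch (by its child node: a species name or an internal node
    label) at whose top the duplication occurs; a Bernoulli(``retention``)
    draw decides per family whether both copies survive.
    """

    species_tree: str
    wgd_branch: str
    retention: float
    n_families: int
    seq_length_codons: int
    seed: int
    ts_tv_ratio: float = 2.0

    def tree(self) -> dendropy.Tree:
        try:
            tree = dendropy.Tree.get(
                data=self.species_tree, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"invalid scenario: empty or unparsable species tree ({exc})")
        if sum(1 for _ in tree.leaf_node_iter()) == 0:
            raise ValueError("invalid scenario: empty species tree")
        return tree

    def validate(self) -> dendropy.Tree:
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("invalid scenario: retention must be in [0, 1]")
        if self.n_families <= 0:
            raise ValueError("invalid scenario: n_families must be positive")
        if self.seq_length_codons <= 0:
            raise ValueError(
                "invalid scenario: seq_length_codons must be positive "
                "(zero-length sequences)"
            )
        if self.ts_tv_ratio < 0:
            raise ValueError("invalid scenario: ts_tv_ratio must be nonnegative")
        tree = self.tree()
        wgd = None
        for node in tree.preorder_node_iter():
            if (node.edge.length or 0) < 0:
                raise ValueError("invalid scenario: negative branch length")
            label = node.taxon.label if node.is_leaf() else node.label
            if label == self.wgd_branch:
                wgd = node
        if wgd is None:
            raise ValueError(
                f"invalid scenario: wgd_branch {self.wgd_branch!r} names no "
                "edge of the species tree"
            )
        return tree


def _evolve(seq: np.ndarray, s: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the two-parameter process, vectorised over sites.

    ``s`` and ``tau`` are the expected transitions and transversions per
    site on the branch.  Closed-form substitution probabilities of the
    Kimura-type process:  P(specific transversion) = (1 - exp(-2 tau))/4,
    P(transition) = 1/4 + exp(-2 tau)/4 - exp(-2 s - tau)/2.
    """
    e2t = np.exp(-2.0 * tau)
    p_tv_each = 0.25 * (1.0 - e2t)
    p_ti = 0.25 + 0.25 * e2t - 0.5 * np.exp(-2.0 * s - tau)
    r = rng.random(seq.size)
    child = seq.copy()
    lo = 1.0 - 2.0 * p_tv_each - p_ti
    child[(r >= lo) & (r < lo + p_ti)] ^= 1
    child[(r >= lo + p_ti) & (r < lo + p_ti + p_tv_each)] ^= 2
    child[r >= lo + p_ti + p_tv_each] ^= 3

    # reject mutations that created stop codons: re-evolve those codons
    # from the parent until none remain
    codons = child.reshape(-1, 3)
    parent_codons = seq.reshape(-1, 3)
    for _ in range(64):
        stop = (
            (codons[:, 0] == 3)
            & (
                ((codons[:, 1] == 0) & ((codons[:, 2] == 0) | (codons[:, 2] == 1)))
                | ((codons[:, 1] == 1) & (codons[:, 2] == 0))
            )
        )
        if not stop.any():
            break
        bad = parent_codons[stop].reshape(-1)
        r = rng.random(bad.size)
        redo = bad.copy()
        redo[(r >= lo) & (r < lo + p_ti)] ^= 1
        redo[(r >= lo + p_ti) & (r < lo + p_ti + p_tv_each)] ^= 2
        redo[r >= lo + p_ti + p_tv_each] ^= 3
        codons[stop] = redo.reshape(-1, 3)
    return codons.reshape(-1)


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def sim_cds_families(scenario: WgdScenario):
    """Simulate aligned CDS families on the scenario's species tree.

    Returns ``(families, truth)`` where ``families`` maps family id to a
    dict of leaf name ("SPECIES__family_copy") -> sequence string, and the
    truth carries per-family gene-tree newicks, the duplicated-family list,
    and the true cumulative transversion distance and paralog/ortholog
    class of every leaf pair.  Root sequences are drawn codon-by-codon from
    the 61 sense codons; sequences are aligned by construction (no indels).
    """
    stree = scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    length = 3 * scenario.seq_length_codons
    ratio = scenario.ts_tv_ratio

    def node_label(node):
        return node.taxon.label if node.is_leaf() else node.label

    families: dict[str, dict[str, str]] = {}
    gene_trees: dict[str, str] = {}
    dup_families: list[str] = []
    pair_tv: dict[str, dict[str, float]] = {}
    pair_class: dict[str, dict[str, str]] = {}

    for fi in range(scenario.n_families):
        fam = f"fam{fi:04d}"
        has_dup = rng.random() < scenario.retention
        codon_idx = rng.integers(0, len(_SENSE_CODONS), scenario.seq_length_codons)
        root_seq = _SENSE_CODONS[codon_idx].reshape(-1).astype(np.int8)

        def grow(sp_node, seq, depth, copy, dup_pending):
            """Build the gene subtree below sp_node; returns a node dict."""
            if sp_node.is_leaf():
                name = f"{sp_node.taxon.label}{'__'}{fam}_{copy}"
                return {"leaf": name, "depth": depth, "seq": seq}
            children = []
            for child in sp_node.child_nodes():
                tau = float(child.edge.length or 0.0)
                s = ratio * tau
                if dup_pending and node_label(child) == scenario.wgd_branch:
                    copies = []
                    for tag in ("1", "2"):
                        cseq = _evolve(seq, s, tau, rng)
                        copies.append(grow(child, cseq, depth + tau, tag, False))
                    children.append(
                        {"event": "duplication", "children": copies, "depth": depth}
                    )
                else:
                    cseq = _evolve(seq, s, tau, rng)
                    children.append(grow(child, cseq, depth + tau, copy, dup_pending))
            if len(children) == 1:
                return children[0]
            return {"event": "speciation", "children": children, "depth": depth}

        root = grow(stree.seed_node, root_seq, 0.0, "0", has_dup)

        seqs: dict[str, str] = {}
        tv: dict[str, float] = {}
        cls: dict[str, str] = {}

        def collect(node):
            """Return [(leaf_name, depth)] while filling seqs/tv/cls."""
            if "leaf" in node:
                seqs[node["leaf"]] = _decode(node["seq"])
                return [(node["leaf"], node["depth"])]
            groups = [collect(c) for c in node["children"]]
            label = "paralog" if node["event"] == "duplication" else "ortholog"
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            key = "|".join(sorted((la, lb)))
                            tv[key] = (da - node["depth"]) + (db - node["depth"])
                            cls[key] = label
            return [x for g in groups for x in g]

        collect(root)

        def newick(node):
            if "leaf" in node:
                return node["leaf"]
            parts = []
            for c in node["children"]:
                cdepth = c["depth"] if "event" in c else c["depth"]
                parts.append(f"{newick(c)}:{cdepth - node['depth']:.6g}")
            return "(" + ",".join(parts) + ")"

        families[fam] = seqs
        gene_trees[fam] = newick(root) + ";"
        pair_tv[fam] = tv
        pair_class[fam] = cls
        if has_dup:
            dup_families.append(fam)

    truth = SimTruth(
        seed=scenario.seed,
        scenario=asdict(scenario),
        gene_trees=gene_trees,
        dup_families=dup_families,
        pair_tv=pair_tv,
        pair_class=pair_class,
    )
    return families, truth


def write_families_fasta(families: Mapping[str, Mapping[str, str]], path) -> None:
    """All family sequences as one multi-FASTA (ids are the leaf names)."""
    with open(path, "w") as fh:
        for fam in sorted(families):
            for name, seq in sorted(families[fam].items()):
                fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# k-mer histograms
# ---------------------------------------------------------------------------

def sim_kmer_histogram(
    genome_size: int,
    peak_depth: float,
    dispersion: float = 0.5,
    error_mass_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[KmerHistogram, SimTruth]:
    """Unimodal genomic depth distribution plus a depth-1..3 error tail.

    The genomic component places ``genome_size`` distinct k-mers on a
    discretised normal around ``peak_depth`` with standard deviation
    dispersion * sqrt(peak_depth) (dispersion = 1 is Poisson-like width,
    0 collapses to a spike), so total genomic k-mer mass is approximately
    genome_size * peak_depth and the modal depth is peak_depth.  Error
    k-mers are confined to depths 1-3 with steeply decreasing counts and
    contribute ``error_mass_fraction`` of the total mass.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if peak_depth <= 3:
        raise ValueError("peak_depth must exceed 3 so an error valley can exist")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    if not 0 <= error_mass_fraction < 1:
        raise ValueError("error_mass_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    mu = float(peak_depth)
    sigma = dispersion * np.sqrt(mu)
    if sigma == 0.0:
        depths = np.array([int(round(mu))])
        counts = np.array([genome_size], dtype=np.int64)
    else:
        from scipy.stats import norm

        top = int(np.ceil(mu + 8 * sigma)) + 3
        grid = np.arange(1, top + 1)
        pmf = norm.cdf(grid + 0.5, mu, sigma) - norm.cdf(grid - 0.5, mu, sigma)
        pmf /= pmf.sum()
        counts = rng.multinomial(genome_size, pmf).astype(np.int64)
        keep = counts > 0
        depths, counts = grid[keep], counts[keep]

    dense: dict[int, int] = {int(d): int(c) for d, c in zip(depths, counts)}
    genomic_mass = int(np.sum(depths * counts))
    if error_mass_fraction > 0:
        err_mass = error_mass_fraction / (1 - error_mass_fraction) * genomic_mass
        ratio = 0.1  # count decay per extra depth unit
        base = err_mass / (1 * 1 + 2 * ratio + 3 * ratio**2)
        for d in (1, 2, 3):
            extra = int(round(base * ratio ** (d - 1)))
            if extra:
                dense[d] = dense.get(d, 0) + extra

    hist = KmerHistogram.from_mapping(dense)
    truth = SimTruth(seed=seed, genome_size=int(genome_size), peak_depth=mu)
    return hist, truth


# ---------------------------------------------------------------------------
# Genetic maps with planted chimeric scaffolds
# ---------------------------------------------------------------------------

def sim_map_scaffolds(
    n_lgs: int,
    n_scaffolds: int,
    markers_per_scaffold: int,
    chimera_rate: float,
    seed: int,
    inverted_fraction: float = 0.25,
    length_range: tuple[int, int] = (100_000, 500_000),
    cm_per_mb: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Genetic map + scaffold length table with planted chimeras.

    Clean scaffolds carry ``markers_per_scaffold`` markers on one linkage
    group with cM strictly increasing along the underlying chromosome
    (decreasing with bp for the planted inverted fraction); chimeric
    scaffolds concatenate two segments from different linkage groups, each
    segment carrying ``markers_per_scaffold`` markers, with the junction
    recorded as the true breakpoint.
    """
    if n_lgs < 1 or n_scaffolds < 1 or markers_per_scaffold < 1:
        raise ValueError("n_lgs, n_scaffolds, markers_per_scaffold must be positive")
    if not 0 <= chimera_rate <= 1:
        raise ValueError("chimera_rate must be in [0, 1]")
    if chimera_rate > 0 and n_lgs < 2:
        raise ValueError("chimeric scaffolds need at least 2 linkage groups")
    if chimera_rate > 0 and markers_per_scaffold < 2:
        raise ValueError("chimeric scaffolds need >= 2 markers per LG segment")
    rng = np.random.default_rng(seed)

    lg_names = [f"LG{i + 1:02d}" for i in range(n_lgs)]
    lg_pos = dict.fromkeys(lg_names, 0)
    rows = []
    lengths = []
    chimeric: dict[str, int] = {}
    scaffold_lg: dict[str, object] = {}
    inverted: list[str] = []
    marker_no = 0
    slope = cm_per_mb / 1e6

    def markers_on_segment(sid, lg, seg_len, bp_offset, invert):
        nonlocal marker_no
        u = np.sort(rng.choice(seg_len, size=markers_per_scaffold, replace=False) + 1)
        cm = (lg_pos[lg] + u) * slope
        bp = (seg_len - u + 1) if invert else u
        for uu_bp, uu_cm in zip(bp, cm):
            marker_no += 1
            rows.append(
                {
                    "marker_id": f"M{marker_no:06d}",
                    "linkage_group": lg,
                    "position_cM": float(uu_cm),
                    "scaffold_id": sid,
                    "position_bp": int(uu_bp) + bp_offset,
                }
            )
        lg_pos[lg] += seg_len

    for i in range(n_scaffolds):
        sid = f"scf{i:05d}"
        is_chimeric = rng.random() < chimera_rate
        if is_chimeric:
            lg_a, lg_b = rng.choice(n_lgs, size=2, replace=False)
            len_a = int(rng.integers(*length_range))
            len_b = int(rng.integers(*length_range))
            markers_on_segment(sid, lg_names[lg_a], len_a, 0, False)
            markers_on_segment(sid, lg_names[lg_b], len_b, len_a, False)
            lengths.append({"scaffold_id": sid, "length": len_a + len_b})
            chimeric[sid] = len_a
            scaffold_lg[sid] = [lg_names[lg_a], lg_names[lg_b]]
        else:
            lg = lg_names[int(rng.integers(n_lgs))]
            length = int(rng.integers(*length_range))
            invert = rng.random() < inverted_fraction
            markers_on_segment(sid, lg, length, 0, invert)
            lengths.append({"scaffold_id": sid, "length": length})
            scaffold_lg[sid] = lg
            if invert:
                inverted.append(sid)

    map_df = pd.DataFrame(rows)
    lengths_df = pd.DataFrame(lengths)
    truth = SimTruth(
        seed=seed,
        chimeric_scaffolds=chimeric,
        scaffold_lg=scaffold_lg,
        inverted_scaffolds=inverted,
    )
    return map_df, lengths_df, truth


# ---------------------------------------------------------------------------
# Mate pairs with a planted chimera fraction
# ---------------------------------------------------------------------------

def sim_matepairs(
    n_pairs: int,
    insert_mean: float,
    insert_sd: float,
    chimera_fraction: float,
    scaffold_lengths: Mapping[str, int],
    seed: int,
    orientation: str = "RF",
) -> tuple[list[MatePairRecord], SimTruth]:
    """Mate-pair records with a planted fraction of chimeric pairs.

    Valid pairs have the library's expected orientation and an outer
    distance ~ Normal(insert_mean, insert_sd).  Chimeric pairs either
    violate the orientation (half of them, distance drawn as valid) or keep
    the orientation but draw their distance from a far-separated
    distribution, uniform on [2.5, 3.5] x insert_mean, so the two classes
    are separable whenever insert_sd << insert_mean.
    """
    if insert_sd <= 0 or insert_mean <= 0:
        raise ValueError("insert_mean and insert_sd must be positive")
    if not 0 <= chimera_fraction <= 1:
        raise ValueError("chimera_fraction must be in [0, 1]")
    if orientation not in ("FR", "RF"):
        raise ValueError("orientation must be FR or RF")
    names = list(scaffold_lengths)
    lens = np.array([scaffold_lengths[n] for n in names], dtype=np.int64)
    if lens.size == 0 or lens.max() < insert_mean + 6 * insert_sd:
        raise ValueError(
            "placement error: no scaffold long enough for "
            f"insert_mean + 6*insert_sd = {insert_mean + 6 * insert_sd:.0f}"
        )
    rng = np.random.default_rng(seed)
    far_ok = lens.max() > 3.5 * insert_mean + 1

    records: list[MatePairRecord] = []
    labels: dict[str, str] = {}
    strands = {"RF": ("-", "+"), "FR": ("+", "-")}
    wrong_orients = {"RF": ["FR", "++", "--"], "FR": ["RF", "++", "--"]}

    for i in range(n_pairs):
        pid = f"mp{i:06d}"
        is_chimeric = rng.random() < chimera_fraction
        mode = "valid"
        if is_chimeric:
            if far_ok and rng.random() < 0.5:
                mode = "far"
            else:
                mode = "orient"
        if mode == "far":
            dist = int(round(rng.uniform(2.5, 3.5) * insert_mean))
        else:
            dist = max(1, int(round(rng.normal(insert_mean, insert_sd))))
        eligible = np.flatnonzero(lens > dist + 1)
        if eligible.size == 0:
            raise ValueError(f"placement error: no scaffold longer than {dist}")
        sc = int(eligible[rng.integers(eligible.size)])
        pos_left = int(rng.integers(1, lens[sc] - dist + 1))
        pos_right = pos_left + dist
        if mode == "orient":
            pat = wrong_orients[orientation][int(rng.integers(3))]
            if pat == "++":
                s_left = s_right = "+"
            elif pat == "--":
                s_left = s_right = "-"
            else:
                s_left, s_right = strands[pat]
        else:
            s_left, s_right = strands[orientation]
        ends = [(pos_left, s_left), (pos_right, s_right)]
        if rng.random() < 0.5:
            ends.reverse()
        records.append(
            MatePairRecord(
                pid, names[sc], ends[0][0], ends[0][1],
                names[sc], ends[1][0], ends[1][1],
            )
        )
        labels[pid] = "chimeric" if is_chimeric else "valid"

    truth = SimTruth(seed=seed, pair_labels=labels)
    return records, truth


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def sim_expression_components(
    n_components: int,
    transcripts_per_component: int,
    below_threshold_fraction: float,
    seed: int,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-component expression with a planted below-1%-of-max fraction.

    Each component's first transcript carries the maximum; each remaining
    transcript is, with the planted probability, drawn below 1% of that
    maximum (uniform on [0.01%, 0.9%] of it), otherwise well above
    (uniform on [2%, 100%]).
    """
    if n_components < 1 or transcripts_per_component < 1:
        raise ValueError("n_components and transcripts_per_component must be >= 1")
    if not 0 <= below_threshold_fraction <= 1:
        raise ValueError("below_threshold_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    below: list[str] = []
    for c in range(n_components):
        comp = f"comp{c:04d}"
        peak = 10.0 ** rng.uniform(2, 4)
        rows.append({"transcript_id": f"{comp}_t000", "component": comp,
                     "expression": peak})
        for t in range(1, transcripts_per_component):
            tid = f"{comp}_t{t:03d}"
            if rng.random() < below_threshold_fraction:
                expr = peak * rng.uniform(1e-4, 9e-3)
                below.append(tid)
            else:
                expr = peak * rng.uniform(0.02, 1.0)
            rows.append({"transcript_id": tid, "component": comp, "expression": expr})
    truth = SimTruth(seed=seed, below_threshold_ids=below)
    return pd.DataFrame(rows), truth
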