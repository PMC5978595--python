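"""Determinism, conservation and truth-exhaustiveness of the simulators."""

import numpy as np
import pytest

from cucwgd import matepair_qc, seqdiv, simdata
from cucwgd.simdata import WgdScenario


def _scenario(**kw):
    base = dict(
        species_tree="(A:0.06,B:0.06);", wgd_branch="A", retention=1.0,
        n_families=20, seq_length_codons=100, seed=5,
    )
    base.update(kw)
    return WgdScenario(**base)


class TestCdsFamilies:
    def test_determinism(self):
        f1, t1 = simdata.sim_cds_families(_scenario())
        f2, t2 = simdata.sim_cds_families(_scenario())
        assert f1 == f2
        assert t1.gene_trees == t2.gene_trees
        assert t1.pair_tv == t2.pair_tv

    def test_zero_branch_lengths_identical_sequences(self):
        fams, truth = simdata.sim_cds_families(
            _scenario(species_tree="(A:0,B:0);", n_families=5)
        )
        for fam, seqs in fams.items():
            vals = list(seqs.values())
            assert all(v == vals[0] for v in vals)
            for key in truth.pair_tv[fam]:
                a, b = key.split("|")
                rec = seqdiv.raw_4dtv(seqdiv.CodonPair(a, b, seqs[a], seqs[b]))
                assert rec.p_raw == 0.0

    def test_alignment_by_construction(self):
        fams, _ = simdata.sim_cds_families(_scenario(n_families=3))
        for seqs in fams.values():
            lengths = {len(s) for s in seqs.values()}
            assert lengths == {300}

    def test_no_stop_codons(self):
        fams, _ = simdata.sim_cds_families(_scenario(n_families=5, seed=2))
        stops = {"TAA", "TAG", "TGA"}
        for seqs in fams.values():
            for s in seqs.values():
                codons = {s[i:i + 3] for i in range(0, len(s), 3)}
                assert not (codons & stops)

    def test_retention_controls_duplication(self):
        fams, truth = simdata.sim_cds_families(_scenario(retention=0.0))
        assert truth.dup_families == []
        assert all(len(seqs) == 2 for seqs in fams.values())
        fams, truth = simdata.sim_cds_families(_scenario(retention=1.0))
        assert len(truth.dup_families) == 20
        assert all(len(seqs) == 3 for seqs in fams.values())

    def test_truth_is_exhaustive(self):
        fams, truth = simdata.sim_cds_families(_scenario(retention=0.5, seed=3))
        for fam, seqs in fams.items():
            names = sorted(seqs)
            n = len(names)
            assert len(truth.pair_tv[fam]) == n * (n - 1) // 2
            assert set(truth.pair_tv[fam]) == set(truth.pair_class[fam])

    def test_mean_corrected_4dtv_matches_planted_distance(self):
        # Monte-Carlo check against the closed-form expectation: paralog
        # path transversion distance 0.12 planted on the A lineage
        fams, truth = simdata.sim_cds_families(
            _scenario(n_families=300, seq_length_codons=300, seed=17)
        )
        ds = []
        for fam, seqs in fams.items():
            for key, cls in truth.pair_class[fam].items():
                if cls != "paralog":
                    continue
                assert truth.pair_tv[fam][key] == pytest.approx(0.12)
                a, b = key.split("|")
                rec = seqdiv.raw_4dtv(seqdiv.CodonPair(a, b, seqs[a], seqs[b]))
                ds.append(rec.d_corrected)
        ds = np.asarray(ds)
        se = ds.std(ddof=1) / np.sqrt(ds.size)
        assert abs(ds.mean() - 0.12) <= 3 * se

    @pytest.mark.parametrize(
        "kw,msg",
        [
            (dict(retention=1.5), "retention"),
            (dict(n_families=0), "n_families"),
            (dict(seq_length_codons=0), "zero-length"),
            (dict(wgd_branch="Z"), "names no"),
            (dict(species_tree=";"), "empty"),
            (dict(species_tree="(A:-0.1,B:0.1);"), "negative"),
        ],
    )
    def test_invalid_scenarios(self, kw, msg):
        with pytest.raises(ValueError, match=msg):
            simdata.sim_cds_families(_scenario(**kw))


class TestMapSim:
    def test_no_chimeras_single_lg_per_scaffold(self):
        m, lens, truth = simdata.sim_map_scaffolds(3, 25, 4, 0.0, seed=1)
        per_scaffold = m.groupby("scaffold_id")["linkage_group"].nunique()
        assert (per_scaffold == 1).all()
        assert truth.chimeric_scaffolds == {}

    def test_all_chimeric_with_interior_breakpoints(self):
        m, lens, truth = simdata.sim_map_scaffolds(2, 10, 3, 1.0, seed=2)
        lengths = dict(zip(lens["scaffold_id"], lens["length"]))
        assert len(truth.chimeric_scaffolds) == 10
        for sid, bp in truth.chimeric_scaffolds.items():
            assert 0 < bp < lengths[sid]

    def test_positions_valid(self):
        m, lens, _ = simdata.sim_map_scaffolds(4, 40, 5, 0.3, seed=3)
        assert (m["position_cM"] >= 0).all()
        assert np.isfinite(m["position_cM"]).all()
        lengths = dict(zip(lens["scaffold_id"], lens["length"]))
        for row in m.itertuples(index=False):
            assert 1 <= row.position_bp <= lengths[row.scaffold_id]

    def test_determinism(self):
        a = simdata.sim_map_scaffolds(3, 15, 4, 0.2, seed=7)
        b = simdata.sim_map_scaffolds(3, 15, 4, 0.2, seed=7)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_chimeras_need_two_lgs(self):
        with pytest.raises(ValueError):
            simdata.sim_map_scaffolds(1, 10, 4, 0.5, seed=1)


class TestMatePairSim:
    def test_clean_library_all_valid_geometry(self):
        recs, truth = simdata.sim_matepairs(500, 7000, 700, 0.0, {"s": 10**6}, seed=4)
        lib = matepair_qc.LibrarySpec(7000, "RF")
        for r in recs:
            assert matepair_qc.pair_orientation(r) == "RF"
            assert abs(matepair_qc.outer_distance(r) - 7000) < 6 * 700
        assert set(truth.pair_labels.values()) == {"valid"}

    def test_planted_fraction_binomial(self):
        recs, truth = simdata.sim_matepairs(
            10_000, 7000, 700, 0.4, {"s": 10**6}, seed=5
        )
        n_chim = sum(1 for v in truth.pair_labels.values() if v == "chimeric")
        sigma = np.sqrt(10_000 * 0.4 * 0.6)
        assert abs(n_chim - 4000) <= 3 * sigma

    def test_determinism(self):
        r1, _ = simdata.sim_matepairs(50, 3000, 300, 0.4, {"s": 10**5}, seed=6)
        r2, _ = simdata.sim_matepairs(50, 3000, 300, 0.4, {"s": 10**5}, seed=6)
        assert r1 == r2

    def test_truth_exhaustive(self):
        recs, truth = simdata.sim_matepairs(200, 3000, 300, 0.3, {"s": 10**5}, seed=8)
        assert sorted(truth.pair_labels) == sorted(r.pair_id for r in recs)

    def test_short_scaffolds_rejected(self):
        with pytest.raises(ValueError, match="placement"):
            simdata.sim_matepairs(10, 7000, 700, 0.0, {"s": 5000}, seed=1)


class TestExpressionSim:
    def test_single_transcript_components_never_below(self):
        df, truth = simdata.sim_expression_components(10, 1, 0.9, seed=1)
        assert truth.below_threshold_ids == []
        assert (df["expression"] >= 0).all()

    def test_planted_fraction_binomial(self):
        df, truth = simdata.sim_expression_components(10, 100, 0.3, seed=2)
        n_eligible = 10 * 99  # the component maximum is never below threshold
        sigma = np.sqrt(n_eligible * 0.3 * 0.7)
        assert abs(len(truth.below_threshold_ids) - 0.3 * n_eligible) <= 3 * sigma

    def test_truth_matches_threshold_rule(self):
        df, truth = simdata.sim_expression_components(5, 50, 0.4, seed=3)
        comp_max = df.groupby("component")["expression"].transform("max")
        below = set(df.loc[df["expression"] < 0.01 * comp_max, "transcript_id"])
        assert below == set(truth.below_threshold_ids)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            simdata.sim_expression_components(5, 5, -0.1, seed=1)


class TestTruthSerialization:
    def test_json_sidecar(self, tmp_path):
        _, truth = simdata.sim_kmer_histogram(10**5, 40, 0.5, 0.05, seed=1)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["genome_size"] == 10**5
        assert data["peak_depth"] == 40
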