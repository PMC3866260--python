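"""Set-algebra analyses over circuit results, checked against naive oracles."""

import numpy as np
import pytest

import circuitminer as cm
from circuitminer.context import circuits_by_stage, circuit_network
from circuitminer.data_io import GeneSet

from conftest import make_fake_results


def _gene_set(ids, name="ctx"):
    return GeneSet(name=name, ids=frozenset(ids))


class TestOverlapAnalysis:
    def test_identical_stage_sets_fully_intersect(self):
        rng = np.random.default_rng(0)
        results = make_fake_results(rng, stages=("early",), p_circuit=1.0)
        # clone every early row into a late row with the same verdicts
        late = [
            cm.CircuitResult(
                candidate=r.candidate, stage="late", mirna_gene=r.mirna_gene,
                tf_gene=r.tf_gene, mirna_tf=r.mirna_tf, is_circuit=r.is_circuit,
            )
            for r in results
        ]
        rep = cm.overlap_analysis(results + late, ["early", "late"])
        pattern = frozenset({"early", "late"})
        n = len({r.candidate for r in results if r.is_circuit})
        assert rep.counts("circuit") == {pattern: n}

    def test_disjoint_circuits_can_share_a_mirna(self):
        rng = np.random.default_rng(1)
        base = make_fake_results(rng, stages=("early",), p_circuit=1.0)[:1]
        c = base[0]
        other = cm.CircuitCandidate(c.candidate.mirna_id, "TFX", "GX")
        late = [
            cm.CircuitResult(
                candidate=other, stage="late", mirna_gene=c.mirna_gene,
                tf_gene=c.tf_gene, mirna_tf=c.mirna_tf, is_circuit=True,
            )
        ]
        rep = cm.overlap_analysis(base + late, ["early", "late"])
        both = frozenset({"early", "late"})
        assert rep.counts("circuit").get(both, 0) == 0
        assert rep.counts("mirna") == {both: 1}

    def test_unknown_stage_label_errors(self):
        rng = np.random.default_rng(2)
        results = make_fake_results(rng)
        with pytest.raises(ValueError, match="unknown stage"):
            cm.overlap_analysis(results, ["early", "bogus"])

    @pytest.mark.parametrize("seed", range(5))
    def test_regions_match_brute_force_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        results = make_fake_results(rng)
        stages = ["early", "late", "whole"]
        rep = cm.overlap_analysis(results, stages)
        by_stage = circuits_by_stage(results)
        for cls, extract in [
            ("circuit", lambda c: c),
            ("tf", lambda c: c.tf_id),
            ("mirna", lambda c: c.mirna_id),
            ("gene", lambda c: c.gene_id),
        ]:
            sets = {s: {extract(c) for c in by_stage[s]} for s in stages}
            union = set().union(*sets.values())
            # regions disjoint, cover the union, counts equal brute force
            assert rep.union_size(cls) == len(union)
            for pat, ids in rep.regions[cls].items():
                expected = set(union)
                for s in stages:
                    expected &= sets[s] if s in pat else (union - sets[s])
                assert set(ids) == expected


class TestSubsetByGeneSet:
    def test_full_gene_set_is_identity(self):
        rng = np.random.default_rng(3)
        results = make_fake_results(rng)
        gs = _gene_set({r.candidate.gene_id for r in results})
        assert cm.subset_by_gene_set(results, gs, "within") == results

    @pytest.mark.parametrize("seed", range(5))
    def test_within_and_outside_partition_the_input(self, seed):
        rng = np.random.default_rng(seed)
        results = make_fake_results(rng)
        gs = _gene_set({f"G{i}" for i in range(0, 10, 2)})
        within = cm.subset_by_gene_set(results, gs, "within")
        outside = cm.subset_by_gene_set(results, gs, "outside")
        assert len(within) + len(outside) == len(results)
        assert not (set(map(id, within)) & set(map(id, outside)))
        for r in within:
            assert r.candidate.gene_id in gs
        for r in outside:
            assert r.candidate.gene_id not in gs


class TestExclusiveRegulators:
    def test_all_genes_inside_means_no_exclusives(self):
        rng = np.random.default_rng(4)
        results = make_fake_results(rng)
        gs = _gene_set({r.candidate.gene_id for r in results})
        for tfs, mirnas in cm.exclusive_regulators(results, gs).values():
            assert tfs == set() and mirnas == set()

    def test_regulator_of_only_outside_genes_is_exclusive(self):
        rng = np.random.default_rng(5)
        results = [r for r in make_fake_results(rng, p_circuit=1.0) if r.stage == "early"]
        inside_genes = {r.candidate.gene_id for r in results[:-1]}
        lone = results[-1]
        gs = _gene_set(inside_genes - {lone.candidate.gene_id})
        excl_tfs, excl_mirnas = cm.exclusive_regulators(results, gs)["early"]
        within_regs = {
            r.candidate.tf_id for r in results if r.candidate.gene_id in gs
        }
        if lone.candidate.tf_id not in within_regs:
            assert lone.candidate.tf_id in excl_tfs

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_difference_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        results = make_fake_results(rng)
        gs = _gene_set({f"G{i}" for i in range(5)})
        got = cm.exclusive_regulators(results, gs)
        by_stage = circuits_by_stage(results)
        for stage, (tfs, mirnas) in got.items():
            w = {c for c in by_stage[stage] if c.gene_id in gs}
            o = {c for c in by_stage[stage] if c.gene_id not in gs}
            assert tfs == {c.tf_id for c in o} - {c.tf_id for c in w}
            assert mirnas == {c.mirna_id for c in o} - {c.mirna_id for c in w}


class TestCommonNodeNetwork:
    def test_identical_stages_tag_all_edges_with_both(self):
        rng = np.random.default_rng(6)
        early = [r for r in make_fake_results(rng, p_circuit=1.0) if r.stage == "early"]
        late = [
            cm.CircuitResult(
                candidate=r.candidate, stage="late", mirna_gene=r.mirna_gene,
                tf_gene=r.tf_gene, mirna_tf=r.mirna_tf, is_circuit=True,
            )
            for r in early
        ]
        net = cm.common_node_network(early + late, "early", "late")
        full = circuit_network({r.candidate for r in early})
        assert set(net.edges) == set(full.edges)
        for _, _, data in net.edges(data=True):
            assert data["stages"] == ("early", "late")

    def test_no_shared_nodes_gives_empty_network(self):
        rng = np.random.default_rng(7)
        a = cm.CircuitCandidate("mir-A", "TFA", "GA")
        b = cm.CircuitCandidate("mir-B", "TFB", "GB")
        template = make_fake_results(rng, p_circuit=1.0)[0]
        results = [
            cm.CircuitResult(candidate=a, stage="early", mirna_gene=template.mirna_gene,
                             tf_gene=template.tf_gene, mirna_tf=template.mirna_tf,
                             is_circuit=True),
            cm.CircuitResult(candidate=b, stage="late", mirna_gene=template.mirna_gene,
                             tf_gene=template.tf_gene, mirna_tf=template.mirna_tf,
                             is_circuit=True),
        ]
        net = cm.common_node_network(results, "early", "late")
        assert net.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_first_principles_construction(self, seed):
        rng = np.random.default_rng(seed + 20)
        results = make_fake_results(rng)
        net = cm.common_node_network(results, "early", "late")
        by_stage = circuits_by_stage(results)
        ca, cb = by_stage["early"], by_stage["late"]
        common_nodes = (
            ({c.tf_id for c in ca} & {c.tf_id for c in cb})
            | ({c.mirna_id for c in ca} & {c.mirna_id for c in cb})
            | ({c.gene_id for c in ca} & {c.gene_id for c in cb})
        )
        expected_edges = set()
        for stage, circuits in (("early", ca), ("late", cb)):
            for c in circuits:
                if {c.tf_id, c.mirna_id, c.gene_id} & common_nodes:
                    expected_edges |= {
                        (c.mirna_id, c.gene_id), (c.tf_id, c.gene_id),
                        (c.mirna_id, c.tf_id),
                    }
        assert set(net.edges) == expected_edges


class TestCancerContext:
    def test_disjoint_cancer_set_empty_at_both_levels(self):
        rng = np.random.default_rng(8)
        results = make_fake_results(rng)
        cc = cm.cancer_context(results, _gene_set({"NOPE"}), _gene_set({"G0"}))
        assert all(len(v) == 0 for v in cc.cancer_circuits.values())
        assert all(len(v) == 0 for v in cc.tissue_cancer_circuits.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_tissue_cancer_nests_inside_cancer(self, seed):
        rng = np.random.default_rng(seed + 30)
        results = make_fake_results(rng)
        cancer = _gene_set({f"G{i}" for i in range(0, 10, 2)}, "cancer")
        tissue = _gene_set({f"G{i}" for i in range(0, 10, 3)}, "tissue")
        cc = cm.cancer_context(results, cancer, tissue)
        for stage, circuits in cc.tissue_cancer_circuits.items():
            assert circuits <= cc.cancer_circuits.get(stage, set())
        # summary counts equal brute-force recomputation
        by_stage = circuits_by_stage(results)
        for row in cc.summary.itertuples():
            ref = {
                c for c in by_stage[row.stage]
                if c.gene_id in cancer and (row.level == "cancer" or c.gene_id in tissue)
            }
            assert row.n_circuits == len(ref)
            assert row.n_genes == len({c.gene_id for c in ref})
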