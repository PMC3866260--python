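"""Correlation formula, permutation test and the circuit significance call."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import pearsonr

import circuitminer as cm
from circuitminer.data_io import EntityKind
from circuitminer.detection import permutation_pvalue, stage_vector
from circuitminer.detection import test_edge as run_edge_test


class TestPearson:
    def test_hand_examples(self):
        assert cm.pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cm.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert cm.pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / math.sqrt(84))

    def test_zero_variance_is_undefined_not_error(self):
        assert math.isnan(cm.pearson([1, 1, 1], [1, 2, 3]))

    def test_bad_shapes_error(self):
        with pytest.raises(ValueError):
            cm.pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            cm.pearson([1], [2])

    def test_matches_scipy_to_1e12_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            assert cm.pearson(x, y) == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)

    def test_symmetry_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, y = rng.standard_normal(8), rng.standard_normal(8)
            r = cm.pearson(x, y)
            assert cm.pearson(y, x) == pytest.approx(r, abs=1e-12)
            assert cm.pearson(2.5 * x + 3, y) == pytest.approx(r, abs=1e-12)
            assert cm.pearson(-x, y) == pytest.approx(-r, abs=1e-12)


def _brute_force_exhaustive_p(x, y, tol=1e-12):
    """Independent enumeration over all n! permutations using np.corrcoef."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    obs = abs(np.corrcoef(x, y)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        total += 1
        if abs(np.corrcoef(x, y[list(perm)])[0, 1]) >= obs - tol:
            count += 1
    return count / total


class TestPermutationPvalue:
    def test_exhaustive_three_point_example(self):
        res = permutation_pvalue([1, 2, 3], [1, 2, 3], cm.DetectionConfig())
        assert res.method == "exhaustive"
        assert res.permutations_used == 6
        # identity and full reversal both reach |R| = 1
        assert res.p == pytest.approx(2 / 6)

    def test_three_point_stages_can_never_be_significant(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            res = permutation_pvalue(
                rng.standard_normal(3), rng.standard_normal(3), cm.DetectionConfig()
            )
            assert res.p >= 1 / 6 > 0.05

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exhaustive_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            res = permutation_pvalue(x, y, cm.DetectionConfig())
            assert res.method == "exhaustive"
            assert res.p == pytest.approx(_brute_force_exhaustive_p(x, y))

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(5), rng.standard_normal(5)
        exact = permutation_pvalue(x, y, cm.DetectionConfig()).p
        mc = permutation_pvalue(
            x, y, cm.DetectionConfig(exhaustive_cap=1, n_permutations=100_000, seed=9)
        )
        assert mc.method == "monte_carlo"
        assert abs(mc.p - exact) <= 0.01

    def test_monte_carlo_p_has_add_one_floor(self):
        x = np.arange(10.0)
        res = permutation_pvalue(
            x, x, cm.DetectionConfig(exhaustive_cap=1, n_permutations=500, seed=0)
        )
        assert res.method == "monte_carlo"
        assert res.p >= 1 / 501

    def test_undefined_correlation_returns_marker(self):
        res = permutation_pvalue([1, 1, 1], [1, 2, 3], cm.DetectionConfig())
        assert res.method == "undefined" and math.isnan(res.p)

    def test_sign_constrained_tail(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cfg = cm.DetectionConfig(
            tail="sign_constrained",
            sign_constraints={cm.EdgeKind.MIRNA_GENE: -1},
        )
        up = permutation_pvalue(x, x, cfg, edge_kind=cm.EdgeKind.MIRNA_GENE)
        down = permutation_pvalue(x, -x, cfg, edge_kind=cm.EdgeKind.MIRNA_GENE)
        assert down.p < up.p  # only the required direction counts as extreme


class TestTestEdge:
    def test_planted_edge_significant_in_its_stage(self, planted_dataset):
        ds = planted_dataset
        part = ds.config.stage_design
        cfg = cm.DetectionConfig(seed=5)
        hits = 0
        picks = ds.truth.planted_circuits[:20]
        for pc in picks:
            res = run_edge_test(
                ds.mirna_expr, ds.gene_expr, ds.tf_map,
                (pc.candidate.mirna_id, pc.candidate.gene_id),
                cm.EdgeKind.MIRNA_GENE,
                (pc.stage, part.stage_indices(pc.stage)),
                cfg,
            )
            assert res.n == 6
            hits += res.p <= cfg.alpha
        assert hits >= 18

    def test_off_stage_pvalues_are_calibrated(self, planted_dataset):
        """Planted edges tested in the other stage behave like the null."""
        ds = planted_dataset
        part = ds.config.stage_design
        cfg = cm.DetectionConfig(seed=6)
        other = {"early": "late", "late": "early"}
        pvals = []
        for pc in ds.truth.planted_circuits:
            stage = other[pc.stage]
            for pair, kind in (
                ((pc.candidate.mirna_id, pc.candidate.gene_id), cm.EdgeKind.MIRNA_GENE),
                ((pc.candidate.tf_id, pc.candidate.gene_id), cm.EdgeKind.TF_GENE),
                ((pc.candidate.mirna_id, pc.candidate.tf_id), cm.EdgeKind.MIRNA_TF),
            ):
                pvals.append(
                    run_edge_test(
                        ds.mirna_expr, ds.gene_expr, ds.tf_map, pair, kind,
                        (stage, part.stage_indices(stage)), cfg,
                    ).p
                )
        frac = np.mean(np.asarray(pvals) <= cfg.alpha)
        assert len(pvals) >= 200
        assert cfg.alpha / 2 <= frac <= 2 * cfg.alpha

    def test_missing_tf_mapping_errors_with_name(self, planted_dataset):
        ds = planted_dataset
        with pytest.raises(KeyError, match="GhostTF"):
            run_edge_test(
                ds.mirna_expr, ds.gene_expr, ds.tf_map,
                (ds.mirna_expr.entity_ids[0], "GhostTF"),
                cm.EdgeKind.MIRNA_TF,
                ("early", [0, 1, 2]),
                cm.DetectionConfig(),
            )

    def test_replicate_average_halves_n(self, planted_dataset):
        ds = planted_dataset
        v = stage_vector(ds.mirna_expr, ds.mirna_expr.entity_ids[0], [0, 1, 2], "average")
        assert v.shape == (3,)


def _tiny_universe(values_x):
    """One miRNA, one TF (via coding gene), one gene, all sharing profile x."""
    x = np.asarray(values_x, dtype=float)
    cols = [(i, "r1") for i in range(x.size)]
    tps = [f"t{i + 1}" for i in range(x.size)]
    mirna = cm.ExpressionMatrix(
        kind=EntityKind.MIRNA, entity_ids=["mir-a"], time_points=tps,
        columns=cols, values=x[None, :],
    )
    genes = cm.ExpressionMatrix(
        kind=EntityKind.GENE, entity_ids=["G1", "CT1"], time_points=tps,
        columns=cols, values=np.vstack([x, x]),
    )
    return mirna, genes, cm.TFMap(mapping={"T1": "CT1"})


class TestDetectCircuits:
    def test_identical_vectors_give_enumeration_p(self):
        mirna, genes, tfm = _tiny_universe([1, 2, 3, 4, 5, 6])
        part = cm.StagePartition(stages={"s": [0, 1, 2, 3, 4, 5]}, n_timepoints=6)
        res = cm.detect_circuits(
            [cm.CircuitCandidate("mir-a", "T1", "G1")], mirna, genes, tfm, part,
            cm.DetectionConfig(),
        )
        by_stage = {r.stage: r for r in res}
        r = by_stage["s"]
        assert r.is_circuit
        for t in r.edge_tests:
            assert abs(t.r) == pytest.approx(1.0)
            assert t.p == pytest.approx(2 / 720)

    def test_empty_candidates_warns_and_returns_empty(self, planted_dataset, caplog):
        ds = planted_dataset
        with caplog.at_level("WARNING"):
            out = cm.detect_circuits(
                [], ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design
            )
        assert out == [] and "no candidates" in caplog.text

    def test_cache_is_semantically_invisible(self, small_dataset):
        ds = small_dataset
        cands = [pc.candidate for pc in ds.truth.planted_circuits[:8]]
        cfg = cm.DetectionConfig(seed=3, n_permutations=500)
        with_cache = cm.detect_circuits(
            cands, ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design,
            cfg, use_cache=True,
        )
        without = cm.detect_circuits(
            cands, ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design,
            cfg, use_cache=False,
        )
        assert with_cache == without

    def test_results_independent_of_candidate_order(self, small_dataset):
        ds = small_dataset
        cands = [pc.candidate for pc in ds.truth.planted_circuits[:6]]
        cfg = cm.DetectionConfig(seed=3, n_permutations=500)
        fwd = cm.detect_circuits(
            cands, ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design, cfg
        )
        rev = cm.detect_circuits(
            cands[::-1], ds.mirna_expr, ds.gene_expr, ds.tf_map,
            ds.config.stage_design, cfg,
        )
        key = lambda r: (r.candidate, r.stage)
        assert sorted(fwd, key=key) == sorted(rev, key=key)

    def test_lowering_alpha_never_adds_circuits(self, small_dataset):
        ds = small_dataset
        cands = [pc.candidate for pc in ds.truth.planted_circuits]
        loose = cm.detect_circuits(
            cands, ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design,
            cm.DetectionConfig(alpha=0.05, seed=3, n_permutations=500),
        )
        strict = cm.detect_circuits(
            cands, ds.mirna_expr, ds.gene_expr, ds.tf_map, ds.config.stage_design,
            cm.DetectionConfig(alpha=0.01, seed=3, n_permutations=500),
        )
        loose_set = {(r.candidate, r.stage) for r in loose if r.is_circuit}
        strict_set = {(r.candidate, r.stage) for r in strict if r.is_circuit}
        assert strict_set <= loose_set

    def test_circuits_are_a_subset_of_candidates(self, planted_results):
        cands, results = planted_results
        cand_set = set(cands)
        assert {r.candidate for r in results if r.is_circuit} <= cand_set
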