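import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arrayimpute import (Clustering, apply_mask, blci, cpp, inject_missing,
                         kmeans_clusters, make_clustered, make_twogroup, nrmse,
                         row_mean_impute, sam_de_genes, score_round)
from arrayimpute.baselines import oracle_impute
from arrayimpute.exceptions import (DesignError, MetricUndefinedError,
                                    ParameterError, ValidationError)
from arrayimpute.sam import DEGeneSet
from sklearn.metrics import adjusted_rand_score


class TestNrmse:
    def test_perfect_imputation_scores_zero(self):
        v = np.array([0.3, -1.2, 2.2])
        assert nrmse(v, v) == 0.0

    def test_hand_computed_value(self):
        # mse = 1/3, population variance of (0,2,4) = 8/3
        assert nrmse([1, 2, 4], [0, 2, 4]) == pytest.approx(np.sqrt((1 / 3) / (8 / 3)))
        assert nrmse([1, 2, 4], [0, 2, 4]) == pytest.approx(0.3535533905932738)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100), seed=st.integers(0, 1000))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(20)
        g = y + rng.standard_normal(20)
        assert nrmse(a * g + b, a * y + b) == pytest.approx(nrmse(g, y), rel=1e-9)

    def test_errors(self):
        with pytest.raises(MetricUndefinedError):
            nrmse([1.0, 2.0], [3.0, 3.0])  # zero variance
        with pytest.raises(ValidationError):
            nrmse([1.0, 2.0], [1.0, 2.0, 3.0])


class TestKmeansCpp:
    def test_separated_clouds_recovered(self):
        m, truth = make_clustered(60, 6, n_clusters=3, separation=20, noise_sd=1.0, seed=1)
        c = kmeans_clusters(m, n_clusters=3, seed=0)
        a = [truth[g] for g in m.gene_ids]
        b = [c.labels[g] for g in m.gene_ids]
        assert adjusted_rand_score(a, b) == 1.0

    def test_deterministic_given_seed(self, complete_matrix):
        a = kmeans_clusters(complete_matrix, 4, seed=5)
        b = kmeans_clusters(complete_matrix, 4, seed=5)
        assert a.labels == b.labels

    def test_one_cluster_per_gene_zero_inertia(self, complete_matrix):
        c = kmeans_clusters(complete_matrix, complete_matrix.n_genes, seed=0)
        assert c.inertia == pytest.approx(0.0, abs=1e-9)
        assert len(set(c.labels.values())) == complete_matrix.n_genes

    def test_too_few_genes_rejected(self, complete_matrix):
        with pytest.raises(ParameterError):
            kmeans_clusters(complete_matrix, complete_matrix.n_genes + 1, seed=0)

    def test_cpp_identity_and_label_permutation_invariance(self):
        c1 = Clustering({"g1": 1, "g2": 1, "g3": 2, "g4": 2}, 2, 0)
        c2 = Clustering({"g1": 2, "g2": 2, "g3": 1, "g4": 1}, 2, 0)
        assert cpp(c1, c1) == 1.0
        assert cpp(c1, c2) == 1.0  # same partition, relabeled

    def test_cpp_no_preserved_pairs_scores_zero(self):
        c1 = Clustering({"g1": 1, "g2": 1, "g3": 2, "g4": 2}, 2, 0)
        c2 = Clustering({"g1": 1, "g2": 2, "g3": 1, "g4": 2}, 2, 0)
        assert cpp(c1, c2) == 0.0

    def test_cpp_universe_mismatch(self):
        c1 = Clustering({"g1": 1, "g2": 1}, 1, 0)
        c2 = Clustering({"g1": 1, "g3": 1}, 1, 0)
        with pytest.raises(ValidationError):
            cpp(c1, c2)

    def test_cpp_within_unit_interval(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(20):
            c1 = Clustering({g: int(x) for g, x in zip(genes, rng.integers(1, 5, 30))}, 4, 0)
            c2 = Clustering({g: int(x) for g, x in zip(genes, rng.integers(1, 5, 30))}, 4, 0)
            assert 0.0 <= cpp(c1, c2) <= 1.0


def _de(universe, sig):
    return DEGeneSet(significant=set(sig), universe=set(universe),
                     statistic={g: 0.0 for g in universe})


class TestBlci:
    def test_identical_lists_score_one(self):
        u = [f"g{i}" for i in range(10)]
        b = _de(u, ["g1", "g2"])
        assert blci(b, b) == pytest.approx(1.0)

    def test_disjoint_lists_hand_value(self):
        u = [f"g{i}" for i in range(1, 11)]
        # 0/2 + 6/8 - 1 = -0.25
        assert blci(_de(u, ["g1", "g2"]), _de(u, ["g3", "g4"])) == pytest.approx(-0.25)

    def test_complement_list_scores_minus_one(self):
        u = [f"g{i}" for i in range(1, 11)]
        b_cd = _de(u, ["g1", "g2"])
        b_id = _de(u, [g for g in u if g not in ("g1", "g2")])
        assert blci(b_cd, b_id) == pytest.approx(-1.0)

    def test_undefined_for_empty_or_full_reference(self):
        u = [f"g{i}" for i in range(5)]
        with pytest.raises(MetricUndefinedError):
            blci(_de(u, []), _de(u, ["g1"]))
        with pytest.raises(MetricUndefinedError):
            blci(_de(u, u), _de(u, ["g1"]))

    def test_adding_true_positive_never_decreases(self):
        u = [f"g{i}" for i in range(12)]
        b_cd = _de(u, ["g1", "g2", "g3"])
        current = _de(u, ["g1", "g5"])
        improved = _de(u, ["g1", "g5", "g2"])  # g2 is a true positive
        assert blci(b_cd, improved) >= blci(b_cd, current)

    def test_range(self):
        rng = np.random.default_rng(4)
        u = [f"g{i}" for i in range(20)]
        for _ in range(50):
            s1 = [g for g in u if rng.random() < 0.3] or ["g0"]
            if len(s1) == len(u):
                s1 = s1[:-1]
            s2 = [g for g in u if rng.random() < 0.3]
            v = blci(_de(u, s1), _de(u, s2))
            assert -1.0 <= v <= 1.0


class TestSam:
    def test_all_constant_genes_yield_empty_set(self):
        from arrayimpute import ExpressionMatrix
        vals = np.ones((20, 8))
        m = ExpressionMatrix([f"g{i}" for i in range(20)], [f"s{j}" for j in range(8)], vals)
        labels = {f"s{j}": ("A" if j < 4 else "B") for j in range(8)}
        assert sam_de_genes(m, labels, seed=0).significant == set()

    def test_class_with_one_sample_rejected(self):
        m, labels, _ = make_twogroup(50, 6, 5, 2.0, seed=0)
        bad = dict(labels)
        bad[m.sample_ids[0]] = "group2"
        bad[m.sample_ids[1]] = "group2"
        with pytest.raises(DesignError):
            sam_de_genes(m, bad, seed=0)

    def test_planted_signal_recovered(self):
        m, labels, truth = make_twogroup(300, 12, 30, 3.0, seed=5)
        de = sam_de_genes(m, labels, seed=5)
        called = de.significant
        recall = len(called & truth) / len(truth)
        precision = len(called & truth) / max(len(called), 1)
        assert recall >= 0.85 and precision >= 0.8

    def test_null_fdr_estimate_is_conservative(self):
        # on pure-null data the caller should almost always call nothing;
        # when it does call, the estimated FDR must not understate the
        # realised false-call fraction too often
        n_ok = 0
        reps = 50
        for rep in range(reps):
            m, labels, _ = make_twogroup(500, 12, 0, 0.0, seed=1000 + rep)
            de = sam_de_genes(m, labels, n_permutations=100, seed=rep)
            realized = 1.0 if de.significant else 0.0  # every call is false
            estimated = de.threshold_meta["estimated_fdr"]
            est = estimated if estimated is not None else 0.0
            if est >= realized:
                n_ok += 1
        assert n_ok >= 0.9 * reps


class TestScoreRound:
    def test_perfect_imputation_is_the_fixed_point(self):
        m, labels, _ = make_twogroup(60, 12, 10, 3.0, seed=7)
        md = inject_missing(m, 0.1, seed=8)
        res = oracle_impute(apply_mask(md), masked=md)
        rec = score_round(md, res, labels=labels, seed=9, n_clusters=5)
        assert rec.nrmse == pytest.approx(0.0, abs=1e-12)
        assert rec.cpp == pytest.approx(1.0)
        assert rec.blci == pytest.approx(1.0)

    def test_missing_labels_leave_blci_undefined(self):
        m, _, _ = make_twogroup(40, 8, 5, 3.0, seed=11)
        md = inject_missing(m, 0.1, seed=12)
        rec = score_round(md, row_mean_impute(apply_mask(md)), labels=None,
                          seed=13, n_clusters=4)
        assert rec.blci is None
        assert rec.nrmse is not None and rec.cpp is not None

    def test_records_share_round_metadata_across_algorithms(self):
        m, _, _ = make_twogroup(40, 8, 5, 3.0, seed=14)
        md = inject_missing(m, 0.1, seed=15)
        mm = apply_mask(md)
        r1 = score_round(md, row_mean_impute(mm), seed=16, round_no=3,
                         dataset="d", n_clusters=4)
        r2 = score_round(md, oracle_impute(mm, masked=md), seed=16, round_no=3,
                         dataset="d", n_clusters=4)
        assert (r1.dataset, r1.rate, r1.round) == (r2.dataset, r2.rate, r2.round)
        assert r1.algorithm != r2.algorithm
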