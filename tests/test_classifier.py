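"""KNN class prediction with abstention, LOOCV, and performance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from kdsig.classify import (
    ClassCounts,
    ConfusionCounts,
    KnnConfig,
    NOT_CLASSIFIED,
    clopper_pearson,
    knn_predict,
    loocv_confusion,
    performance_metrics,
    rank_genes,
    select_classifier_genes,
    train_knn,
)

from conftest import matrix_from


def _two_class(x_a, x_b, prefix=("A", "B")):
    x = np.vstack([x_a, x_b])
    n_a = len(x_a)
    sample_ids = [f"{prefix[0]}{i}" for i in range(n_a)] + [
        f"{prefix[1]}{i}" for i in range(len(x_b))
    ]
    m = matrix_from(x, sample_ids=sample_ids)
    labels = {s: ("A" if s.startswith("A") else "B") for s in sample_ids}
    return m, labels


class TestRankGenes:
    def test_signal_to_noise_hand_computation(self):
        rng = np.random.default_rng(0)
        # gene 0: class means 10 vs 6 with unit SDs -> s = (10-6)/(1+1) = 2
        a = np.column_stack([10 + _unit(rng, 8), 8 + rng.normal(0, 2, 8)])
        b = np.column_stack([6 + _unit(rng, 8), 8 + rng.normal(0, 2, 8)])
        m, labels = _two_class(a, b)
        ranked = dict(rank_genes(m, labels))
        assert ranked["T0"] == pytest.approx(2.0, abs=1e-9)

    def test_uninformative_gene_ranked_last(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(8, 1, 20)
        a = np.column_stack([rng.normal(12, 1, 10), shared[:10]])
        b = np.column_stack([rng.normal(6, 1, 10), shared[:10]])  # identical col 1
        m, labels = _two_class(a, b)
        ranked = rank_genes(m, labels)
        assert ranked[-1][0] == "T1"
        assert ranked[-1][1] == pytest.approx(0.0, abs=1e-12)

    def test_planted_discriminative_genes_rank_in_top_decile(self):
        rng = np.random.default_rng(2)
        n_genes, n_planted = 200, 10
        a = rng.normal(8, 1, size=(15, n_genes))
        b = rng.normal(8, 1, size=(15, n_genes))
        a[:, :n_planted] += 3.0
        m, labels = _two_class(a, b)
        top = {g for g, _ in rank_genes(m, labels)[: n_genes // 10]}
        assert {f"T{j}" for j in range(n_planted)} <= top


def _unit(rng, n):
    """n draws rescaled to sample mean 0 and sample SD exactly 1."""
    x = rng.normal(0, 1, n)
    return (x - x.mean()) / x.std(ddof=1)


class TestKnnPredict:
    def test_unanimous_neighbourhood_classifies(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, size=(8, 3))
        b = rng.normal(5, 0.2, size=(8, 3))
        m, labels = _two_class(a, b)
        model = train_knn(m, labels, m.transcript_ids, KnnConfig(k=6))
        label, votes, ratio = knn_predict(model, dict(zip(m.transcript_ids, [0.0, 0.0, 0.0])))
        assert label == "A"
        assert votes == {"A": 6, "B": 0}

    def test_balanced_split_abstains_at_default_cutoff(self):
        """A 3-3 neighbour split in a balanced training set gives equal
        hypergeometric tail p-values -> ratio 1 > 0.5 -> not classified."""
        a = np.array([[0.0], [0.1], [0.2], [3.0], [3.1], [3.2]])
        b = np.array([[1.0], [1.1], [1.2], [-2.0], [-2.1], [-2.2]])
        m, labels = _two_class(a, b)
        model = train_knn(m, labels, m.transcript_ids, KnnConfig(k=6))
        label, votes, ratio = knn_predict(model, {"T0": 0.55})
        assert votes["A"] == 3 and votes["B"] == 3
        assert ratio == pytest.approx(1.0)
        assert label == NOT_CLASSIFIED

    def test_hypergeometric_tail_hand_computation(self):
        # 12 training samples, 6 per class, k=6, 3 observed: P(X >= 3) with
        # X ~ Hypergeom(N=12, K=6, n=6) = (C(6,3)^2 + C(6,4)C(6,2) +
        # C(6,5)C(6,1) + 1) / C(12,6) = (400 + 225 + 36 + 1) / 924
        expected = stats.hypergeom.sf(2, 12, 6, 6)
        assert expected == pytest.approx(662 / 924, abs=1e-12)

    def test_two_dimensional_toy_with_brute_force_distances(self):
        """5-1 neighbour split computed against hand-checked Euclidean
        distances in standardized coordinates."""
        a = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5], [0.4, 0.6]], dtype=float)
        b = np.array([[8, 8], [8, 9], [9, 8], [9, 9], [8.5, 8.5], [0.6, 0.4]], dtype=float)
        m, labels = _two_class(a, b)
        model = train_knn(m, labels, m.transcript_ids, KnnConfig(k=6))
        query = {"T0": 0.5, "T1": 0.5}
        # brute-force nearest neighbours in the model's z-space
        v = np.array([0.5, 0.5])
        z = (v - model._mean) / model._sd
        d = np.sqrt(((model._z - z) ** 2).sum(axis=1))
        nearest = np.array(model.training_labels)[np.argsort(d)[:6]]
        assert (nearest == "A").sum() == 5
        label, votes, _ = knn_predict(model, query)
        assert votes == {"A": 5, "B": 1}
        assert label == "A"

    def test_missing_gene_rejected(self):
        m, labels = _two_class(np.zeros((3, 2)), np.ones((3, 2)))
        model = train_knn(m, labels, m.transcript_ids, KnnConfig(k=3))
        with pytest.raises(ValueError, match="missing"):
            knn_predict(model, {"T0": 0.0})

    def test_training_order_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(10, 4))
        b = rng.normal(2, 1, size=(10, 4))
        m, labels = _two_class(a, b)
        perm = rng.permutation(20)
        m_perm = matrix_from(
            m.values[perm], sample_ids=[m.sample_ids[i] for i in perm],
            transcript_ids=m.transcript_ids,
        )
        model1 = train_knn(m, labels, m.transcript_ids)
        model2 = train_knn(m_perm, labels, m.transcript_ids)
        query = dict(zip(m.transcript_ids, rng.normal(1, 1, 4)))
        assert knn_predict(model1, query)[0] == knn_predict(model2, query)[0]

    def test_cutoff_one_with_unanimous_neighbourhood_never_abstains(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(8, 2))
        b = rng.normal(6, 0.1, size=(8, 2))
        m, labels = _two_class(a, b)
        model = train_knn(m, labels, m.transcript_ids, KnnConfig(k=6, p_ratio_cutoff=1.0))
        for _ in range(10):
            q = dict(zip(m.transcript_ids, rng.normal(0, 0.5, 2)))
            label, votes, _ = knn_predict(model, q)
            if max(votes.values()) == 6:
                assert label != NOT_CLASSIFIED


class TestSelectAndLoocv:
    def test_separable_pair_needs_few_genes_and_perfect_loocv(self):
        rng = np.random.default_rng(0)
        n_genes = 50
        a = rng.normal(8, 1, size=(12, n_genes))
        b = rng.normal(8, 1, size=(12, n_genes))
        a[:, :5] += 4.0  # 5 informative genes
        m, labels = _two_class(a, b)
        model = select_classifier_genes(m, labels, KnnConfig(k=6), max_genes=15)
        assert len(model.classifier_genes) <= 10
        confusion = loocv_confusion(m, labels, model.classifier_genes)
        assert confusion.accuracy() == 1.0

    def test_equidistant_sample_not_classified(self):
        a = np.array([[0.0], [0.1], [0.2], [3.0], [3.1], [3.2]])
        b = np.array([[1.0], [1.1], [1.2], [-2.0], [-2.1], [-2.2]])
        m, labels = _two_class(a, b)
        extra = matrix_from(np.array([[0.55]]), sample_ids=["Q0"])
        import pandas as pd

        m_all = matrix_from(
            np.vstack([m.values, extra.values]),
            sample_ids=m.sample_ids + ["Q0"],
        )
        labels_all = labels | {"Q0": "A"}
        confusion = loocv_confusion(m_all, labels_all, m.transcript_ids, KnnConfig(k=6))
        assert confusion.per_class["A"].not_classified >= 1

    def test_single_sample_class_rejected(self):
        m, labels = _two_class(np.zeros((1, 2)), np.ones((4, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            loocv_confusion(m, labels, m.transcript_ids, KnnConfig(k=2))

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(8, 1, size=(24, 40))
        m = matrix_from(x)
        accs = []
        for rep in range(10):
            perm = rng.permutation(24)
            labels = {m.sample_ids[i]: ("A" if j < 12 else "B")
                      for j, i in enumerate(perm)}
            accs.append(loocv_confusion(m, labels, None, n_genes=5).accuracy())
        # pure-noise LOOCV accuracy sits around chance
        assert 0.25 < float(np.mean(accs)) < 0.75


class TestPerformanceMetrics:
    def test_printed_test_set_counts_give_92_and_100(self):
        counts = ConfusionCounts(per_class={
            "KD": ClassCounts(correct=11, incorrect=1, not_classified=0),
            "AdV": ClassCounts(correct=10, incorrect=0, not_classified=0),
        })
        perf = performance_metrics(counts, positive_class="KD")
        assert perf.sensitivity == 92
        assert perf.specificity == 100
        assert perf.ci_specificity[0] == pytest.approx(69.2, abs=0.05)

    def test_all_correct_13_of_13_lower_bound_75(self):
        counts = ConfusionCounts(per_class={
            "KD": ClassCounts(13, 0, 0), "AdV": ClassCounts(8, 1, 0),
        })
        perf = performance_metrics(counts, positive_class="KD")
        assert perf.sensitivity == 100
        assert round(perf.ci_sensitivity[0]) == 75

    def test_zero_correct_gives_zero_sensitivity(self):
        counts = ConfusionCounts(per_class={
            "KD": ClassCounts(0, 4, 1), "AdV": ClassCounts(5, 0, 0),
        })
        assert performance_metrics(counts, "KD").sensitivity == 0

    def test_abstentions_count_against_sensitivity(self):
        counts = ConfusionCounts(per_class={
            "KD": ClassCounts(6, 1, 1), "GAS": ClassCounts(7, 1, 0),
        })
        assert performance_metrics(counts, "KD").sensitivity == 75


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,lo,hi",
        [
            (10, 10, 69.2, 100.0),
            (13, 13, 75.3, 100.0),
            (0, 1, 0.0, 97.5),
        ],
    )
    def test_printed_bounds(self, x, n, lo, hi):
        got = clopper_pearson(x, n)
        assert got[0] == pytest.approx(lo, abs=0.05)
        assert got[1] == pytest.approx(hi, abs=0.05)

    def test_x_equals_n_closed_form(self):
        # lower bound = (alpha/2)^(1/n) when all trials succeed
        lo, hi = clopper_pearson(7, 7)
        assert hi == 100.0
        assert lo == pytest.approx(100 * 0.025 ** (1 / 7), abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=1, max_value=40).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(min_value=0, max_value=n))
    ))
    def test_intervals_nested_in_level(self, xn):
        n, x = xn
        lo95, hi95 = clopper_pearson(x, n, 0.95)
        lo99, hi99 = clopper_pearson(x, n, 0.99)
        assert lo99 <= lo95 and hi99 >= hi95
        # interval contains the point estimate
        assert lo95 <= 100 * x / n <= hi95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
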