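"""Multi-label KNN: distances, neighbor search, AL scores, prediction."""

import numpy as np
import pytest

from gnegloc import (
    FeatureVector,
    GOVector,
    Mode,
    Neighbor,
    TrainedModel,
    al_scale,
    euclidean_distance,
    jackknife,
    k_nearest,
    make_dataset,
    make_feature_context,
    matched_training_vectors,
    predict,
    predict_cardinality,
    represent,
    SyntheticSpec,
)
from gnegloc.representation import ModeMismatchError

from conftest import toy_context


def brute_force_neighbors(q, ctx, exclude, k):
    """Independent oracle: exhaustive pairwise sort, stable in training order."""
    cands = matched_training_vectors(q.mode, ctx, exclude)
    dists = [(euclidean_distance(q, fv), i) for i, (_, _, fv) in enumerate(cands)]
    order = sorted(range(len(dists)), key=lambda i: dists[i])
    return [cands[i][0] for i in order[:k]]


class TestDistance:
    def test_identical_vectors_have_zero_distance(self):
        a = FeatureVector("a", Mode.SEQEVO, seqevo=np.arange(210.0))
        b = FeatureVector("b", Mode.SEQEVO, seqevo=np.arange(210.0))
        assert euclidean_distance(a, b) == 0.0

    def test_sparse_three_four_five(self):
        a = FeatureVector("a", Mode.GO, go=GOVector({1: 1.0}, 10))
        b = FeatureVector("b", Mode.GO, go=GOVector({2: 1.0}, 10))
        # scaled 3-4-5: components (0.6, 0) vs (0, 0.8)
        a = FeatureVector("a", Mode.GO, go=GOVector({1: 0.6}, 10))
        b = FeatureVector("b", Mode.GO, go=GOVector({2: 0.8}, 10))
        assert euclidean_distance(a, b) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = FeatureVector("a", Mode.SEQEVO, seqevo=rng.normal(size=210))
            b = FeatureVector("b", Mode.SEQEVO, seqevo=rng.normal(size=210))
            assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_mode_mismatch_rejected(self):
        a = FeatureVector("a", Mode.SEQEVO, seqevo=np.zeros(210))
        b = FeatureVector("b", Mode.GO, go=GOVector({1: 1.0}, 10))
        with pytest.raises(ModeMismatchError):
            euclidean_distance(a, b)

    def test_sparse_matches_dense_computation(self, rng):
        U = 40
        ca = {int(r) + 1: float(v) for r, v in
              zip(rng.choice(U, 5, replace=False), rng.random(5))}
        cb = {int(r) + 1: float(v) for r, v in
              zip(rng.choice(U, 5, replace=False), rng.random(5))}
        a = FeatureVector("a", Mode.GO, go=GOVector(ca, U))
        b = FeatureVector("b", Mode.GO, go=GOVector(cb, U))
        da = np.zeros(U); db = np.zeros(U)
        for r, v in ca.items():
            da[r - 1] = v
        for r, v in cb.items():
            db[r - 1] = v
        assert euclidean_distance(a, b) == pytest.approx(
            np.linalg.norm(da - db), abs=1e-12)


class TestKNearest:
    def test_single_training_protein_always_returned(self):
        ctx = toy_context({"T": np.array([100.0])}, {"T": frozenset({2})}, k=1)
        model = TrainedModel(ctx, k=1)
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        ns = k_nearest(q, model)
        assert [nb.accession for nb in ns] == ["T"]

    @pytest.mark.parametrize("mode", [Mode.SEQEVO, Mode.GO])
    def test_matches_exhaustive_sort_oracle(self, mode, small_context):
        dataset, ctx = small_context
        model = TrainedModel(ctx, k=7)
        for rec in dataset.records[:25]:
            q = represent(rec.accession, ctx, exclude={rec.accession})
            if q.mode is not mode:
                continue
            ns = k_nearest(q, model, exclude={rec.accession})
            oracle = brute_force_neighbors(q, ctx, {rec.accession}, 7)
            assert [nb.accession for nb in ns] == oracle

    def test_self_exclusion_finds_second_closest(self, small_context):
        dataset, ctx = small_context
        model = TrainedModel(ctx, k=1)
        acc = dataset.records[0].accession
        q = FeatureVector(acc, Mode.SEQEVO, seqevo=ctx.seqevo[acc])
        unexcluded = k_nearest(q, model)[0]
        assert unexcluded.accession == acc and unexcluded.distance == 0.0
        excluded = k_nearest(q, model, exclude={acc})[0]
        oracle = brute_force_neighbors(q, ctx, {acc}, 1)[0]
        assert excluded.accession == oracle != acc

    def test_distance_ties_broken_by_training_order(self):
        points = {"A": np.array([1.0]), "B": np.array([-1.0]),
                  "C": np.array([1.0])}
        labels = {a: frozenset({1}) for a in points}
        ctx = toy_context(points, labels)
        model = TrainedModel(ctx, k=2)
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        ns = k_nearest(q, model)
        assert [nb.accession for nb in ns] == ["A", "B"]  # file order on ties

    def test_k_clamped_with_warning(self, caplog):
        ctx = toy_context({"A": np.array([0.0]), "B": np.array([1.0])},
                          {"A": frozenset({1}), "B": frozenset({2})})
        model = TrainedModel(ctx, k=10)
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        import logging
        with caplog.at_level(logging.WARNING):
            ns = k_nearest(q, model)
        assert len(ns) == 2
        assert any("clamped" in r.message for r in caplog.records)


class TestALScale:
    def test_single_neighbor_dual_labels(self):
        ns = [Neighbor("n", 0.1, frozenset({1, 3}))]
        A = al_scale(ns)
        assert A[1] == A[3] == 1 and sum(A.values()) == 2

    def test_hand_counted_fixture(self):
        labels = [{3}, {3}, {1, 8}, {3}, {8}]
        ns = [Neighbor(f"n{i}", 0.1 * i, frozenset(l))
              for i, l in enumerate(labels)]
        A = al_scale(ns)
        assert (A[1], A[3], A[8]) == (1, 3, 2)
        assert all(A[c] == 0 for c in (2, 4, 5, 6, 7))

    def test_score_conservation(self, rng):
        for _ in range(10):
            ns = [
                Neighbor(f"n{i}", float(i), frozenset(
                    int(c) + 1 for c in
                    rng.choice(8, size=rng.integers(1, 3), replace=False)))
                for i in range(7)
            ]
            A = al_scale(ns)
            assert sum(A.values()) == sum(len(nb.labels) for nb in ns)
            assert all(0 <= A[c] <= 7 for c in A)


class TestPrediction:
    def fixture_model(self):
        # q at origin; neighbors engineered so AL = {1:1, 3:3, 8:2} with K=5
        points = {
            "n1": np.array([1.0]), "n2": np.array([1.1]),
            "n3": np.array([1.2]), "n4": np.array([1.3]),
            "n5": np.array([1.4]),
        }
        labels = {
            "n1": frozenset({3}), "n2": frozenset({3}),
            "n3": frozenset({1, 8}), "n4": frozenset({3}),
            "n5": frozenset({8}),
        }
        return TrainedModel(toy_context(points, labels), k=5)

    def test_single_location_query_takes_top_score(self):
        model = self.fixture_model()
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        pred = predict(q, model)
        assert pred.m == 1  # nearest neighbor n1 is single-location
        assert pred.labels == frozenset({3})  # A3=3 is the highest score

    def test_dual_location_query_takes_two_top_scores(self):
        model = self.fixture_model()
        # move the dual-label neighbor closest so the cardinality rule fires
        model.ctx.seqevo["n3"][0] = 0.5
        model.ctx._seqevo_cache = None
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        pred = predict(q, model)
        assert pred.m == 2 and pred.nearest == "n3"
        assert pred.labels == frozenset({3, 8})  # A3=3, A8=2 top two

    def test_cardinality_follows_nearest_neighbor(self):
        single = [Neighbor("a", 0.0, frozenset({5}))]
        dual = [Neighbor("a", 0.0, frozenset({5, 6}))]
        assert predict_cardinality(single) == 1
        assert predict_cardinality(dual) == 2

    def test_cardinality_never_exceeds_eight(self, small_context):
        dataset, ctx = small_context
        model = TrainedModel(ctx, k=3)
        for rec in dataset.records[:20]:
            q = represent(rec.accession, ctx, exclude={rec.accession})
            pred = predict(q, model, exclude={rec.accession})
            assert 1 <= pred.m <= 8
            assert len(pred.labels) == pred.m
            assert pred.labels <= set(range(1, 9))

    def test_single_training_protein_forces_its_label_set(self):
        ctx = toy_context({"T": np.array([5.0])}, {"T": frozenset({2, 7})})
        model = TrainedModel(ctx, k=1)
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        pred = predict(q, model)
        assert pred.labels == frozenset({2, 7}) and pred.m == 2

    def test_al_tie_broken_by_summed_distance(self):
        # A2 == A3 == 1; carrier of 3 is nearer, so 3 wins the tie
        points = {"x": np.array([1.0]), "y": np.array([2.0])}
        labels = {"x": frozenset({3}), "y": frozenset({2})}
        model = TrainedModel(toy_context(points, labels), k=2)
        q = FeatureVector("q", Mode.SEQEVO, seqevo=np.zeros(210))
        pred = predict(q, model)
        assert pred.labels == frozenset({3})

    def test_k1_jackknife_copies_nearest_neighbor(self, small_context):
        dataset, ctx = small_context
        model = TrainedModel(ctx, k=1)
        for rec in dataset.records[:15]:
            q = represent(rec.accession, ctx, exclude={rec.accession})
            pred = predict(q, model, exclude={rec.accession})
            assert pred.labels == model.labels[pred.nearest]

    def test_deterministic_across_runs(self):
        spec = SyntheticSpec(seed=11).scaled(80)
        ds, _ = make_dataset(spec)
        ctx1 = make_feature_context(ds, spec)
        ctx2 = make_feature_context(ds, spec)
        r1 = jackknife(ds, ctx1, k=3)
        r2 = jackknife(ds, ctx2, k=3)
        assert [(p.accession, p.predicted) for p in r1.records] == \
            [(p.accession, p.predicted) for p in r2.records]
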