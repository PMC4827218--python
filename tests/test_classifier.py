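"""k-NN prediction: harmonization, voting, batch independence, summaries."""

import numpy as np
import pytest

from mbsubtype import (
    SUBTYPES,
    ExpressionMatrix,
    build_reference,
    classify_human,
    classify_mouse,
    generate_cohort,
    generate_species_pair,
    harmonize_genesets,
    knn_predict,
    ssgsea,
    summarize_by_sample,
    summarize_by_subtype,
    translate_to_mouse,
)
from mbsubtype.reference import TrainingReference, rank_transform
from mbsubtype.simulate import SimulationConfig
from mbsubtype.ssgsea import DegenerateProfileError, EnrichmentMatrix
from mbsubtype.types import MBSubtypeError

from helpers import brute_knn_neighbors


def _hand_reference(rank_rows, labels, names=None, k=1):
    rank_rows = np.asarray(rank_rows, dtype=float)
    names = names or [f"GS{i}" for i in range(rank_rows.shape[1])]
    samples = [f"ref{j:02d}" for j in range(rank_rows.shape[0])]
    return TrainingReference(
        names, samples, labels, rank_rows,
        hyperparams={"alpha": 0.25, "k": k, "es_mode": "integrated"},
    )


# Seven hand-placed rank permutations over 5 genesets. Distances to the test
# vector (1,2,3,4,5): rows a-e are near (0, sqrt2 x3, sqrt8), f-g are far.
_NEAR_FAR_ROWS = [
    [1, 2, 3, 4, 5],  # d = 0
    [2, 1, 3, 4, 5],  # d = sqrt(2)
    [1, 2, 3, 5, 4],  # d = sqrt(2)
    [1, 3, 2, 4, 5],  # d = sqrt(2)
    [3, 2, 1, 4, 5],  # d = sqrt(8)
    [4, 5, 2, 1, 3],  # d = sqrt(32)
    [5, 4, 3, 2, 1],  # d = sqrt(40)
]


class TestKnnPredict:
    def test_zero_distance_single_neighbor(self):
        ref = _hand_reference(
            [[1, 2, 3], [3, 2, 1], [2, 1, 3], [1, 3, 2]],
            ["WNT", "SHH", "Group3", "Group4"],
        )
        res = knn_predict(np.array([3.0, 2.0, 1.0]), ref, k=1)
        assert res.predicted == "SHH"
        assert res.confidence_percent == 100.0
        assert res.neighbors == [("ref01", 0.0)]

    @pytest.mark.parametrize("labels,winner,conf,call", [
        (["Group3"] * 5 + ["SHH", "WNT"], "Group3", 100.0, "high_confidence"),
        (["Group3"] * 4 + ["SHH"] + ["SHH", "WNT"], "Group3", 80.0,
         "high_confidence"),
        (["Group3"] * 3 + ["SHH"] * 2 + ["SHH", "WNT"], "Group3", 60.0,
         "intermediate"),
    ])
    def test_vote_fraction_thresholds(self, labels, winner, conf, call):
        ref = _hand_reference(_NEAR_FAR_ROWS, labels)
        res = knn_predict(np.array([1.0, 2, 3, 4, 5]), ref, k=5)
        near_ids = {f"ref0{j}" for j in range(5)}
        assert {sid for sid, _ in res.neighbors} == near_ids
        assert res.predicted == winner
        assert res.confidence_percent == conf
        assert res.call_class == call

    def test_k_exceeding_reference_rejected(self):
        ref = _hand_reference(
            [[1, 2, 3], [3, 2, 1]], ["WNT", "SHH"]
        )
        with pytest.raises(MBSubtypeError, match="k=3"):
            knn_predict(np.array([1.0, 2, 3]), ref, k=3)

    def test_vote_conservation_and_confidence_grid(self, rng):
        for _ in range(20):
            es = rng.normal(size=(8, 20))
            names = [f"GS{i}" for i in range(8)]
            samples = [f"ref{j:02d}" for j in range(20)]
            ranks = rank_transform(EnrichmentMatrix(names, samples, es), names)
            labels = [SUBTYPES[int(rng.integers(0, 5))] for _ in range(20)]
            if len(set(labels)) < 2:
                labels[0] = "WNT" if labels[1] != "WNT" else "SHH"
            ref = TrainingReference(names, samples, labels, ranks)
            vec = rank_transform(
                EnrichmentMatrix(names, ["t"], rng.normal(size=(8, 1))), names
            )[0]
            res = knn_predict(vec, ref, k=5)
            assert sum(res.votes.values()) == 5
            assert res.confidence_percent in {20.0, 40.0, 60.0, 80.0, 100.0}

    def test_neighbors_match_brute_force(self, rng):
        es = rng.normal(size=(10, 60))
        names = [f"GS{i}" for i in range(10)]
        samples = [f"ref{j:03d}" for j in range(60)]
        ranks = rank_transform(EnrichmentMatrix(names, samples, es), names)
        labels = [SUBTYPES[j % 5] for j in range(60)]
        ref = TrainingReference(names, samples, labels, ranks)
        for metric in ("euclidean", "manhattan"):
            for _ in range(10):
                vec = rank_transform(
                    EnrichmentMatrix(names, ["t"], rng.normal(size=(10, 1))),
                    names,
                )[0]
                res = knn_predict(vec, ref, k=7, metric=metric)
                want = brute_knn_neighbors(vec, ranks, samples, 7, metric)
                assert [sid for sid, _ in res.neighbors] == [s for s, _ in want]


class TestHarmonization:
    def _ref(self, rng, m=8, n=10):
        es = rng.normal(size=(m, n))
        names = [f"GS{i}" for i in range(m)]
        samples = [f"ref{j:02d}" for j in range(n)]
        ranks = rank_transform(EnrichmentMatrix(names, samples, es), names)
        labels = [("SHH" if j % 2 else "Group4") for j in range(n)]
        return TrainingReference(names, samples, labels, ranks)

    def test_full_overlap_is_identity(self, rng):
        ref = self._ref(rng)
        test_es = EnrichmentMatrix(
            list(ref.geneset_names), ["t"], rng.normal(size=(8, 1))
        )
        filtered, new_ref, common = harmonize_genesets(test_es, ref)
        assert common == ref.geneset_names
        np.testing.assert_array_equal(new_ref.rank_matrix, ref.rank_matrix)

    def test_half_overlap_reranks_reference(self, rng):
        ref = self._ref(rng, m=8)
        half = ref.geneset_names[::2]
        test_es = EnrichmentMatrix(half, ["t"], rng.normal(size=(4, 1)))
        _, new_ref, common = harmonize_genesets(test_es, ref)
        assert common == half
        # re-ranked rows are valid rankings of 4 items: row sums = 4*5/2
        np.testing.assert_allclose(new_ref.rank_matrix.sum(axis=1), 10.0)

    def test_subset_without_rerank_keeps_stale_ranks(self, rng):
        ref = self._ref(rng, m=8)
        half = ref.geneset_names[:4]
        test_es = EnrichmentMatrix(half, ["t"], rng.normal(size=(4, 1)))
        _, new_ref, _ = harmonize_genesets(test_es, ref, rerank=False)
        np.testing.assert_array_equal(
            new_ref.rank_matrix, ref.rank_matrix[:, :4]
        )

    def test_disjoint_namespaces_rejected(self, rng):
        ref = self._ref(rng)
        test_es = EnrichmentMatrix(["OTHER1", "OTHER2"], ["t"],
                                   rng.normal(size=(2, 1)))
        with pytest.raises(MBSubtypeError, match="no genesets shared"):
            harmonize_genesets(test_es, ref)


@pytest.fixture(scope="module")
def trained(small_cohort_module):
    config, expr, labels, coll = small_cohort_module
    ref = build_reference(expr, labels, coll, k=5, n_top=10)
    return config, expr, labels, coll, ref


@pytest.fixture(scope="module")
def small_cohort_module():
    config = SimulationConfig(
        n_per_class=8, classes=("SHH", "Group3", "Group4"),
        n_genes=240, n_genesets=16, genes_per_set=15,
        signature_sets_per_class=2, signal_shift=3.0, noise_sd=1.0, seed=11,
    )
    expr, labels, collection = generate_cohort(config)
    return config, expr, labels, collection


class TestClassifyPipelines:
    def test_batch_of_one_equals_batch_of_many(self, trained):
        config, _, _, coll, ref = trained
        held = SimulationConfig(**{**config.__dict__, "seed": 99, "n_per_class": 7})
        expr, _, _ = generate_cohort(held)
        batch = classify_human(expr, ref, coll)
        for sid in expr.sample_ids[::5]:
            solo = classify_human(expr.subset_samples([sid]), ref, coll)[0]
            inside = next(r for r in batch if r.sample_id == sid)
            assert solo.votes == inside.votes
            assert solo.neighbors == inside.neighbors
            assert solo.predicted == inside.predicted

    def test_synthetic_class_template_recovered(self, trained):
        config, _, _, coll, ref = trained
        held = SimulationConfig(**{**config.__dict__, "seed": 77, "n_per_class": 4})
        expr, labels, _ = generate_cohort(held)
        results = classify_human(expr, ref, coll)
        for r in results:
            assert r.predicted == labels[r.sample_id]

    def test_constant_sample_is_explicit_error(self, trained):
        _, expr, _, coll, ref = trained
        flat = ExpressionMatrix(
            expr.gene_ids, ["flat"], np.ones((expr.n_genes, 1))
        )
        with pytest.raises(DegenerateProfileError):
            classify_human(flat, ref, coll)

    def test_mouse_gmt_without_shared_terms_rejected(self, trained, rng):
        config, expr, _, _, ref = trained
        from mbsubtype.types import GeneSetCollection
        alien = GeneSetCollection("mouse", {
            "ALIEN_TERM": ("d", [g.lower() for g in expr.gene_ids[:10]])
        })
        with pytest.raises(MBSubtypeError):
            classify_mouse(expr, ref, alien)

    def test_cross_species_equivalence(self, trained):
        config, _, _, coll, ref = trained
        human_gmt, mouse_gmt, orthologs = generate_species_pair(config)
        held = SimulationConfig(**{**config.__dict__, "seed": 55, "n_per_class": 3})
        expr_h, labels, _ = generate_cohort(held)
        expr_m = translate_to_mouse(expr_h, orthologs)

        es_h = ssgsea(expr_h, human_gmt)
        es_m = ssgsea(expr_m, mouse_gmt)
        np.testing.assert_array_equal(es_h.es, es_m.es)

        res_h = classify_human(expr_h, ref, human_gmt)
        res_m = classify_mouse(expr_m, ref, mouse_gmt)
        for a, b in zip(res_h, res_m):
            assert a.votes == b.votes
            assert a.predicted == b.predicted
            assert a.neighbors == b.neighbors


class TestSummaries:
    def _results(self, trained, n_per_class=4, seed=123):
        config, _, _, coll, ref = trained
        held = SimulationConfig(
            **{**config.__dict__, "seed": seed, "n_per_class": n_per_class}
        )
        expr, _, _ = generate_cohort(held)
        return classify_human(expr, ref, coll)

    def test_counts_match_naive_tally(self, trained):
        results = self._results(trained)
        counts, confidences = summarize_by_subtype(results)
        tally = {s: 0 for s in SUBTYPES}
        for r in results:
            tally[r.predicted] += 1
        assert counts.to_dict() == tally
        assert counts.sum() == len(results)
        for s in SUBTYPES:
            assert sorted(confidences[s]) == sorted(
                r.confidence_percent for r in results if r.predicted == s
            )

    def test_sample_table_covers_every_sample(self, trained):
        results = self._results(trained)
        df = summarize_by_sample(results)
        assert list(df["sample_id"]) == [r.sample_id for r in results]
        assert (df["mean_neighbor_distance"] >= 0).all()

    def test_empty_results_rejected(self):
        with pytest.raises(MBSubtypeError):
            summarize_by_subtype([])
        with pytest.raises(MBSubtypeError):
            summarize_by_sample([])
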