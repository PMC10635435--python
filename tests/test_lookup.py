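"""Lookup mechanism: routing, weighted means, harmonic weights, ensemble."""

import numpy as np
import pytest

from helpers_oracles import lookup_one_new_oracle, lookup_two_new_oracle
from lamfp.amfp import EmbeddingModel
from lamfp.data_model import PATH_DIRECT, PATH_ONE_NEW, PATH_TWO_NEW, Drug, DrugSet
from lamfp.lookup import LookupConfig, NoSupportError, ensemble_predict, predict_all, predict_pair
from lamfp.similarity import nearest_neighbors


def make_model(ids, seed=0):
    rng = np.random.default_rng(seed)
    return EmbeddingModel(
        ids,
        mu=float(rng.normal(scale=0.5)),
        bias=rng.normal(scale=0.5, size=len(ids)),
        factors=rng.normal(scale=0.5, size=(len(ids), 4)),
        alpha=0.0,
    )


class TableMeasure:
    """Similarity measure backed by an explicit lookup table."""

    def __init__(self, table):
        self.table = table

    def __call__(self, a, b):
        return self.table.get((a.id, b.id), self.table.get((b.id, a.id), 0.0))


@pytest.fixture()
def world():
    known_ids = [f"k{i}" for i in range(5)]
    known = DrugSet([Drug(k, "CC" + "O" * i) for i, k in enumerate(known_ids)])
    model = make_model(known_ids, seed=42)
    # chosen so the two unseen drugs have different neighbour rankings
    new_a = Drug("na", "CCCN")
    new_b = Drug("nb", "CCOOOON")
    return known, model, new_a, new_b


class TestRouting:
    def test_both_known_is_bitwise_direct_score(self, world):
        known, model, *_ = world
        a, b = known["k0"], known["k1"]
        rec = predict_pair(a, b, model, known, "edit", m=3)
        assert rec.path == PATH_DIRECT
        assert rec.score == model.predict_proba("k0", "k1")

    def test_one_new_path_tag_and_swap_symmetry(self, world):
        known, model, new_a, _ = world
        b = known["k2"]
        r1 = predict_pair(new_a, b, model, known, "edit", m=3)
        r2 = predict_pair(b, new_a, model, known, "edit", m=3)
        assert r1.path == r2.path == PATH_ONE_NEW
        assert r1.score == r2.score

    def test_two_new_path_and_symmetry(self, world):
        known, model, new_a, new_b = world
        r1 = predict_pair(new_a, new_b, model, known, "edit", m=3)
        r2 = predict_pair(new_b, new_a, model, known, "edit", m=3)
        assert r1.path == r2.path == PATH_TWO_NEW
        assert r1.score == pytest.approx(r2.score, abs=1e-12)

    def test_same_drug_rejected(self, world):
        known, model, new_a, _ = world
        with pytest.raises(Exception):
            predict_pair(new_a, new_a, model, known, "edit", m=3)


class TestOneNewArithmetic:
    def test_equal_similarities_give_unweighted_mean(self, world):
        known, model, new_a, _ = world
        b = known["k4"]
        sims = {("na", k): 0.5 for k in ("k0", "k1", "k2")}
        measure = TableMeasure(sims)
        rec = predict_pair(new_a, b, model, known, measure, m=3)
        expected = np.mean([model.predict_proba(k, "k4") for k in ("k0", "k1", "k2")])
        assert rec.score == pytest.approx(expected)

    def test_weighted_mean_matches_oracle(self, world):
        known, model, new_a, _ = world
        b = known["k4"]
        sims = {("na", "k0"): 0.8, ("na", "k1"): 0.4, ("na", "k2"): 0.1}
        measure = TableMeasure(sims)
        rec = predict_pair(new_a, b, model, known, measure, m=3)
        nl = nearest_neighbors(new_a, known, 3, measure)
        oracle = lookup_one_new_oracle(
            nl.entries, {k: model.predict_proba(k, "k4") for k, _ in nl.entries}, skip_id="k4"
        )
        assert rec.score == pytest.approx(oracle)

    def test_self_similar_unseen_with_m1_equals_direct(self, world):
        known, model, _, _ = world
        clone = Drug("clone", known["k1"].smiles)  # byte-identical SMILES
        b = known["k3"]
        rec = predict_pair(clone, b, model, known, "edit", m=1)
        assert rec.score == pytest.approx(model.predict_proba("k1", "k3"))

    def test_all_zero_similarity_raises_no_support(self, world):
        known, model, new_a, _ = world
        rec = TableMeasure({})  # every similarity 0
        with pytest.raises(NoSupportError):
            predict_pair(new_a, known["k0"], model, known, rec, m=3)

    def test_score_bounded_by_contributing_probabilities(self, world):
        known, model, new_a, _ = world
        b = known["k4"]
        sims = {("na", "k0"): 0.9, ("na", "k1"): 0.3, ("na", "k2"): 0.2}
        measure = TableMeasure(sims)
        rec = predict_pair(new_a, b, model, known, measure, m=3)
        probas = [model.predict_proba(k, "k4") for k in ("k0", "k1", "k2")]
        assert min(probas) <= rec.score <= max(probas)

    def test_increasing_a_neighbors_weight_pulls_score_toward_it(self, world):
        known, model, new_a, _ = world
        b = known["k4"]
        target_proba = model.predict_proba("k0", "k4")

        def score_with(w0):
            sims = {("na", "k0"): w0, ("na", "k1"): 0.5, ("na", "k2"): 0.5}
            return predict_pair(new_a, b, model, known, TableMeasure(sims), m=3).score

        lo, hi = score_with(0.1), score_with(0.9)
        assert abs(hi - target_proba) < abs(lo - target_proba)


class TestTwoNewArithmetic:
    def test_m1_score_is_single_pair_probability(self, world):
        known, model, new_a, new_b = world
        sims = {("na", "k0"): 0.7, ("nb", "k3"): 0.2}
        measure = TableMeasure(sims)
        rec = predict_pair(new_a, new_b, model, known, measure, m=1)
        assert rec.score == pytest.approx(model.predict_proba("k0", "k3"))

    def test_harmonic_mean_weights_match_oracle(self, world):
        known, model, new_a, new_b = world
        sims = {
            ("na", "k0"): 0.9, ("na", "k1"): 0.6, ("na", "k2"): 0.3,
            ("nb", "k3"): 0.8, ("nb", "k4"): 0.5, ("nb", "k0"): 0.2,
        }
        measure = TableMeasure(sims)
        rec = predict_pair(new_a, new_b, model, known, measure, m=3)
        nla = nearest_neighbors(new_a, known, 3, measure)
        nlb = nearest_neighbors(new_b, known, 3, measure)
        probas = {
            (ca, cb): model.predict_proba(ca, cb)
            for ca, _ in nla.entries
            for cb, _ in nlb.entries
            if ca != cb
        }
        oracle = lookup_two_new_oracle(nla.entries, nlb.entries, probas)
        assert rec.score == pytest.approx(oracle)

    def test_identical_neighbor_pairs_skipped(self, world):
        known, model, new_a, new_b = world
        # rank-1 neighbours coincide -> that index pair must be skipped
        sims = {
            ("na", "k0"): 0.9, ("na", "k1"): 0.5,
            ("nb", "k0"): 0.9, ("nb", "k2"): 0.4,
        }
        rec = predict_pair(new_a, new_b, model, known, TableMeasure(sims), m=2)
        # surviving pair: (k1, k2) with w = harmonic(0.5, 0.4)
        assert rec.score == pytest.approx(model.predict_proba("k1", "k2"))

    def test_all_pairs_skipped_raises_no_support(self, world):
        known, model, new_a, new_b = world
        sims = {("na", "k0"): 0.9, ("nb", "k0"): 0.8}
        with pytest.raises(NoSupportError):
            predict_pair(new_a, new_b, model, known, TableMeasure(sims), m=1)


class TestEnsemble:
    def test_mean_of_per_measure_scores(self, world):
        known, model, new_a, _ = world
        b = known["k2"]
        cfg = LookupConfig(m=3)
        per_measure = [
            predict_pair(new_a, b, model, known, name, m=3).score for name in cfg.measures
        ]
        rec = ensemble_predict(new_a, b, model, known, cfg)
        assert rec.score == pytest.approx(np.mean(per_measure))

    def test_both_known_equals_direct_score(self, world):
        known, model, *_ = world
        rec = ensemble_predict(known["k0"], known["k3"], model, known, LookupConfig())
        assert rec.score == model.predict_proba("k0", "k3")
        assert rec.path == PATH_DIRECT


class TestBatch:
    def test_batch_of_one_matches_single_call(self, world):
        known, model, new_a, _ = world
        drugs = DrugSet(list(known.values()) + [new_a])
        cfg = LookupConfig(m=2, measures=("edit",), ensemble=False)
        batch = predict_all([("na", "k1")], model, drugs, known, cfg)
        single = predict_pair(new_a, known["k1"], model, known, "edit", m=2)
        assert batch.records == [single]

    def test_duplicated_pair_scores_identically(self, world):
        known, model, new_a, new_b = world
        drugs = DrugSet(list(known.values()) + [new_a, new_b])
        batch = predict_all([("na", "nb"), ("na", "nb")], model, drugs, known, LookupConfig())
        assert batch.records[0].score == batch.records[1].score

    def test_paths_classified_per_pair(self, world):
        known, model, new_a, new_b = world
        drugs = DrugSet(list(known.values()) + [new_a, new_b])
        batch = predict_all(
            [("k0", "k1"), ("na", "k1"), ("na", "nb")], model, drugs, known, LookupConfig()
        )
        assert [r.path for r in batch.records] == [PATH_DIRECT, PATH_ONE_NEW, PATH_TWO_NEW]

    def test_per_pair_errors_collected_not_fatal(self, world):
        known, model, new_a, _ = world
        drugs = DrugSet(list(known.values()) + [new_a])
        batch = predict_all(
            [("na", "missing"), ("k0", "k1")], model, drugs, known, LookupConfig()
        )
        assert len(batch.records) == 1 and len(batch.failures) == 1
        assert batch.summary()["n_failed"] == 1
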