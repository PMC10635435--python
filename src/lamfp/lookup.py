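"""Similarity lookup for cold-start pairs, with the measure-level ensemble.

A pair is routed by training-set membership:

* both drugs known — the factorization score is returned unchanged
  (the lookup is bypassed entirely);
* exactly one drug unseen — the unseen drug is replaced by its m nearest
  known neighbours; the prediction is the similarity-weighted mean of the
  factorization scores of (neighbour, known drug);
* both unseen — each drug gets its own neighbour list; rank-aligned
  neighbour pairs are scored and combined with weights equal to the
  harmonic mean of the two similarities.

The ensemble averages the final pair scores across the configured
similarity measures (not the similarities themselves).

Degenerate cases: a neighbour pair that would require a drug's score
against itself is skipped, as is any pair whose weight is zero (a
zero-similarity neighbour carries no information and the harmonic mean's
limit there is zero). A pair with no surviving neighbour contribution
raises :class:`NoSupportError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lamfp.amfp import EmbeddingModel
from lamfp.data_model import (
    PATH_DIRECT,
    PATH_ONE_NEW,
    PATH_TWO_NEW,
    Drug,
    DrugSet,
    PredictionRecord,
    ValidationError,
)
from lamfp.similarity import MEASURE_NAMES, NeighborList, SimilarityFn, get_measure, nearest_neighbors


class NoSupportError(ValueError):
    """No usable neighbour support to predict for a pair with unseen drugs."""

    def __init__(self, drug_a: str, drug_b: str, reason: str):
        super().__init__(f"no lookup support for pair ({drug_a}, {drug_b}): {reason}")
        self.pair = (drug_a, drug_b)


@dataclass(frozen=True)
class LookupConfig:
    """m: neighbours per unseen drug (3 by default — the average number of
    similar drugs per drug in curated interaction databases); measures: the
    similarity measures averaged by the ensemble; pair_all_combinations:
    score all m x m neighbour pairs in the two-unseen case instead of the
    default rank-aligned pairing (experimental)."""

    m: int = 3
    measures: tuple[str, ...] = MEASURE_NAMES
    ensemble: bool = True
    pair_all_combinations: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if not self.measures:
            raise ValidationError("at least one similarity measure is required")
        for name in self.measures:
            get_measure(name)  # validates

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "measures": list(self.measures),
            "ensemble": self.ensemble,
            "pair_all_combinations": self.pair_all_combinations,
        }


NeighborCache = dict[tuple[str, int], NeighborList]


def _neighbors(
    a: Drug,
    known: DrugSet,
    m: int,
    measure: SimilarityFn,
    cache: NeighborCache | None,
) -> NeighborList:
    if cache is None:
        return nearest_neighbors(a, known, m, measure)
    available = len(known) - (1 if a.id in known else 0)
    key = (a.id, id(measure))
    nl = cache.get(key)
    if nl is None or len(nl) < min(m, available):
        nl = nearest_neighbors(a, known, m, measure)
        cache[key] = nl
    if len(nl) > m:  # cached with a larger m: truncate, order is already by rank
        nl = NeighborList(query=nl.query, entries=nl.entries[:m])
    return nl


def _one_new(
    new: Drug,
    known_partner: Drug,
    model: EmbeddingModel,
    known: DrugSet,
    measure: SimilarityFn,
    m: int,
    cache: NeighborCache | None,
) -> float:
    neighbours = _neighbors(new, known, m, measure, cache)
    num = 0.0
    den = 0.0
    for c, sim in neighbours.entries:
        if c == known_partner.id or sim == 0.0:
            continue  # no self-pair score; zero similarity carries no weight
        num += model.predict_proba(c, known_partner.id) * sim
        den += sim
    if den == 0.0:
        raise NoSupportError(new.id, known_partner.id, "all neighbour similarities are zero")
    return num / den


def _two_new(
    a: Drug,
    b: Drug,
    model: EmbeddingModel,
    known: DrugSet,
    measure: SimilarityFn,
    m: int,
    cache: NeighborCache | None,
    all_combinations: bool,
) -> float:
    na = _neighbors(a, known, m, measure, cache)
    nb = _neighbors(b, known, m, measure, cache)
    if all_combinations:
        pairs = [(ea, eb) for ea in na.entries for eb in nb.entries]
    else:
        pairs = list(zip(na.entries, nb.entries))  # rank-aligned
    num = 0.0
    den = 0.0
    for (ca, sa), (cb, sb) in pairs:
        if ca == cb or sa == 0.0 or sb == 0.0:
            continue
        w = 2.0 / (1.0 / sa + 1.0 / sb)  # harmonic mean of the similarities
        num += model.predict_proba(ca, cb) * w
        den += w
    if den == 0.0:
        raise NoSupportError(a.id, b.id, "no usable neighbour pair (zero weights or self-pairs)")
    return num / den


def predict_pair(
    a: Drug,
    b: Drug,
    model: EmbeddingModel,
    known: DrugSet,
    measure: SimilarityFn | str,
    m: int = 3,
    neighbor_cache: NeighborCache | None = None,
    pair_all_combinations: bool = False,
) -> PredictionRecord:
    """Score one drug pair, routing unseen drugs through the lookup.

    Symmetric in (a, b): when exactly one drug is unseen the arguments are
    normalized so the unseen drug plays the lookup role, and the two-unseen
    combination rule is itself symmetric.
    """
    if a.id == b.id:
        raise ValidationError(f"cannot predict a drug against itself ({a.id!r})")
    if isinstance(measure, str):
        measure = get_measure(measure)
    a_known = a.id in known and a.id in model
    b_known = b.id in known and b.id in model
    if a_known and b_known:
        return PredictionRecord(a.id, b.id, model.predict_proba(a.id, b.id), PATH_DIRECT)
    if a_known != b_known:
        new, old = (b, a) if a_known else (a, b)
        score = _one_new(new, old, model, known, measure, m, neighbor_cache)
        return PredictionRecord(a.id, b.id, score, PATH_ONE_NEW)
    score = _two_new(a, b, model, known, measure, m, neighbor_cache, pair_all_combinations)
    return PredictionRecord(a.id, b.id, score, PATH_TWO_NEW)


def ensemble_predict(
    a: Drug,
    b: Drug,
    model: EmbeddingModel,
    known: DrugSet,
    cfg: LookupConfig,
    neighbor_cache: NeighborCache | None = None,
) -> PredictionRecord:
    """Mean of the per-measure pair scores.

    A measure that fails with :class:`NoSupportError` is dropped from the
    average; if every measure fails the error propagates.
    """
    scores: list[float] = []
    path = None
    last_error: NoSupportError | None = None
    for name in cfg.measures:
        try:
            rec = predict_pair(
                a, b, model, known, name, cfg.m, neighbor_cache, cfg.pair_all_combinations
            )
        except NoSupportError as exc:
            last_error = exc
            continue
        scores.append(rec.score)
        path = rec.path
    if not scores:
        assert last_error is not None
        raise last_error
    return PredictionRecord(a.id, b.id, sum(scores) / len(scores), path)


@dataclass
class BatchResult:
    """Predictions for a batch of pairs plus any per-pair failures."""

    records: list[PredictionRecord]
    failures: list[tuple[str, str, str]] = field(default_factory=list)

    def summary(self) -> dict:
        paths: dict[str, int] = {}
        for r in self.records:
            paths[r.path] = paths.get(r.path, 0) + 1
        return {"n_predicted": len(self.records), "n_failed": len(self.failures), "paths": paths}


def predict_all(
    pairs: list[tuple[str, str]],
    model: EmbeddingModel,
    drugs: DrugSet,
    known: DrugSet,
    cfg: LookupConfig,
) -> BatchResult:
    """Score a batch of id pairs, caching neighbour lists per unseen drug.

    Order-preserving and identical to per-pair calls; per-pair errors are
    collected in the result instead of aborting the batch.
    """
    cache: NeighborCache = {}
    result = BatchResult(records=[])
    for ida, idb in pairs:
        try:
            a, b = drugs[ida], drugs[idb]
        except KeyError as exc:
            result.failures.append((ida, idb, f"unknown drug id {exc.args[0]!r}"))
            continue
        try:
            if cfg.ensemble:
                rec = ensemble_predict(a, b, model, known, cfg, cache)
            else:
                rec = predict_pair(
                    a, b, model, known, cfg.measures[0], cfg.m, cache, cfg.pair_all_combinations
                )
        except (NoSupportError, ValidationError, ValueError) as exc:
            result.failures.append((ida, idb, str(exc)))
            continue
        result.records.append(rec)
    return result
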