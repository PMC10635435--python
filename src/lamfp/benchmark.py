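"""End-to-end cold-start study on synthetic data.

Generates a retrospective split, trains the factorization on the known
drugs, scores the test pairs with the similarity-lookup ensemble and with
the two chemistry-free baselines, and reports per-subset AUCs. Used by the
acceptance script and the headline mechanism test: the lookup should beat
both baselines decisively when chemical similarity tracks the interaction
structure, and the advantage should collapse when the two are decoupled
(high SMILES mutation rate).
"""

from __future__ import annotations

from dataclasses import dataclass

from lamfp.amfp import TrainConfig, train_amfp
from lamfp.baselines import extend_with_random_embeddings, popularity_scores
from lamfp.data_model import PredictionRecord, RetrospectiveSplit
from lamfp.evaluation import (
    SUBSET_KNOWN_NEW,
    SUBSET_NEW_NEW,
    EvaluationReport,
    auc,
    build_subsets,
    evaluate,
)
from lamfp.lookup import LookupConfig, predict_all
from lamfp.synthetic import SynthConfig, generate_dataset


@dataclass
class StudyResult:
    """AUCs per method and subset, plus the full lookup evaluation report."""

    lamfp_auc: dict[str, float | None]
    random_embedding_auc: dict[str, float | None]
    popularity_auc: dict[str, float | None]
    report: EvaluationReport
    split: RetrospectiveSplit
    n_test_pairs: int


def _subset_auc(
    subsets: dict[str, list[tuple[str, str, int]]],
    scores: dict[tuple[str, str], float],
) -> dict[str, float | None]:
    out: dict[str, float | None] = {}
    for name, pairs in subsets.items():
        pairs = [(a, b, lab) for a, b, lab in pairs if (a, b) in scores]
        labels = [lab for _, _, lab in pairs]
        if not labels or min(labels) == max(labels):
            out[name] = None
            continue
        out[name] = auc(labels, [scores[(a, b)] for a, b, _ in pairs])
    return out


def run_cold_start_study(
    synth_cfg: SynthConfig,
    train_cfg: TrainConfig | None = None,
    lookup_cfg: LookupConfig | None = None,
) -> StudyResult:
    """Simulate, train, predict and evaluate one cold-start condition."""
    if train_cfg is None:
        train_cfg = TrainConfig(k=32, epochs=300, learning_rate=0.05, seed=synth_cfg.seed)
    if lookup_cfg is None:
        lookup_cfg = LookupConfig()
    synth, _, split = generate_dataset(synth_cfg)
    model = train_amfp(split.train, train_cfg)
    known = split.train.drugs
    pairs = [(a, b) for a, b, _ in split.test_pairs]

    batch = predict_all(pairs, model, split.drugs, known, lookup_cfg)
    lookup_scores = {(r.drug_a, r.drug_b): r.score for r in batch.records}

    unseen = sorted({d for pair in pairs for d in pair if d not in model})
    rand_model = extend_with_random_embeddings(model, unseen, seed=train_cfg.seed + 10_000)
    rand_scores = {(a, b): rand_model.predict_proba(a, b) for a, b in pairs}

    pop = popularity_scores(pairs, split.train)
    pop_scores = {pair: s for pair, s in zip(pairs, pop)}

    subsets = build_subsets(split)
    report = evaluate(batch.records, split)
    return StudyResult(
        lamfp_auc=_subset_auc(subsets, lookup_scores),
        random_embedding_auc=_subset_auc(subsets, rand_scores),
        popularity_auc=_subset_auc(subsets, pop_scores),
        report=report,
        split=split,
        n_test_pairs=len(pairs),
    )


def lookup_advantage(result: StudyResult, subset: str = SUBSET_KNOWN_NEW) -> dict[str, float]:
    """Lookup AUC minus each baseline's AUC on one subset."""
    lam = result.lamfp_auc[subset]
    rnd = result.random_embedding_auc[subset]
    pop = result.popularity_auc[subset]
    if lam is None or rnd is None or pop is None:
        raise ValueError(f"AUC undefined on subset {subset!r}")
    return {
        "lamfp": lam,
        "vs_random_embedding": lam - rnd,
        "vs_popularity": lam - pop,
    }


__all__ = [
    "StudyResult",
    "run_cold_start_study",
    "lookup_advantage",
    "SUBSET_KNOWN_NEW",
    "SUBSET_NEW_NEW",
]
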