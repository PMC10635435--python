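"""Reference baselines for cold-start evaluation.

Neither baseline uses chemistry; they bracket what the lookup mechanism
must beat to show that chemical similarity carries signal:

* random-embedding factorization — the trained model extended with freshly
  drawn random factors and zero biases for the unseen drugs, the naive way
  to force a factorization model to emit a score for a cold-start pair;
* popularity — score(a, b) = deg(a) + deg(b) in the training graph (0 for
  unseen drugs), the degree heuristic that exploits the tendency of
  highly connected drugs to keep acquiring interactions.
"""

from __future__ import annotations

import numpy as np

from lamfp.amfp import EmbeddingModel
from lamfp.data_model import InteractionGraph


def extend_with_random_embeddings(
    model: EmbeddingModel, new_ids: list[str], seed: int
) -> EmbeddingModel:
    """Add unseen drugs to a trained model with random factors and zero bias.

    Factors are drawn from the same Normal(0, 0.1/sqrt(k)) used at training
    initialization, seeded independently of training.
    """
    fresh = [d for d in new_ids if d not in model]
    rng = np.random.default_rng(seed)
    extra = rng.normal(0.0, 0.1 / np.sqrt(model.k), size=(len(fresh), model.k))
    return EmbeddingModel(
        ids=model.ids + fresh,
        mu=model.mu,
        bias=np.concatenate([model.bias, np.zeros(len(fresh))]),
        factors=np.vstack([model.factors, extra]),
        alpha=model.alpha,
        config=model.config,
    )


def popularity_scores(
    pairs: list[tuple[str, str]], train: InteractionGraph
) -> list[float]:
    """deg(a) + deg(b) in the training graph, normalized to [0, 1]."""
    def deg(d: str) -> int:
        return train.degree(d) if d in train.drugs else 0

    raw = [float(deg(a) + deg(b)) for a, b in pairs]
    top = max(raw) if raw else 1.0
    if top == 0.0:
        return raw
    return [v / top for v in raw]
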