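"""Biased adjacency-matrix factorization (AMF) and latent-factor propagation (AMFP).

The interaction network's adjacency matrix A (binary, symmetric, zero
diagonal) is modelled with a biased inner-product factorization:

    y_hat(i, j) = sigmoid( mu + b_i + b_j + p_i . p_j )

where mu is a fixed global offset (the adjacency density), b_i are per-drug
biases and p_i are k-dimensional latent factors living in a single shared
vector space — the same factor matrix plays the role of both row and column
embeddings, which makes the raw score symmetric by construction. Training
minimizes binary cross-entropy of y_hat against the adjacency entries
(edges are positives; non-edges among the training drugs are negatives).

AMFP adds one latent-factor propagation step after training: every drug's
factor is mixed with the mean factor of its interaction neighbours,
controlled by the propagation factor alpha in [0, 1]. At alpha = 0 the
factors are untouched and AMFP coincides with AMF; at alpha = 1 each factor
is replaced by its neighbourhood mean. The step is applied simultaneously
from a frozen copy of the factors (one Jacobi-style pass, not iterated
diffusion); drugs with no neighbours keep their factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from lamfp.data_model import InteractionGraph, ValidationError


class UnknownDrugError(KeyError):
    """A drug id was not part of the training graph."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for AMF/AMFP training.

    negative_ratio: "all" uses every non-edge among the training drugs as a
    negative (the default at desk scale); a float r samples r * n_positives
    negatives once, seeded, and masks the rest out of the loss.
    """

    k: int = 64
    alpha: float = 0.3
    learning_rate: float = 0.01
    epochs: int = 100
    negative_ratio: float | str = "all"
    l2: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValidationError(f"latent dimension k must be positive, got {self.k}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.learning_rate <= 0 or self.epochs <= 0:
            raise ValidationError("learning_rate and epochs must be positive")
        if self.negative_ratio != "all" and float(self.negative_ratio) <= 0:
            raise ValidationError("negative_ratio must be 'all' or a positive float")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        ratio = d.get("negative_ratio", "all")
        if ratio != "all":
            ratio = float(ratio)
        return cls(
            k=int(d["k"]),
            alpha=float(d["alpha"]),
            learning_rate=float(d["learning_rate"]),
            epochs=int(d["epochs"]),
            negative_ratio=ratio,
            l2=float(d["l2"]),
            seed=int(d["seed"]),
        )


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


class EmbeddingModel:
    """Trained factorization: global mean, per-drug biases and latent factors."""

    def __init__(
        self,
        ids: list[str],
        mu: float,
        bias: np.ndarray,
        factors: np.ndarray,
        alpha: float,
        config: TrainConfig | None = None,
    ):
        n = len(ids)
        if bias.shape != (n,):
            raise ValidationError(f"bias shape {bias.shape} does not match {n} drugs")
        if factors.ndim != 2 or factors.shape[0] != n:
            raise ValidationError(f"factor shape {factors.shape} does not match {n} drugs")
        self.ids = list(ids)
        self._index = {d: i for i, d in enumerate(self.ids)}
        self.mu = float(mu)
        self.bias = np.asarray(bias, dtype=np.float64)
        self.factors = np.asarray(factors, dtype=np.float64)
        self.alpha = float(alpha)
        self.config = config

    @property
    def k(self) -> int:
        return self.factors.shape[1]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._index

    def index(self, drug_id: str) -> int:
        try:
            return self._index[drug_id]
        except KeyError:
            raise UnknownDrugError(
                f"drug {drug_id!r} was not in the training graph; "
                "route it through the similarity lookup"
            ) from None

    def raw_score(self, i: str, j: str) -> float:
        """mu + b_i + b_j + p_i . p_j; symmetric in (i, j)."""
        if i == j:
            raise ValidationError(f"no self-interaction score for drug {i!r}")
        a, b = self.index(i), self.index(j)
        # grouping keeps the float result exactly symmetric in (i, j)
        return float(self.mu + (self.bias[a] + self.bias[b]) + self.factors[a] @ self.factors[b])

    def predict_proba(self, i: str, j: str) -> float:
        """Logistic transform of the raw score — interaction probability."""
        return float(_sigmoid(self.raw_score(i, j)))

    def score_matrix(self) -> tuple[np.ndarray, list[str]]:
        """All-pairs probabilities (diagonal meaningless, set to 0)."""
        raw = self.mu + self.bias[:, None] + self.bias[None, :] + self.factors @ self.factors.T
        prob = np.asarray(_sigmoid(raw))
        np.fill_diagonal(prob, 0.0)
        return prob, list(self.ids)


def _loss_mask(a: np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Symmetric 0/1 mask of pair entries included in the loss (zero diagonal)."""
    n = a.shape[0]
    mask = np.ones((n, n), dtype=np.float64)
    np.fill_diagonal(mask, 0.0)
    if cfg.negative_ratio == "all":
        return mask
    iu, ju = np.triu_indices(n, k=1)
    neg = np.flatnonzero(a[iu, ju] == 0.0)
    pos = np.flatnonzero(a[iu, ju] == 1.0)
    n_keep = min(len(neg), int(round(float(cfg.negative_ratio) * max(len(pos), 1))))
    keep = rng.choice(neg, size=n_keep, replace=False)
    mask[:] = 0.0
    sel = np.concatenate([pos, keep])
    mask[iu[sel], ju[sel]] = 1.0
    mask[ju[sel], iu[sel]] = 1.0
    return mask


def train_amf(graph: InteractionGraph, cfg: TrainConfig) -> EmbeddingModel:
    """Fit the biased factorization to the interaction graph.

    mu is fixed to the adjacency density; biases start at zero and factors
    at Normal(0, 0.1/sqrt(k)). Optimization is full-batch Adam on the mean
    binary cross-entropy over the included pairs plus an L2 penalty.
    Deterministic for a fixed config (single seeded generator, pure numpy).
    """
    if graph.n_drugs() == 0 or graph.n_edges() == 0:
        raise ValidationError("cannot train on an empty interaction graph")
    a, ids = graph.adjacency()
    n = len(ids)
    rng = np.random.default_rng(cfg.seed)
    p = rng.normal(0.0, 0.1 / np.sqrt(cfg.k), size=(n, cfg.k))
    b = np.zeros(n, dtype=np.float64)
    mu = graph.density()
    mask = _loss_mask(a, cfg, rng)
    n_pairs = mask.sum() / 2.0  # each unordered pair appears twice in mask

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_p = np.zeros_like(p)
    v_p = np.zeros_like(p)
    m_b = np.zeros_like(b)
    v_b = np.zeros_like(b)

    for t in range(1, cfg.epochs + 1):
        raw = mu + b[:, None] + b[None, :] + p @ p.T
        err = (np.asarray(_sigmoid(raw)) - a) * mask / n_pairs  # symmetric, zero diag
        grad_p = err @ p + 2.0 * cfg.l2 * p
        grad_b = err.sum(axis=1) + 2.0 * cfg.l2 * b
        for g, m_s, v_s, theta in ((grad_p, m_p, v_p, p), (grad_b, m_b, v_b, b)):
            m_s *= beta1
            m_s += (1 - beta1) * g
            v_s *= beta2
            v_s += (1 - beta2) * g * g
            m_hat = m_s / (1 - beta1**t)
            v_hat = v_s / (1 - beta2**t)
            theta -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    return EmbeddingModel(ids, mu=mu, bias=b, factors=p, alpha=0.0, config=cfg)


def propagate(model: EmbeddingModel, graph: InteractionGraph, alpha: float) -> EmbeddingModel:
    """One latent-factor propagation pass over the interaction graph.

    p_i <- (1 - alpha) * p_i + alpha * mean_{j in N(i)} p_j, computed
    simultaneously from the pre-propagation factors. Biases and mu are
    unchanged. alpha = 0 returns the factors bit-for-bit; degree-0 drugs
    keep their factor at any alpha.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if alpha == 0.0:
        return EmbeddingModel(
            model.ids, model.mu, model.bias.copy(), model.factors.copy(), alpha=0.0,
            config=model.config,
        )
    old = model.factors
    new = old.copy()
    for row, drug_id in enumerate(model.ids):
        if drug_id not in graph.drugs:
            continue
        nbrs = graph.neighbors(drug_id)
        if not nbrs:
            continue
        idx = [model.index(x) for x in nbrs]
        new[row] = (1.0 - alpha) * old[row] + alpha * old[idx].mean(axis=0)
    return EmbeddingModel(model.ids, model.mu, model.bias.copy(), new, alpha=alpha, config=model.config)


def train_amfp(graph: InteractionGraph, cfg: TrainConfig) -> EmbeddingModel:
    """AMF training followed by one propagation pass with cfg.alpha."""
    model = train_amf(graph, cfg)
    return propagate(model, graph, cfg.alpha)


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Serialize to a single .npz archive; load_model round-trips exactly."""
    path = Path(path)
    cfg_json = json.dumps(model.config.to_dict()) if model.config is not None else ""
    np.savez(
        path,
        ids=np.array(model.ids, dtype=np.str_),
        mu=np.float64(model.mu),
        bias=model.bias,
        factors=model.factors,
        alpha=np.float64(model.alpha),
        config_json=np.str_(cfg_json),
    )


def load_model(path: str | Path) -> EmbeddingModel:
    with np.load(Path(path), allow_pickle=False) as z:
        ids = [str(x) for x in z["ids"]]
        cfg_json = str(z["config_json"])
        cfg = TrainConfig.from_dict(json.loads(cfg_json)) if cfg_json else None
        return EmbeddingModel(
            ids,
            mu=float(z["mu"]),
            bias=z["bias"].copy(),
            factors=z["factors"].copy(),
            alpha=float(z["alpha"]),
            config=cfg,
        )
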