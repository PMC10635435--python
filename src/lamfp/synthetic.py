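"""Synthetic drug sets, interaction networks and retrospective splits.

Emulates the shape of a curated DDI resource at desk scale: a few hundred
drugs with SMILES, a sparse symmetric interaction network, and — crucially
for the lookup mechanism — a statistical coupling between chemical
similarity and shared interaction partners. Drugs are generated in
structural families: each family has a prototype molecule (a linear
heteroalkane SMILES over the atoms C/N/O) and members are seeded point
mutations of the prototype (substitutions, insertions, deletions of single
atoms). Interactions are drawn from a family-pair propensity matrix with a
high within-family probability and low between-family probabilities, so
drugs that look alike also interact alike. Raising the mutation rate
towards 1 decouples string/fingerprint similarity from family membership
while leaving the interaction structure unchanged — the control condition
for testing that the lookup exploits chemistry rather than an artifact.

The retrospective split marks a seeded fraction of drugs as "new": all
pairs incident to a new drug (positive and negative) become test pairs and
every trace of those drugs is removed from the training graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from lamfp.data_model import (
    Drug,
    DrugSet,
    InteractionGraph,
    RetrospectiveSplit,
    ValidationError,
    filter_connected,
    normalize_pair,
)

_ATOMS = ("C", "N", "O")
_ATOM_WEIGHTS = (0.7, 0.15, 0.15)
_MIN_LEN = 4
_MAX_MUTATION_ATTEMPTS = 20


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults give ~200 drugs in 10 structural families with a mutation
    rate low enough that family members stay chemically recognizable,
    within-family interaction probability 0.6 against a between-family
    mean of 0.03 (overall positive density a few percent), and 20% of
    drugs held out as new for the retrospective split.
    """

    n_drugs: int = 200
    n_families: int = 10
    smiles_mutation_rate: float = 0.1
    within_family_edge_prob: float = 0.6
    between_family_edge_mean: float = 0.03
    fraction_new: float = 0.2
    prototype_min_len: int = 12
    prototype_max_len: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_drugs or self.n_families < 1:
            raise ValidationError("need 1 <= n_families <= n_drugs")
        for name in ("smiles_mutation_rate", "within_family_edge_prob", "fraction_new"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.fraction_new < 1.0:
            raise ValidationError(f"fraction_new must be in (0, 1), got {self.fraction_new}")
        if self.between_family_edge_mean < 0:
            raise ValidationError("between_family_edge_mean must be non-negative")
        if self.prototype_min_len < _MIN_LEN or self.prototype_max_len < self.prototype_min_len:
            raise ValidationError("invalid prototype length range")

    def to_dict(self) -> dict:
        return {
            "n_drugs": self.n_drugs,
            "n_families": self.n_families,
            "smiles_mutation_rate": self.smiles_mutation_rate,
            "within_family_edge_prob": self.within_family_edge_prob,
            "between_family_edge_mean": self.between_family_edge_mean,
            "fraction_new": self.fraction_new,
            "prototype_min_len": self.prototype_min_len,
            "prototype_max_len": self.prototype_max_len,
            "seed": self.seed,
        }


@dataclass
class SyntheticDrugs:
    """Generated drugs with their family memberships."""

    drugs: DrugSet
    family: dict[str, int]


def _random_atom(rng: np.random.Generator) -> str:
    return str(rng.choice(_ATOMS, p=_ATOM_WEIGHTS))


def _prototype(rng: np.random.Generator, cfg: SynthConfig) -> str:
    length = int(rng.integers(cfg.prototype_min_len, cfg.prototype_max_len + 1))
    return "".join(_random_atom(rng) for _ in range(length))


def _mutate(smiles: str, rate: float, rng: np.random.Generator, cfg: SynthConfig) -> str:
    out: list[str] = []
    for ch in smiles:
        if rng.random() >= rate:
            out.append(ch)
            continue
        op = int(rng.integers(3))  # 0: substitute, 1: insert, 2: delete
        if op == 0:
            out.append(_random_atom(rng))
        elif op == 1:
            out.append(_random_atom(rng))
            out.append(ch)
    # Length drift: per-character edits preserve the prototype's length in
    # expectation, and string length alone would keep family members
    # recognizable even when every character has been rewritten. With
    # probability `rate` the chain length is redrawn from the prototype
    # length distribution so that at rate -> 1 the molecule is independent
    # of its family, which is the contract of the decoupling dial.
    if rng.random() < rate:
        target = int(rng.integers(cfg.prototype_min_len, cfg.prototype_max_len + 1))
        while len(out) > max(target, _MIN_LEN):
            out.pop(int(rng.integers(len(out))))
        while len(out) < target:
            out.insert(int(rng.integers(len(out) + 1)), _random_atom(rng))
    while len(out) < _MIN_LEN:
        out.append(_random_atom(rng))
    return "".join(out)


def generate_drugs(cfg: SynthConfig) -> SyntheticDrugs:
    """Drugs as mutated copies of family prototypes; every SMILES parses."""
    rng = np.random.default_rng(cfg.seed)
    prototypes = [_prototype(rng, cfg) for _ in range(cfg.n_families)]
    width = max(4, len(str(cfg.n_drugs)))
    drugs: list[Drug] = []
    family: dict[str, int] = {}
    for i in range(cfg.n_drugs):
        fam = i % cfg.n_families
        drug_id = f"D{i + 1:0{width}d}"
        smiles = None
        for _ in range(_MAX_MUTATION_ATTEMPTS):
            candidate = _mutate(prototypes[fam], cfg.smiles_mutation_rate, rng, cfg)
            if Chem.MolFromSmiles(candidate) is not None:
                smiles = candidate
                break
        if smiles is None:
            raise ValidationError(
                f"could not generate a parseable SMILES for {drug_id} "
                f"after {_MAX_MUTATION_ATTEMPTS} attempts"
            )
        drugs.append(Drug(id=drug_id, smiles=smiles))
        family[drug_id] = fam
    return SyntheticDrugs(drugs=DrugSet(drugs), family=family)


def generate_interactions(synth: SyntheticDrugs, cfg: SynthConfig) -> InteractionGraph:
    """Sample edges from a symmetric family-pair propensity matrix.

    Within-family pairs interact with probability
    ``within_family_edge_prob``; each between-family pair of families gets
    a propensity drawn from an exponential with the configured mean
    (clipped to [0, 1]).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    f = cfg.n_families
    prop = np.zeros((f, f))
    for i in range(f):
        for j in range(i, f):
            if i == j:
                prop[i, j] = cfg.within_family_edge_prob
            else:
                prop[i, j] = prop[j, i] = min(
                    1.0, float(rng.exponential(cfg.between_family_edge_mean))
                )
    ids = synth.drugs.ids()
    edges: list[tuple[str, str]] = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            if rng.random() < prop[synth.family[a], synth.family[b]]:
                edges.append((a, b))
    return InteractionGraph(synth.drugs, edges)


def make_retrospective_split(
    synth: SyntheticDrugs, graph: InteractionGraph, cfg: SynthConfig
) -> RetrospectiveSplit:
    """Hold out a seeded fraction of drugs as new and export their pairs.

    Every pair (positive or negative) incident to a new drug becomes a
    labelled test pair; the training graph is the interaction network
    induced on the remaining drugs, restricted to drugs that keep at least
    one interaction.
    """
    ids = synth.drugs.ids()
    n_new = int(round(cfg.fraction_new * len(ids)))
    if n_new < 2:
        raise ValidationError("fraction_new * n_drugs must be at least 2")
    rng = np.random.default_rng(cfg.seed + 2)
    new_ids = frozenset(str(x) for x in rng.choice(ids, size=n_new, replace=False))
    known_ids = [i for i in ids if i not in new_ids]
    train_edges = [(a, b) for a, b in graph.sorted_edges() if a not in new_ids and b not in new_ids]
    train = filter_connected(InteractionGraph(synth.drugs.subset(known_ids), train_edges))
    if train.n_drugs() == 0 or train.n_edges() == 0:
        raise ValidationError("retrospective split left an empty training graph")
    test_pairs: list[tuple[str, str, int]] = []
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            if a in new_ids or b in new_ids:
                label = 1 if normalize_pair(a, b) in graph.edges else 0
                test_pairs.append((a, b, label))
    return RetrospectiveSplit(
        train=train,
        test_pairs=tuple(test_pairs),
        new_drugs=new_ids,
        drugs=synth.drugs,
    )


def generate_dataset(cfg: SynthConfig) -> tuple[SyntheticDrugs, InteractionGraph, RetrospectiveSplit]:
    """Convenience: drugs, interaction graph and retrospective split in one call."""
    synth = generate_drugs(cfg)
    graph = generate_interactions(synth, cfg)
    split = make_retrospective_split(synth, graph, cfg)
    return synth, graph, split
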