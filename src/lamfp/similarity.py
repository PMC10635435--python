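"""Drug-drug chemical similarity measures and the nearest-neighbour lookup.

Four measures, all symmetric with range [0, 1]:

* ``tanimoto`` — Tanimoto coefficient on 2048-bit Morgan fingerprints
  (radius 2, ECFP4-equivalent) of the parsed molecules. The only measure
  that needs a parseable SMILES; two distinct strings for the same molecule
  score 1.
* ``edit`` — 1 - levenshtein(s, t) / max(len(s), len(t)) on the raw SMILES.
* ``nlcs`` — len(LCS(s, t))^2 / (len(s) * len(t)), the normalized longest
  common subsequence.
* ``tf_cosine`` — cosine similarity of the character-frequency vectors of
  the two strings (order-invariant; depends only on the character multiset).

``nearest_neighbors`` returns the m most similar known drugs for a query,
with deterministic tie-breaking (score descending, then id ascending).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Callable

import edlib
import pandas as pd
from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from lamfp.data_model import Drug, DrugSet, ValidationError

RDLogger.DisableLog("rdApp.*")  # silence per-molecule parse warnings

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048

SimilarityFn = Callable[[Drug, Drug], float]


class SmilesParseError(ValueError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, drug: Drug):
        super().__init__(f"SMILES for drug {drug.id!r} is not parseable: {drug.smiles!r}")
        self.drug_id = drug.id


_morgan_generator = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
)
_fp_cache: dict[tuple[str, str], object] = {}


def morgan_fingerprint(drug: Drug):
    """2048-bit Morgan fingerprint of the parsed molecule (cached)."""
    key = (drug.id, drug.smiles)
    fp = _fp_cache.get(key)
    if fp is None:
        mol = Chem.MolFromSmiles(drug.smiles)
        if mol is None:
            raise SmilesParseError(drug)
        fp = _morgan_generator.GetFingerprint(mol)
        _fp_cache[key] = fp
    return fp


def tanimoto_similarity(a: Drug, b: Drug) -> float:
    fa, fb = morgan_fingerprint(a), morgan_fingerprint(b)
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        return 0.0  # no substructure evidence either way
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def levenshtein_distance(s: str, t: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if not s or not t:
        return max(len(s), len(t))
    return int(edlib.align(s, t, task="distance", mode="NW")["editDistance"])


def _require_smiles(*drugs: Drug) -> None:
    for d in drugs:
        if not d.smiles:
            raise ValidationError(f"drug {d.id!r} has an empty SMILES")


def edit_similarity(a: Drug, b: Drug) -> float:
    _require_smiles(a, b)
    s, t = a.smiles, b.smiles
    return 1.0 - levenshtein_distance(s, t) / max(len(s), len(t))


def lcs_length(s: str, t: str) -> int:
    """Length of the longest common (not necessarily contiguous) subsequence."""
    if not s or not t:
        return 0
    if len(t) < len(s):
        s, t = t, s
    prev = [0] * (len(s) + 1)
    for ch in t:
        cur = [0] * (len(s) + 1)
        for i, sc in enumerate(s, start=1):
            if sc == ch:
                cur[i] = prev[i - 1] + 1
            else:
                cur[i] = cur[i - 1] if cur[i - 1] >= prev[i] else prev[i]
        prev = cur
    return prev[-1]


def nlcs_similarity(a: Drug, b: Drug) -> float:
    _require_smiles(a, b)
    s, t = a.smiles, b.smiles
    return lcs_length(s, t) ** 2 / (len(s) * len(t))


def tf_cosine_similarity(a: Drug, b: Drug) -> float:
    _require_smiles(a, b)
    ca, cb = Counter(a.smiles), Counter(b.smiles)
    dot = sum(ca[ch] * cb[ch] for ch in ca.keys() & cb.keys())
    norm = sqrt(sum(v * v for v in ca.values())) * sqrt(sum(v * v for v in cb.values()))
    return min(1.0, dot / norm)  # clamp float round-off above 1


MEASURES: dict[str, SimilarityFn] = {
    "tanimoto": tanimoto_similarity,
    "edit": edit_similarity,
    "nlcs": nlcs_similarity,
    "tf_cosine": tf_cosine_similarity,
}

MEASURE_NAMES = tuple(MEASURES)


def get_measure(name: str) -> SimilarityFn:
    try:
        return MEASURES[name]
    except KeyError:
        raise ValidationError(
            f"unknown similarity measure {name!r}; expected one of {sorted(MEASURES)}"
        ) from None


@dataclass(frozen=True)
class NeighborList:
    """Ordered (drug id, similarity) entries for one query drug, length <= m."""

    query: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValidationError(f"neighbour list for {self.query!r} is not score-sorted")

    def __len__(self) -> int:
        return len(self.entries)


def nearest_neighbors(a: Drug, known: DrugSet, m: int, measure: SimilarityFn) -> NeighborList:
    """The m most similar known drugs to the query, descending by similarity.

    Returns fewer than m entries when the known set is smaller; the query
    itself is excluded if its id happens to be in the known set. Ties break
    on ascending drug id for determinism.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    candidates = [c for c in known.ids() if c != a.id]
    if not candidates:
        raise ValidationError(f"no known drugs to look up for query {a.id!r}")
    scored = [(c, measure(a, known[c])) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    return NeighborList(query=a.id, entries=tuple(scored[:m]))


def export_neighbor_table(
    queries: DrugSet,
    known: DrugSet,
    m: int,
    path: str | Path,
    measures: tuple[str, ...] = MEASURE_NAMES,
) -> None:
    """Audit export: (query_id, neighbor_id, measure, score) rows for each measure."""
    rows = []
    for name in measures:
        fn = get_measure(name)
        for q in queries.ids():
            for c, s in nearest_neighbors(queries[q], known, m, fn).entries:
                rows.append((q, c, name, s))
    pd.DataFrame(rows, columns=["query_id", "neighbor_id", "measure", "score"]).to_csv(
        Path(path), index=False
    )
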