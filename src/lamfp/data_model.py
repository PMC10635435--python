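"""Domain types and I/O for drug tables, interaction edge lists and predictions.

A drug is an identifier plus a SMILES string; the SMILES is kept verbatim
(not canonicalized) because the string-based similarity measures operate on
the raw text. The interaction network is a simple undirected graph over drug
identifiers with no self-loops; edges are stored as lexicographically
normalized unordered pairs so that iteration order is deterministic.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass(frozen=True)
class Drug:
    """A small molecule: unique identifier plus its SMILES string."""

    id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("drug id must be non-empty")
        if not self.smiles:
            raise ValidationError(f"drug {self.id!r} has an empty SMILES")


class DrugSet(Mapping[str, Drug]):
    """Immutable id -> Drug mapping with uniqueness enforced."""

    def __init__(self, drugs: Iterable[Drug]):
        table: dict[str, Drug] = {}
        for d in drugs:
            if d.id in table:
                raise ValidationError(f"duplicate drug id {d.id!r}")
            table[d.id] = d
        self._table = table

    def __getitem__(self, drug_id: str) -> Drug:
        return self._table[drug_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._table)

    def __len__(self) -> int:
        return len(self._table)

    def ids(self) -> list[str]:
        """Sorted drug identifiers."""
        return sorted(self._table)

    def drugs(self) -> list[Drug]:
        """Drugs in sorted-id order."""
        return [self._table[i] for i in self.ids()]

    def subset(self, ids: Iterable[str]) -> "DrugSet":
        return DrugSet(self._table[i] for i in ids)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"DrugSet({len(self)} drugs)"


@dataclass(frozen=True)
class ReadReport:
    """Summary of a drug-table read: how many records were kept or dropped."""

    n_read: int
    n_kept: int
    n_dropped: int
    dropped_ids: tuple[str, ...]


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair as (min, max); rejects self-pairs."""
    if a == b:
        raise ValidationError(f"self-pair for drug {a!r} is not allowed")
    return (a, b) if a < b else (b, a)


class InteractionGraph:
    """Undirected binary interaction network over a drug set.

    Edges are unordered id pairs; no self-loops. Supports adjacency-matrix
    export in a caller-supplied id order for the factorization step.
    """

    def __init__(self, drugs: DrugSet, edges: Iterable[tuple[str, str]]):
        edge_set: set[tuple[str, str]] = set()
        for a, b in edges:
            if a not in drugs or b not in drugs:
                missing = a if a not in drugs else b
                raise ValidationError(f"edge references unknown drug {missing!r}")
            edge_set.add(normalize_pair(a, b))
        self.drugs = drugs
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        nbrs: dict[str, set[str]] = {i: set() for i in drugs}
        for a, b in edge_set:
            nbrs[a].add(b)
            nbrs[b].add(a)
        self._neighbors = {i: tuple(sorted(s)) for i, s in nbrs.items()}

    def has_edge(self, a: str, b: str) -> bool:
        return normalize_pair(a, b) in self.edges

    def neighbors(self, drug_id: str) -> tuple[str, ...]:
        return self._neighbors[drug_id]

    def degree(self, drug_id: str) -> int:
        return len(self._neighbors[drug_id])

    def n_drugs(self) -> int:
        return len(self.drugs)

    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        """Fraction of 1-entries in the (zero-diagonal) adjacency matrix."""
        n = len(self.drugs)
        if n < 2:
            return 0.0
        return 2.0 * len(self.edges) / (n * n)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def adjacency(self, order: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Dense 0/1 adjacency matrix and the id order used for its rows."""
        ids = order if order is not None else self.drugs.ids()
        index = {d: i for i, d in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)), dtype=np.float64)
        for u, v in self.edges:
            i, j = index[u], index[v]
            a[i, j] = a[j, i] = 1.0
        return a, ids


@dataclass(frozen=True)
class RetrospectiveSplit:
    """Train graph over known drugs plus labelled test pairs and the new-drug set.

    Emulates a retrospective evaluation: the train graph is an earlier
    snapshot of the interaction network, the test pairs involve drugs that
    only appear later ("new" drugs with no training interactions).
    """

    train: InteractionGraph
    test_pairs: tuple[tuple[str, str, int], ...]
    new_drugs: frozenset[str]
    drugs: DrugSet

    def __post_init__(self) -> None:
        known = set(self.train.drugs)
        if known & self.new_drugs:
            overlap = sorted(known & self.new_drugs)[0]
            raise ValidationError(f"new drug {overlap!r} also appears in the train graph")
        for a, b, label in self.test_pairs:
            if label not in (0, 1):
                raise ValidationError(f"test pair ({a},{b}) has non-binary label {label!r}")
            if normalize_pair(a, b) in self.train.edges:
                raise ValidationError(f"test pair ({a},{b}) is also a train edge")
            for d in (a, b):
                if d not in self.drugs:
                    raise ValidationError(f"test pair references drug {d!r} with no SMILES record")

    @property
    def known_ids(self) -> frozenset[str]:
        return frozenset(self.train.drugs)


PATH_DIRECT = "direct"
PATH_ONE_NEW = "lookup_one_new"
PATH_TWO_NEW = "lookup_two_new"


@dataclass(frozen=True)
class PredictionRecord:
    """One scored drug pair with the prediction route that produced it."""

    drug_a: str
    drug_b: str
    score: float
    path: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1] for ({self.drug_a},{self.drug_b})")
        if self.path not in (PATH_DIRECT, PATH_ONE_NEW, PATH_TWO_NEW):
            raise ValidationError(f"unknown prediction path {self.path!r}")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_drug_table(path: str | Path) -> tuple[DrugSet, ReadReport]:
    """Read a delimited drug table with columns ``drug_id`` and ``smiles``.

    Records with an empty SMILES are dropped (and counted in the report);
    a duplicated identifier is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValidationError(f"drug table {path} is missing required column {col!r}")
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate drug id {dup.iloc[0]!r} in {path}")
    kept: list[Drug] = []
    dropped: list[str] = []
    for drug_id, smiles in zip(df["drug_id"], df["smiles"]):
        if smiles.strip() == "":
            dropped.append(drug_id)
        else:
            kept.append(Drug(id=drug_id, smiles=smiles))
    report = ReadReport(
        n_read=len(df), n_kept=len(kept), n_dropped=len(dropped), dropped_ids=tuple(dropped)
    )
    return DrugSet(kept), report


def write_drug_table(drugs: DrugSet, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"drug_id": drugs.ids(), "smiles": [drugs[i].smiles for i in drugs.ids()]})
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_edge_list(path: str | Path, drugs: DrugSet) -> InteractionGraph:
    """Read a two-column edge list; symmetric duplicates collapse to one edge."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"edge list {path} must have two columns")
    pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return InteractionGraph(drugs, pairs)


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    path = Path(path)
    edges = graph.sorted_edges()
    df = pd.DataFrame(edges, columns=["drug_a", "drug_b"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_test_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Read labelled test pairs: columns drug_a, drug_b, label (0/1)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("drug_a", "drug_b", "label"):
        if col not in df.columns:
            raise ValidationError(f"test pair file {path} is missing column {col!r}")
    out = []
    for a, b, lab in zip(df["drug_a"], df["drug_b"], df["label"]):
        out.append((a, b, int(lab)))
    return out


def write_test_pairs(pairs: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(list(pairs), columns=["drug_a", "drug_b", "label"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    path = Path(path)
    rows = [(r.drug_a, r.drug_b, r.score, r.path) for r in records]
    df = pd.DataFrame(rows, columns=["drug_a", "drug_b", "score", "path"])
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"drug_a": str, "drug_b": str})
    return [
        PredictionRecord(drug_a=r.drug_a, drug_b=r.drug_b, score=float(r.score), path=str(r.path))
        for r in df.itertuples(index=False)
    ]


def filter_connected(graph: InteractionGraph) -> InteractionGraph:
    """Keep only drugs with at least one interaction partner. Idempotent."""
    keep = [i for i in graph.drugs if graph.degree(i) >= 1]
    return InteractionGraph(graph.drugs.subset(keep), graph.edges)


def split_to_files(split: RetrospectiveSplit, out_dir: str | Path) -> dict[str, str]:
    """Write a retrospective split as the delimited files the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugs": str(out / "drugs.csv"),
        "train_edges": str(out / "train_edges.csv"),
        "test_pairs": str(out / "test_pairs.csv"),
        "split_report": str(out / "split_report.json"),
    }
    write_drug_table(split.drugs, paths["drugs"])
    write_edge_list(split.train, paths["train_edges"])
    write_test_pairs(split.test_pairs, paths["test_pairs"])
    labels = [lab for _, _, lab in split.test_pairs]
    report = {
        "n_drugs": len(split.drugs),
        "n_known": len(split.train.drugs),
        "n_new": len(split.new_drugs),
        "new_drugs": sorted(split.new_drugs),
        "n_train_edges": split.train.n_edges(),
        "n_test_pairs": len(split.test_pairs),
        "n_test_positive": int(sum(labels)),
        "fraction_new": len(split.new_drugs) / max(len(split.drugs), 1),
    }
    Path(paths["split_report"]).write_text(json.dumps(report, indent=2))
    return paths
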