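"""Probabilistic knowledge graph construction.

A heterogeneous graph over typed biological entities (drugs, proteins,
diseases, side effects) in which every edge carries a probability.  Edges of
the literature-supported relation types get ``sigmoid(count + alpha)`` where
``count`` is the number of documents mentioning both endpoints; dense
similarity relations carry the similarity score itself; all other observed
edges carry probability 1; unobserved pairs carry 0.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "EntityCatalog",
    "RelationSpec",
    "CooccurrenceMatrix",
    "ProbAdjacency",
    "ProbKG",
    "sigmoid",
    "edge_probability",
    "load_networks",
    "assign_edge_probabilities",
    "mask_entries",
    "save_probkg",
    "load_probkg",
]


_BELOW_ONE = float(np.nextafter(1.0, 0.0))


def sigmoid(x):
    """Numerically stable logistic function ``1 / (1 + exp(-x))``."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


class EntityCatalog:
    """Ordered identifier lists per entity type, with optional text synonyms.

    Parameters
    ----------
    entities
        Mapping from entity type (e.g. ``"drug"``) to an ordered sequence of
        unique identifiers.
    synonyms
        Optional mapping ``type -> identifier -> list of synonyms`` used for
        literature matching.  Every synonym must be a non-empty string.
    """

    def __init__(
        self,
        entities: Mapping[str, Sequence[str]],
        synonyms: Optional[Mapping[str, Mapping[str, Sequence[str]]]] = None,
    ):
        self.entities: dict[str, list[str]] = {}
        self._index: dict[str, dict[str, int]] = {}
        for etype, ids in entities.items():
            ids = list(ids)
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate identifiers in entity type {etype!r}")
            self.entities[etype] = ids
            self._index[etype] = {eid: i for i, eid in enumerate(ids)}
        self.synonyms: dict[str, dict[str, list[str]]] = {}
        if synonyms:
            for etype, table in synonyms.items():
                if etype not in self.entities:
                    raise KeyError(f"synonyms given for unknown entity type {etype!r}")
                clean: dict[str, list[str]] = {}
                for eid, names in table.items():
                    if eid not in self._index[etype]:
                        raise KeyError(f"synonym for uncatalogued entity {eid!r}")
                    names = list(names)
                    if any((not isinstance(n, str)) or n == "" for n in names):
                        raise ValueError(f"empty synonym for entity {eid!r}")
                    clean[eid] = names
                self.synonyms[etype] = clean

    def size(self, etype: str) -> int:
        return len(self.entities[etype])

    def index(self, etype: str, eid: str) -> int:
        try:
            return self._index[etype][eid]
        except KeyError:
            raise KeyError(f"unknown {etype} identifier {eid!r}") from None

    def identifier(self, etype: str, idx: int) -> str:
        return self.entities[etype][idx]

    @property
    def types(self) -> list[str]:
        return list(self.entities)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EntityCatalog)
            and self.entities == other.entities
            and self.synonyms == other.synonyms
        )


@dataclass(frozen=True)
class RelationSpec:
    """A relation type: endpoint entity types plus membership flags.

    ``in_similarity_set`` marks the two dense similarity relations (R_s);
    ``in_literature_set`` marks relations whose edge probabilities and loss
    weights incorporate literature co-occurrence counts (R_c).
    """

    name: str
    source_type: str
    target_type: str
    in_similarity_set: bool = False
    in_literature_set: bool = False
    symmetric: bool = False

    def __post_init__(self):
        if self.in_similarity_set:
            if self.source_type != self.target_type or not self.symmetric:
                raise ValueError(
                    f"similarity relation {self.name!r} must be symmetric with "
                    "identical endpoint types"
                )
            if self.in_literature_set:
                raise ValueError(
                    f"{self.name!r} cannot be in both the similarity and the "
                    "literature set"
                )
        if self.symmetric and self.source_type != self.target_type:
            raise ValueError(f"symmetric relation {self.name!r} must join one type")


@dataclass
class CooccurrenceMatrix:
    """Non-negative integer document co-occurrence counts for one relation."""

    spec: RelationSpec
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("co-occurrence counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("co-occurrence counts must be non-negative")


@dataclass
class ProbAdjacency:
    """Edge probabilities for one relation.

    ``observed`` flags the pairs present in the input networks (for similarity
    relations every pair is observed — the subgraph is fully connected).
    ``probs`` is 0 wherever ``observed`` is False.
    """

    spec: RelationSpec
    probs: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.probs.shape != self.observed.shape:
            raise ValueError("probs/observed shape mismatch")

    def validate(self) -> None:
        if np.any(self.probs < 0) or np.any(self.probs > 1):
            raise ValueError(f"{self.spec.name}: probabilities outside [0, 1]")
        if np.any(self.probs[~self.observed] != 0):
            raise ValueError(f"{self.spec.name}: nonzero probability at unobserved pair")
        if self.spec.symmetric:
            if not np.array_equal(self.probs, self.probs.T):
                raise ValueError(f"{self.spec.name}: symmetric relation not symmetric")
        if self.spec.in_similarity_set:
            if not np.all(np.diag(self.probs) == 1.0):
                raise ValueError(f"{self.spec.name}: similarity diagonal must be 1")


@dataclass
class ProbKG:
    """The probabilistic knowledge graph.

    Holds the entity catalog, the relation specifications, one probability
    grid per relation, co-occurrence counts for the literature relations, the
    two evidence hyperparameters, and (after :func:`mask_entries`) a per-
    relation boolean mask of entries excluded from the training loss.
    """

    catalog: EntityCatalog
    specs: list[RelationSpec]
    adjacency: dict[str, ProbAdjacency]
    cooccurrence: dict[str, CooccurrenceMatrix] = field(default_factory=dict)
    alpha: float = 0.0
    beta: float = 0.0
    loss_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate relation names")
        for s in self.specs:
            for t in (s.source_type, s.target_type):
                if t not in self.catalog.entities:
                    raise ValueError(f"relation {s.name!r} references unknown type {t!r}")
            shape = self.shape_of(s)
            adj = self.adjacency.get(s.name)
            if adj is None:
                raise ValueError(f"missing adjacency for relation {s.name!r}")
            if adj.probs.shape != shape:
                raise ValueError(f"{s.name}: adjacency shape {adj.probs.shape} != {shape}")
            if s.name in self.cooccurrence:
                if self.cooccurrence[s.name].counts.shape != shape:
                    raise ValueError(f"{s.name}: co-occurrence shape mismatch")
            if s.name in self.loss_mask and self.loss_mask[s.name].shape != shape:
                raise ValueError(f"{s.name}: loss mask shape mismatch")

    def shape_of(self, spec: RelationSpec) -> tuple[int, int]:
        return (self.catalog.size(spec.source_type), self.catalog.size(spec.target_type))

    def spec_by_name(self, name: str) -> RelationSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(f"unknown relation {name!r}")

    @property
    def tda_name(self) -> str:
        """Name of the protein-disease association relation (the prediction task)."""
        cands = [
            s.name
            for s in self.specs
            if {s.source_type, s.target_type} == {"protein", "disease"}
            and not s.in_similarity_set
        ]
        if len(cands) != 1:
            raise ValueError(
                f"expected exactly one protein-disease relation, found {cands}"
            )
        return cands[0]

    def mask_of(self, name: str) -> np.ndarray:
        """Loss-exclusion mask for a relation (all-False if never masked)."""
        if name in self.loss_mask:
            return self.loss_mask[name]
        return np.zeros(self.shape_of(self.spec_by_name(name)), dtype=bool)

    def validate(self) -> None:
        for adj in self.adjacency.values():
            adj.validate()


def edge_probability(
    count: int,
    observed: bool,
    spec: RelationSpec,
    alpha: float,
    similarity_value: Optional[float] = None,
) -> float:
    """Probability of a single edge.

    Unobserved pairs get 0.  Observed similarity edges carry the similarity
    score; observed literature-set edges get ``sigmoid(count + alpha)``; every
    other observed edge gets 1.
    """
    if count < 0:
        raise ValueError("co-occurrence count must be non-negative")
    if not observed:
        return 0.0
    if spec.in_similarity_set:
        if similarity_value is None:
            raise ValueError(
                f"similarity relation {spec.name!r} requires a similarity value"
            )
        return float(similarity_value)
    if spec.in_literature_set:
        # clamp below 1: sigmoid rounds to 1.0 in float64 for large counts,
        # which would break the [sigmoid(alpha), 1) range contract
        return min(float(sigmoid(float(count) + alpha)), _BELOW_ONE)
    return 1.0


def load_networks(
    edge_files: Mapping[str, str | os.PathLike],
    catalog: EntityCatalog,
    specs: Sequence[RelationSpec],
) -> ProbKG:
    """Read per-relation TSV edge lists into a :class:`ProbKG`.

    Each file has a header ``source<TAB>target[<TAB>value]``; the value column
    is required for similarity relations (a score in [0, 1]) and ignored
    otherwise.  Duplicate edges are deduplicated; symmetric relations are
    symmetrized (an edge present in either orientation sets both entries;
    conflicting similarity values keep the maximum).  The returned graph has
    binary association adjacencies and no co-occurrence counts — feed it to
    :func:`assign_edge_probabilities` next.
    """
    specs = list(specs)
    by_name = {s.name: s for s in specs}
    for name in edge_files:
        if name not in by_name:
            raise KeyError(f"edge file given for unknown relation {name!r}")
    adjacency: dict[str, ProbAdjacency] = {}
    for spec in specs:
        n_a = catalog.size(spec.source_type)
        n_b = catalog.size(spec.target_type)
        probs = np.zeros((n_a, n_b))
        observed = np.zeros((n_a, n_b), dtype=bool)
        path = edge_files.get(spec.name)
        if path is not None:
            _read_edges(path, spec, catalog, probs, observed)
        if spec.in_similarity_set:
            np.fill_diagonal(probs, 1.0)
            observed[:] = True  # fully-connected subgraph
        adjacency[spec.name] = ProbAdjacency(spec, probs, observed)
    return ProbKG(catalog=catalog, specs=specs, adjacency=adjacency)


def _read_edges(path, spec, catalog, probs, observed) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 2 or cols[0] != "source" or cols[1] != "target":
            raise ValueError(f"{path}: expected header 'source\\ttarget[\\tvalue]'")
        has_value = len(cols) >= 3
        if spec.in_similarity_set and not has_value:
            raise ValueError(
                f"{path}: similarity relation {spec.name!r} needs a value column"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed line {line!r}")
            try:
                i = catalog.index(spec.source_type, parts[0])
                j = catalog.index(spec.target_type, parts[1])
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: {exc.args[0]}") from None
            if spec.in_similarity_set:
                value = float(parts[2])
                if not 0.0 <= value <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: similarity value {value} outside [0, 1]"
                    )
                # conflicting duplicates keep the maximum
                probs[i, j] = max(probs[i, j], value)
                probs[j, i] = max(probs[j, i], value)
            else:
                probs[i, j] = 1.0
                if spec.symmetric:
                    probs[j, i] = 1.0
            observed[i, j] = True
            if spec.symmetric:
                observed[j, i] = True


def assign_edge_probabilities(
    kg: ProbKG,
    cooccurrence: Mapping[str, CooccurrenceMatrix],
    alpha: Optional[float] = None,
) -> ProbKG:
    """Replace every observed entry with its evidence-weighted probability.

    Literature-set relations must appear in ``cooccurrence``.  Similarity
    grids are untouched (they already carry scores); plain association edges
    stay at 1; observed literature edges become ``sigmoid(count + alpha)``.
    Returns a new graph; the input is not modified.
    """
    if alpha is None:
        alpha = kg.alpha
    adjacency: dict[str, ProbAdjacency] = {}
    cooc: dict[str, CooccurrenceMatrix] = dict(kg.cooccurrence)
    for spec in kg.specs:
        adj = kg.adjacency[spec.name]
        if spec.in_literature_set:
            if spec.name not in cooccurrence:
                raise ValueError(
                    f"relation {spec.name!r} is in the literature set but has no "
                    "co-occurrence matrix"
                )
            cm = cooccurrence[spec.name]
            if cm.counts.shape != adj.probs.shape:
                raise ValueError(f"{spec.name}: co-occurrence shape mismatch")
            probs = np.where(
                adj.observed, np.minimum(sigmoid(cm.counts + alpha), _BELOW_ONE), 0.0
            )
            cooc[spec.name] = cm
            adjacency[spec.name] = ProbAdjacency(spec, probs, adj.observed.copy())
        elif spec.in_similarity_set:
            adjacency[spec.name] = ProbAdjacency(spec, adj.probs.copy(), adj.observed.copy())
        else:
            probs = np.where(adj.observed, 1.0, 0.0)
            adjacency[spec.name] = ProbAdjacency(spec, probs, adj.observed.copy())
    return replace(
        kg,
        adjacency=adjacency,
        cooccurrence=cooc,
        alpha=alpha,
        loss_mask={k: v.copy() for k, v in kg.loss_mask.items()},
    )


def mask_entries(
    kg: ProbKG,
    mask: Iterable[tuple[int, int]],
    relation: Optional[str] = None,
) -> ProbKG:
    """Zero out held-out entries of a relation and exclude them from the loss.

    For every ``(i, j)`` pair the probability, observed flag, and literature
    count are cleared so no evidence about the pair leaks into training; the
    returned graph records the pairs in ``loss_mask`` so the objective can
    give them weight 0.  Idempotent; other relations are untouched.
    """
    if relation is None:
        relation = kg.tda_name
    spec = kg.spec_by_name(relation)
    shape = kg.shape_of(spec)
    mask_grid = kg.mask_of(relation).copy()
    pairs = list(mask)
    for i, j in pairs:
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise IndexError(f"mask entry ({i}, {j}) out of range for shape {shape}")
        mask_grid[i, j] = True

    adj = kg.adjacency[relation]
    probs = adj.probs.copy()
    observed = adj.observed.copy()
    probs[mask_grid] = 0.0
    observed[mask_grid] = False

    adjacency = dict(kg.adjacency)
    adjacency[relation] = ProbAdjacency(spec, probs, observed)

    cooc = dict(kg.cooccurrence)
    if relation in cooc:
        counts = cooc[relation].counts.copy()
        counts[mask_grid] = 0
        cooc[relation] = CooccurrenceMatrix(spec, counts)

    loss_mask = {k: v.copy() for k, v in kg.loss_mask.items()}
    loss_mask[relation] = mask_grid
    return replace(kg, adjacency=adjacency, cooccurrence=cooc, loss_mask=loss_mask)


# ---------------------------------------------------------------------------
# serialization: directory of sparse-coordinate TSVs + a JSON manifest


def save_probkg(kg: ProbKG, directory: str | os.PathLike) -> None:
    """Write a graph as plain-text TSVs; round-trips bit-exactly."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "alpha": kg.alpha,
        "beta": kg.beta,
        "entity_types": {t: kg.catalog.entities[t] for t in kg.catalog.types},
        "relations": [
            {
                "name": s.name,
                "source_type": s.source_type,
                "target_type": s.target_type,
                "in_similarity_set": s.in_similarity_set,
                "in_literature_set": s.in_literature_set,
                "symmetric": s.symmetric,
            }
            for s in kg.specs
        ],
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    if kg.catalog.synonyms:
        with open(os.path.join(directory, "synonyms.tsv"), "w") as fh:
            fh.write("type\tid\tsynonym\n")
            for etype, table in kg.catalog.synonyms.items():
                for eid, names in table.items():
                    for name in names:
                        fh.write(f"{etype}\t{eid}\t{name}\n")
    for spec in kg.specs:
        adj = kg.adjacency[spec.name]
        with open(os.path.join(directory, f"{spec.name}.edges.tsv"), "w") as fh:
            fh.write("i\tj\tprob\n")
            for i, j in zip(*np.nonzero(adj.observed)):
                fh.write(f"{i}\t{j}\t{float(adj.probs[i, j])!r}\n")
        if spec.name in kg.cooccurrence:
            counts = kg.cooccurrence[spec.name].counts
            with open(os.path.join(directory, f"{spec.name}.counts.tsv"), "w") as fh:
                fh.write("i\tj\tcount\n")
                for i, j in zip(*np.nonzero(counts)):
                    fh.write(f"{i}\t{j}\t{counts[i, j]}\n")
        if spec.name in kg.loss_mask and kg.loss_mask[spec.name].any():
            with open(os.path.join(directory, f"{spec.name}.mask.tsv"), "w") as fh:
                fh.write("i\tj\n")
                for i, j in zip(*np.nonzero(kg.loss_mask[spec.name])):
                    fh.write(f"{i}\t{j}\n")


def load_probkg(directory: str | os.PathLike) -> ProbKG:
    directory = os.fspath(directory)
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    synonyms: dict[str, dict[str, list[str]]] = {}
    syn_path = os.path.join(directory, "synonyms.tsv")
    if os.path.exists(syn_path):
        with open(syn_path) as fh:
            fh.readline()
            for line in fh:
                etype, eid, name = line.rstrip("\n").split("\t")
                synonyms.setdefault(etype, {}).setdefault(eid, []).append(name)
    catalog = EntityCatalog(manifest["entity_types"], synonyms or None)
    specs = [RelationSpec(**r) for r in manifest["relations"]]
    adjacency: dict[str, ProbAdjacency] = {}
    cooccurrence: dict[str, CooccurrenceMatrix] = {}
    loss_mask: dict[str, np.ndarray] = {}
    for spec in specs:
        shape = (catalog.size(spec.source_type), catalog.size(spec.target_type))
        probs = np.zeros(shape)
        observed = np.zeros(shape, dtype=bool)
        with open(os.path.join(directory, f"{spec.name}.edges.tsv")) as fh:
            fh.readline()
            for line in fh:
                i, j, p = line.rstrip("\n").split("\t")
                probs[int(i), int(j)] = float(p)
                observed[int(i), int(j)] = True
        adjacency[spec.name] = ProbAdjacency(spec, probs, observed)
        cpath = os.path.join(directory, f"{spec.name}.counts.tsv")
        if os.path.exists(cpath):
            counts = np.zeros(shape, dtype=np.int64)
            with open(cpath) as fh:
                fh.readline()
                for line in fh:
                    i, j, c = line.rstrip("\n").split("\t")
                    counts[int(i), int(j)] = int(c)
            cooccurrence[spec.name] = CooccurrenceMatrix(spec, counts)
        mpath = os.path.join(directory, f"{spec.name}.mask.tsv")
        if os.path.exists(mpath):
            grid = np.zeros(shape, dtype=bool)
            with open(mpath) as fh:
                fh.readline()
                for line in fh:
                    i, j = line.rstrip("\n").split("\t")
                    grid[int(i), int(j)] = True
            loss_mask[spec.name] = grid
    return ProbKG(
        catalog=catalog,
        specs=specs,
        adjacency=adjacency,
        cooccurrence=cooccurrence,
        alpha=manifest["alpha"],
        beta=manifest["beta"],
        loss_mask=loss_mask,
    )
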