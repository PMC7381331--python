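"""Semantic pointers and similarity-structured vocabularies.

A semantic pointer (S-pointer) is a high-dimensional unit vector standing for
a cognitive item -- a concept, a lemma, a phonological form, a cue, or a task
control action.  Similarity between two items is the plain dot product of
their pointers.  Relations between items ("assoc_with") are realised
geometrically: a related pointer is drawn as a seeded mixture of fresh noise
and the (mean of its) parent vector(s), so that the expected dot product with
a single parent equals the mixing weight ``w`` and the expected dot product
between two children of the same parent equals ``w**2``.

All randomness flows through a single seeded generator per vocabulary;
regenerating a vocabulary with the same seed and insertion order reproduces
bit-identical vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPointer",
    "AssocRelation",
    "SPVocabulary",
    "similarity",
    "cleanup_lookup",
]


@dataclass(frozen=True)
class SPointer:
    """A labelled unit vector of the owning vocabulary's dimensionality."""

    label: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "vector", v)

    @property
    def dimension(self) -> int:
        return self.vector.shape[0]

    def __matmul__(self, other: "SPointer | np.ndarray") -> float:
        return similarity(self, other)


@dataclass(frozen=True)
class AssocRelation:
    """An ``assoc_with`` relation: ``child`` derived from ``parents``.

    ``weight`` is the similarity-injection weight in (0, 1): the expected dot
    product between the child and a single parent.
    """

    child: str
    parents: tuple[str, ...]
    weight: float
    kind: str = "assoc_with"

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError(
                f"relation weight must lie strictly in (0, 1), got {self.weight}"
            )
        object.__setattr__(self, "parents", tuple(self.parents))


def similarity(a: "SPointer | np.ndarray", b: "SPointer | np.ndarray") -> float:
    """Dot product between two pointers (or raw vectors of equal dimension)."""
    va = a.vector if isinstance(a, SPointer) else np.asarray(a, dtype=float)
    vb = b.vector if isinstance(b, SPointer) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    return float(va @ vb)


def cleanup_lookup(
    prototypes: "list[SPointer]",
    query: np.ndarray,
    threshold: float,
) -> str | None:
    """Label of the best-matching prototype, or ``None`` below threshold.

    Ties are broken in favour of the earliest-registered prototype
    (``np.argmax`` returns the first maximal index).
    """
    if not prototypes:
        raise ValueError("prototype set must be non-empty")
    q = query.vector if isinstance(query, SPointer) else np.asarray(query, dtype=float)
    sims = np.array([p.vector @ q for p in prototypes])
    best = int(np.argmax(sims))
    if sims[best] >= threshold:
        return prototypes[best].label
    return None


@dataclass
class SPVocabulary:
    """An insertion-ordered collection of S-pointers with assoc_with relations.

    Parameters
    ----------
    dimension:
        Pointer dimensionality ``D``.  The full model uses 64; tests use 16.
    seed:
        Seed of the vector stream.  Vectors depend only on the seed and the
        insertion order, never on labels or wall-clock state.
    """

    dimension: int
    seed: int = 0
    entries: dict[str, SPointer] = field(default_factory=dict, repr=False)
    relations: list[AssocRelation] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        self._rng = np.random.default_rng(self.seed)

    # -- construction ---------------------------------------------------

    def _fresh_unit(self) -> np.ndarray:
        v = self._rng.standard_normal(self.dimension)
        return v / np.linalg.norm(v)

    def create(self, label: str) -> SPointer:
        """Register a fresh, independent unit pointer under ``label``."""
        if label in self.entries:
            raise ValueError(f"duplicate label: {label!r}")
        p = SPointer(label, self._fresh_unit())
        self.entries[label] = p
        return p

    def derive(
        self, label: str, parents: "list[str] | tuple[str, ...]", weight: float
    ) -> SPointer:
        """Register a pointer related to ``parents`` with similarity ``weight``.

        The child is ``normalize(sqrt(1 - w^2) * u + w * pbar)`` with ``u`` a
        fresh unit vector and ``pbar`` the normalised mean of the parent
        vectors, so that E[child . parent] ~ w for a single parent.
        """
        rel = AssocRelation(child=label, parents=tuple(parents), weight=weight)
        if label in self.entries:
            raise ValueError(f"duplicate label: {label!r}")
        for parent in rel.parents:
            if parent not in self.entries:
                raise KeyError(f"missing parent: {parent!r}")
        pbar = np.mean([self.entries[p].vector for p in rel.parents], axis=0)
        pbar = pbar / np.linalg.norm(pbar)
        u = self._fresh_unit()
        w = rel.weight
        v = np.sqrt(1.0 - w * w) * u + w * pbar
        v = v / np.linalg.norm(v)
        p = SPointer(label, v)
        self.entries[label] = p
        self.relations.append(rel)
        return p

    # -- access ---------------------------------------------------------

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> SPointer:
        return self.entries[label]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    def matrix(self, labels: "list[str] | None" = None) -> np.ndarray:
        """Stacked pointer vectors, one row per label (insertion order)."""
        labels = self.labels if labels is None else labels
        if not labels:
            return np.zeros((0, self.dimension))
        return np.stack([self.entries[lb].vector for lb in labels])

    def similarity(self, a, b) -> float:
        va = self.entries[a] if isinstance(a, str) else a
        vb = self.entries[b] if isinstance(b, str) else b
        return similarity(va, vb)

    def cleanup(
        self,
        query: np.ndarray,
        threshold: float = 0.2,
        labels: "list[str] | None" = None,
    ) -> str | None:
        labels = self.labels if labels is None else labels
        return cleanup_lookup([self.entries[lb] for lb in labels], query, threshold)

    def neighbors(self, label: str) -> list[str]:
        """Labels related to ``label`` through any assoc_with relation."""
        out: list[str] = []
        for rel in self.relations:
            if rel.child == label:
                out.extend(p for p in rel.parents if p not in out)
            elif label in rel.parents and rel.child not in out:
                out.append(rel.child)
        return out

    # -- serialization ---------------------------------------------------

    def to_json(self, store_vectors: bool = False) -> str:
        doc = {
            "dimension": self.dimension,
            "seed": self.seed,
            "labels": self.labels,
            "derived": {
                rel.child: {"parents": list(rel.parents), "weight": rel.weight}
                for rel in self.relations
            },
        }
        if store_vectors:
            doc["vectors"] = {lb: p.vector.tolist() for lb, p in self.entries.items()}
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "SPVocabulary":
        doc = json.loads(text)
        vocab = cls(dimension=doc["dimension"], seed=doc["seed"])
        if "vectors" in doc:
            for lb in doc["labels"]:
                vocab.entries[lb] = SPointer(lb, np.asarray(doc["vectors"][lb]))
            for child, rel in doc["derived"].items():
                vocab.relations.append(
                    AssocRelation(child, tuple(rel["parents"]), rel["weight"])
                )
            return vocab
        for lb in doc["labels"]:
            if lb in doc["derived"]:
                rel = doc["derived"][lb]
                vocab.derive(lb, rel["parents"], rel["weight"])
            else:
                vocab.create(lb)
        return vocab
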