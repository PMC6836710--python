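"""Minimal RDF data model: terms, triples, graphs.

The model is deliberately small: IRIs, literals and blank nodes, immutable
triples, and a set-semantics graph.  It underpins the OBDA engine, the
orthology/VoIDext graph emitters and the federation layer, and is simple
enough that the naive query evaluator over it can be verified against
brute-force enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union


class RDFError(ValueError):
    """Invalid RDF term, triple or graph construction."""


@dataclass(frozen=True, slots=True)
class IRI:
    """An absolute IRI.

    Must contain a scheme separator (``:``) and no whitespace or angle
    brackets; relative IRIs are rejected because virtual links require
    globally stable identifiers.
    """

    value: str

    def __post_init__(self) -> None:
        v = self.value
        if ":" not in v:
            raise RDFError(f"relative IRI not allowed: {v!r}")
        if any(c.isspace() for c in v) or "<" in v or ">" in v:
            raise RDFError(f"IRI contains forbidden characters: {v!r}")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True, slots=True)
class Literal:
    """An RDF literal: lexical form plus optional datatype IRI or language tag.

    Equality is term equality: two literals are equal iff lexical form,
    datatype and language tag all coincide ("1" ^^xsd:integer != "1").
    """

    lexical: str
    datatype: Optional[IRI] = None
    lang: Optional[str] = None

    def __post_init__(self) -> None:
        if self.datatype is not None and self.lang is not None:
            raise RDFError("literal cannot carry both datatype and language tag")

    def __str__(self) -> str:
        return self.lexical


@dataclass(frozen=True, slots=True)
class BlankNode:
    """A document-scoped blank node with a local label."""

    label: str

    def __post_init__(self) -> None:
        if not self.label or any(c.isspace() for c in self.label):
            raise RDFError(f"invalid blank node label: {self.label!r}")

    def __str__(self) -> str:
        return f"_:{self.label}"


@dataclass(frozen=True, slots=True)
class Variable:
    """A named placeholder in a triple pattern (``?name``)."""

    name: str

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise RDFError(f"invalid variable name: {self.name!r}")

    def __str__(self) -> str:
        return f"?{self.name}"


Term = Union[IRI, Literal, BlankNode]
PatternTerm = Union[IRI, Literal, BlankNode, Variable]


@dataclass(frozen=True, slots=True)
class Triple:
    """A subject-predicate-object statement; the predicate is always an IRI."""

    subject: Term
    predicate: IRI
    object: Term

    def __post_init__(self) -> None:
        if isinstance(self.subject, Literal):
            raise RDFError("literal subjects are not allowed")
        if not isinstance(self.predicate, IRI):
            raise RDFError(f"predicate must be an IRI, got {self.predicate!r}")

    def __iter__(self) -> Iterator[Term]:
        return iter((self.subject, self.predicate, self.object))


@dataclass
class Graph:
    """A set of triples, optionally named.

    Set semantics: adding a duplicate triple leaves the cardinality
    unchanged.  Equality between graphs is triple-set equality (the name is
    ignored, matching RDF graph equality for ground graphs).
    """

    triples: set[Triple] = field(default_factory=set)
    name: Optional[IRI] = None

    def __init__(self, triples: Iterable[Triple] = (), name: Optional[IRI] = None):
        self.triples = set(triples)
        self.name = name

    def add(self, triple: Triple) -> None:
        self.triples.add(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        self.triples.update(triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self.triples == other.triples

    def __or__(self, other: "Graph") -> "Graph":
        return Graph(self.triples | other.triples)

    def subjects_of_type(self, cls: IRI, type_pred: IRI) -> set[Term]:
        return {t.subject for t in self.triples if t.predicate == type_pred and t.object == cls}
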