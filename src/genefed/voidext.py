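"""Virtual-link metadata: a VoID extension for federated join points.

A *virtual link* is an intersection data point between two datasets — a
class whose instance IRIs occur in both (shared-instance), or a pair of
predicates whose literal values coincide (literal-match, optionally modulo a
named transformation).  Declared links are the join contract of the
federation layer: a federated plan is only accepted where its stage joins
ride on an active link.

Link metadata round-trips through an RDF vocabulary that extends VoID with
a project-namespace ``voidext:`` vocabulary (link kind, cardinality,
status, transformation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Protocol, Sequence

from .evaluate import SolutionSet
from .sparql import Query, TriplePattern
from .terms import BlankNode, Graph, IRI, Literal, Term, Triple, Variable
from .vocab import A, LABEL, SCIENTIFIC_NAME, VOID, VOIDEXT, EX, XSD

ACTIVE = "active"
BROKEN = "broken"
UNVERIFIED = "unverified"

#: Literal-valued predicates compared during literal-match discovery.  The
#: comparison is restricted to label-like and identifier-like predicates to
#: avoid the quadratic, mostly-noise all-pairs scan.
DEFAULT_LITERAL_PREDICATES: tuple[IRI, ...] = (LABEL, SCIENTIFIC_NAME)


class VoidextError(ValueError):
    """Invalid virtual-link metadata."""


@dataclass(frozen=True)
class PredicateSignature:
    """Classes observed for a predicate's subjects/objects in one dataset."""

    subject_class: Optional[IRI] = None
    object_class: Optional[IRI] = None


@dataclass(frozen=True)
class DatasetDescription:
    id: IRI
    endpoint: str
    classes: frozenset[IRI]
    predicates: frozenset[IRI]
    signatures: Mapping[IRI, PredicateSignature] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.classes and not self.predicates:
            raise VoidextError(f"dataset {self.id} describes no classes or predicates")


@dataclass(frozen=True)
class VirtualLinkSet:
    id: IRI
    dataset_a: IRI
    dataset_b: IRI
    kind: str  # "shared-instance" | "literal-match"
    cls: Optional[IRI] = None
    predicate_a: Optional[IRI] = None
    predicate_b: Optional[IRI] = None
    transformation: Optional[str] = None
    cardinality: int = 0
    status: str = ACTIVE

    def __post_init__(self) -> None:
        if self.dataset_a == self.dataset_b:
            raise VoidextError("a virtual link must connect two distinct datasets")
        if self.kind == "shared-instance":
            if self.cls is None or self.predicate_a is not None or self.predicate_b is not None:
                raise VoidextError("shared-instance links name exactly one class")
        elif self.kind == "literal-match":
            if self.predicate_a is None or self.predicate_b is None or self.cls is not None:
                raise VoidextError("literal-match links name exactly two predicates")
        else:
            raise VoidextError(f"unknown link kind {self.kind!r}")
        if self.cardinality < 0:
            raise VoidextError("cardinality must be non-negative")
        if self.status not in (ACTIVE, BROKEN, UNVERIFIED):
            raise VoidextError(f"unknown status {self.status!r}")

    def datasets(self) -> frozenset[IRI]:
        return frozenset((self.dataset_a, self.dataset_b))


def _local(iri: IRI) -> str:
    value = iri.value
    for sep in ("#", "/"):
        if sep in value:
            value = value.rsplit(sep, 1)[1]
    return value or "x"


def describe_dataset(g: Graph, dataset_id: IRI, endpoint: str) -> DatasetDescription:
    """Summarize a materialized graph: classes, predicates and per-predicate
    subject/object classes (used by the planner's link-coverage check)."""
    classes = {t.object for t in g if t.predicate == A and isinstance(t.object, IRI)}
    predicates = {t.predicate for t in g}
    type_of: dict[Term, set[IRI]] = {}
    for t in g:
        if t.predicate == A and isinstance(t.object, IRI):
            type_of.setdefault(t.subject, set()).add(t.object)
    signatures: dict[IRI, PredicateSignature] = {}
    for pred in predicates:
        subj_classes: dict[IRI, int] = {}
        obj_classes: dict[IRI, int] = {}
        for t in g:
            if t.predicate != pred:
                continue
            for c in type_of.get(t.subject, ()):
                subj_classes[c] = subj_classes.get(c, 0) + 1
            for c in type_of.get(t.object, ()):
                obj_classes[c] = obj_classes.get(c, 0) + 1

        def best(counts: dict[IRI, int]) -> Optional[IRI]:
            if not counts:
                return None
            return max(sorted(counts, key=lambda c: c.value), key=lambda c: counts[c])

        sig = PredicateSignature(best(subj_classes), best(obj_classes))
        if sig.subject_class is not None or sig.object_class is not None:
            signatures[pred] = sig
    return DatasetDescription(
        id=dataset_id,
        endpoint=endpoint,
        classes=frozenset(classes),
        predicates=frozenset(predicates),
        signatures=signatures,
    )


def discover_links(
    g_a: Graph,
    g_b: Graph,
    dataset_a: IRI,
    dataset_b: IRI,
    literal_predicates: Sequence[IRI] = DEFAULT_LITERAL_PREDICATES,
) -> list[VirtualLinkSet]:
    """Find intersection data points between two materialized graphs.

    One shared-instance link per class with at least one IRI typed into it
    in both graphs (cardinality = number of shared instance IRIs; blank
    nodes are skipped, being document-scoped), and one literal-match link
    per candidate predicate pair sharing at least one identical literal.
    Discovered links start out ``active``.
    """
    links: list[VirtualLinkSet] = []
    pair = f"{_local(dataset_a)}-{_local(dataset_b)}"
    classes_a = {t.object for t in g_a if t.predicate == A and isinstance(t.object, IRI)}
    classes_b = {t.object for t in g_b if t.predicate == A and isinstance(t.object, IRI)}
    for cls in sorted(classes_a & classes_b, key=lambda c: c.value):
        inst_a = {t.subject for t in g_a if t.predicate == A and t.object == cls and isinstance(t.subject, IRI)}
        inst_b = {t.subject for t in g_b if t.predicate == A and t.object == cls and isinstance(t.subject, IRI)}
        shared = inst_a & inst_b
        if shared:
            links.append(
                VirtualLinkSet(
                    id=EX(f"link/si-{pair}-{_local(cls)}"),
                    dataset_a=dataset_a,
                    dataset_b=dataset_b,
                    kind="shared-instance",
                    cls=cls,
                    cardinality=len(shared),
                )
            )
    for pa in literal_predicates:
        vals_a = {t.object for t in g_a if t.predicate == pa and isinstance(t.object, Literal)}
        if not vals_a:
            continue
        for pb in literal_predicates:
            vals_b = {t.object for t in g_b if t.predicate == pb and isinstance(t.object, Literal)}
            shared_vals = vals_a & vals_b
            if shared_vals:
                links.append(
                    VirtualLinkSet(
                        id=EX(f"link/lm-{pair}-{_local(pa)}-{_local(pb)}"),
                        dataset_a=dataset_a,
                        dataset_b=dataset_b,
                        kind="literal-match",
                        predicate_a=pa,
                        predicate_b=pb,
                        cardinality=len(shared_vals),
                    )
                )
    return links


# --- RDF serialization ----------------------------------------------------

_KIND_IRI = {
    "shared-instance": VOIDEXT.SharedInstance,
    "literal-match": VOIDEXT.LiteralMatch,
}
_IRI_KIND = {v: k for k, v in _KIND_IRI.items()}


def serialize_voidext(
    links: Iterable[VirtualLinkSet],
    datasets: Iterable[DatasetDescription],
) -> Graph:
    """Emit the VoID/VoIDext metadata graph; inverse of :func:`parse_voidext`."""
    g = Graph()
    dataset_ids = set()
    for ds in datasets:
        dataset_ids.add(ds.id)
        g.add(Triple(ds.id, A, VOID.Dataset))
        g.add(Triple(ds.id, VOIDEXT.endpoint, Literal(ds.endpoint)))
        for cls in ds.classes:
            g.add(Triple(ds.id, VOID("class"), cls))
        for pred in ds.predicates:
            g.add(Triple(ds.id, VOID.property, pred))
        for i, pred in enumerate(sorted(ds.signatures, key=lambda p: p.value)):
            sig = ds.signatures[pred]
            if sig.subject_class is None and sig.object_class is None:
                continue
            node = IRI(f"{ds.id.value}#sig{i}")
            g.add(Triple(ds.id, VOIDEXT.propertySignature, node))
            g.add(Triple(node, VOIDEXT.aboutProperty, pred))
            if sig.subject_class is not None:
                g.add(Triple(node, VOIDEXT.subjectClass, sig.subject_class))
            if sig.object_class is not None:
                g.add(Triple(node, VOIDEXT.objectClass, sig.object_class))
    for link in links:
        for ref in (link.dataset_a, link.dataset_b):
            if ref not in dataset_ids:
                raise VoidextError(f"link {link.id} references unregistered dataset {ref}")
        g.add(Triple(link.id, A, VOIDEXT.VirtualLinkSet))
        g.add(Triple(link.id, VOIDEXT.kind, _KIND_IRI[link.kind]))
        g.add(Triple(link.id, VOIDEXT.datasetA, link.dataset_a))
        g.add(Triple(link.id, VOIDEXT.datasetB, link.dataset_b))
        g.add(Triple(link.id, VOIDEXT.cardinality, Literal(str(link.cardinality), datatype=XSD.integer)))
        g.add(Triple(link.id, VOIDEXT.status, Literal(link.status)))
        if link.cls is not None:
            g.add(Triple(link.id, VOIDEXT.sharedInstanceClass, link.cls))
        if link.predicate_a is not None:
            g.add(Triple(link.id, VOIDEXT.literalPredicateA, link.predicate_a))
        if link.predicate_b is not None:
            g.add(Triple(link.id, VOIDEXT.literalPredicateB, link.predicate_b))
        if link.transformation is not None:
            g.add(Triple(link.id, VOIDEXT.transformation, Literal(link.transformation)))
    return g


def _po(g: Graph, s: Term, p: IRI) -> list[Term]:
    return [t.object for t in g if t.subject == s and t.predicate == p]


def _one(g: Graph, s: Term, p: IRI, what: str) -> Term:
    values = _po(g, s, p)
    if len(values) != 1:
        raise VoidextError(f"{what}: expected exactly one {p.value}, found {len(values)}")
    return values[0]


def parse_voidext(g: Graph) -> tuple[list[DatasetDescription], list[VirtualLinkSet]]:
    """Read the metadata graph back into dataset and link descriptions."""
    datasets: list[DatasetDescription] = []
    for ds_id in sorted(g.subjects_of_type(VOID.Dataset, A), key=lambda t: str(t)):
        if not isinstance(ds_id, IRI):
            raise VoidextError("dataset ids must be IRIs")
        endpoint = _one(g, ds_id, VOIDEXT.endpoint, f"dataset {ds_id}")
        if not isinstance(endpoint, Literal):
            raise VoidextError(f"dataset {ds_id}: endpoint must be a literal")
        classes = frozenset(c for c in _po(g, ds_id, VOID("class")) if isinstance(c, IRI))
        predicates = frozenset(p for p in _po(g, ds_id, VOID.property) if isinstance(p, IRI))
        signatures: dict[IRI, PredicateSignature] = {}
        for node in _po(g, ds_id, VOIDEXT.propertySignature):
            pred = _one(g, node, VOIDEXT.aboutProperty, f"signature {node}")
            if not isinstance(pred, IRI):
                raise VoidextError("signature aboutProperty must be an IRI")
            subj = _po(g, node, VOIDEXT.subjectClass)
            obj = _po(g, node, VOIDEXT.objectClass)
            signatures[pred] = PredicateSignature(
                subject_class=subj[0] if subj else None,  # type: ignore[arg-type]
                object_class=obj[0] if obj else None,  # type: ignore[arg-type]
            )
        datasets.append(
            DatasetDescription(ds_id, endpoint.lexical, classes, predicates, signatures)
        )
    links: list[VirtualLinkSet] = []
    for link_id in sorted(g.subjects_of_type(VOIDEXT.VirtualLinkSet, A), key=lambda t: str(t)):
        if not isinstance(link_id, IRI):
            raise VoidextError("link ids must be IRIs")
        kind_terms = _po(g, link_id, VOIDEXT.kind)
        if not kind_terms:
            raise VoidextError(f"link {link_id} is missing its kind")
        kind_iri = kind_terms[0]
        if kind_iri not in _IRI_KIND:
            raise VoidextError(f"link {link_id}: unknown kind IRI {kind_iri}")
        kind = _IRI_KIND[kind_iri]  # type: ignore[index]
        card = _one(g, link_id, VOIDEXT.cardinality, f"link {link_id}")
        status = _one(g, link_id, VOIDEXT.status, f"link {link_id}")
        cls = _po(g, link_id, VOIDEXT.sharedInstanceClass)
        pa = _po(g, link_id, VOIDEXT.literalPredicateA)
        pb = _po(g, link_id, VOIDEXT.literalPredicateB)
        transform = _po(g, link_id, VOIDEXT.transformation)
        links.append(
            VirtualLinkSet(
                id=link_id,
                dataset_a=_one(g, link_id, VOIDEXT.datasetA, f"link {link_id}"),  # type: ignore[arg-type]
                dataset_b=_one(g, link_id, VOIDEXT.datasetB, f"link {link_id}"),  # type: ignore[arg-type]
                kind=kind,
                cls=cls[0] if cls else None,  # type: ignore[arg-type]
                predicate_a=pa[0] if pa else None,  # type: ignore[arg-type]
                predicate_b=pb[0] if pb else None,  # type: ignore[arg-type]
                transformation=transform[0].lexical if transform else None,  # type: ignore[union-attr]
                cardinality=int(str(card)),
                status=status.lexical if isinstance(status, Literal) else str(status),
            )
        )
    return datasets, links


# --- validation -----------------------------------------------------------


class AnswersQueries(Protocol):
    """Anything that answers service-free queries (a federation endpoint)."""

    def answer(self, q: Query) -> SolutionSet: ...


@dataclass(frozen=True)
class LinkReport:
    link: VirtualLinkSet
    cardinality_before: int
    cardinality_after: Optional[int]
    status: str


def _instances(endpoint: AnswersQueries, cls: IRI) -> set[Term]:
    x = Variable("x")
    q = Query(variables=(x,), bgp=(TriplePattern(x, A, cls),), distinct=True)
    return {sol[x] for sol in endpoint.answer(q) if not isinstance(sol.get(x), BlankNode)}


def _literal_values(endpoint: AnswersQueries, pred: IRI) -> set[Term]:
    s, v = Variable("s"), Variable("v")
    q = Query(variables=(v,), bgp=(TriplePattern(s, pred, v),), distinct=True)
    return {sol[v] for sol in endpoint.answer(q) if isinstance(sol.get(v), Literal)}


def validate_links(
    links: Iterable[VirtualLinkSet],
    endpoints: Mapping[IRI, AnswersQueries],
    datasets: Mapping[IRI, DatasetDescription],
) -> tuple[list[VirtualLinkSet], list[LinkReport]]:
    """Re-count every link's intersection against live endpoints.

    Zero intersection flips the link to ``broken``; a nonzero count
    refreshes the cardinality and keeps the link ``active`` (shrunk-but-
    nonzero is ordinary data evolution, not schema drift).  An unreachable
    endpoint marks its links ``unverified`` rather than broken.
    """
    refreshed: list[VirtualLinkSet] = []
    reports: list[LinkReport] = []
    for link in links:
        try:
            ep_a = endpoints[link.dataset_a]
            ep_b = endpoints[link.dataset_b]
            if link.kind == "shared-instance":
                assert link.cls is not None
                count = len(_instances(ep_a, link.cls) & _instances(ep_b, link.cls))
            else:
                assert link.predicate_a is not None and link.predicate_b is not None
                count = len(_literal_values(ep_a, link.predicate_a) & _literal_values(ep_b, link.predicate_b))
        except Exception:
            updated = replace(link, status=UNVERIFIED)
            refreshed.append(updated)
            reports.append(LinkReport(updated, link.cardinality, None, UNVERIFIED))
            continue
        status = ACTIVE if count > 0 else BROKEN
        updated = replace(link, cardinality=count if count > 0 else link.cardinality, status=status)
        refreshed.append(updated)
        reports.append(LinkReport(updated, link.cardinality, count, status))
    return refreshed, reports
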