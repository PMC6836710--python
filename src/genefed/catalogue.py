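"""The template catalogue: plain-English questions with editable slots.

Each template pairs a natural-language sentence with a SPARQL-subset query;
both carry the same named ``{slot}`` placeholders.  Rendering substitutes
escaped parameter values (literal slots are quote-escaped, IRI slots
validated) and attaches a default result limit unless disabled, then parses
the text — so a rendered template is always a structurally valid query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import yaml

from .sparql import Query, parse_query
from .terms import IRI, RDFError
from .vocab import PREFIXES

#: Attached to rendered queries unless the caller turns limiting off.
DEFAULT_RESULT_LIMIT = 1000

LITERAL_KINDS = {"gene_label", "keyword"}
IRI_KINDS = {"taxon", "anatomical_entity", "stage", "clade"}
SLOT_KINDS = LITERAL_KINDS | IRI_KINDS

_SLOT_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


class CatalogueError(ValueError):
    """Malformed catalogue document or template parameters."""


@dataclass(frozen=True)
class SlotSpec:
    name: str
    kind: str
    default: str

    def __post_init__(self) -> None:
        if self.kind not in SLOT_KINDS:
            raise CatalogueError(f"unknown slot kind {self.kind!r} for slot {self.name!r}")


@dataclass(frozen=True)
class QueryTemplate:
    id: str
    nl_text: str
    sparql_text: str
    slots: tuple[SlotSpec, ...]
    tags: tuple[str, ...] = ()
    group: Optional[str] = None
    cost: str = "fast"

    def slot_names(self) -> set[str]:
        return {s.name for s in self.slots}


def _used_slots(text: str) -> set[str]:
    return set(_SLOT_RE.findall(text))


def _escape_literal(value: str) -> str:
    return value.replace("\\", "\\\\").replace('"', '\\"')


def _validate_iri(value: str, slot: str) -> str:
    try:
        IRI(value)
    except RDFError as exc:
        raise CatalogueError(f"slot {slot!r} requires an IRI: {exc}") from exc
    return value


def render(
    template: QueryTemplate,
    params: Optional[Mapping[str, str]] = None,
    limit: Optional[int] = DEFAULT_RESULT_LIMIT,
    no_limit: bool = False,
) -> Query:
    """Instantiate a template; defaults fill unset slots.

    Literal-kind values are escaped into quoted literals (so a stray quote
    cannot change the query structure); IRI-kind values must be absolute
    IRIs.  ``limit`` is attached to the parsed query unless the template
    text carries its own LIMIT or ``no_limit`` is set.
    """
    params = dict(params or {})
    unknown = set(params) - template.slot_names()
    if unknown:
        raise CatalogueError(f"template {template.id}: unknown slot(s) {sorted(unknown)}")
    text = template.sparql_text
    for slot in template.slots:
        value = params.get(slot.name, slot.default)
        if slot.kind in LITERAL_KINDS:
            value = _escape_literal(value)
        else:
            value = _validate_iri(value, slot.name)
        text = text.replace("{" + slot.name + "}", value)
    q = parse_query(text, extra_prefixes=PREFIXES)
    if not no_limit and q.limit is None and limit is not None:
        q = q.with_limit(limit)
    if no_limit:
        q = q.with_limit(None)
    return q


def render_nl(template: QueryTemplate, params: Optional[Mapping[str, str]] = None) -> str:
    params = dict(params or {})
    text = template.nl_text
    for slot in template.slots:
        text = text.replace("{" + slot.name + "}", params.get(slot.name, slot.default))
    return text


def load_catalogue(doc: str) -> list[QueryTemplate]:
    """Parse a catalogue document and sanity-check every template.

    Errors name the template id: slot sets must coincide between the
    sentence and the query text, every declared slot must have a known
    kind, and the default rendering must parse.
    """
    data = yaml.safe_load(doc)
    if data is None:
        return []
    if not isinstance(data, dict) or "templates" not in data:
        raise CatalogueError("catalogue document must contain a 'templates' list")
    templates: list[QueryTemplate] = []
    seen: set[str] = set()
    for entry in data["templates"] or []:
        tid = str(entry.get("id", "?"))
        if tid in seen:
            raise CatalogueError(f"duplicate template id {tid!r}")
        seen.add(tid)
        try:
            slots = tuple(
                SlotSpec(str(s["name"]), str(s["kind"]), str(s["default"]))
                for s in entry.get("slots", [])
            )
        except KeyError as exc:
            raise CatalogueError(f"template {tid}: slot missing field {exc}") from exc
        template = QueryTemplate(
            id=tid,
            nl_text=str(entry["nl"]),
            sparql_text=str(entry["sparql"]),
            slots=slots,
            tags=tuple(str(t) for t in entry.get("tags", ())),
            group=entry.get("group"),
            cost=str(entry.get("cost", "fast")),
        )
        declared = template.slot_names()
        nl_used = _used_slots(template.nl_text)
        sparql_used = _used_slots(template.sparql_text)
        if nl_used != sparql_used:
            raise CatalogueError(
                f"template {tid}: slot mismatch between sentence ({sorted(nl_used)}) "
                f"and query ({sorted(sparql_used)})"
            )
        undeclared = sparql_used - declared
        if undeclared:
            raise CatalogueError(f"template {tid}: undeclared slot(s) {sorted(undeclared)}")
        render(template)  # defaults must produce a parseable query
        templates.append(template)
    return templates


def load_shipped_catalogue() -> list[QueryTemplate]:
    doc = resources.files("genefed.data").joinpath("catalogue.yaml").read_text(encoding="utf-8")
    return load_catalogue(doc)


def search_templates(catalogue: Sequence[QueryTemplate], keyword: str) -> list[QueryTemplate]:
    """Case-insensitive substring search over sentences and tags."""
    needle = keyword.lower()
    return [
        t for t in catalogue
        if needle in t.nl_text.lower() or any(needle in tag.lower() for tag in t.tags)
    ]
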