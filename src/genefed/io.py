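"""N-Triples and Turtle-subset reading; canonical N-Triples/Turtle writing.

The Turtle subset accepted on input covers prefix declarations (``@prefix``
or ``PREFIX``), the ``a`` keyword, and ``;``/``,`` predicate/object lists —
enough to read every file the package ships.  Canonical N-Triples output is
lexicographically sorted so that serializations are diff-stable and
byte-identical across runs.
"""

from __future__ import annotations

import re
from typing import Optional

from .terms import IRI, BlankNode, Graph, Literal, RDFError, Term, Triple
from .vocab import PREFIXES, RDF, XSD


class ParseError(ValueError):
    """Malformed RDF document; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


_TOKEN_RE = re.compile(
    r"""
      (?P<ws>\s+)
    | (?P<comment>\#[^\n]*)
    | (?P<iriref><[^<>"{}|^`\\\s]*>)
    | (?P<string>"(?:[^"\\\n]|\\.)*")
    | (?P<prefix_decl>@prefix|PREFIX\b)
    | (?P<langtag>@[a-zA-Z]+(?:-[a-zA-Z0-9]+)*)
    | (?P<dtype>\^\^)
    | (?P<blank>_:[A-Za-z0-9][A-Za-z0-9_.-]*)
    | (?P<pname>[A-Za-z][A-Za-z0-9_.-]*:[A-Za-z0-9][A-Za-z0-9_.%-]*)
    | (?P<a>a\b)
    | (?P<name>[A-Za-z][A-Za-z0-9_-]*)
    | (?P<number>[+-]?\d+(?:\.\d+)?)
    | (?P<punct>[.;,:])
    """,
    re.VERBOSE,
)

_STRING_ESCAPES = {
    "t": "\t",
    "n": "\n",
    "r": "\r",
    "b": "\b",
    "f": "\f",
    '"': '"',
    "'": "'",
    "\\": "\\",
}


def _unescape(raw: str, line: int) -> str:
    out: list[str] = []
    i = 0
    while i < len(raw):
        c = raw[i]
        if c != "\\":
            out.append(c)
            i += 1
            continue
        if i + 1 >= len(raw):
            raise ParseError("dangling escape in string", line)
        e = raw[i + 1]
        if e in _STRING_ESCAPES:
            out.append(_STRING_ESCAPES[e])
            i += 2
        elif e == "u":
            out.append(chr(int(raw[i + 2 : i + 6], 16)))
            i += 6
        elif e == "U":
            out.append(chr(int(raw[i + 2 : i + 10], 16)))
            i += 10
        else:
            raise ParseError(f"unknown string escape \\{e}", line)
    return "".join(out)


def _escape(s: str) -> str:
    out = []
    for c in s:
        if c == "\\":
            out.append("\\\\")
        elif c == '"':
            out.append('\\"')
        elif c == "\n":
            out.append("\\n")
        elif c == "\r":
            out.append("\\r")
        elif c == "\t":
            out.append("\\t")
        elif ord(c) < 0x20:  # other control characters break line canonicality
            out.append(f"\\u{ord(c):04X}")
        else:
            out.append(c)
    return "".join(out)


class _Tokenizer:
    def __init__(self, text: str):
        self.tokens: list[tuple[str, str, int]] = []  # (kind, value, line)
        line = 1
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None:
                raise ParseError(f"unexpected character {text[pos]!r}", line)
            kind = m.lastgroup or ""
            value = m.group()
            if kind not in ("ws", "comment"):
                self.tokens.append((kind, value, line))
            line += value.count("\n")
            pos = m.end()
        self.i = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            last_line = self.tokens[-1][2] if self.tokens else 1
            raise ParseError("unexpected end of input", last_line)
        self.i += 1
        return tok

    @property
    def line(self) -> int:
        tok = self.peek()
        if tok is not None:
            return tok[2]
        return self.tokens[-1][2] if self.tokens else 1


class _Parser:
    """Shared machinery for the N-Triples and Turtle-subset readers."""

    def __init__(self, text: str, allow_turtle: bool):
        self.tz = _Tokenizer(text)
        self.allow_turtle = allow_turtle
        self.prefixes: dict[str, str] = {}

    def _expand_pname(self, pname: str, line: int) -> IRI:
        prefix, _, local = pname.partition(":")
        if prefix not in self.prefixes:
            raise ParseError(f"unknown prefix {prefix!r}", line)
        return IRI(self.prefixes[prefix] + local)

    def _iri(self, raw: str, line: int) -> IRI:
        value = raw[1:-1]
        try:
            return IRI(value)
        except RDFError as exc:
            raise ParseError(str(exc), line) from None

    def term(self, position: str) -> Term:
        kind, value, line = self.tz.next()
        if kind == "iriref":
            return self._iri(value, line)
        if kind == "blank":
            return BlankNode(value[2:])
        if kind == "a" and self.allow_turtle and position == "predicate":
            return RDF.type
        if kind == "pname" and self.allow_turtle:
            return self._expand_pname(value, line)
        if position == "object":
            if kind == "string":
                lexical = _unescape(value[1:-1], line)
                nxt = self.tz.peek()
                if nxt and nxt[0] == "dtype":
                    self.tz.next()
                    dkind, dval, dline = self.tz.next()
                    if dkind == "iriref":
                        return Literal(lexical, datatype=self._iri(dval, dline))
                    if dkind == "pname" and self.allow_turtle:
                        return Literal(lexical, datatype=self._expand_pname(dval, dline))
                    raise ParseError("expected datatype IRI after ^^", dline)
                if nxt and nxt[0] == "langtag":
                    self.tz.next()
                    return Literal(lexical, lang=nxt[1][1:])
                return Literal(lexical)
            if kind == "number" and self.allow_turtle:
                dt = XSD.decimal if "." in value else XSD.integer
                return Literal(value, datatype=dt)
        raise ParseError(f"unexpected token {value!r} in {position} position", line)

    def expect_punct(self, char: str) -> None:
        kind, value, line = self.tz.next()
        if kind != "punct" or value != char:
            raise ParseError(f"expected {char!r}, got {value!r}", line)

    def make_triple(self, s: Term, p: Term, o: Term, line: int) -> Triple:
        try:
            if not isinstance(p, IRI):
                raise RDFError(f"predicate must be an IRI, got {p}")
            return Triple(s, p, o)
        except RDFError as exc:
            raise ParseError(str(exc), line) from None


def parse_ntriples(text: str) -> Graph:
    """Parse an N-Triples document into a :class:`Graph`.

    Raises :class:`ParseError` naming the offending line for malformed
    statements or relative IRIs.
    """
    parser = _Parser(text, allow_turtle=False)
    g = Graph()
    tz = parser.tz
    while tz.peek() is not None:
        line = tz.line
        s = parser.term("subject")
        p = parser.term("predicate")
        o = parser.term("object")
        parser.expect_punct(".")
        g.add(parser.make_triple(s, p, o, line))
    return g


def parse_turtle(text: str, extra_prefixes: Optional[dict[str, str]] = None) -> Graph:
    """Parse the supported Turtle subset into a :class:`Graph`.

    Supports ``@prefix``/``PREFIX`` declarations, prefixed names, ``a``,
    ``;``/``,`` lists, bare integers/decimals, and N-Triples-style terms.
    """
    parser = _Parser(text, allow_turtle=True)
    if extra_prefixes:
        parser.prefixes.update(extra_prefixes)
    g = Graph()
    tz = parser.tz
    while tz.peek() is not None:
        kind, value, line = tz.peek()  # type: ignore[misc]
        if kind == "prefix_decl":
            tz.next()
            nkind, label, nline = tz.next()
            if nkind != "name":
                raise ParseError("expected prefix label after prefix keyword", nline)
            parser.expect_punct(":")
            ikind, ival, iline = tz.next()
            if ikind != "iriref":
                raise ParseError("expected IRI in prefix declaration", iline)
            parser.prefixes[label] = ival[1:-1]
            if value == "@prefix":
                parser.expect_punct(".")
            continue
        s = parser.term("subject")
        while True:
            p = parser.term("predicate")
            while True:
                o = parser.term("object")
                g.add(parser.make_triple(s, p, o, line))
                nxt = tz.peek()
                if nxt and nxt[0] == "punct" and nxt[1] == ",":
                    tz.next()
                    continue
                break
            nxt = tz.peek()
            if nxt and nxt[0] == "punct" and nxt[1] == ";":
                tz.next()
                after = tz.peek()
                if after and after[0] == "punct" and after[1] == ".":
                    tz.next()
                    break
                continue
            parser.expect_punct(".")
            break
    return g


def _nt_term(term: Term) -> str:
    if isinstance(term, IRI):
        return f"<{term.value}>"
    if isinstance(term, BlankNode):
        return f"_:{term.label}"
    if isinstance(term, Literal):
        base = f'"{_escape(term.lexical)}"'
        if term.datatype is not None:
            return f"{base}^^<{term.datatype.value}>"
        if term.lang is not None:
            return f"{base}@{term.lang}"
        return base
    raise RDFError(f"cannot serialize {term!r}")


def _shrink(iri: IRI, prefixes: dict[str, str]) -> Optional[str]:
    for prefix, base in prefixes.items():
        if iri.value.startswith(base):
            local = iri.value[len(base):]
            if re.fullmatch(r"[A-Za-z0-9][A-Za-z0-9_.%-]*", local):
                return f"{prefix}:{local}"
    return None


def serialize_graph(g: Graph, format: str = "ntriples") -> str:
    """Serialize a graph; ``ntriples`` output is canonically sorted.

    The ``turtle`` format writes the shared prefix header and one statement
    per line with prefixed names where possible; it also sorts statements so
    both formats are deterministic.
    """
    if format == "ntriples":
        lines = sorted(
            f"{_nt_term(t.subject)} {_nt_term(t.predicate)} {_nt_term(t.object)} ."
            for t in g
        )
        return "".join(line + "\n" for line in lines)
    if format == "turtle":
        used: set[str] = set()

        def ttl_term(term: Term, position: str) -> str:
            if isinstance(term, IRI):
                if position == "predicate" and term == RDF.type:
                    return "a"
                short = _shrink(term, PREFIXES)
                if short is not None:
                    used.add(short.partition(":")[0])
                    return short
            return _nt_term(term)

        body = sorted(
            f"{ttl_term(t.subject, 's')} {ttl_term(t.predicate, 'predicate')} "
            f"{ttl_term(t.object, 'o')} ."
            for t in g
        )
        header = [f"@prefix {p}: <{PREFIXES[p]}> ." for p in sorted(used)]
        return "\n".join(header + [""] + body) + "\n"
    raise ValueError(f"unknown serialization format: {format!r}")
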