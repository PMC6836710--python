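"""Named value transformations used inside relational-to-RDF mappings.

Two transformations come from the source schemas themselves: anatomical
entity and stage identifiers arrive as CURIEs (``UBERON:0000955``) and must
be rewritten to ontology IRI local names (``UBERON_0000955``), and organism
rows carry separate genus/species columns that concatenate into the taxon
scientific name used as the cross-store literal join key.
"""

from __future__ import annotations

import re
from typing import Callable, Optional

from .terms import IRI, Literal
from .vocab import OBO

_CURIE_RE = re.compile(r"[A-Za-z][A-Za-z0-9]*:\d+$")


class TransformError(ValueError):
    """Invalid input to a named transformation."""


def curie_to_underscore(curie: str) -> str:
    """``UBERON:0000955`` -> ``UBERON_0000955`` (string level)."""
    if ":" not in curie:
        raise TransformError(f"not a CURIE (missing ':'): {curie!r}")
    if not _CURIE_RE.fullmatch(curie):
        raise TransformError(f"not a PREFIX:digits CURIE: {curie!r}")
    return curie.replace(":", "_", 1)


def underscore_to_curie(local: str) -> str:
    if "_" not in local:
        raise TransformError(f"not an underscore-form identifier: {local!r}")
    prefix, _, digits = local.partition("_")
    return f"{prefix}:{digits}"


def transform_uberon(curie: str, base: str = OBO.base) -> IRI:
    """Map an anatomical-entity (or stage) CURIE onto its ontology IRI.

    The colon is replaced by an underscore and the result appended to the
    ontology IRI base, so ``UBERON:0000955`` becomes
    ``.../UBERON_0000955``.
    """
    return IRI(base + curie_to_underscore(curie))


def transform_scientific_name(genus: str, species: str) -> Literal:
    """Concatenate genus and species into a scientific-name literal."""
    if not genus or not species:
        raise TransformError("genus and species must both be non-empty")
    return Literal(f"{genus} {species}")


# Registry of transformations available to {column|name} template
# placeholders.  Each entry maps a column value (string) to a string; the
# optional inverse lets the OBDA engine push query constants down to SQL.
TRANSFORMS: dict[str, Callable[[str], str]] = {
    "uberon": curie_to_underscore,
}

INVERSES: dict[str, Optional[Callable[[str], str]]] = {
    "uberon": underscore_to_curie,
}
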