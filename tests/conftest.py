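"""Shared fixtures: the default synthetic federation is built once."""

from __future__ import annotations

import pytest

from genefed.catalogue import load_shipped_catalogue, render
from genefed.fixtures import build_fixtures, worked_example
from genefed.ground_truth import compute_ground_truth, export_bgee_graph


@pytest.fixture(scope="session")
def fx():
    return build_fixtures()


@pytest.fixture(scope="session")
def catalogue():
    return load_shipped_catalogue()


@pytest.fixture(scope="session")
def rendered_queries(catalogue):
    return {t.id: render(t) for t in catalogue}


@pytest.fixture(scope="session")
def ground_truth(fx, rendered_queries):
    return compute_ground_truth(fx.conn, fx.orth_graph, fx.protein_graph, rendered_queries)


@pytest.fixture(scope="session")
def union_graph(fx):
    return export_bgee_graph(fx.conn) | fx.orth_graph | fx.protein_graph


@pytest.fixture(scope="session")
def we():
    return worked_example()
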