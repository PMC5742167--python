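"""Shared fixtures: tiny hand-built resources and one default synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from wordbeauty import BeautyDataset, FrequencyTable, GeneratorConfig, generate_study
from wordbeauty.resources import SemanticTaxonomy

import networkx as nx


def make_taxonomy(edges: list[tuple[str, str]], lemmas: dict[str, set[str]]) -> SemanticTaxonomy:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return SemanticTaxonomy(g, {w: set(n) for w, n in lemmas.items()})


@pytest.fixture
def chain_taxonomy() -> SemanticTaxonomy:
    """root -> a -> (b, c); lemmas at the two leaves and the root."""
    return make_taxonomy(
        [("a", "root"), ("b", "a"), ("c", "a")],
        {"wurzel": {"root"}, "blatt": {"b"}, "zweig": {"c"}},
    )


@pytest.fixture
def toy_freq() -> FrequencyTable:
    return FrequencyTable({"hand": 8, "band": 4, "hund": 2, "hang": 1, "hans": 1})


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (75/55 words), shared across tests."""
    return generate_study(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_study) -> BeautyDataset:
    return BeautyDataset.from_targets(default_study.dataset, default_study.feature_context())


# ---------------------------------------------------------------------------
# Independent oracles (never call the implementation under test)
# ---------------------------------------------------------------------------

def hamming_neighbor_count(word: str, lexicon: list[str]) -> int:
    """All-pairs scan: same length, exactly one substitution, self excluded."""
    n = 0
    for other in lexicon:
        if other == word or len(other) != len(word):
            continue
        if sum(a != b for a, b in zip(word, other)) == 1:
            n += 1
    return n


def concordant_pair_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of concordant positive/negative pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def bruteforce_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Direct sums-of-squares decomposition; returns (F, R2, R2_adj)."""
    grand = values.mean()
    ss_total = ((values - grand) ** 2).sum()
    ss_within = 0.0
    levels = sorted(set(groups.tolist()))
    for lev in levels:
        xi = values[groups == lev]
        ss_within += ((xi - xi.mean()) ** 2).sum()
    ss_between = ss_total - ss_within
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    f = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total
    return f, r2, 1 - (1 - r2) * (len(values) - 1) / df_w


def bfs_distance(edges: list[tuple[str, str]], src: str, dst: str) -> int:
    """Breadth-first shortest path on the undirected edge list."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    frontier, seen, d = {src}, {src}, 0
    while frontier:
        if dst in frontier:
            return d
        frontier = {n for u in frontier for n in adj.get(u, ()) if n not in seen}
        seen |= frontier
        d += 1
    raise AssertionError(f"no path {src}->{dst}")
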