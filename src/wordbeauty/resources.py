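"""Lexical resources: corpus frequency table, semantic taxonomy, coverage.

The study consumes two external resources: a word-frequency table standing
in for a large web corpus (source of surprisal and the lexicon used for
orthographic-neighborhood counts), and a wordnet-style ``is-a`` taxonomy
standing in for a lexical-semantic database (source of all relatedness-based
features).  Both are read from plain UTF-8 TSV files so that the pipeline is
self-contained; the real, license-restricted resources can be exported into
the same formats.

Word forms are normalized by lowercasing and stripping surrounding
whitespace; German umlauts and eszett are preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "FrequencyTable",
    "SemanticTaxonomy",
    "CoverageReport",
    "ResourceError",
    "normalize_word",
    "load_frequency_table",
    "load_taxonomy",
    "coverage",
    "intersect_targets",
]


class ResourceError(ValueError):
    """Raised when a resource file is malformed or a lookup cannot proceed."""


def normalize_word(word: str) -> str:
    """Lowercase and strip a word form, preserving umlauts and eszett."""
    return word.strip().lower()


def _data_rows(lines: Iterable[str]):
    """Yield (row_number, fields) for non-empty, non-comment TSV lines."""
    for i, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line.split("\t")


@dataclass(frozen=True)
class FrequencyTable:
    """Corpus word-frequency table: normalized word form -> token count."""

    entries: Mapping[str, int]
    total_tokens: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        total = sum(self.entries.values())
        if total <= 0:
            raise ResourceError("frequency table has zero total token count")
        object.__setattr__(self, "total_tokens", total)

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def count(self, word: str) -> int:
        return self.entries[normalize_word(word)]

    def words(self) -> list[str]:
        return list(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.entries):
                fh.write(f"{word}\t{self.entries[word]}\n")


def load_frequency_table(path: str | Path | io.TextIOBase) -> FrequencyTable:
    """Read a word<TAB>count TSV into a :class:`FrequencyTable`.

    Word forms are normalized and duplicate forms are summed (corpus dumps
    commonly split counts by capitalization).  Comment lines starting with
    ``#`` and blank lines are ignored.  A malformed or negative-count row
    rejects the whole file, naming the offending row.
    """
    if isinstance(path, io.TextIOBase):
        lines: Iterable[str] = path
        name = getattr(path, "name", "<stream>")
        opened = False
    else:
        lines = open(path, encoding="utf-8")
        name = str(path)
        opened = True
    entries: dict[str, int] = {}
    n_rows = 0
    try:
        for row_no, fields in _data_rows(lines):
            if len(fields) != 2:
                raise ResourceError(
                    f"{name}: row {row_no}: expected 2 tab-separated columns, got {len(fields)}"
                )
            word = normalize_word(fields[0])
            try:
                count = int(fields[1])
            except ValueError:
                raise ResourceError(
                    f"{name}: row {row_no}: count {fields[1]!r} is not an integer"
                ) from None
            if count < 0:
                raise ResourceError(f"{name}: row {row_no}: negative count {count}")
            if not word:
                raise ResourceError(f"{name}: row {row_no}: empty word form")
            entries[word] = entries.get(word, 0) + count
            n_rows += 1
    finally:
        if opened:
            lines.close()
    if n_rows == 0:
        raise ResourceError(f"{name}: file contains no data rows")
    return FrequencyTable(entries)


@dataclass
class SemanticTaxonomy:
    """Rooted is-a DAG of concept nodes with lemma attachments.

    ``graph`` stores directed child -> parent edges; ``lemma_index`` maps a
    normalized word form to the set of concept nodes it attaches to.  The
    root is the unique node without outgoing (child -> parent) edges, and
    ``depth`` is the eccentricity of the root in the undirected graph, used
    to normalize path-based relatedness.
    """

    graph: nx.DiGraph
    lemma_index: dict[str, set[str]]
    root: str = field(init=False)
    depth: int = field(init=False)

    def __post_init__(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise ResourceError("taxonomy has no nodes")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ResourceError(f"taxonomy contains a cycle: {cycle}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ResourceError(
                f"taxonomy must have exactly one root; found {len(roots)}: {sorted(roots)[:5]}"
            )
        self.root = roots[0]
        undirected = g.to_undirected(as_view=True)
        dist_from_root = nx.single_source_shortest_path_length(undirected, self.root)
        unreachable = set(g.nodes) - set(dist_from_root)
        if unreachable:
            raise ResourceError(
                f"{len(unreachable)} taxonomy nodes cannot reach the root, e.g. {sorted(unreachable)[:5]}"
            )
        for lemma, nodes in self.lemma_index.items():
            missing = nodes - set(g.nodes)
            if missing:
                raise ResourceError(f"lemma {lemma!r} attached to unknown nodes {sorted(missing)}")
        self.depth = max(dist_from_root.values()) if len(dist_from_root) > 1 else 1
        self._undirected = g.to_undirected()
        self._dist_cache: dict[str, dict[str, int]] = {}

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.lemma_index

    def nodes_of(self, word: str) -> set[str]:
        w = normalize_word(word)
        if w not in self.lemma_index:
            raise ResourceError(f"lemma {w!r} not in taxonomy")
        return self.lemma_index[w]

    def node_distances(self, node: str) -> dict[str, int]:
        """Shortest-path distances (in edges, undirected) from ``node``; memoized."""
        cached = self._dist_cache.get(node)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._undirected, node)
            self._dist_cache[node] = cached
        return cached

    def to_tsv(self, edge_path: str | Path, lemma_path: str | Path) -> None:
        with open(edge_path, "w", encoding="utf-8") as fh:
            for child, parent in sorted(self.graph.edges):
                fh.write(f"{child}\t{parent}\n")
        with open(lemma_path, "w", encoding="utf-8") as fh:
            for lemma in sorted(self.lemma_index):
                for node in sorted(self.lemma_index[lemma]):
                    fh.write(f"{lemma}\t{node}\n")


def load_taxonomy(path: str | Path, lemma_path: str | Path) -> SemanticTaxonomy:
    """Read a child<TAB>parent edge list and a lemma<TAB>node file.

    Validates that the edges form a DAG with a unique root in which every
    node reaches the root, and that every lemma attaches to a known node.
    """
    g = nx.DiGraph()
    with open(path, encoding="utf-8") as fh:
        for row_no, fields in _data_rows(fh):
            if len(fields) != 2:
                raise ResourceError(f"{path}: row {row_no}: expected child<TAB>parent")
            child, parent = fields[0].strip(), fields[1].strip()
            if not child or not parent:
                raise ResourceError(f"{path}: row {row_no}: empty node name")
            g.add_edge(child, parent)
    lemma_index: dict[str, set[str]] = {}
    with open(lemma_path, encoding="utf-8") as fh:
        for row_no, fields in _data_rows(fh):
            if len(fields) != 2:
                raise ResourceError(f"{lemma_path}: row {row_no}: expected lemma<TAB>node")
            lemma = normalize_word(fields[0])
            lemma_index.setdefault(lemma, set()).add(fields[1].strip())
    return SemanticTaxonomy(g, lemma_index)


@dataclass(frozen=True)
class CoverageReport:
    """Hit rate of a word list against a resource (fraction of targets found)."""

    n_targets: int
    n_hit: int
    missing: tuple[str, ...]

    @property
    def hit_rate(self) -> float:
        return self.n_hit / self.n_targets

    def __str__(self) -> str:
        return f"{self.n_hit}/{self.n_targets} targets covered (hit rate {self.hit_rate:.1%})"


def coverage(targets: Sequence[str], resource: FrequencyTable | SemanticTaxonomy) -> CoverageReport:
    """Hit rate of ``targets`` against a frequency table or taxonomy.

    Membership is tested on normalized word forms; ``missing`` preserves the
    input order of the uncovered targets.
    """
    if len(targets) == 0:
        raise ResourceError("coverage requires a non-empty target list")
    missing = tuple(t for t in targets if normalize_word(t) not in resource)
    return CoverageReport(len(targets), len(targets) - len(missing), missing)


def intersect_targets(
    targets: Sequence[tuple[str, object]],
    freq: FrequencyTable,
    tax: SemanticTaxonomy,
) -> tuple[list[tuple[str, object]], CoverageReport, CoverageReport]:
    """Keep labeled targets present in BOTH resources.

    Mirrors the study's resource-intersection step in which only target
    words covered by both the corpus and the taxonomy survive to the final
    analysis.  Returns the surviving ``(word, label)`` pairs (input order,
    labels retained) plus the per-resource coverage reports.
    """
    words = [w for w, _ in targets]
    cov_freq = coverage(words, freq)
    cov_tax = coverage(words, tax)
    survivors = [
        (normalize_word(w), lab)
        for w, lab in targets
        if normalize_word(w) in freq and normalize_word(w) in tax
    ]
    if not survivors:
        raise ResourceError(
            "no target word is present in both resources; "
            "check that the frequency table and taxonomy describe the same lexicon"
        )
    return survivors, cov_freq, cov_tax
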