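"""The eight quantitative-narrative-analysis (QNA) word features.

Two sublexical (syllable-based) features:

* ``n_syllables`` — number of syllables, counted as vowel groups after
  merging German diphthongs/digraphs (ei, ai, au, eu, äu, ie);
* ``sonority`` — mean sonority rank of the word's letters under a fixed
  German grapheme-class scale (plosives low, vowels high), a sublexical
  estimate of phonological euphony.

Six lexical features:

* ``length`` — number of letters;
* ``surprisal`` — information content in bits, −log2 of the word's relative
  corpus frequency;
* ``neighborhood_n`` — Coltheart's N: same-length lexicon entries differing
  by exactly one letter substitution;
* ``similarity`` — mean taxonomy-based semantic relatedness of the word to
  all other target words (label-blind);
* ``valence`` — signed relatedness contrast against a 36-label
  positive/negative set;
* ``ap`` — *aesthetic potential*, the same contrast against a 124-label
  aesthetic vocabulary.

Relatedness between two lemmas is a normalized inverse shortest-path length
over the is-a taxonomy (Leacock–Chodorow style), maximized over attachment
node pairs and rescaled to [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import pandas as pd

from .label_sets import LabelSetConfig, default_ap_labels, default_valence_labels
from .resources import FrequencyTable, SemanticTaxonomy, normalize_word

__all__ = [
    "FEATURE_NAMES",
    "SonorityScale",
    "FeatureVector",
    "FeatureContext",
    "FeatureError",
    "count_syllables",
    "sonority_score",
    "surprisal",
    "orthographic_n",
    "relatedness",
    "word_similarity",
    "label_score",
    "featurize",
    "featurize_dataset",
]

#: Canonical column order of the feature matrix.
FEATURE_NAMES = (
    "n_syllables",
    "sonority",
    "length",
    "surprisal",
    "neighborhood_n",
    "similarity",
    "valence",
    "ap",
)

VOWELS = frozenset("aeiouäöüy")

#: German diphthongs/digraphs merged into a single syllable nucleus.
DIPHTHONGS = ("äu", "ei", "ai", "au", "eu", "ie")


class FeatureError(ValueError):
    """Raised when a feature cannot be computed for a word."""


@dataclass(frozen=True)
class SonorityScale:
    """Per-letter sonority ranks via a grapheme-class table.

    Ranks must increase strictly from plosive to vowel, mirroring the
    sonority hierarchy (obstruents are least sonorous, vowels most).  The
    default German table assigns every letter of the extended alphabet
    (including umlauts and ß) to one of six classes.
    """

    ranks: dict[str, float] = field(
        default_factory=lambda: {
            "plosive": 1.0,
            "fricative": 2.0,
            "nasal": 3.0,
            "liquid": 4.0,
            "glide": 4.5,
            "vowel": 5.0,
        }
    )
    letter_classes: dict[str, str] = field(
        default_factory=lambda: {
            **{c: "plosive" for c in "bdgptkqc"},
            **{c: "fricative" for c in "fvwsßzhx"},
            **{c: "nasal" for c in "mn"},
            **{c: "liquid" for c in "lr"},
            "j": "glide",
            **{c: "vowel" for c in "aeiouäöüy"},
        }
    )

    def __post_init__(self) -> None:
        order = ["plosive", "fricative", "nasal", "liquid", "glide", "vowel"]
        present = [c for c in order if c in self.ranks]
        vals = [self.ranks[c] for c in present]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("sonority ranks must increase strictly from plosive to vowel")
        unknown = set(self.letter_classes.values()) - set(self.ranks)
        if unknown:
            raise ValueError(f"letter classes without a rank: {sorted(unknown)}")

    def rank_of(self, letter: str) -> float:
        cls = self.letter_classes.get(letter)
        if cls is None:
            raise FeatureError(f"letter {letter!r} has no sonority class")
        return self.ranks[cls]


DEFAULT_SONORITY_SCALE = SonorityScale()


def count_syllables(word: str, backend: Callable[[str], int] | None = None) -> int:
    """Number of syllables of ``word``.

    The default rule counts vowel groups: maximal runs of vowel letters,
    with German diphthongs/digraphs inside a run merged greedily from the
    left so that e.g. ``aue`` yields two nuclei (au + e) but ``ei`` one.
    A hyphenation-dictionary backend may be substituted via ``backend``.
    """
    w = normalize_word(word)
    if backend is not None:
        return backend(w)
    if not any(c in VOWELS for c in w):
        raise FeatureError(f"{w!r} contains no vowel letter; syllable count undefined")
    n = 0
    i = 0
    while i < len(w):
        if w[i] not in VOWELS:
            i += 1
            continue
        j = i
        while j < len(w) and w[j] in VOWELS:
            j += 1
        run = w[i:j]
        k = 0
        while k < len(run):
            if run[k : k + 2] in DIPHTHONGS:
                k += 2
            else:
                k += 1
            n += 1
        i = j
    return n


def sonority_score(word: str, scale: SonorityScale = DEFAULT_SONORITY_SCALE) -> float:
    """Mean sonority rank of the word's letters (composition over letters)."""
    w = normalize_word(word)
    if not w:
        raise FeatureError("empty word")
    return sum(scale.rank_of(c) for c in w) / len(w)


def surprisal(word: str, freq: FrequencyTable) -> float:
    """Information content in bits: −log2(count / total tokens)."""
    w = normalize_word(word)
    if w not in freq:
        raise FeatureError(f"{w!r} absent from frequency table; filter targets first")
    count = freq.count(w)
    if count < 1:
        raise FeatureError(f"{w!r} has zero count; surprisal undefined")
    return -math.log2(count / freq.total_tokens)


def orthographic_n(word: str, lexicon: FrequencyTable) -> int:
    """Coltheart's N: same-length lexicon words at Hamming distance exactly 1."""
    w = normalize_word(word)
    n = 0
    L = len(w)
    for other in lexicon.entries:
        if len(other) != L or other == w:
            continue
        mismatches = 0
        for a, b in zip(w, other):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        if mismatches == 1:
            n += 1
    return n


def _node_pair_distance(tax: SemanticTaxonomy, nodes1: set[str], nodes2: set[str]) -> int:
    """Minimum undirected shortest-path distance over attachment node pairs."""
    best = None
    # BFS from the smaller side; distances are memoized on the taxonomy.
    src, dst = (nodes1, nodes2) if len(nodes1) <= len(nodes2) else (nodes2, nodes1)
    for u in src:
        dists = tax.node_distances(u)
        for v in dst:
            d = dists.get(v)
            if d is not None and (best is None or d < best):
                best = d
    if best is None:  # cannot happen in a validated single-root taxonomy
        raise FeatureError("no path between attachment nodes")
    return best


def relatedness(
    w1: str,
    w2: str,
    tax: SemanticTaxonomy,
    measure: Literal["depth", "path"] = "depth",
) -> float:
    """Semantic relatedness of two lemmas in [0, 1].

    ``depth`` (default): 1 − d/(2·D) where d is the shortest undirected
    path length between the closest attachment nodes and D the taxonomy
    depth (clipped at 0) — a linearized Leacock–Chodorow measure.
    ``path``: 1/(1 + d).  Both are symmetric and equal 1 iff the lemmas
    share a node.
    """
    d = _node_pair_distance(tax, tax.nodes_of(w1), tax.nodes_of(w2))
    if measure == "depth":
        return max(0.0, 1.0 - d / (2.0 * tax.depth))
    if measure == "path":
        return 1.0 / (1.0 + d)
    raise ValueError(f"unknown relatedness measure {measure!r}")


def word_similarity(
    word: str,
    targets: Sequence[str],
    tax: SemanticTaxonomy,
    measure: Literal["depth", "path"] = "depth",
) -> float:
    """Mean relatedness of ``word`` to every *other* word in ``targets``.

    Label-blind by design: the mean runs over all other targets regardless
    of their beauty class, so the feature can serve as a classifier input.
    """
    w = normalize_word(word)
    norm_targets = [normalize_word(t) for t in targets]
    if w not in norm_targets:
        raise FeatureError(f"{w!r} is not among the targets")
    others = [t for t in norm_targets if t != w]
    if not others:
        raise FeatureError("similarity needs at least two distinct targets")
    return sum(relatedness(w, t, tax, measure) for t in others) / len(others)


def label_score(
    word: str,
    labels: LabelSetConfig,
    tax: SemanticTaxonomy,
    measure: Literal["depth", "path"] = "depth",
) -> float:
    """Signed relatedness contrast: mean(positive labels) − mean(negative).

    Labels not resolvable in the taxonomy are dropped with a warning; an
    empty pole after dropping is an error.  Swapping the poles flips the
    sign (antisymmetry).
    """
    w = normalize_word(word)
    sides = []
    for pole, pole_words in (("positive", labels.positive), ("negative", labels.negative)):
        resolved = [l for l in pole_words if l in tax]
        dropped = len(pole_words) - len(resolved)
        if dropped:
            warnings.warn(
                f"label set {labels.name!r}: {dropped} {pole} label(s) not in taxonomy, dropped",
                stacklevel=2,
            )
        if not resolved:
            raise FeatureError(
                f"label set {labels.name!r}: no {pole} label resolvable in the taxonomy"
            )
        sides.append(sum(relatedness(w, l, tax, measure) for l in resolved) / len(resolved))
    return sides[0] - sides[1]


@dataclass(frozen=True)
class FeatureVector:
    """The eight QNA features of one word, in canonical column order."""

    word: str
    n_syllables: int
    sonority: float
    length: int
    surprisal: float
    neighborhood_n: int
    similarity: float
    valence: float
    ap: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


@dataclass
class FeatureContext:
    """Everything needed to featurize a target word.

    Bundles the two resources, the two label-set configs, the full target
    list (for the similarity feature) and the tunable sublexical machinery.
    """

    freq: FrequencyTable
    tax: SemanticTaxonomy
    targets: Sequence[str]
    valence_labels: LabelSetConfig = field(default_factory=default_valence_labels)
    ap_labels: LabelSetConfig = field(default_factory=default_ap_labels)
    sonority_scale: SonorityScale = field(default_factory=SonorityScale)
    syllable_backend: Callable[[str], int] | None = None
    relatedness_measure: Literal["depth", "path"] = "depth"


def featurize(word: str, ctx: FeatureContext) -> FeatureVector:
    """Compute the full eight-feature vector for one target word.

    Deterministic given the resources and configs; sub-operation failures
    are re-raised with the word named.
    """
    w = normalize_word(word)
    try:
        return FeatureVector(
            word=w,
            n_syllables=count_syllables(w, ctx.syllable_backend),
            sonority=sonority_score(w, ctx.sonority_scale),
            length=len(w),
            surprisal=surprisal(w, ctx.freq),
            neighborhood_n=orthographic_n(w, ctx.freq),
            similarity=word_similarity(w, ctx.targets, ctx.tax, ctx.relatedness_measure),
            valence=label_score(w, ctx.valence_labels, ctx.tax, ctx.relatedness_measure),
            ap=label_score(w, ctx.ap_labels, ctx.tax, ctx.relatedness_measure),
        )
    except FeatureError as err:
        raise FeatureError(f"featurizing {w!r}: {err}") from err


def featurize_dataset(
    labeled_targets: Sequence[tuple[str, int]], ctx: FeatureContext
) -> pd.DataFrame:
    """Feature matrix for labeled targets: word index, 8 columns + ``label``."""
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        rows = [featurize(w, ctx) for w, _ in labeled_targets]
    df = pd.DataFrame([r.as_tuple() for r in rows], columns=list(FEATURE_NAMES))
    df.insert(0, "word", [r.word for r in rows])
    df["label"] = [lab for _, lab in labeled_targets]
    return df.set_index("word")
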