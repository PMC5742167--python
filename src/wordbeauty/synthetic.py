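"""Synthetic study generator: lexicon, frequencies, taxonomy, labeled words.

The real study rests on three license-restricted resources (a billion-token
web corpus, a German wordnet, a curated beautiful/ugly word list).  This
module generates stand-ins with the statistical structure the analysis
assumes, so the full pipeline runs and is testable without any downloads:

* **word forms** — pronounceable German-like strings built from alternating
  consonant/vowel clusters.  Each group's letter-class composition is solved
  analytically from its target mean sonority (the vowel share is fixed
  across groups; the consonant-class mixture absorbs the group difference),
  so the generated group sonority means land on the configured targets.
* **frequencies** — a Zipf rank-frequency law with configurable exponent,
  ranks assigned to words at random.
* **taxonomy** — a rooted tree with four affective hub subtrees (positive/
  negative aesthetic, positive/negative valence) plus a neutral region.
  Label lemmas attach inside their hub subtree; beautiful words attach near
  the positive-aesthetic hub and ugly words near the negative one, with an
  attachment-noise parameter controlling the effect size.  The noise is
  calibrated by bisection against the measured z-scored group separation of
  the aesthetic-potential feature.

Defaults encode the study conditions: 75 beautiful / 55 ugly words, target
AP z-means 0.25 vs −0.33 (separation 0.58), sonority means 3.12 vs 2.9,
mean word length 12 letters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .features import FeatureContext, label_score
from .label_sets import LabelSetConfig, default_ap_labels, default_valence_labels
from .resources import FrequencyTable, SemanticTaxonomy

__all__ = [
    "GeneratorConfig",
    "SyntheticStudy",
    "generate_word_forms",
    "generate_frequencies",
    "generate_taxonomy",
    "generate_study",
]

_MAX_SEED = 2**31 - 1

# Letter pools per sonority class (generation avoids the rarer letters
# q/c/x/ß/j; the scoring table still classifies them).
_VOWEL_LETTERS = tuple("aeiouäöü")
_VOWEL_WEIGHTS = np.array([0.23, 0.29, 0.16, 0.12, 0.10, 0.04, 0.03, 0.03])
_CLASS_LETTERS = {
    "plosive": tuple("bdgptk"),
    "fricative": tuple("fswvzh"),
    "nasal": tuple("mn"),
    "liquid": tuple("lr"),
}
_CLASS_RANKS = np.array([1.0, 2.0, 3.0, 4.0])  # plosive, fricative, nasal, liquid

# Consonant-class mixture family: linear interpolation between a plosive-
# heavy and a sonorant-heavy mixture; the interpolation weight is solved
# from the required consonant mean rank.
_MIX_LOW = np.array([0.70, 0.25, 0.05, 0.00])   # mean rank 1.35
_MIX_HIGH = np.array([0.15, 0.20, 0.25, 0.40])  # mean rank 2.90

#: Fixed vowel share of generated words (identical across groups so that a
#: sonority group difference never leaks into the syllable-count feature).
_VOWEL_SHARE = 0.37
#: Per-word jitter on the vowel share; decorrelates syllable count from
#: length so their squared correlation stays moderate (~0.5) as in corpora.
_VOWEL_SHARE_SD = 0.10


class GeneratorError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-generator parameters; defaults are the study conditions."""

    n_beautiful: int = 75
    n_ugly: int = 55
    lexicon_size: int = 1000
    zipf_exponent: float = 1.0
    taxonomy_depth: int = 6
    ap_effect: float = 0.58
    ap_noise: float | None = None
    sonority_means: tuple[float, float] = (3.12, 2.9)
    length_mean: float = 12.0
    length_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beautiful < 1 or self.n_ugly < 1:
            raise GeneratorError("group sizes must be positive")
        if self.lexicon_size < self.n_beautiful + self.n_ugly:
            raise GeneratorError(
                f"lexicon_size {self.lexicon_size} smaller than dataset "
                f"size {self.n_beautiful + self.n_ugly}"
            )
        if self.length_mean < 2:
            raise GeneratorError("length_mean must be at least 2 letters")
        if self.taxonomy_depth < 2:
            raise GeneratorError("taxonomy_depth must be at least 2")
        if self.zipf_exponent <= 0:
            raise GeneratorError("zipf_exponent must be positive")
        if not np.isfinite(self.ap_effect) or self.ap_effect < 0:
            raise GeneratorError("ap_effect must be a finite non-negative separation")
        if self.ap_noise is not None and not (0.0 <= self.ap_noise <= 1.0):
            raise GeneratorError("ap_noise must lie in [0, 1]")
        for t in self.sonority_means:
            _mixture_for_target(t)  # raises if infeasible

    @property
    def n_dataset(self) -> int:
        return self.n_beautiful + self.n_ugly


def _mixture_for_target(target_sonority: float) -> np.ndarray:
    """Consonant-class mixture whose letters yield the target word mean.

    With fixed vowel share p the word mean is 5p + c̄(1−p); solving for the
    consonant mean c̄ and interpolating within the mixture family gives the
    class probabilities.  Targets outside the family's reachable range are
    rejected as infeasible.
    """
    p = _VOWEL_SHARE
    c_mean = (target_sonority - 5.0 * p) / (1.0 - p)
    lo = float(_MIX_LOW @ _CLASS_RANKS)
    hi = float(_MIX_HIGH @ _CLASS_RANKS)
    t = (c_mean - lo) / (hi - lo)
    if not (0.0 <= t <= 1.0):
        raise GeneratorError(
            f"target sonority {target_sonority} infeasible: consonant mean rank "
            f"{c_mean:.2f} outside [{lo:.2f}, {hi:.2f}]"
        )
    return (1.0 - t) * _MIX_LOW + t * _MIX_HIGH


def _assemble(vowels: list[str], consonants: list[str], rng: np.random.Generator) -> str:
    """Interleave consonant clusters between vowel nuclei, pronounceably.

    Consonants are spread as evenly as possible over the nv+1 gaps around
    the vowels; onset clusters rise in sonority toward the nucleus and the
    final coda falls, following the sonority sequencing principle.
    """
    nv, nc = len(vowels), len(consonants)
    gaps = nv + 1
    sizes = np.full(gaps, nc // gaps)
    extra = rng.permutation(gaps)[: nc % gaps]
    sizes[extra] += 1
    rank = {
        c: float(_CLASS_RANKS[i])
        for i, letters in enumerate(_CLASS_LETTERS.values())
        for c in letters
    }
    pieces: list[str] = []
    pos = 0
    for i in range(gaps):
        cluster = consonants[pos : pos + sizes[i]]
        pos += sizes[i]
        cluster.sort(key=rank.__getitem__, reverse=(i == gaps - 1))
        pieces.append("".join(cluster))
        if i < nv:
            pieces.append(vowels[i])
    return "".join(pieces)


def _sample_word(
    mixture: np.ndarray,
    length_mean: float,
    length_sd: float,
    rng: np.random.Generator,
) -> str:
    length = int(np.clip(round(rng.normal(length_mean, length_sd)), 3, 28))
    share = float(np.clip(rng.normal(_VOWEL_SHARE, _VOWEL_SHARE_SD), 0.12, 0.65))
    # deterministic vowel count given the jittered share: the binomial noise
    # of per-letter draws would otherwise swamp the shared length signal and
    # push the length/syllable correlation far below its corpus-like level
    nv = int(np.clip(round(share * length), 1, length - 1))
    vowels = list(rng.choice(_VOWEL_LETTERS, size=nv, p=_VOWEL_WEIGHTS))
    classes = rng.choice(4, size=length - nv, p=mixture)
    consonants = [
        str(rng.choice(_CLASS_LETTERS[("plosive", "fricative", "nasal", "liquid")[c]]))
        for c in classes
    ]
    return _assemble([str(v) for v in vowels], consonants, rng)


@dataclass
class WordForms:
    """Generated lexicon, partitioned into the study groups and distractors."""

    beautiful: list[str]
    ugly: list[str]
    distractors: list[str]

    @property
    def all_words(self) -> list[str]:
        return self.beautiful + self.ugly + self.distractors


def generate_word_forms(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> WordForms:
    """Generate the unique synthetic lexicon.

    The two study groups use group-specific consonant mixtures solved from
    the configured sonority targets.  Distractors fill the lexicon to
    ``lexicon_size``; a fraction of them are single-letter substitutions of
    dataset words so the orthographic neighborhood feature has variance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    forbidden = set(default_ap_labels().positive + default_ap_labels().negative)
    forbidden |= set(default_valence_labels().positive + default_valence_labels().negative)
    seen: set[str] = set()

    def draw(mixture: np.ndarray, n: int) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            w = _sample_word(mixture, config.length_mean, config.length_sd, rng)
            if w not in seen and w not in forbidden:
                seen.add(w)
                out.append(w)
        return out

    mix_b = _mixture_for_target(config.sonority_means[0])
    mix_u = _mixture_for_target(config.sonority_means[1])
    beautiful = draw(mix_b, config.n_beautiful)
    ugly = draw(mix_u, config.n_ugly)

    dataset = beautiful + ugly
    n_extra = config.lexicon_size - len(dataset)
    mix_pool = 0.5 * (mix_b + mix_u)
    distractors: list[str] = []
    alphabet = _VOWEL_LETTERS + tuple(c for ls in _CLASS_LETTERS.values() for c in ls)
    while len(distractors) < n_extra:
        if rng.random() < 0.3 and dataset:
            # orthographic neighbor: one-letter substitution of a dataset word
            base = dataset[int(rng.integers(len(dataset)))]
            pos = int(rng.integers(len(base)))
            repl = str(rng.choice(alphabet))
            w = base[:pos] + repl + base[pos + 1 :]
            if w == base:
                continue
        else:
            w = _sample_word(mix_pool, config.length_mean, config.length_sd, rng)
        if w not in seen and w not in forbidden:
            seen.add(w)
            distractors.append(w)
    return WordForms(beautiful, ugly, distractors)


def generate_frequencies(
    words: list[str], config: GeneratorConfig, rng: np.random.Generator | None = None
) -> FrequencyTable:
    """Zipfian frequency table over ``words``.

    Rank r receives ``max(1, round(C / r^s))`` tokens with s the configured
    exponent and C a fixed top count; ranks are assigned to words in random
    order, so corpus frequency is independent of the beauty grouping.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(set(words)) != len(words):
        raise GeneratorError("words must be unique")
    top = 1_000_000.0
    order = rng.permutation(len(words))
    entries = {
        words[idx]: max(1, round(top / (rank + 1) ** config.zipf_exponent))
        for rank, idx in enumerate(order)
    }
    return FrequencyTable(entries)


def _build_backbone(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[nx.DiGraph, dict[str, list[str]]]:
    """Rooted tree with four affective hub subtrees and a neutral region."""
    g = nx.DiGraph()
    depth = {"root": 0}
    counter = [0]

    def add(parent: str, prefix: str) -> str:
        counter[0] += 1
        node = f"{prefix}{counter[0]}"
        g.add_edge(node, parent)
        depth[node] = depth[parent] + 1
        return node

    g.add_node("root")
    pools: dict[str, list[str]] = {}
    for name, size in [
        ("ap_pos", 40), ("ap_neg", 40), ("val_pos", 25), ("val_neg", 25), ("neutral", 50),
    ]:
        branch = add("root", f"{name}_b")
        hub = add(branch, f"{name}_h")
        members = [hub]
        for _ in range(size):
            parent = members[int(rng.integers(len(members)))]
            if depth[parent] >= config.taxonomy_depth:
                parent = hub
            members.append(add(parent, f"{name}_n"))
        pools[name] = members
    # guarantee the configured depth via a chain in the neutral region
    node = pools["neutral"][0]
    while depth[node] < config.taxonomy_depth:
        node = add(node, "chain")
        pools["neutral"].append(node)
    return g, pools


def generate_taxonomy(
    words: WordForms,
    valence_labels: LabelSetConfig,
    ap_labels: LabelSetConfig,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SemanticTaxonomy, float]:
    """Synthetic is-a taxonomy with a calibrated aesthetic-potential effect.

    Beautiful words attach to a node inside the positive-aesthetic hub
    subtree with probability 1−q and to a uniformly random node with
    probability q (symmetrically for ugly words and the negative hub); the
    attachment noise q is the effect dial.  With ``config.ap_noise`` unset,
    q is calibrated by bisection until the z-scored AP group-mean
    separation of the generated dataset matches ``config.ap_effect``; with
    ``ap_noise`` set it is used verbatim (0 → perfect separation, 1 → no
    signal).  Returns the taxonomy and the q actually used.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g, pools = _build_backbone(config, rng)
    all_nodes = [n for n in g.nodes if n != "root"]

    lemma_fixed: dict[str, set[str]] = {}
    for pole, pool_name in [("positive", "ap_pos"), ("negative", "ap_neg")]:
        for lab in getattr(ap_labels, pole):
            node = pools[pool_name][int(rng.integers(len(pools[pool_name])))]
            lemma_fixed.setdefault(lab, set()).add(node)
    for pole, pool_name in [("positive", "val_pos"), ("negative", "val_neg")]:
        for lab in getattr(valence_labels, pole):
            node = pools[pool_name][int(rng.integers(len(pools[pool_name])))]
            lemma_fixed.setdefault(lab, set()).add(node)

    # pre-drawn randomness shared across candidate noise levels, so the
    # measured separation is a monotone step function of q and bisection
    # is well behaved
    dataset = [(w, "ap_pos") for w in words.beautiful] + [(w, "ap_neg") for w in words.ugly]
    u = rng.random(len(dataset))
    hub_pick = [pools[pool][int(rng.integers(len(pools[pool])))] for _, pool in dataset]
    noise_pick = [all_nodes[int(rng.integers(len(all_nodes)))] for _ in dataset]

    def build(q: float) -> SemanticTaxonomy:
        lemma_index = {k: set(v) for k, v in lemma_fixed.items()}
        for i, (w, _) in enumerate(dataset):
            node = noise_pick[i] if u[i] < q else hub_pick[i]
            lemma_index.setdefault(w, set()).add(node)
        return SemanticTaxonomy(g.copy(), lemma_index)

    def separation(tax: SemanticTaxonomy) -> float:
        ap = np.array([label_score(w, ap_labels, tax) for w, _ in dataset])
        z = (ap - ap.mean()) / ap.std(ddof=1)
        nb = len(words.beautiful)
        return float(z[:nb].mean() - z[nb:].mean())

    if config.ap_noise is not None:
        q = float(config.ap_noise)
        return build(q), q
    if config.ap_effect == 0.0:
        # no signal means uniform attachment, not a calibrated approximation
        return build(1.0), 1.0

    lo, hi = 0.0, 1.0  # separation decreases in q
    tax = build(lo)
    if separation(tax) <= config.ap_effect:
        return tax, lo
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        tax = build(mid)
        if separation(tax) > config.ap_effect:
            lo = mid
        else:
            hi = mid
    q = 0.5 * (lo + hi)
    return build(q), q


@dataclass
class SyntheticStudy:
    """A complete generated study: resources, label sets, labeled words."""

    config: GeneratorConfig
    frequency_table: FrequencyTable
    taxonomy: SemanticTaxonomy
    valence_labels: LabelSetConfig
    ap_labels: LabelSetConfig
    dataset: list[tuple[str, int]]
    ground_truth: dict = field(default_factory=dict)

    def feature_context(self) -> FeatureContext:
        return FeatureContext(
            freq=self.frequency_table,
            tax=self.taxonomy,
            targets=[w for w, _ in self.dataset],
            valence_labels=self.valence_labels,
            ap_labels=self.ap_labels,
        )

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write all study files in the formats the loaders consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "frequencies": "frequencies.tsv",
            "taxonomy_edges": "taxonomy_edges.tsv",
            "taxonomy_lemmas": "taxonomy_lemmas.tsv",
            "dataset": "dataset.csv",
            "valence_labels": "valence_labels.cfg",
            "ap_labels": "ap_labels.cfg",
        }
        self.frequency_table.to_tsv(out / files["frequencies"])
        self.taxonomy.to_tsv(out / files["taxonomy_edges"], out / files["taxonomy_lemmas"])
        with open(out / files["dataset"], "w", encoding="utf-8") as fh:
            fh.write("word,class\n")
            for w, lab in self.dataset:
                fh.write(f"{w},{'beautiful' if lab == 1 else 'ugly'}\n")
        self.valence_labels.to_file(out / files["valence_labels"])
        self.ap_labels.to_file(out / files["ap_labels"])
        manifest = {
            "config": asdict(self.config),
            "ground_truth": self.ground_truth,
            "files": files,
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, ensure_ascii=False)
        return files


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study from one master seed.

    Composes the word-form, frequency and taxonomy generators (independent
    seed streams fanned out from ``config.seed``) with the default label
    sets, and records the injected group effects as ground truth.
    """
    config = config or GeneratorConfig()
    kids = np.random.SeedSequence(config.seed).spawn(3)
    rng_words, rng_freq, rng_tax = (np.random.default_rng(k) for k in kids)
    words = generate_word_forms(config, rng_words)
    freq = generate_frequencies(words.all_words, config, rng_freq)
    val_cfg = default_valence_labels()
    ap_cfg = default_ap_labels()
    tax, q = generate_taxonomy(words, val_cfg, ap_cfg, config, rng_tax)
    dataset = [(w, 1) for w in words.beautiful] + [(w, 0) for w in words.ugly]
    ground_truth = {
        "ap_z_separation": config.ap_effect if config.ap_noise is None else None,
        "sonority_means": list(config.sonority_means),
        "length_difference": 0.0,
        "attachment_noise": q,
        "n_beautiful": config.n_beautiful,
        "n_ugly": config.n_ugly,
    }
    return SyntheticStudy(config, freq, tax, val_cfg, ap_cfg, dataset, ground_truth)
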