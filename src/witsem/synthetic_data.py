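"""Synthetic inputs: cluster-structured corpora, statements, and word lists.

The generator emulates the *shape* of the testimony data the pipeline
was designed for — several hundred to ~1,500 short cued-recall
statements, roughly three-quarters coded correct, spread over 11 topical
themes with unequal accuracy base rates — together with an n-gram corpus
whose vocabulary carries planted co-occurrence clusters (a topic-style
mixture model), so every stage of the pipeline is exercisable without
any external download.

Cluster layout: one cluster per theme, one shared high-frequency
"function word" cluster, and one *target* cluster playing the role of a
construct vocabulary (communion-like).  Within each cluster word
probabilities follow a Zipf law, so frequency-ranked vocabularies are
meaningful.

The planted accuracy-construct association is parameterised by a
standardised enrichment delta: incorrect statements allocate extra token
probability to the target cluster, with the shift scaled analytically
(from the share noise and the statement-length distribution) so that
delta approximates the standardised mean difference of the
target-cluster token rate between incorrect and correct statements.
With delta = 0 the two classes are exchangeable given theme.

All generators are pure functions of (config, seed): fixed seeds give
bitwise-identical output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import (
    ConstructWordList,
    NGramCorpus,
    RatingList,
    StatementRecord,
)

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "cluster_assignments",
    "simulate_corpus",
    "simulate_statements",
    "simulate_rating_list",
    "simulate_bundle",
]

# distinct sub-streams of the config seed, so corpus / statements /
# ratings can be regenerated independently yet reproducibly
_STREAM_CORPUS = 1
_STREAM_STATEMENTS = 2
_STREAM_RATINGS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with testimony-like defaults.

    Defaults mirror the first-study data shape: 800 statements, 78%
    correct overall, 11 themes whose base rates spread +-10 points, and
    short cued-recall answers (truncated-geometric lengths, mean ~12
    tokens).  ``delta`` is the planted standardised enrichment of
    target-cluster words in incorrect statements (0 = no effect).
    """

    vocab_size: int = 240
    n_clusters: int = 13
    n_themes: int = 11
    function_cluster: int = 11
    target_cluster: int = 12
    zipf_exponent: float = 1.0
    leakage: float = 0.15
    function_weight: float = 3.0
    ngram_length: int = 5
    n_grams: int = 30_000
    n_statements: int = 800
    mean_statement_length: float = 12.0
    min_statement_length: int = 4
    max_statement_length: int = 40
    base_accuracy: float = 0.78
    accuracy_spread: float = 0.10
    theme_base_rates: tuple[float, ...] | None = None
    delta: float = 0.0
    target_base_share: float = 0.10
    target_share_sd: float = 0.05
    function_share: float = 0.30
    noise_share: float = 0.08
    theme_alpha_own: float = 6.0
    theme_alpha_other: float = 0.3
    rating_noise_sd: float = 0.5
    rating_scale: tuple[float, float] = (1.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < self.n_clusters:
            raise ValueError("vocab_size must be >= n_clusters")
        if self.n_themes < 2:
            raise ValueError("need at least 2 themes")
        if self.n_clusters < self.n_themes + 2:
            raise ValueError("need a cluster per theme plus function and target clusters")
        if not 0.0 <= self.leakage <= 1.0:
            raise ValueError("leakage must be in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        rates = self.resolved_base_rates()
        if any(not 0.0 < r < 1.0 for r in rates):
            raise ValueError("theme base rates must lie in (0, 1)")
        if not 1 <= self.min_statement_length <= self.max_statement_length:
            raise ValueError("invalid statement length bounds")

    def resolved_base_rates(self) -> tuple[float, ...]:
        """Per-theme accuracy base rates (explicit, or an even spread)."""
        if self.theme_base_rates is not None:
            if len(self.theme_base_rates) != self.n_themes:
                raise ValueError("theme_base_rates length must equal n_themes")
            return tuple(self.theme_base_rates)
        return tuple(
            np.linspace(
                self.base_accuracy - self.accuracy_spread,
                self.base_accuracy + self.accuracy_spread,
                self.n_themes,
            )
        )


# ---------------------------------------------------------------------------
# Vocabulary clusters
# ---------------------------------------------------------------------------


def cluster_assignments(config: SimulationConfig) -> dict[str, int]:
    """Deterministic word -> cluster map (contiguous near-equal blocks)."""
    words = [f"w{i:03d}" for i in range(config.vocab_size)]
    blocks = np.array_split(np.arange(config.vocab_size), config.n_clusters)
    assignment: dict[str, int] = {}
    for c, block in enumerate(blocks):
        for i in block:
            assignment[words[i]] = c
    return assignment


def _cluster_distributions(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Per-cluster Zipf word distributions as a (G x V) row-stochastic matrix."""
    assignment = cluster_assignments(config)
    words = sorted(assignment, key=lambda w: int(w[1:]))
    dists = np.zeros((config.n_clusters, config.vocab_size))
    for c in range(config.n_clusters):
        idx = [i for i, w in enumerate(words) if assignment[w] == c]
        ranks = np.arange(1, len(idx) + 1, dtype=np.float64)
        weights = ranks ** (-config.zipf_exponent)
        dists[c, idx] = weights / weights.sum()
    return words, dists


def _cluster_draw_probs(config: SimulationConfig) -> np.ndarray:
    """Corpus-level cluster frequencies (function words over-weighted)."""
    weights = np.ones(config.n_clusters)
    weights[config.function_cluster] = config.function_weight
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# Corpus
# ---------------------------------------------------------------------------


def simulate_corpus(config: SimulationConfig) -> tuple[NGramCorpus, dict[str, int]]:
    """Sample an n-gram corpus from the cluster mixture.

    Each gram draws a cluster, then n tokens from that cluster's Zipf
    distribution; with probability ``leakage`` a token is drawn from the
    corpus-wide marginal instead, producing weak cross-cluster
    co-occurrence.  With leakage 0 between-cluster co-occurrence is
    exactly zero by construction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_CORPUS]))
    words, dists = _cluster_distributions(config)
    cluster_probs = _cluster_draw_probs(config)
    global_dist = cluster_probs @ dists
    n, G = config.ngram_length, config.n_clusters
    gram_clusters = rng.choice(G, size=config.n_grams, p=cluster_probs)
    tokens = np.empty((config.n_grams, n), dtype=np.int64)
    for c in range(G):
        rows = np.flatnonzero(gram_clusters == c)
        if rows.size:
            tokens[rows] = rng.choice(
                config.vocab_size, size=(rows.size, n), p=dists[c]
            )
    if config.leakage > 0:
        leak = rng.random((config.n_grams, n)) < config.leakage
        n_leak = int(leak.sum())
        if n_leak:
            tokens[leak] = rng.choice(config.vocab_size, size=n_leak, p=global_dist)
    counts: Counter[tuple[str, ...]] = Counter(
        tuple(words[i] for i in row) for row in tokens
    )
    corpus = NGramCorpus(n)
    for gram in sorted(counts):
        corpus.add(gram, counts[gram])
    return corpus, cluster_assignments(config)


# ---------------------------------------------------------------------------
# Statements
# ---------------------------------------------------------------------------


def _length_pmf(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Truncated-geometric statement-length pmf over [min, max] tokens."""
    lo, hi = config.min_statement_length, config.max_statement_length
    p = 1.0 / max(config.mean_statement_length - lo + 1.0, 1.0)
    lengths = np.arange(lo, hi + 1)
    pmf = p * (1 - p) ** (lengths - lo)
    pmf[-1] += (1 - p) ** (hi - lo + 1)  # lump the tail at the maximum
    return lengths, pmf / pmf.sum()


def _delta_scale(config: SimulationConfig) -> float:
    """sd of the per-statement target-cluster token rate under the null.

    var(rate) ~= share-noise variance + binomial sampling variance
    E[p(1-p)/L], evaluated at the base share, with E[1/L] taken exactly
    over the truncated-geometric length distribution.  Scaling the
    planted share shift by this sd makes ``delta`` approximate the
    standardised rate difference.
    """
    lengths, pmf = _length_pmf(config)
    e_inv_len = float(np.sum(pmf / lengths))
    p0 = config.target_base_share
    return math.sqrt(config.target_share_sd**2 + p0 * (1 - p0) * e_inv_len)


def simulate_statements(config: SimulationConfig) -> list[StatementRecord]:
    """Sample the statement table with theme structure and planted effect.

    Each statement draws a theme uniformly, its accuracy from the
    theme's base rate, a length from the truncated geometric, and its
    tokens from a per-statement mixture of (theme clusters, function
    cluster, corpus-wide noise, target cluster).  The target-cluster
    share is ``target_base_share`` plus Gaussian noise, plus
    ``delta`` x (null rate sd) for incorrect statements.

    Topical content is *soft*: the theme share is spread over all theme
    clusters with Dirichlet weights concentrated on the statement's own
    theme (``theme_alpha_own`` vs ``theme_alpha_other``).  Statements of
    one theme therefore still touch other themes' vocabulary — as real
    testimony statements do — which keeps leave-one-theme-out
    regression well-posed instead of forcing it to extrapolate into a
    vocabulary it has never seen.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _STREAM_STATEMENTS])
    )
    words, dists = _cluster_distributions(config)
    cluster_probs = _cluster_draw_probs(config)
    global_dist = cluster_probs @ dists
    rates = config.resolved_base_rates()
    lengths_support, length_pmf = _length_pmf(config)
    shift = config.delta * _delta_scale(config)

    records: list[StatementRecord] = []
    for i in range(config.n_statements):
        theme = int(rng.integers(config.n_themes))
        acc = int(rng.random() < rates[theme])
        length = int(rng.choice(lengths_support, p=length_pmf))
        share = config.target_base_share + rng.normal(0.0, config.target_share_sd)
        if acc == 0:
            share += shift
        share = float(np.clip(share, 0.01, 0.55))
        theme_share = max(
            1.0 - share - config.function_share - config.noise_share, 0.05
        )
        alpha = np.full(config.n_themes, config.theme_alpha_other)
        alpha[theme] = config.theme_alpha_own
        theme_weights = rng.dirichlet(alpha)
        probs = (
            share * dists[config.target_cluster]
            + config.function_share * dists[config.function_cluster]
            + config.noise_share * global_dist
            + theme_share * (theme_weights @ dists[: config.n_themes])
        )
        probs = probs / probs.sum()
        token_idx = rng.choice(config.vocab_size, size=length, p=probs)
        text = " ".join(words[j] for j in token_idx)
        records.append(
            StatementRecord(
                statement_id=f"s{i + 1:04d}",
                text=text,
                theme=f"theme{theme + 1:02d}",
                accuracy=acc,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Rating and construct word lists
# ---------------------------------------------------------------------------


def simulate_rating_list(
    config: SimulationConfig,
    name: str = "dominance",
    construct_cluster: int | None = None,
    n_construct_words: int = 12,
) -> tuple[RatingList, ConstructWordList]:
    """Ratings linear in cluster membership, and a target-cluster word list.

    Every vocabulary word gets a rating equal to its cluster's level
    (levels evenly spaced across the declared scale) plus Gaussian noise
    of sd ``rating_noise_sd``, clipped to the scale.  The construct list
    is the ``n_construct_words`` most frequent words of the chosen
    cluster (default: the target cluster).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_RATINGS]))
    assignment = cluster_assignments(config)
    lo, hi = config.rating_scale
    margin = 0.05 * (hi - lo)
    levels = np.linspace(lo + margin, hi - margin, config.n_clusters)
    entries: dict[str, float] = {}
    for word in sorted(assignment, key=lambda w: int(w[1:])):
        rating = levels[assignment[word]] + rng.normal(0.0, config.rating_noise_sd)
        entries[word] = float(np.clip(rating, lo, hi))
    cluster = config.target_cluster if construct_cluster is None else construct_cluster
    # within a cluster, lower word index = higher Zipf weight = more frequent
    cluster_words = sorted(
        (w for w, c in assignment.items() if c == cluster), key=lambda w: int(w[1:])
    )
    construct = ConstructWordList(
        name=f"{name}_cluster_words" if construct_cluster is not None else "communion",
        words=tuple(cluster_words[:n_construct_words]),
    )
    return (
        RatingList(name=name, entries=entries, scale_min=lo, scale_max=hi),
        construct,
    )


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticBundle:
    """Everything one simulated study provides to the pipeline."""

    config: SimulationConfig
    corpus: NGramCorpus
    clusters: Mapping[str, int]
    statements: list[StatementRecord]
    rating_list: RatingList
    construct_lists: Mapping[str, ConstructWordList] = field(default_factory=dict)


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate corpus, statements, ratings, and construct lists together.

    Besides the target-cluster ("communion") list, a second list drawn
    from the function-word cluster plays the role of a
    tentativeness-style construct.
    """
    corpus, clusters = simulate_corpus(config)
    statements = simulate_statements(config)
    ratings, communion = simulate_rating_list(config)
    _, tentativeness = simulate_rating_list(
        config, name="tentativeness", construct_cluster=config.function_cluster
    )
    tentativeness = ConstructWordList(name="tentativeness", words=tentativeness.words)
    return SyntheticBundle(
        config=config,
        corpus=corpus,
        clusters=clusters,
        statements=statements,
        rating_list=ratings,
        construct_lists={"communion": communion, "tentativeness": tentativeness},
    )
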