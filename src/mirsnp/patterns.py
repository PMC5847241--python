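"""De-novo (L,W) wildcard-pattern discovery over a mature-miRNA corpus.

A pattern is a motif over {A,C,G,U,'.'} where '.' matches any single base.
Validity requires: the motif starts and ends with a literal, and every run of
L consecutive literals spans at most W positions (the Teiresias density
constraint). Support counts corpus *sequences* containing at least one match,
so long miRNAs cannot dominate.

Discovery enumerates, by depth-first occurrence-list growth, every valid
pattern with at least L literals and support >= min_support, then keeps the
maximal ones. Maximality is one-step irreducibility: a pattern is maximal iff
no valid one-step specialization — filling one wildcard with a literal, or
extending either end by k wildcards plus a literal — preserves its support.
Significance is assessed against a Markov background model fitted to the
corpus, with the expected support estimated by Monte Carlo simulation of
replicate null corpora.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .seqio import MatureMiRNA

logger = logging.getLogger(__name__)

BASES = "ACGU"
WILDCARD = "."


# ---------------------------------------------------------------------------
# pattern representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pattern:
    motif: str
    support: int
    literal_count: int
    log_odds: float = math.nan

    def __post_init__(self):
        if not motif_valid_shape(self.motif):
            raise ParameterError(f"motif {self.motif!r} must start and end with a literal")


def motif_valid_shape(motif: str) -> bool:
    return bool(motif) and motif[0] != WILDCARD and motif[-1] != WILDCARD


def motif_literal_positions(motif: str) -> list[int]:
    return [i for i, c in enumerate(motif) if c != WILDCARD]


def motif_density_ok(motif: str, L: int, W: int) -> bool:
    """True iff every run of L consecutive literals spans <= W positions."""
    pos = motif_literal_positions(motif)
    return all(pos[i + L - 1] - pos[i] + 1 <= W for i in range(len(pos) - L + 1))


def motif_is_valid(motif: str, L: int, W: int) -> bool:
    return motif_valid_shape(motif) and motif_density_ok(motif, L, W)


def _motif_regex(motif: str, alphabet: str = BASES) -> re.Pattern:
    # '.' must match exactly one base of the alphabet (never N downstream)
    return re.compile("".join(f"[{alphabet}]" if c == WILDCARD else re.escape(c)
                              for c in motif))


def motif_matches(motif: str, seq: str) -> bool:
    return _motif_regex(motif).search(seq) is not None


def pattern_support(motif: str, corpus: list[MatureMiRNA] | list[str]) -> int:
    """Number of corpus sequences with >= 1 match of ``motif``."""
    rx = _motif_regex(motif)
    seqs = [m.sequence if isinstance(m, MatureMiRNA) else m for m in corpus]
    return sum(1 for s in seqs if rx.search(s))


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def discover_patterns(
    corpus: list[MatureMiRNA] | list[str],
    L: int = 4,
    W: int = 6,
    min_support: int | None = None,
) -> list[Pattern]:
    """Enumerate all maximal (L,W) patterns with support >= min_support.

    ``min_support`` defaults to ``max(2, ceil(0.01 * len(corpus)))``. Output
    is sorted by (support desc, literal_count desc, motif lexicographic) so
    identical inputs give byte-identical results.
    """
    seqs = [m.sequence if isinstance(m, MatureMiRNA) else m for m in corpus]
    if not seqs:
        raise ParameterError("corpus must be non-empty")
    if min_support is None:
        min_support = max(2, math.ceil(0.01 * len(seqs)))
    if not (2 <= L <= W):
        raise ParameterError(f"require 2 <= L <= W, got L={L}, W={W}")
    if min_support < 2:
        raise ParameterError(f"min_support must be >= 2, got {min_support}")

    supported = _enumerate_supported(seqs, L, W, min_support)
    maximal = [
        Pattern(motif, support, len(motif_literal_positions(motif)))
        for motif, support in supported.items()
        if len(motif_literal_positions(motif)) >= L
        and _is_maximal(motif, support, seqs, L, W)
    ]
    maximal.sort(key=lambda p: (-p.support, -p.literal_count, p.motif))
    return maximal


def _enumerate_supported(seqs: list[str], L: int, W: int,
                         min_support: int) -> dict[str, int]:
    """DFS over left-to-right pattern growth with occurrence-list pruning.

    A state is (motif, occurrences) where occurrences are (seq idx, start)
    pairs of live matches. Appending ``'.'*g + literal`` filters occurrences;
    support is the number of distinct sequences left. Pruning is sound since
    support is non-increasing under extension.
    """
    out: dict[str, int] = {}
    max_gap = W - 2  # two consecutive literals must fit in a W window when L=2

    def grow(motif: str, occs: list[tuple[int, int]]):
        support = len({si for si, _ in occs})
        if support < min_support:
            return
        out[motif] = support
        base_len = len(motif)
        for g in range(0, max_gap + 1):
            by_char: dict[str, list[tuple[int, int]]] = {c: [] for c in BASES}
            for si, start in occs:
                j = start + base_len + g
                if j < len(seqs[si]):
                    c = seqs[si][j]
                    if c in by_char:
                        by_char[c].append((si, start))
            for c in BASES:
                new_motif = motif + WILDCARD * g + c
                if not _last_run_ok(new_motif, L, W):
                    continue
                grow(new_motif, by_char[c])

    for c in BASES:
        occs = [(si, j) for si, s in enumerate(seqs)
                for j in range(len(s)) if s[j] == c]
        grow(c, occs)
    return out


def _last_run_ok(motif: str, L: int, W: int) -> bool:
    """Density check for the run of L literals ending at the new last literal;
    earlier runs were validated when their own last literal was appended."""
    pos = motif_literal_positions(motif)
    if len(pos) < L:
        return True
    return pos[-1] - pos[-L] + 1 <= W


def one_step_specializations(motif: str, L: int, W: int) -> list[str]:
    """All valid one-step specializations of ``motif``: wildcard fills and
    single-literal extensions of either end (with any wildcard gap)."""
    out = []
    for i, c in enumerate(motif):
        if c == WILDCARD:
            for b in BASES:
                cand = motif[:i] + b + motif[i + 1:]
                if motif_density_ok(cand, L, W):
                    out.append(cand)
    for g in range(0, W - 1):
        for b in BASES:
            left = b + WILDCARD * g + motif
            if motif_density_ok(left, L, W):
                out.append(left)
            right = motif + WILDCARD * g + b
            if motif_density_ok(right, L, W):
                out.append(right)
    return out


def _is_maximal(motif: str, support: int, seqs: list[str], L: int, W: int) -> bool:
    return all(pattern_support(s, seqs) < support
               for s in one_step_specializations(motif, L, W))


# ---------------------------------------------------------------------------
# background model + significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundModel:
    """Markov chain over {A,C,G,U} with add-one smoothed ML transitions.

    ``transitions`` has shape (4**order, 4); rows sum to 1. The first
    ``order`` bases of a simulated sequence are drawn from the order-0
    marginal of the training corpus.
    """

    order: int
    transitions: np.ndarray
    marginal: np.ndarray
    trained_on: str = ""

    def __post_init__(self):
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("transition rows must sum to 1")

    def sample(self, rng: np.random.Generator, length: int) -> str:
        idx = np.empty(length, dtype=np.int64)
        ctx = 0
        for i in range(length):
            if i < self.order:
                b = rng.choice(4, p=self.marginal)
            else:
                b = rng.choice(4, p=self.transitions[ctx])
            idx[i] = b
            if self.order > 0:
                ctx = (ctx * 4 + b) % (4 ** self.order)
        return "".join(BASES[i] for i in idx)


def fit_background(corpus: list[MatureMiRNA] | list[str], order: int = 2,
                   ) -> BackgroundModel:
    """Fit an order-0/1/2 Markov background with add-one smoothing."""
    seqs = [m.sequence if isinstance(m, MatureMiRNA) else m for m in corpus]
    if not seqs:
        raise ParameterError("corpus must be non-empty")
    if order not in (0, 1, 2):
        raise ParameterError(f"order must be 0, 1 or 2, got {order}")
    total = sum(len(s) for s in seqs)
    if total <= 4 ** (order + 1):
        logger.warning(
            "corpus length %d is small for a Markov order-%d fit", total, order
        )
    b2i = {c: i for i, c in enumerate(BASES)}
    counts = np.zeros((4 ** order, 4))
    marg = np.zeros(4)
    for s in seqs:
        for i, c in enumerate(s):
            marg[b2i[c]] += 1
            if i >= order:
                ctx = 0
                for k in range(order):
                    ctx = ctx * 4 + b2i[s[i - order + k]]
                counts[ctx, b2i[c]] += 1
    trans = (counts + 1.0) / (counts.sum(axis=1, keepdims=True) + 4.0)
    marginal = (marg + 1.0) / (marg.sum() + 4.0)
    return BackgroundModel(order, trans, marginal, trained_on=f"{len(seqs)} sequences")


def keep_significant(
    patterns: list[Pattern],
    model: BackgroundModel,
    corpus_size: int,
    lengths: list[int],
    min_log_odds: float = math.log(2.0),
    n_null: int = 1000,
    seed: int = 0,
) -> list[Pattern]:
    """Retain patterns whose observed support exceeds the background
    expectation by at least ``min_log_odds`` (natural log of the ratio).

    The per-sequence match probability is estimated from ``n_null`` simulated
    replicate corpora (each mirroring the observed ``lengths``); expected
    support is ``corpus_size * p_hat``, with an add-one count on the null
    matches so the expectation is never zero.
    """
    if not patterns:
        return []
    rng = np.random.default_rng(seed)
    null_seqs = [model.sample(rng, lengths[i % len(lengths)])
                 for i in range(n_null * len(lengths))]
    n = len(null_seqs)
    kept = []
    for p in patterns:
        matches = pattern_support(p.motif, null_seqs)
        p_hat = (matches + 1.0) / (n + 1.0)
        expected = corpus_size * p_hat
        lo = math.log(p.support / expected)
        if lo >= min_log_odds:
            kept.append(replace(p, log_odds=lo))
    logger.info("keep_significant: %d of %d patterns retained", len(kept), len(patterns))
    return kept


def write_patterns(patterns: list[Pattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tsupport\tliteral_count\tlog_odds\n")
        for p in patterns:
            fh.write(f"{p.motif}\t{p.support}\t{p.literal_count}\t{p.log_odds:.4f}\n")
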