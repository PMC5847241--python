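"""Independent brute-force oracles used to validate the pipeline stages.

Everything here is deliberately naive — exhaustive enumeration, closed
forms, exact rational arithmetic — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

BASES = "ACGU"


# ---------------------------------------------------------------------------
# pattern discovery
# ---------------------------------------------------------------------------

def _lits(motif):
    return [i for i, c in enumerate(motif) if c != "."]


def valid_motif(motif: str, L: int, W: int) -> bool:
    if not motif or motif[0] == "." or motif[-1] == ".":
        return False
    pos = _lits(motif)
    return all(pos[i + L - 1] - pos[i] + 1 <= W
               for i in range(len(pos) - L + 1))


def motif_hits_seq(motif: str, seq: str) -> bool:
    for off in range(len(seq) - len(motif) + 1):
        if all(c == "." or c == seq[off + i] for i, c in enumerate(motif)):
            return True
    return False


def support_of(motif: str, seqs: list[str]) -> int:
    return sum(1 for s in seqs if motif_hits_seq(motif, s))


def one_step_specs(motif: str, L: int, W: int) -> list[str]:
    out = []
    for i, c in enumerate(motif):
        if c == ".":
            out.extend(motif[:i] + b + motif[i + 1:] for b in BASES)
    for g in range(W - 1):
        for b in BASES:
            out.append(b + "." * g + motif)
            out.append(motif + "." * g + b)
    return [m for m in out if valid_motif(m, L, W)]


def enumerate_maximal_patterns(seqs: list[str], L: int, W: int,
                               min_support: int) -> set[tuple[str, int]]:
    """All maximal (L,W) patterns with >= L literals and support >=
    min_support, by exhaustive enumeration of wildcard masks of substrings
    (any motif with support >= 1 is a masked substring of some sequence)."""
    cands = set()
    for s in seqs:
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                sub = s[i:j]
                interior = max(len(sub) - 2, 0)
                for mask in range(1 << interior):
                    chars = list(sub)
                    for b in range(interior):
                        if mask >> b & 1:
                            chars[1 + b] = "."
                    cands.add("".join(chars))
    out = set()
    for motif in cands:
        if not valid_motif(motif, L, W) or len(_lits(motif)) < L:
            continue
        sup = support_of(motif, seqs)
        if sup < min_support:
            continue
        if all(support_of(sp, seqs) < sup
               for sp in one_step_specs(motif, L, W)):
            out.add((motif, sup))
    return out


# ---------------------------------------------------------------------------
# scanning / islands
# ---------------------------------------------------------------------------

def scan_positions(seq: str, motif: str) -> list[int]:
    """All (overlapping) match starts of a DNA-space motif; '.' matches
    A/C/G/T only, N matches nothing."""
    out = []
    for off in range(len(seq) - len(motif) + 1):
        ok = True
        for i, c in enumerate(motif):
            s = seq[off + i]
            if c == ".":
                if s not in "ACGT":
                    ok = False
                    break
            elif s != c:
                ok = False
                break
        if ok:
            out.append(off)
    return out


def islands_all_spans(hits: list[tuple[int, int]], utr_len: int,
                      window: int, min_hits: int) -> list[tuple[int, int, int]]:
    """(start, end, hit_count) islands from every integer window position."""
    raw = []
    for x in range(utr_len + 1):
        inside = [(s, e) for s, e in hits if x <= s < x + window]
        if len(inside) >= min_hits:
            raw.append((min(s for s, _ in inside), max(e for _, e in inside)))
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, min(e, utr_len), sum(1 for hs, _ in hits if s <= hs < e))
            for s, e in merged]


# ---------------------------------------------------------------------------
# duplex alignment
# ---------------------------------------------------------------------------

def _pairs_table(params):
    wc = {("A", "T"), ("U", "A"), ("C", "G"), ("G", "C")}
    gu = {("G", "T"), ("U", "G")}

    def score(a, b):
        if (a, b) in wc:
            return params.match_wc
        if (a, b) in gu:
            return params.match_gu
        return params.mismatch

    return score


def duplex_best_score(mseq: str, island: str, params) -> float:
    """Pair-to-pair recursion over the last aligned column, with closed-form
    affine gap runs between consecutive columns. Independent of the Gotoh
    three-matrix formulation."""
    t = island.upper().replace("U", "T")[::-1]
    score = _pairs_table(params)

    def gap(k: int) -> float:
        return 0.0 if k == 0 else params.gap_open + (k - 1) * params.gap_extend

    n, m = len(mseq), len(t)
    B = [[0.0] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        for j in range(m):
            inner = 0.0
            for i2 in range(i):
                for j2 in range(j):
                    cand = B[i2][j2] + gap(i - i2 - 1) + gap(j - j2 - 1)
                    if cand > inner:
                        inner = cand
            B[i][j] = score(mseq[i], t[j]) + inner
            best = max(best, B[i][j])
    return best


def duplex_enumerate_all(mseq: str, island: str, params,
                         seed_filter: int | None = None,
                         seed_range: tuple[int, int] = (1, 7),
                         wobble_counts: bool = True) -> float:
    """Literal enumeration of every monotone antiparallel column set (tiny
    instances only). With ``seed_filter`` set, restricts to alignments whose
    seed pairs (WC, plus GU if ``wobble_counts``) number at least that."""
    t = island.upper().replace("U", "T")[::-1]
    score = _pairs_table(params)

    def gap(k):
        return 0.0 if k == 0 else params.gap_open + (k - 1) * params.gap_extend

    n, m = len(mseq), len(t)
    best = 0.0
    idx_i = range(n)
    idx_j = range(m)
    for k in range(1, min(n, m) + 1):
        for rows in itertools.combinations(idx_i, k):
            for cols in itertools.combinations(idx_j, k):
                total = 0.0
                seeds = 0
                for (r, c) in zip(rows, cols):
                    pr = score(mseq[r], t[c])
                    total += pr
                    if seed_range[0] <= r <= seed_range[1]:
                        if pr == params.match_wc or (
                                wobble_counts and pr == params.match_gu):
                            seeds += 1
                for a in range(k - 1):
                    total += gap(rows[a + 1] - rows[a] - 1)
                    total += gap(cols[a + 1] - cols[a] - 1)
                if seed_filter is not None and seeds < seed_filter:
                    continue
                best = max(best, total)
    return best


# ---------------------------------------------------------------------------
# Mendelian trios
# ---------------------------------------------------------------------------

GENOTYPES = (("A", "A"), ("A", "B"), ("B", "B"))


def trio_consistent_enumeration(child, father, mother) -> bool:
    """Marginalize missing members over all genotypes and transmissions."""
    if child is None:
        return True
    f_opts = GENOTYPES if father is None else (father,)
    m_opts = GENOTYPES if mother is None else (mother,)
    want = tuple(sorted(child))
    for f in f_opts:
        for m in m_opts:
            for fa in f:
                for ma in m:
                    if tuple(sorted((fa, ma))) == want:
                        return True
    return False


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_fraction(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact conditional HWE p-value in rational arithmetic."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return Fraction(1)
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return Fraction(1)

    def weight(het: int) -> Fraction:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        if hom_c < 0:
            return Fraction(0)
        return Fraction(
            2 ** het,
            math.factorial(hom_r) * math.factorial(het) * math.factorial(hom_c),
        )

    hets = list(range(n_rare % 2, n_rare + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total
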