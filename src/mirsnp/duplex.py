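"""miRNA:target-island heteroduplex scoring by complementarity alignment.

The miRNA (RNA, 5'->3') is aligned antiparallel against an island sequence
(DNA or RNA; transliterated internally to DNA). Watson-Crick pairs (A:T, U:A,
C:G, G:C) score ``match_wc``, G:U wobbles (miRNA G vs island T, miRNA U vs
island G) score ``match_gu``, any other aligned pair scores ``mismatch``, and
gaps are affine (first gapped base ``gap_open``, each further ``gap_extend``).
The alignment is local (Smith-Waterman/Gotoh): a score below zero floors at
zero, i.e. "no alignment".

An alignment *qualifies* when its score reaches ``min_report_score`` and at
least ``seed_min_pairs`` of miRNA positions 2-8 (1-based from the 5' end) are
paired; this is the gate behind "the most favorable alignments" — sites
pairing only the miRNA 3' region never qualify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError
from .seqio import MatureMiRNA

WC_PAIRS = {("A", "T"), ("U", "A"), ("C", "G"), ("G", "C")}
GU_PAIRS = {("G", "T"), ("U", "G")}


@dataclass(frozen=True)
class DuplexParams:
    match_wc: float = 5.0
    match_gu: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -8.0      # cost of the first gapped base
    gap_extend: float = -2.0    # each subsequent gapped base
    seed_start: int = 2         # 1-based miRNA position, inclusive
    seed_end: int = 8           # inclusive
    seed_min_pairs: int = 6
    seed_counts_wobble: bool = True
    min_report_score: float = 40.0

    def __post_init__(self):
        if not (self.match_wc > self.match_gu > 0 > self.mismatch):
            raise ParameterError("require match_wc > match_gu > 0 > mismatch")
        if not (self.gap_open <= self.gap_extend < 0):
            raise ParameterError("require gap_open <= gap_extend < 0")


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    island_start: int
    island_end: int
    score: float
    # (miRNA index, island index, 'WC'|'GU'|'MM'); miRNA indices strictly
    # increasing, island indices strictly decreasing (antiparallel)
    paired_positions: tuple = field(default_factory=tuple)
    seed_pairs: int = 0
    qualifies: bool = False

    def cigarish(self) -> str:
        return ",".join(f"{mi}:{ii}:{t}" for mi, ii, t in self.paired_positions)


def pair_type(mirna_base: str, island_base: str) -> str:
    """'WC', 'GU' or 'MM' for an (RNA, DNA) base pair."""
    key = (mirna_base, island_base)
    if key in WC_PAIRS:
        return "WC"
    if key in GU_PAIRS:
        return "GU"
    return "MM"


def _pair_score(a: str, b: str, params: DuplexParams) -> float:
    t = pair_type(a, b)
    if t == "WC":
        return params.match_wc
    if t == "GU":
        return params.match_gu
    return params.mismatch


def align_duplex(
    mirna: MatureMiRNA | str,
    island_seq: str,
    params: DuplexParams = DuplexParams(),
    island_offset: int = 0,
) -> DuplexAlignment:
    """Optimal local antiparallel complementarity alignment (Gotoh DP).

    ``island_offset`` shifts reported island coordinates (so an island cut
    from a UTR reports UTR positions). Tie-breaks are deterministic: highest
    score, then the end cell earliest on the miRNA and then on the (reversed)
    island; the traceback prefers pairing over gaps.
    """
    if isinstance(mirna, MatureMiRNA):
        mid, mseq = mirna.mirna_id, mirna.sequence
    else:
        mid, mseq = "", mirna
    if len(island_seq) < 8:
        raise ParameterError("island sequence must be at least 8 nt")
    tseq = island_seq.upper().replace("U", "T")[::-1]  # 3'->5', so both ascend
    n, m = len(mseq), len(tseq)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in miRNA (island base unpaired)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in island
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        row_m = mseq[i - 1]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] + params.gap_open, Ei[j - 1] + params.gap_extend)
            f = max(Hi1[j] + params.gap_open, Fi1[j] + params.gap_extend)
            d = Hi1[j - 1] + _pair_score(row_m, tseq[j - 1], params)
            h = max(0.0, d, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0.0:
        return DuplexAlignment(mid, island_offset, island_offset, 0.0)

    pairs: list[tuple[int, int, str]] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0.0:
                break
            d = H[i - 1][j - 1] + _pair_score(mseq[i - 1], tseq[j - 1], params)
            if h == d:
                pairs.append((i - 1, j - 1, pair_type(mseq[i - 1], tseq[j - 1])))
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i][j] == H[i][j - 1] + params.gap_open:
                state = "H"
            j -= 1
        else:
            if F[i][j] == H[i - 1][j] + params.gap_open:
                state = "H"
            i -= 1
    pairs.reverse()
    # map reversed-island indices back to original island coordinates
    mapped = tuple(
        (mi, island_offset + (len(island_seq) - 1 - ji), t) for mi, ji, t in pairs
    )
    seed_lo, seed_hi = params.seed_start - 1, params.seed_end - 1
    seed_pairs = sum(
        1 for mi, _, t in mapped
        if seed_lo <= mi <= seed_hi
        and (t == "WC" or (t == "GU" and params.seed_counts_wobble))
    )
    ii = [p[1] for p in mapped]
    return DuplexAlignment(
        mid,
        island_start=min(ii),
        island_end=max(ii) + 1,
        score=best,
        paired_positions=mapped,
        seed_pairs=seed_pairs,
        qualifies=(best >= params.min_report_score
                   and seed_pairs >= params.seed_min_pairs),
    )


def best_seeded_score(
    mirna: MatureMiRNA | str,
    island_seq: str,
    params: DuplexParams = DuplexParams(),
) -> float | None:
    """Best local alignment score among alignments with at least
    ``seed_min_pairs`` seed pairs, or ``None`` when no such alignment has
    positive score.

    Unlike :func:`align_duplex`, which reports the single optimal alignment,
    this searches the full alignment space under the seed constraint (a
    qualifying alignment can be shadowed by a higher-scoring alignment that
    fails the seed gate). Used to certify that a sequence has *no*
    qualifying alignment anywhere in a region.
    """
    mseq = mirna.sequence if isinstance(mirna, MatureMiRNA) else mirna
    tseq = island_seq.upper().replace("U", "T")[::-1]
    n, m = len(mseq), len(tseq)
    K = params.seed_min_pairs
    seed_lo, seed_hi = params.seed_start - 1, params.seed_end - 1
    NEG = float("-inf")
    # [k][j] layers, k = seed pairs capped at K; rows swept over i
    H = [[NEG] * (m + 1) for _ in range(K + 1)]
    E = [[NEG] * (m + 1) for _ in range(K + 1)]
    F = [[NEG] * (m + 1) for _ in range(K + 1)]
    for j in range(m + 1):
        H[0][j] = 0.0
    best = NEG
    for i in range(1, n + 1):
        a = mseq[i - 1]
        in_seed = seed_lo <= i - 1 <= seed_hi
        newH = [[NEG] * (m + 1) for _ in range(K + 1)]
        newE = [[NEG] * (m + 1) for _ in range(K + 1)]
        newF = [[NEG] * (m + 1) for _ in range(K + 1)]
        for k in range(K + 1):
            newH[k][0] = 0.0 if k == 0 else NEG
        for k in range(K + 1):
            Hk, Ek, Fk = newH[k], newE[k], newF[k]
            prevHk, prevFk = H[k], F[k]
            for j in range(1, m + 1):
                e = max(Hk[j - 1] + params.gap_open, Ek[j - 1] + params.gap_extend)
                f = max(prevHk[j] + params.gap_open, prevFk[j] + params.gap_extend)
                t = pair_type(a, tseq[j - 1])
                counts = in_seed and (t == "WC" or
                                      (t == "GU" and params.seed_counts_wobble))
                if counts:
                    if k == 0:
                        d = NEG  # a counting pair cannot keep k at 0
                    else:
                        # k stays capped at K once reached
                        src = H[k - 1][j - 1] if k < K else max(
                            H[k - 1][j - 1], H[k][j - 1])
                        d = src + _pair_score(a, tseq[j - 1], params)
                else:
                    d = H[k][j - 1] + _pair_score(a, tseq[j - 1], params)
                h = max(d, e, f)
                if k == 0:
                    h = max(h, 0.0)
                Ek[j], Fk[j], Hk[j] = e, f, h
                if k == K and h > best:
                    best = h
        H, E, F = newH, newE, newF
    return best if best > 0 else None


def rank_mirnas(
    island_seq: str,
    corpus: list[MatureMiRNA],
    params: DuplexParams = DuplexParams(),
    island_offset: int = 0,
) -> list[DuplexAlignment]:
    """All qualifying alignments of corpus miRNAs to one island, sorted by
    score descending then miRNA id; empty when nothing qualifies."""
    if not corpus:
        raise ParameterError("miRNA corpus must be non-empty")
    out = [
        aln
        for mirna in corpus
        if (aln := align_duplex(mirna, island_seq, params, island_offset)).qualifies
    ]
    out.sort(key=lambda a: (-a.score, a.mirna_id))
    return out
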