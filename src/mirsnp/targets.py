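"""Map miRNA-derived patterns into 3'UTR target space and call target islands.

Patterns discovered on miRNAs (RNA) are matched against UTRs (DNA) as reverse
complements: a pattern's target-space form is its reverse complement
transliterated to DNA, with wildcards self-mapping. Both alleles of every
SNP-bearing UTR are scanned; dense clusters of hits ("target islands") are
the unit passed on to duplex alignment. ``N`` in a UTR never matches a
pattern position, literal or wildcard.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import ParameterError
from .patterns import Pattern, WILDCARD
from .seqio import SNPRecord, UTRRecord

_COMPLEMENT = str.maketrans("ACGUT.", "TGCAA.")


@dataclass(frozen=True)
class AllelicUTR:
    """A UTR with one SNP allele substituted in."""

    base: UTRRecord
    snp: SNPRecord
    applied_allele: str
    sequence: str


@dataclass(frozen=True)
class PatternHit:
    pattern_motif: str  # target-space (DNA) motif
    start: int
    end: int  # half-open; end - start == len(motif)
    allele_context: str


@dataclass(frozen=True)
class TargetIsland:
    start: int
    end: int
    hit_count: int
    overlaps_snp: bool


def target_space_pattern(p: Pattern | str) -> str:
    """Reverse-complement a motif into DNA space ('.' maps to itself).

    Applying it twice returns the U->T transliteration of the original.
    """
    motif = p.motif if isinstance(p, Pattern) else p
    return motif.translate(_COMPLEMENT)[::-1]


def apply_allele(utr: UTRRecord, snp: SNPRecord, allele: str) -> AllelicUTR:
    """Substitute ``allele`` at the SNP offset; the input record is untouched."""
    if allele not in snp.alleles:
        raise ParameterError(
            f"allele {allele!r} not among SNP {snp.rsid} alleles {snp.alleles}"
        )
    if not (0 <= snp.utr_offset < len(utr.sequence)):
        raise ParameterError(
            f"SNP {snp.rsid} offset {snp.utr_offset} outside UTR "
            f"{utr.transcript_id} (length {len(utr.sequence)})"
        )
    seq = utr.sequence
    new_seq = seq[: snp.utr_offset] + allele + seq[snp.utr_offset + 1:]
    return AllelicUTR(utr, snp, allele, new_seq)


def scan_hits(autr: AllelicUTR | str, patterns: list[str],
              allele_context: str | None = None) -> list[PatternHit]:
    """Report every match position of every target-space motif (overlapping
    matches included), sorted by (start, motif).

    Wildcards match A/C/G/T only; N matches nothing.
    """
    if isinstance(autr, AllelicUTR):
        seq = autr.sequence
        ctx = autr.applied_allele if allele_context is None else allele_context
    else:
        seq = autr
        ctx = allele_context or ""
    hits: list[PatternHit] = []
    for motif in patterns:
        rx = re.compile("(?=(%s))" % "".join(
            "[ACGT]" if c == WILDCARD else re.escape(c) for c in motif
        ))
        for m in rx.finditer(seq):
            hits.append(PatternHit(motif, m.start(), m.start() + len(motif), ctx))
    hits.sort(key=lambda h: (h.start, h.pattern_motif))
    return hits


def call_islands(
    hits: list[PatternHit],
    utr_len: int,
    window: int = 25,
    min_island_hits: int = 5,
    snp_offset: int | None = None,
) -> list[TargetIsland]:
    """Cluster hits into target islands.

    Every group of >= ``min_island_hits`` hit-starts falling within one
    ``window``-length span yields a candidate island spanning from the
    group's first hit start to its last hit end; overlapping candidates are
    merged. ``overlaps_snp`` flags islands containing ``snp_offset``.
    """
    if window < 1 or min_island_hits < 1:
        raise ParameterError("window and min_island_hits must be >= 1")
    if not hits:
        return []
    starts = [h.start for h in hits]
    ends = [h.end for h in hits]
    intervals: list[tuple[int, int]] = []
    # anchoring candidate windows at hit starts is exhaustive: shifting any
    # qualifying span right to its first hit start keeps all its hits
    n = len(hits)
    j = 0
    for i in range(n):
        lo = starts[i]
        j = max(j, i)
        while j < n and starts[j] < lo + window:
            j += 1
        if j - i >= min_island_hits:
            intervals.append((lo, max(ends[i:j])))
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    islands = []
    for s, e in merged:
        count = sum(1 for h in hits if s <= h.start < e)
        islands.append(
            TargetIsland(
                s, min(e, utr_len), count,
                snp_offset is not None and s <= snp_offset < e,
            )
        )
    return islands


def islands_to_bed(islands: list[TargetIsland], transcript_id: str,
                   name: str) -> str:
    """Serialize islands as BED lines (transcript-relative, 0-based half-open,
    score = hit count)."""
    return "".join(
        f"{transcript_id}\t{i.start}\t{i.end}\t{name}\t{i.hit_count}\t+\n"
        for i in islands
    )
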