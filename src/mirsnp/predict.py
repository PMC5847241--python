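"""Pipeline orchestration: from raw inputs to per-SNP allele verdicts.

For every retained SNP, both allelic versions of the host 3'UTR are scanned
with the significant target-space patterns; SNP-overlapping target islands
are ranked against the miRNA corpus by duplex alignment; the best qualifying
score per allele drives the verdict:

``stronger:<allele>``
    one allele's best score exceeds the other's by more than ``epsilon``
    (an allele with no qualifying alignment contributes score 0);
``equal``
    both alleles have qualifying alignments and the score gap is within
    ``epsilon``;
``island_no_alignment``
    at least one island overlaps the SNP but no miRNA qualifies for either
    allele;
``no_island``
    no island overlaps the SNP in either allelic context.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from . import seqio
from .config import RunConfig
from .duplex import DuplexAlignment, rank_mirnas
from .errors import ParameterError
from .patterns import discover_patterns, fit_background, keep_significant
from .seqio import MatureMiRNA, SNPRecord, UTRRecord
from .targets import apply_allele, call_islands, scan_hits, target_space_pattern

logger = logging.getLogger(__name__)

VERDICT_EQUAL = "equal"
VERDICT_NO_ISLAND = "no_island"
VERDICT_ISLAND_NO_ALIGNMENT = "island_no_alignment"


@dataclass(frozen=True)
class MirSNPCall:
    rsid: str
    gene: str
    alleles: tuple[str, str]
    per_allele_best: dict[str, DuplexAlignment | None]
    mirnas: tuple[str, ...]
    verdict: str
    delta: float


def classify(
    best_a: float | None,
    best_b: float | None,
    epsilon: float,
    allele_a: str = "A",
    allele_b: str = "B",
    islands_present: bool = True,
) -> str:
    """Verdict from the two per-allele best qualifying scores.

    ``None`` means the allele had no qualifying alignment; it competes with
    score 0, so an intact site always beats an ablated one. Symmetric: the
    stronger allele is named identically regardless of argument order.
    """
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    if best_a is None and best_b is None:
        return VERDICT_ISLAND_NO_ALIGNMENT if islands_present else VERDICT_NO_ISLAND
    sa = 0.0 if best_a is None else best_a
    sb = 0.0 if best_b is None else best_b
    if abs(sa - sb) <= epsilon:
        return VERDICT_EQUAL
    return f"stronger:{allele_a if sa > sb else allele_b}"


def predict_mirsnp(
    utr: UTRRecord,
    snp: SNPRecord,
    target_patterns: list[str],
    corpus: list[MatureMiRNA],
    config: RunConfig = RunConfig(),
) -> MirSNPCall:
    """Evaluate one SNP: substitute each allele, scan, call islands, rank
    miRNAs on SNP-overlapping islands, and classify the allele pair.

    ``target_patterns`` must already be in target (DNA) space.
    """
    if snp.transcript_id != utr.transcript_id:
        raise ParameterError(
            f"SNP {snp.rsid} is on {snp.transcript_id}, not {utr.transcript_id}"
        )
    best: dict[str, DuplexAlignment | None] = {}
    any_island = False
    for allele in snp.alleles:
        autr = apply_allele(utr, snp, allele)
        hits = scan_hits(autr, target_patterns)
        islands = call_islands(
            hits, len(autr.sequence), config.window, config.min_island_hits,
            snp_offset=snp.utr_offset,
        )
        snp_islands = [isl for isl in islands if isl.overlaps_snp]
        any_island = any_island or bool(snp_islands)
        allele_best: DuplexAlignment | None = None
        for isl in snp_islands:
            ranked = rank_mirnas(
                autr.sequence[isl.start:isl.end], corpus, config.duplex,
                island_offset=isl.start,
            )
            if ranked and (allele_best is None or ranked[0].score > allele_best.score):
                allele_best = ranked[0]
        best[allele] = allele_best
    a, b = snp.alleles
    verdict = classify(
        None if best[a] is None else best[a].score,
        None if best[b] is None else best[b].score,
        config.epsilon, allele_a=a, allele_b=b, islands_present=any_island,
    )
    sa = 0.0 if best[a] is None else best[a].score
    sb = 0.0 if best[b] is None else best[b].score
    mirnas = tuple(sorted({aln.mirna_id for aln in best.values() if aln is not None}))
    return MirSNPCall(snp.rsid, utr.gene, snp.alleles, best, mirnas, verdict,
                      abs(sa - sb))


def prepare_target_patterns(
    corpus: list[MatureMiRNA], config: RunConfig
) -> tuple[list, list[str]]:
    """Discover patterns on the corpus, keep the significant ones, and map
    them to target space. Returns (significant patterns, target motifs)."""
    patterns = discover_patterns(corpus, config.L, config.W, config.min_support)
    model = fit_background(corpus, config.markov_order)
    significant = keep_significant(
        patterns, model, len(corpus), [len(m) for m in corpus],
        min_log_odds=config.min_log_odds, n_null=config.n_null, seed=config.seed,
    )
    return significant, [target_space_pattern(p) for p in significant]


def run_pipeline(
    mirna_fasta,
    utr_fasta,
    snp_table,
    config: RunConfig = RunConfig(),
    out_dir=None,
    snp_format: str = "tsv",
) -> list[MirSNPCall]:
    """Full prediction run: read inputs, discover significant patterns,
    evaluate every retained SNP, optionally write the report.

    Deterministic for fixed inputs + config (the config seed drives the only
    stochastic step, the Monte Carlo significance null).
    """
    corpus = seqio.read_fasta(mirna_fasta, alphabet="rna")
    utrs = {u.transcript_id: u for u in seqio.read_fasta(utr_fasta, alphabet="dna")}
    snps = seqio.read_snp_table(snp_table, format=snp_format,
                                maf_min=config.maf_min, utrs=utrs)
    if not corpus:
        raise ParameterError("miRNA corpus is empty", stage="mirsnp_predict")
    significant, target_patterns = prepare_target_patterns(corpus, config)
    logger.info("pipeline: %d significant patterns, %d SNPs", len(significant),
                len(snps))
    calls = []
    for snp in snps:
        utr = utrs[snp.transcript_id]
        calls.append(predict_mirsnp(utr, snp, target_patterns, corpus, config))
    summary = Counter(call.verdict.split(":")[0] for call in calls)
    logger.info("pipeline verdicts: %s", dict(summary))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seqio.write_mirsnp_report(calls, out / "mirsnp_report.tsv")
        config.to_file(out / "config_echo.txt")
    return calls
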