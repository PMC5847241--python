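"""Input/output for every external format the pipeline touches.

Conventions
-----------
* All internal coordinates are 0-based, half-open. Conversion to/from the
  1-based convention happens only at the VCF boundary.
* 3'UTRs are stored as DNA (sense strand, 5'->3'); mature miRNAs as RNA.
* The ambiguity code ``N`` is tolerated in UTRs and never matches a pattern
  literal or wildcard downstream.

Formats: FASTA (miRNAs, UTRs), VCF 4.x or a 6-column TSV for SNPs,
a PED-style pedigree table (family, individual, father, mother, sex, then one
allele pair per SNP, ``0`` = missing), and the tab-separated MirSNP report.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import AlphabetError, ParameterError, ParseError, PedigreeError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

_MISSING = None  # missing genotype sentinel


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3', RNA alphabet."""

    mirna_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise AlphabetError(f"miRNA {self.mirna_id!r} has empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"miRNA {self.mirna_id!r} contains non-RNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UTRRecord:
    """A 3'UTR sequence on the sense strand (DNA alphabet, may contain N)."""

    transcript_id: str
    sequence: str
    gene: str = ""
    source_note: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise AlphabetError(f"UTR {self.transcript_id!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"UTR {self.transcript_id!r} contains non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP located inside a host 3'UTR.

    ``utr_offset`` is the 0-based position in the host UTR sequence;
    ``alleles`` is an ordered pair of single bases, one of which should equal
    the base found in the UTR at that offset (the in-sequence allele).
    """

    rsid: str
    transcript_id: str
    utr_offset: int
    alleles: tuple[str, str]
    maf: float

    def __post_init__(self):
        a, b = self.alleles
        if a == b:
            raise ParameterError(f"SNP {self.rsid}: alleles must be distinct")
        if not (0.0 <= self.maf <= 0.5):
            raise ParameterError(f"SNP {self.rsid}: MAF {self.maf} outside [0, 0.5]")


@dataclass
class PedigreeGenotypes:
    """Pedigree structure plus per-(individual, SNP) unordered allele pairs.

    ``individuals`` preserves file order; ``genotypes[(iid, snp_id)]`` is a
    sorted 2-tuple of allele strings, or ``None`` when missing.
    """

    individuals: list[tuple[str, str, str, str]]  # (iid, father, mother, family)
    snp_ids: list[str]
    genotypes: dict[tuple[str, str], tuple[str, str] | None]
    sexes: dict[str, str] = field(default_factory=dict)

    def ids(self) -> list[str]:
        return [iid for iid, *_ in self.individuals]

    def copy(self) -> "PedigreeGenotypes":
        return PedigreeGenotypes(
            individuals=list(self.individuals),
            snp_ids=list(self.snp_ids),
            genotypes=dict(self.genotypes),
            sexes=dict(self.sexes),
        )


# ---------------------------------------------------------------------------
# sequence normalization
# ---------------------------------------------------------------------------

def normalize_rna(seq: str) -> str:
    """Uppercase and transliterate T->U. Idempotent, length preserving."""
    up = seq.upper().replace("T", "U")
    bad = set(up) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal RNA characters {sorted(bad)} in sequence")
    return up


def normalize_dna(seq: str) -> str:
    """Uppercase and transliterate U->T; allows N."""
    up = seq.upper().replace("U", "T")
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"illegal DNA characters {sorted(bad)} in sequence")
    return up


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str = "rna") -> list:
    """Read a FASTA file into :class:`MatureMiRNA` (rna) or :class:`UTRRecord`
    (dna) records, preserving file order.

    Raises :class:`ParseError` (with line number) when sequence data precedes
    the first header, and :class:`AlphabetError` naming the offending record
    for illegal characters after normalization. Duplicate IDs are tolerated
    with a logged warning.
    """
    if alphabet not in ("rna", "dna"):
        raise ParameterError(f"alphabet must be 'rna' or 'dna', got {alphabet!r}")
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise ParseError(
                f"{path}: sequence data before first FASTA header at line {lineno}",
                stage="seqio",
            )
        break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in seen:
            logger.warning("duplicate FASTA id %r in %s", rec.id, path)
        seen.add(rec.id)
        seq = str(rec.seq)
        try:
            if alphabet == "rna":
                records.append(MatureMiRNA(rec.id, normalize_rna(seq)))
            else:
                # optional second header token carries the gene symbol
                tokens = rec.description.split()
                gene = tokens[1] if len(tokens) > 1 else ""
                records.append(UTRRecord(rec.id, normalize_dna(seq), gene=gene))
        except AlphabetError as exc:
            raise AlphabetError(f"record {rec.id!r}: {exc}", stage="seqio") from exc
    return records


def write_fasta(records: Iterable, path) -> None:
    """Write records with ``.sequence`` and an id attribute, one line per
    sequence (deterministic bytes, exact round trip with :func:`read_fasta`)."""
    with open(path, "w") as fh:
        for rec in records:
            rid = getattr(rec, "mirna_id", None) or getattr(rec, "transcript_id")
            gene = getattr(rec, "gene", "")
            header = f">{rid} {gene}" if gene else f">{rid}"
            fh.write(f"{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(
    path,
    format: str = "tsv",
    maf_min: float = 0.03,
    utrs: dict[str, UTRRecord] | None = None,
    transcript_map: dict[str, str] | None = None,
) -> list[SNPRecord]:
    """Read SNPs from a 6-column TSV or a VCF and apply the MAF filter.

    TSV columns: rsid, transcript_id, utr_offset (0-based), allele1, allele2,
    maf. VCF: CHROM is mapped to a transcript id via ``transcript_map`` (or
    used verbatim) and POS (1-based within the UTR) is converted to a 0-based
    offset. Records are kept when ``maf >= maf_min`` (inclusive, matching the
    published >= 0.03 rule); non-biallelic records and records whose offset
    falls outside the host UTR (when ``utrs`` is given) are skipped with a
    warning.
    """
    if format == "tsv":
        raw = _read_snp_tsv(path)
    elif format == "vcf":
        raw = _read_snp_vcf(path, transcript_map or {})
    else:
        raise ParameterError(f"unknown SNP table format {format!r}")

    kept: list[SNPRecord] = []
    n_maf = n_range = 0
    for rec in raw:
        if utrs is not None:
            host = utrs.get(rec.transcript_id)
            if host is None or not (0 <= rec.utr_offset < len(host)):
                logger.warning(
                    "SNP %s: offset %d outside host UTR %s; skipped",
                    rec.rsid, rec.utr_offset, rec.transcript_id,
                )
                n_range += 1
                continue
        if rec.maf < maf_min:
            n_maf += 1
            continue
        kept.append(rec)
    logger.info(
        "read_snp_table: %d kept, %d below MAF %g, %d out of range",
        len(kept), n_maf, maf_min, n_range,
    )
    return kept


def _read_snp_tsv(path) -> list[SNPRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}",
                    stage="seqio",
                )
            rsid, tx, off, a1, a2, maf = parts
            a1, a2 = a1.upper(), a2.upper()
            if len(a1) != 1 or len(a2) != 1 or a1 == a2:
                logger.warning("SNP %s: not biallelic single-base; skipped", rsid)
                continue
            out.append(SNPRecord(rsid, tx, int(off), (a1, a2), float(maf)))
    return out


def _read_snp_vcf(path, transcript_map: dict[str, str]) -> list[SNPRecord]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for var in vf.fetch() if vf.index is not None else vf:
            if var.alts is None or len(var.alts) != 1:
                logger.warning("VCF %s: non-biallelic record; skipped", var.id)
                continue
            ref, alt = var.ref.upper(), var.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                logger.warning("VCF %s: not a SNP; skipped", var.id)
                continue
            maf = 0.0
            for key in ("MAF", "AF"):
                if key in var.info:
                    maf = var.info[key]
                    break
            if isinstance(maf, (tuple, list)):
                maf = maf[0]
            maf = float(maf)
            maf = min(maf, 1.0 - maf)  # fold to minor-allele frequency
            tx = transcript_map.get(var.chrom, var.chrom)
            out.append(
                SNPRecord(var.id or f"{var.chrom}:{var.pos}", tx, var.pos - 1,
                          (ref, alt), maf)
            )
    return out


def write_snp_table(snps: Sequence[SNPRecord], path) -> None:
    with open(path, "w") as fh:
        for s in snps:
            fh.write(
                f"{s.rsid}\t{s.transcript_id}\t{s.utr_offset}\t"
                f"{s.alleles[0]}\t{s.alleles[1]}\t{s.maf:.6g}\n"
            )


# ---------------------------------------------------------------------------
# MirSNP report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ("rsid", "gene", "alleles", "mirnas", "allele_scores", "verdict")


def write_mirsnp_report(calls, path) -> None:
    """Write the per-SNP verdict table (TSV, header row, sorted by rsid)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for call in sorted(calls, key=lambda c: c.rsid):
            scores = ",".join(
                f"{allele}:{best.score:g}" if best is not None else f"{allele}:-"
                for allele, best in call.per_allele_best.items()
            )
            fh.write(
                f"{call.rsid}\t{call.gene}\t{'/'.join(call.alleles)}\t"
                f"{','.join(call.mirnas)}\t{scores}\t{call.verdict}\n"
            )


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def read_ped(path, snp_ids: Sequence[str]) -> PedigreeGenotypes:
    """Read a PED-style table: family, individual, father, mother, sex, then
    one allele pair (two whitespace-separated fields) per SNP; ``0`` = missing.
    """
    individuals: list[tuple[str, str, str, str]] = []
    genotypes: dict[tuple[str, str], tuple[str, str] | None] = {}
    sexes: dict[str, str] = {}
    n_expected = 5 + 2 * len(snp_ids)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != n_expected:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_expected} fields "
                    f"({len(snp_ids)} SNPs), got {len(parts)}",
                    stage="seqio",
                )
            fam, iid, fid, mid, sex = parts[:5]
            individuals.append((iid, fid, mid, fam))
            sexes[iid] = sex
            for k, snp in enumerate(snp_ids):
                a1, a2 = parts[5 + 2 * k], parts[6 + 2 * k]
                if a1 == "0" or a2 == "0":
                    genotypes[(iid, snp)] = _MISSING
                else:
                    genotypes[(iid, snp)] = tuple(sorted((a1, a2)))
    ped = PedigreeGenotypes(individuals, list(snp_ids), genotypes, sexes)
    _check_parent_links(ped, path)
    return ped


def _check_parent_links(ped: PedigreeGenotypes, path="<pedigree>") -> None:
    known = set(ped.ids())
    for iid, fid, mid, fam in ped.individuals:
        for pid in (fid, mid):
            if pid != "0" and pid not in known:
                raise PedigreeError(
                    f"{path}: individual {iid} (family {fam}) references "
                    f"unknown parent {pid}",
                    stage="mendel_qc",
                )


def write_ped(ped: PedigreeGenotypes, path) -> None:
    with open(path, "w") as fh:
        for iid, fid, mid, fam in ped.individuals:
            fields = [fam, iid, fid, mid, ped.sexes.get(iid, "0")]
            for snp in ped.snp_ids:
                g = ped.genotypes.get((iid, snp))
                fields.extend(("0", "0") if g is None else g)
            fh.write(" ".join(fields) + "\n")
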