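"""Pedigree genotype cleaning: per-SNP filters and Mendelian-error removal.

The cleaning stage mirrors standard family-data QC: drop SNPs with low call
rates, monomorphic SNPs, and SNPs with an excess per-trio Mendelian-error
rate; test surviving SNPs for Hardy-Weinberg equilibrium on founders; then
identify the individual genotypes responsible for the remaining trio
inconsistencies and set them missing.

Trio consistency is evaluated for biallelic autosomal SNPs. Trios with a
missing member genotype are judged by marginalization: the combination is an
error only when *no* assignment of the missing genotypes makes it Mendelian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError
from .seqio import PedigreeGenotypes

Genotype = tuple[str, str] | None


@dataclass(frozen=True)
class TrioGenotypeError:
    snp_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_gt: Genotype
    father_gt: Genotype
    mother_gt: Genotype


@dataclass(frozen=True)
class QcThresholds:
    min_completion: float = 0.98
    mendel_error_rate_max: float = 0.01
    hwe_p_min: float = 0.001

    def __post_init__(self):
        for name, v in (("min_completion", self.min_completion),
                        ("mendel_error_rate_max", self.mendel_error_rate_max),
                        ("hwe_p_min", self.hwe_p_min)):
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must be in (0, 1), got {v}")


# ---------------------------------------------------------------------------
# per-SNP summaries
# ---------------------------------------------------------------------------

def completion_rate(ped: PedigreeGenotypes, snp_id: str) -> float:
    ids = ped.ids()
    if not ids:
        raise ParameterError("pedigree has no individuals")
    called = sum(1 for iid in ids if ped.genotypes.get((iid, snp_id)) is not None)
    return called / len(ids)


def is_monomorphic(ped: PedigreeGenotypes, snp_id: str) -> bool:
    """True iff at most one distinct allele is observed (all-missing counts
    as monomorphic, degenerate but droppable)."""
    alleles = set()
    for iid in ped.ids():
        g = ped.genotypes.get((iid, snp_id))
        if g is not None:
            alleles.update(g)
    return len(alleles) <= 1


# ---------------------------------------------------------------------------
# trio consistency
# ---------------------------------------------------------------------------

def trio_consistent(child: Genotype, father: Genotype, mother: Genotype) -> bool:
    """Mendelian consistency of one biallelic trio; missing genotypes are
    marginalized (consistent unless impossible for every completion)."""
    if child is None:
        return True
    c1, c2 = child

    def from_parent(allele: str, parent: Genotype) -> bool:
        return parent is None or allele in parent

    return (from_parent(c1, father) and from_parent(c2, mother)) or (
        from_parent(c2, father) and from_parent(c1, mother)
    )


def find_mendel_errors(ped: PedigreeGenotypes, snp_id: str,
                       ) -> list[TrioGenotypeError]:
    """All child-father-mother combinations at ``snp_id`` that are jointly
    impossible under Mendelian inheritance (single-parent trios use the
    one-known-parent rule implicitly via marginalization)."""
    errors = []
    for iid, fid, mid, _fam in ped.individuals:
        if fid == "0" and mid == "0":
            continue
        gc = ped.genotypes.get((iid, snp_id))
        gf = ped.genotypes.get((fid, snp_id)) if fid != "0" else None
        gm = ped.genotypes.get((mid, snp_id)) if mid != "0" else None
        if not trio_consistent(gc, gf, gm):
            errors.append(TrioGenotypeError(snp_id, iid, fid, mid, gc, gf, gm))
    return errors


def mendel_error_rate(ped: PedigreeGenotypes, snp_id: str) -> float:
    """Error trios / genotyped trios; the denominator excludes trios whose
    child genotype is missing (a trio with a missing child can never err)."""
    n_errors = 0
    n_trios = 0
    for iid, fid, mid, _fam in ped.individuals:
        if fid == "0" and mid == "0":
            continue
        gc = ped.genotypes.get((iid, snp_id))
        if gc is None:
            continue
        n_trios += 1
        gf = ped.genotypes.get((fid, snp_id)) if fid != "0" else None
        gm = ped.genotypes.get((mid, snp_id)) if mid != "0" else None
        if not trio_consistent(gc, gf, gm):
            n_errors += 1
    return n_errors / n_trios if n_trios else 0.0


def remove_error_genotypes(
    ped: PedigreeGenotypes,
    errors: list[TrioGenotypeError],
    policy: str = "trio",
) -> tuple[PedigreeGenotypes, int]:
    """Blank the genotypes implicated in each error trio.

    ``policy='trio'`` sets all three member genotypes missing (the
    conservative, PLINK-like choice); ``policy='child'`` blanks only the
    child. Returns the cleaned copy and the number of genotypes actually
    removed (each genotype counted once even when shared between trios).
    Re-running :func:`find_mendel_errors` on the result yields no errors
    under either policy, since each error trio loses its child genotype.
    """
    if policy not in ("trio", "child"):
        raise ParameterError(f"policy must be 'trio' or 'child', got {policy!r}")
    cleaned = ped.copy()
    removed = 0
    for err in errors:
        members = [err.child_id] if policy == "child" else [
            err.child_id, err.father_id, err.mother_id
        ]
        for iid in members:
            if iid == "0":
                continue
            key = (iid, err.snp_id)
            if cleaned.genotypes.get(key) is not None:
                cleaned.genotypes[key] = None
                removed += 1
    return cleaned, removed


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditional on the observed allele counts, the probabilities of every
    possible heterozygote count are enumerated and those no more probable
    than the observed table are summed (the standard conditional exact test).
    Monomorphic counts give p = 1 (a single possible table).
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    # log P(n_ab | n, n_rare) up to a shared constant
    def log_prob(het: int) -> float:
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return (het * math.log(2.0)
                - math.lgamma(hom_rare + 1)
                - math.lgamma(het + 1)
                - math.lgamma(hom_common + 1))

    hets = [h for h in range(n_rare % 2, n_rare + 1, 2) if n - h - (n_rare - h) // 2 >= 0]
    logs = [log_prob(h) for h in hets]
    mx = max(logs)
    probs = [math.exp(lp - mx) for lp in logs]
    total = sum(probs)
    obs = probs[hets.index(n_ab)]
    # tolerate float noise when deciding "as or less probable"
    p = sum(pr for pr in probs if pr <= obs * (1.0 + 1e-12)) / total
    return min(p, 1.0)


def founders(ped: PedigreeGenotypes) -> list[str]:
    return [iid for iid, fid, mid, _ in ped.individuals if fid == "0" and mid == "0"]


def founder_genotype_counts(ped: PedigreeGenotypes, snp_id: str,
                            ) -> tuple[int, int, int]:
    """(hom-A, het, hom-B) counts among founders, with A the
    lexicographically first observed allele."""
    alleles = sorted(
        {a for iid in founders(ped)
         for g in [ped.genotypes.get((iid, snp_id))] if g is not None for a in g}
    )
    if not alleles:
        return (0, 0, 0)
    a = alleles[0]
    n_aa = n_ab = n_bb = 0
    for iid in founders(ped):
        g = ped.genotypes.get((iid, snp_id))
        if g is None:
            continue
        k = sum(1 for x in g if x == a)
        if k == 2:
            n_aa += 1
        elif k == 1:
            n_ab += 1
        else:
            n_bb += 1
    return (n_aa, n_ab, n_bb)


# ---------------------------------------------------------------------------
# full QC pipeline
# ---------------------------------------------------------------------------

def qc_pipeline(
    ped: PedigreeGenotypes,
    thresholds: QcThresholds = QcThresholds(),
    removal_policy: str = "trio",
) -> tuple[list[str], dict, PedigreeGenotypes, pd.DataFrame]:
    """Apply the SNP filters in order (completion, monomorphic, Mendel-error
    rate, HWE on founders), then remove the genotypes causing Mendelian
    errors on the surviving SNPs.

    Returns (kept snp ids, drop/removal counts, cleaned pedigree, summary
    table). The summary has one row per input SNP with its statistics and
    the action taken.
    """
    drops = {"completion": 0, "monomorphic": 0, "mendel_rate": 0, "hwe": 0}
    kept: list[str] = []
    rows = []
    for snp in ped.snp_ids:
        comp = completion_rate(ped, snp)
        mono = is_monomorphic(ped, snp)
        rate = mendel_error_rate(ped, snp)
        hwe = hwe_exact_p(*founder_genotype_counts(ped, snp))
        if comp < thresholds.min_completion:
            action = "drop:completion"
            drops["completion"] += 1
        elif mono:
            action = "drop:monomorphic"
            drops["monomorphic"] += 1
        elif rate > thresholds.mendel_error_rate_max:
            action = "drop:mendel_rate"
            drops["mendel_rate"] += 1
        elif hwe <= thresholds.hwe_p_min:
            action = "drop:hwe"
            drops["hwe"] += 1
        else:
            action = "keep"
            kept.append(snp)
        rows.append({"snp_id": snp, "completion": comp, "monomorphic": mono,
                     "mendel_rate": rate, "hwe_p": hwe, "action": action})
    cleaned = ped.copy()
    cleaned.snp_ids = kept
    cleaned.genotypes = {
        (iid, snp): g for (iid, snp), g in ped.genotypes.items() if snp in set(kept)
    }
    n_removed = 0
    for snp in kept:
        errs = find_mendel_errors(cleaned, snp)
        cleaned, k = remove_error_genotypes(cleaned, errs, policy=removal_policy)
        n_removed += k
    counts = {"dropped": drops, "genotypes_removed": n_removed,
              "snps_kept": len(kept)}
    return kept, counts, cleaned, pd.DataFrame(rows)
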