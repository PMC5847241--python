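"""Synthetic fixtures with the statistical structure each stage assumes.

Every generator is a pure function of (spec, seed): labeled substreams are
derived from the seed so adding a generator never perturbs existing outputs,
and identical seeds give byte-identical files.

The MirSNP fixtures emulate the structure the prediction pipeline relies on:

* a miRNA corpus in which a *planted* miRNA shares staggered 6-nt segments
  with a carrier fraction of the corpus (the way miRNA family members share
  sequence), so pattern discovery recovers the segments as significant
  patterns;
* a 3'UTR carrying the exact DNA reverse complement of the planted miRNA, so
  the segments' target-space forms tile the site and island calling fires;
* a SNP inside the site whose in-sequence allele preserves a Watson-Crick
  pair and whose alternate allele breaks it (neither Watson-Crick nor G:U).

Carrier insertions are restricted to miRNA offsets >= 10 (the 3' region), so
a carrier can pair a site only through 3' blocks that never satisfy the seed
gate — qualification is reserved for the planted miRNA by construction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .seqio import (MatureMiRNA, PedigreeGenotypes, SNPRecord, UTRRecord,
                    write_fasta, write_ped, write_snp_table)

RNA = "ACGU"
DNA = "ACGT"

_WC_SITE = {"A": "T", "C": "G", "G": "C", "U": "A"}  # miRNA base -> WC site base
_WOBBLE_SITE = {"G": "T", "U": "G"}  # miRNA base -> wobble site base


def substream(seed: int, label: str) -> np.random.Generator:
    """Stable labeled child stream of ``seed``."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def random_seq(rng: np.random.Generator, length: int, alphabet: str = RNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def revcomp_site(mirna_seq: str) -> str:
    """Exact DNA reverse complement of an RNA sequence (a perfect site)."""
    return "".join(_WC_SITE[b] for b in reversed(mirna_seq))


def nonpairing_site_bases(mirna_base: str) -> list[str]:
    """Site (DNA) bases that neither Watson-Crick- nor wobble-pair the given
    miRNA base, sorted for determinism."""
    banned = {_WC_SITE[mirna_base]}
    if mirna_base in _WOBBLE_SITE:
        banned.add(_WOBBLE_SITE[mirna_base])
    return sorted(set(DNA) - banned)


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    mirna_index: int
    utr_index: int
    offset: int
    snp_offset_within_site: int
    rsid: str
    disrupting_allele: str | None = None  # None -> first non-pairing base


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_mirnas: int = 30
    mirna_len: int = 22
    planted_motif: str | tuple[str, ...] | None = None
    motif_carrier_fraction: float = 0.3
    n_utrs: int = 5
    utr_len: int = 300
    planted_sites: tuple[PlantedSite, ...] = ()
    n_families: int = 40
    children_per_family: int = 2
    mendel_error_rate: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self):
        for name in ("motif_carrier_fraction", "mendel_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# miRNA corpus
# ---------------------------------------------------------------------------

def gen_mirna_corpus(spec: FixtureSpec) -> list[MatureMiRNA]:
    """IID uniform miRNAs; each planted motif is embedded at a random
    position in a ``motif_carrier_fraction`` subset of them."""
    rng = substream(spec.seed, "mirna_corpus")
    seqs = [random_seq(rng, spec.mirna_len) for _ in range(spec.n_mirnas)]
    motifs = spec.planted_motif
    if motifs:
        if isinstance(motifs, str):
            motifs = (motifs,)
        n_carriers = round(spec.motif_carrier_fraction * spec.n_mirnas)
        for motif in motifs:
            if len(motif) > spec.mirna_len:
                raise ParameterError("planted motif longer than miRNA length")
            carriers = rng.choice(spec.n_mirnas, size=n_carriers, replace=False)
            for ci in carriers:
                pos = int(rng.integers(0, spec.mirna_len - len(motif) + 1))
                s = seqs[ci]
                seqs[ci] = s[:pos] + motif + s[pos + len(motif):]
    return [MatureMiRNA(f"syn-miR-{i + 1}", s) for i, s in enumerate(seqs)]


# ---------------------------------------------------------------------------
# UTRs + SNPs
# ---------------------------------------------------------------------------

def gen_snp_utrs(
    spec: FixtureSpec, corpus: list[MatureMiRNA],
) -> tuple[list[UTRRecord], list[SNPRecord]]:
    """Random UTRs with planted perfect sites and site-disrupting SNPs.

    Each planted site is the exact DNA reverse complement of its miRNA; the
    SNP's in-sequence allele keeps the site perfect, the alternate allele
    breaks one Watson-Crick pair (and is never a wobble partner). SNPs for
    UTRs without a planted site are placed at random offsets. MAF is drawn
    uniform on [0.03, 0.5] so every record passes the default MAF filter.
    """
    rng = substream(spec.seed, "snp_utrs")
    utr_seqs = [random_seq(rng, spec.utr_len, DNA) for _ in range(spec.n_utrs)]
    snps: list[SNPRecord] = []
    sited = set()
    for site in spec.planted_sites:
        mirna = corpus[site.mirna_index]
        site_seq = revcomp_site(mirna.sequence)
        if site.offset + len(site_seq) > spec.utr_len:
            raise ParameterError("planted site exceeds UTR bounds")
        u = utr_seqs[site.utr_index]
        utr_seqs[site.utr_index] = (
            u[: site.offset] + site_seq + u[site.offset + len(site_seq):]
        )
        sited.add(site.utr_index)
        snp_off = site.offset + site.snp_offset_within_site
        mirna_pos = len(mirna) - 1 - site.snp_offset_within_site
        ref = site_seq[site.snp_offset_within_site]
        alt = site.disrupting_allele or nonpairing_site_bases(
            mirna.sequence[mirna_pos])[0]
        if alt == ref:
            raise ParameterError("disrupting allele equals the in-sequence allele")
        snps.append(SNPRecord(site.rsid, f"utr{site.utr_index + 1}", snp_off,
                              (ref, alt), float(round(rng.uniform(0.03, 0.5), 4))))
    for ui in range(spec.n_utrs):
        if ui in sited:
            continue
        off = int(rng.integers(0, spec.utr_len))
        ref = utr_seqs[ui][off]
        alt = str(rng.choice(sorted(set(DNA) - {ref})))
        snps.append(SNPRecord(f"rs_syn_{ui + 1}", f"utr{ui + 1}", off,
                              (ref, alt), float(round(rng.uniform(0.03, 0.5), 4))))
    utrs = [UTRRecord(f"utr{i + 1}", s, gene=f"GENE{i + 1}")
            for i, s in enumerate(utr_seqs)]
    return utrs, snps


# ---------------------------------------------------------------------------
# planted-family MirSNP fixtures
# ---------------------------------------------------------------------------

SEGMENT_LEN = 6
SEGMENT_STRIDE = 4
CARRIERS_PER_SEGMENT = 9
CARRIER_SLOTS = (12, 19)  # insertion offsets in carriers; both >= 10 (3' region)
PLANTED_LEN = 26


def fixture_run_config(seed: int):
    """Analysis configuration matched to the planted-family fixtures.

    These corpora are small (tens of sequences) and family segments are
    6-mers carried by 9-10 members, so the discovery parameters differ from
    the genome-scale defaults: (L=6, W=6) restricts patterns to contiguous
    6-mers and longer — exactly the granularity of the planted family
    sharing — which keeps the coincidence tail of shorter and wildcarded
    sub-patterns out of the island stage; support >= 8 then admits only the
    family segments (a chance 6-mer shared by 8 of ~70 random 26-mers is
    essentially impossible). The duplex reporting threshold of 80 (16 net
    Watson-Crick pairs) sits far below the planted sites' scores (112-130
    for a 26-nt duplex) and far above the chance-alignment tail of random
    26-nt sequences (rarely past ~70 even with wobble). The Monte Carlo
    null uses 50 replicate corpora.
    """
    import dataclasses

    from .config import RunConfig

    cfg = RunConfig(L=6, W=6, min_support=8, n_null=50, seed=seed)
    cfg.duplex = dataclasses.replace(cfg.duplex, min_report_score=80.0)
    return cfg


def _segments(seq: str) -> list[str]:
    return [seq[o: o + SEGMENT_LEN]
            for o in range(0, len(seq) - SEGMENT_LEN + 1, SEGMENT_STRIDE)]


def _build_carrier_corpus(rng: np.random.Generator, planted: list[str],
                          extra_segment_sources: list[str]) -> list[str]:
    """Fillers carrying every segment of every source sequence, 9 distinct
    carriers per segment, at most two insertion slots per filler.

    Carrier subsets are drawn independently per segment (with 30% slack
    fillers so assignment never deadlocks); if two segments shared an
    identical carrier set, their concatenation would tie the segments'
    support and displace them from the maximal-pattern output."""
    # (segment, exclusive) pairs; segments of "exclusive" sources may not
    # share a filler with another segment of the same source — two segments
    # adjacent in their source would otherwise form a long contiguous
    # complementary core against that source's site
    tagged = [(s, False) for src in planted for s in _segments(src)] + [
        (s, True) for src in extra_segment_sources for s in _segments(src)
    ]
    tagged.sort(key=lambda t: not t[1])  # exclusive segments placed first
    n_insertions = len(tagged) * CARRIERS_PER_SEGMENT
    n_fillers = -(-int(n_insertions * 1.3) // len(CARRIER_SLOTS))  # ceil
    fillers = [random_seq(rng, PLANTED_LEN) for _ in range(n_fillers)]
    free_slots = [list(CARRIER_SLOTS) for _ in range(n_fillers)]
    has_exclusive = [False] * n_fillers
    for seg, exclusive in tagged:
        chosen: set[int] = set()
        for _ in range(CARRIERS_PER_SEGMENT):
            cands = [i for i in range(n_fillers)
                     if free_slots[i] and i not in chosen
                     and not (exclusive and has_exclusive[i])]
            fi = int(rng.choice(cands))
            chosen.add(fi)
            if exclusive:
                has_exclusive[fi] = True
            slot = free_slots[fi].pop(int(rng.integers(0, len(free_slots[fi]))))
            s = fillers[fi]
            fillers[fi] = s[:slot] + seg + s[slot + SEGMENT_LEN:]
    return fillers


def gen_recovery_fixture(seed: int, utr_len: int = 300, out_dir=None) -> dict:
    """One planted miRNA, one perfect site, one seed-ablating SNP.

    The SNP sits at miRNA seed position 7 (1-based), inside the exclusive
    footprint of a single carrier segment, so the alternate allele breaks one
    seed Watson-Crick pair and removes exactly one island hit. Returns the
    fixture objects plus ground truth (planted miRNA id, intact allele).
    """
    rng = substream(seed, "recovery_fixture")
    planted_seq = random_seq(rng, PLANTED_LEN)
    fillers = _build_carrier_corpus(rng, [planted_seq], [])
    corpus = [MatureMiRNA("syn-miR-planted", planted_seq)] + [
        MatureMiRNA(f"syn-miR-{i + 1}", s) for i, s in enumerate(fillers)
    ]
    mirna_pos = 6  # 0-based; 1-based position 7, within the 2-8 seed
    site_idx = PLANTED_LEN - 1 - mirna_pos
    site_offset = int(rng.integers(30, utr_len - PLANTED_LEN - 30))
    spec = FixtureSpec(
        seed=seed, n_utrs=1, utr_len=utr_len,
        planted_sites=(PlantedSite(0, 0, site_offset, site_idx, "rs_planted"),),
    )
    utrs, snps = gen_snp_utrs(spec, corpus)
    fx = {
        "corpus": corpus, "utrs": utrs, "snps": snps,
        "truth": {
            "planted_mirna": "syn-miR-planted",
            "rsid": "rs_planted",
            "intact_allele": snps[0].alleles[0],
            "site_interval": [site_offset, site_offset + PLANTED_LEN],
        },
    }
    if out_dir is not None:
        _write_fixture(fx, out_dir)
    return fx


def _no_align_regions(utr_seq: str, site_offset: int, snp_offset: int,
                      alleles: tuple[str, str], flank: int = 12) -> list[str]:
    lo = max(0, site_offset - flank)
    hi = min(len(utr_seq), site_offset + PLANTED_LEN + flank)
    return [
        (utr_seq[:snp_offset] + allele + utr_seq[snp_offset + 1:])[lo:hi]
        for allele in alleles
    ]


def _has_qualifying(seq: str, regions: list[str]) -> bool:
    from .duplex import best_seeded_score

    params = fixture_run_config(0).duplex
    for region in regions:
        score = best_seeded_score(seq, region, params)
        if score is not None and score >= params.min_report_score:
            return True
    return False


def _harden_no_align_site(
    carrier_seqs: list[str],
    regions: list[str],
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> list[str]:
    """Negative-control hardening: reroll carriers' 5' seed bases until no
    carrier admits *any* qualifying duplex against the site region.

    Carriers of site segments always hold 6-pair complementary blocks in
    their 3' insertion slots; those can never satisfy the seed gate, but
    random 5' bases occasionally chance-pair well enough that some alignment
    clears both the score and the seed thresholds. The check uses the
    seed-constrained alignment search, so cleared carriers stay cleared no
    matter which sub-interval of the region island calling later selects.
    Positions 1-11 (everything 5' of the first insertion slot except the
    very first base) are rerolled; a cleared carrier needs no recheck since
    neither it nor the site changes afterwards.
    """
    seqs = list(carrier_seqs)
    for i, s in enumerate(seqs):
        for attempt in range(max_rounds):
            if not _has_qualifying(seqs[i], regions):
                break
            seqs[i] = s[0] + random_seq(rng, 11) + s[12:]
        else:
            raise ParameterError("no-alignment site hardening did not converge")
    return seqs


def gen_five_snp_fixture(seed: int, utr_len: int = 300, out_dir=None) -> dict:
    """Five SNPs on five UTRs mirroring the published report shape: one
    equal-binding SNP, three allele-differential SNPs (stronger alleles A, C
    and C, via wobble or mismatch substitutions), and one SNP inside a
    pattern island to which no miRNA aligns.

    The island-without-alignment site is the reverse complement of a
    pseudo-miRNA absent from the corpus; its segments are carried by corpus
    members (so the island fires) but only as 3' blocks that cannot satisfy
    the seed gate.
    """
    rng = substream(seed, "five_snp_fixture")
    x = list(random_seq(rng, PLANTED_LEN))
    # force the miRNA bases opposing each engineered SNP
    x[10] = "U"  # SNP2: site A (WC) vs G (wobble)  -> stronger A
    x[11] = "G"  # SNP3: site C (WC) vs A (mismatch) -> stronger C
    x[14] = "G"  # SNP4: site C (WC) vs T (wobble)  -> stronger C
    x = "".join(x)
    utr_seqs = [random_seq(rng, utr_len, DNA) for _ in range(5)]
    site_x = revcomp_site(x)
    offsets = [int(rng.integers(30, utr_len - PLANTED_LEN - 30)) for _ in range(5)]

    # pseudo-miRNA behind the island-without-alignment site: redrawn until
    # the planted miRNA itself has no qualifying duplex against that site
    for _ in range(50):
        y = random_seq(rng, PLANTED_LEN)
        ref5, alt5 = nonpairing_site_bases(y[11])[:2]
        site5 = revcomp_site(y)
        site5 = site5[:14] + ref5 + site5[15:]
        utr4 = (utr_seqs[4][: offsets[4]] + site5
                + utr_seqs[4][offsets[4] + len(site5):])
        regions5 = _no_align_regions(utr4, offsets[4], offsets[4] + 14,
                                     (ref5, alt5))
        if not _has_qualifying(x, regions5):
            break
    else:
        raise ParameterError("could not draw a pseudo-miRNA orthogonal to the "
                             "planted miRNA")
    site_y = revcomp_site(y)
    fillers = _build_carrier_corpus(rng, [x], [y])

    def place(ui: int, site: str, snp_site_idx: int, ref: str, alt: str,
              rsid: str) -> SNPRecord:
        site = site[:snp_site_idx] + ref + site[snp_site_idx + 1:]
        u = utr_seqs[ui]
        utr_seqs[ui] = u[: offsets[ui]] + site + u[offsets[ui] + len(site):]
        return SNPRecord(rsid, f"utr{ui + 1}", offsets[ui] + snp_site_idx,
                         (ref, alt), float(round(rng.uniform(0.03, 0.5), 4)))

    # equal: both alleles fail to pair the opposing miRNA base (site idx 10
    # opposes miRNA position 15)
    eq_bases = nonpairing_site_bases(x[15])[:2]
    snps = [
        place(0, site_x, 10, eq_bases[0], eq_bases[1], "rs_equal"),
        place(1, site_x, 15, "A", "G", "rs_strong_a"),   # opposes x[10]='U'
        place(2, site_x, 14, "C", "A", "rs_strong_c1"),  # opposes x[11]='G'
        place(3, site_x, 11, "C", "T", "rs_strong_c2"),  # opposes x[14]='G'
        place(4, site_y, 14, ref5, alt5, "rs_no_align"),
    ]
    hardened = _harden_no_align_site(fillers, regions5, rng)
    corpus = [MatureMiRNA("syn-miR-planted", x)] + [
        MatureMiRNA(f"syn-miR-{i + 1}", s) for i, s in enumerate(hardened)
    ]
    utrs = [UTRRecord(f"utr{i + 1}", s, gene=f"GENE{i + 1}")
            for i, s in enumerate(utr_seqs)]
    fx = {
        "corpus": corpus, "utrs": utrs, "snps": snps,
        "truth": {
            "expected_verdicts": {
                "rs_equal": "equal",
                "rs_strong_a": "stronger:A",
                "rs_strong_c1": "stronger:C",
                "rs_strong_c2": "stronger:C",
                "rs_no_align": "island_no_alignment",
            },
            "planted_mirna": "syn-miR-planted",
        },
    }
    if out_dir is not None:
        _write_fixture(fx, out_dir)
    return fx


def gen_null_fixture(seed: int, n_snps: int = 5, utr_len: int = 300,
                     out_dir=None) -> dict:
    """Carrier corpus as in the recovery fixture, but SNPs at random offsets
    in random (site-free) UTRs — the machinery should call no islands and no
    allele asymmetry."""
    rng = substream(seed, "null_fixture")
    planted_seq = random_seq(rng, PLANTED_LEN)
    fillers = _build_carrier_corpus(rng, [planted_seq], [])
    corpus = [MatureMiRNA("syn-miR-planted", planted_seq)] + [
        MatureMiRNA(f"syn-miR-{i + 1}", s) for i, s in enumerate(fillers)
    ]
    spec = FixtureSpec(seed=seed, n_utrs=n_snps, utr_len=utr_len)
    utrs, snps = gen_snp_utrs(spec, corpus)
    fx = {"corpus": corpus, "utrs": utrs, "snps": snps, "truth": {}}
    if out_dir is not None:
        _write_fixture(fx, out_dir)
    return fx


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

def gen_pedigree(spec: FixtureSpec, snp_ids: list[str]) -> tuple[
        PedigreeGenotypes, list[dict]]:
    """Nuclear families with founders drawn from per-SNP Hardy-Weinberg
    proportions and children by Mendelian transmission; then genotype flips
    injected at ``mendel_error_rate`` (children of fully genotyped trios,
    replaced by a genotype inconsistent with the parents) and missingness
    applied at ``missing_rate``.

    Returns the pedigree and the injected-error ground truth (before
    masking); an injected error may become undetectable once masked.
    """
    rng = substream(spec.seed, "pedigree")
    freqs = {s: rng.uniform(0.1, 0.5) for s in snp_ids}
    individuals: list[tuple[str, str, str, str]] = []
    genotypes: dict[tuple[str, str], tuple[str, str] | None] = {}
    sexes: dict[str, str] = {}

    def draw_founder(p: float) -> tuple[str, str]:
        return tuple(sorted("A" if rng.random() < p else "B" for _ in range(2)))

    for f in range(spec.n_families):
        fam = f"fam{f + 1}"
        father, mother = f"{fam}_f", f"{fam}_m"
        individuals += [(father, "0", "0", fam), (mother, "0", "0", fam)]
        sexes[father], sexes[mother] = "1", "2"
        for snp in snp_ids:
            genotypes[(father, snp)] = draw_founder(freqs[snp])
            genotypes[(mother, snp)] = draw_founder(freqs[snp])
        for c in range(spec.children_per_family):
            child = f"{fam}_c{c + 1}"
            individuals.append((child, father, mother, fam))
            sexes[child] = "1" if rng.random() < 0.5 else "2"
            for snp in snp_ids:
                gf, gm = genotypes[(father, snp)], genotypes[(mother, snp)]
                genotypes[(child, snp)] = tuple(sorted((
                    gf[int(rng.integers(0, 2))], gm[int(rng.integers(0, 2))]
                )))

    truth: list[dict] = []
    if spec.mendel_error_rate > 0:
        all_gts = [("A", "A"), ("A", "B"), ("B", "B")]
        for iid, fid, mid, _fam in individuals:
            if fid == "0":
                continue
            for snp in snp_ids:
                if rng.random() >= spec.mendel_error_rate:
                    continue
                gf, gm = genotypes[(fid, snp)], genotypes[(mid, snp)]
                bad = [g for g in all_gts
                       if not _consistent(g, gf, gm)]
                if not bad:  # e.g. both parents heterozygous
                    continue
                new = bad[int(rng.integers(0, len(bad)))]
                genotypes[(iid, snp)] = new
                truth.append({"snp_id": snp, "child_id": iid,
                              "genotype": list(new)})
    if spec.missing_rate > 0:
        for key in list(genotypes):
            if rng.random() < spec.missing_rate:
                genotypes[key] = None
    ped = PedigreeGenotypes(individuals, list(snp_ids), genotypes, sexes)
    return ped, truth


def _consistent(child, father, mother) -> bool:
    c1, c2 = child
    return ((c1 in father and c2 in mother)
            or (c2 in father and c1 in mother))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _write_fixture(fx: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(fx["corpus"], out / "mirnas.fasta")
    write_fasta(fx["utrs"], out / "utrs.fasta")
    write_snp_table(fx["snps"], out / "snps.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(fx["truth"], fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_pedigree_fixture(ped: PedigreeGenotypes, truth: list[dict],
                           out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_ped(ped, out / "families.ped")
    with open(out / "mendel_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
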