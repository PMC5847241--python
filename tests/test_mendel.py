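import itertools

import pytest

import oracles
from mirsnp.errors import ParameterError
from mirsnp.mendel import (QcThresholds, completion_rate, find_mendel_errors,
                           founder_genotype_counts, hwe_exact_p,
                           is_monomorphic, mendel_error_rate, qc_pipeline,
                           remove_error_genotypes, trio_consistent)
from mirsnp.seqio import PedigreeGenotypes

GENOS = (None, ("A", "A"), ("A", "B"), ("B", "B"))


def make_ped(trios, snp_id="snp1"):
    """Build a pedigree of independent trios from (child, father, mother)
    genotype triples."""
    individuals, genotypes = [], {}
    for k, (gc, gf, gm) in enumerate(trios):
        fam = f"fam{k}"
        f, m, c = f"f{k}", f"m{k}", f"c{k}"
        individuals += [(f, "0", "0", fam), (m, "0", "0", fam),
                        (c, f, m, fam)]
        genotypes[(f, snp_id)] = gf
        genotypes[(m, snp_id)] = gm
        genotypes[(c, snp_id)] = gc
    return PedigreeGenotypes(individuals, [snp_id], genotypes)


class TestCompletionAndMonomorphic:
    def test_completion_fraction(self):
        ped = make_ped([(("A", "A"), ("A", "A"), None)])
        assert completion_rate(ped, "snp1") == pytest.approx(2 / 3)

    def test_all_missing_is_zero(self):
        ped = make_ped([(None, None, None)])
        assert completion_rate(ped, "snp1") == 0.0

    def test_monomorphic_detection(self):
        assert is_monomorphic(make_ped([(("A", "A"), ("A", "A"), ("A", "A"))]),
                              "snp1")
        assert not is_monomorphic(
            make_ped([(("A", "B"), ("A", "A"), ("A", "A"))]), "snp1")
        # degenerate: nothing observed at all counts as monomorphic
        assert is_monomorphic(make_ped([(None, None, None)]), "snp1")


class TestTrioConsistency:
    @pytest.mark.parametrize("gc, gf, gm, consistent", [
        (("A", "B"), ("A", "A"), ("A", "A"), False),  # B untransmittable
        (("A", "A"), ("A", "A"), ("B", "B"), False),  # child must be AB
        (("A", "B"), ("A", "A"), None, True),          # B from missing parent
        (("B", "B"), ("A", "A"), None, False),         # no A transmitted
        (("A", "B"), ("A", "B"), ("A", "B"), True),
        (None, ("A", "A"), ("B", "B"), True),          # missing child
    ])
    def test_hand_cases(self, gc, gf, gm, consistent):
        assert trio_consistent(gc, gf, gm) is consistent

    def test_exhaustive_agreement_with_enumeration_oracle(self):
        """All 4^3 genotype combinations (including missing) match the
        transmission-enumeration oracle."""
        for gc, gf, gm in itertools.product(GENOS, repeat=3):
            assert trio_consistent(gc, gf, gm) == \
                oracles.trio_consistent_enumeration(gc, gf, gm), (gc, gf, gm)

    def test_find_errors_lists_inconsistent_trios(self):
        ped = make_ped([
            (("A", "B"), ("A", "A"), ("A", "A")),   # error
            (("A", "B"), ("A", "B"), ("A", "B")),   # fine
            (("B", "B"), ("A", "A"), ("B", "B")),   # error
        ])
        errors = find_mendel_errors(ped, "snp1")
        assert sorted(e.child_id for e in errors) == ["c0", "c2"]

    def test_error_rate_denominator_excludes_missing_children(self):
        ped = make_ped([
            (("A", "B"), ("A", "A"), ("A", "A")),   # error
            (None, ("A", "A"), ("A", "A")),          # not genotyped
            (("A", "A"), ("A", "A"), ("A", "A")),   # fine
        ])
        assert mendel_error_rate(ped, "snp1") == pytest.approx(0.5)


class TestRemoval:
    def test_trio_policy_blanks_all_three(self):
        ped = make_ped([(("A", "B"), ("A", "A"), ("A", "A"))])
        errors = find_mendel_errors(ped, "snp1")
        cleaned, n = remove_error_genotypes(ped, errors, policy="trio")
        assert n == 3
        assert all(cleaned.genotypes[(i, "snp1")] is None
                   for i in ("c0", "f0", "m0"))
        assert find_mendel_errors(cleaned, "snp1") == []

    def test_child_policy_blanks_child_only(self):
        ped = make_ped([(("A", "B"), ("A", "A"), ("A", "A"))])
        errors = find_mendel_errors(ped, "snp1")
        cleaned, n = remove_error_genotypes(ped, errors, policy="child")
        assert n == 1
        assert cleaned.genotypes[("f0", "snp1")] == ("A", "A")
        assert find_mendel_errors(cleaned, "snp1") == []

    def test_no_errors_leaves_pedigree_unchanged(self):
        ped = make_ped([(("A", "A"), ("A", "A"), ("A", "A"))])
        cleaned, n = remove_error_genotypes(ped, [], policy="trio")
        assert n == 0
        assert cleaned.genotypes == ped.genotypes

    def test_shared_individual_removed_once_and_idempotent(self):
        # one father of two error children: his genotype is counted once
        individuals = [("f0", "0", "0", "fam"), ("m0", "0", "0", "fam"),
                       ("c0", "f0", "m0", "fam"), ("c1", "f0", "m0", "fam")]
        genotypes = {("f0", "snp1"): ("A", "A"), ("m0", "snp1"): ("A", "A"),
                     ("c0", "snp1"): ("A", "B"), ("c1", "snp1"): ("B", "B")}
        ped = PedigreeGenotypes(individuals, ["snp1"], genotypes)
        errors = find_mendel_errors(ped, "snp1")
        assert len(errors) == 2
        cleaned, n = remove_error_genotypes(ped, errors, policy="trio")
        assert n == 4  # f0, m0, c0, c1 — parents only once
        again, n2 = remove_error_genotypes(cleaned, errors, policy="trio")
        assert n2 == 0
        assert again.genotypes == cleaned.genotypes


class TestHweExact:
    def test_perfect_proportions_large_p(self):
        assert hwe_exact_p(25, 50, 25) > 0.5

    def test_extreme_heterozygote_deficit_fails_filter(self):
        assert hwe_exact_p(50, 0, 50) < 0.001

    def test_monomorphic_is_one(self):
        assert hwe_exact_p(40, 0, 0) == 1.0
        assert hwe_exact_p(0, 0, 0) == 1.0

    def test_matches_exact_rational_oracle(self, rng):
        cases = [(25, 50, 25), (50, 0, 50), (3, 1, 0), (0, 1, 0)]
        for _ in range(150):
            n = int(rng.integers(1, 67))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            cases.append((n_aa, n_ab, n - n_aa - n_ab))
        for n_aa, n_ab, n_bb in cases:
            got = hwe_exact_p(n_aa, n_ab, n_bb)
            want = float(oracles.hwe_exact_fraction(n_aa, n_ab, n_bb))
            assert got == pytest.approx(want, abs=1e-9), (n_aa, n_ab, n_bb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            hwe_exact_p(-1, 0, 0)


class TestQcPipeline:
    def _ped(self):
        """30 trios; snp_good clean, snp_incomplete heavily missing,
        snp_mono monomorphic, snp_mendel full of trio errors."""
        snps = ["snp_good", "snp_incomplete", "snp_mono", "snp_mendel"]
        aa, ab, bb = ("A", "A"), ("A", "B"), ("B", "B")
        fathers = [aa, ab, ab, bb]   # founders cycle through near-HWE
        mothers = [ab, aa, bb, ab]   # proportions (1:2:1 overall)
        individuals, genotypes = [], {}
        for k in range(30):
            fam = f"fam{k}"
            f, m, c = f"f{k}", f"m{k}", f"c{k}"
            individuals += [(f, "0", "0", fam), (m, "0", "0", fam),
                            (c, f, m, fam)]
            gf, gm = fathers[k % 4], mothers[k % 4]
            child = tuple(sorted((gf[0], gm[1])))
            gts = {"snp_good": [gf, gm, child],
                   "snp_incomplete": [None if k % 3 else ab] * 3,
                   "snp_mono": [aa] * 3,
                   "snp_mendel": [gf, gm, bb if k % 2 else child]}
            for s in snps:
                genotypes[(f, s)], genotypes[(m, s)], genotypes[(c, s)] = gts[s]
        return PedigreeGenotypes(individuals, snps, genotypes)

    def test_each_bad_snp_drops_in_its_own_category(self):
        kept, counts, cleaned, summary = qc_pipeline(self._ped())
        actions = dict(zip(summary.snp_id, summary.action))
        assert actions["snp_incomplete"] == "drop:completion"
        assert actions["snp_mono"] == "drop:monomorphic"
        assert actions["snp_mendel"] == "drop:mendel_rate"
        assert actions["snp_good"] == "keep"
        assert kept == ["snp_good"]
        assert counts["dropped"] == {"completion": 1, "monomorphic": 1,
                                     "mendel_rate": 1, "hwe": 0}

    def test_extreme_thresholds_disable_completion_filter(self):
        thresholds = QcThresholds(min_completion=1e-9)
        _, counts, _, _ = qc_pipeline(self._ped(), thresholds)
        assert counts["dropped"]["completion"] == 0

    def test_error_free_pedigree_unchanged(self):
        ped = make_ped([(("A", "B"), ("A", "B"), ("A", "B"))] * 3)
        kept, counts, cleaned, _ = qc_pipeline(ped)
        assert counts["genotypes_removed"] == 0
        assert cleaned.genotypes == {
            k: v for k, v in ped.genotypes.items() if k[1] in kept}

    def test_surviving_snps_have_no_mendel_errors(self):
        ped = self._ped()
        # sprinkle one error into the otherwise clean SNP
        ped.genotypes[("c0", "snp_good")] = ("B", "B")
        ped.genotypes[("f0", "snp_good")] = ("A", "A")
        ped.genotypes[("m0", "snp_good")] = ("A", "A")
        # one error in 30 trios is a 3.3% rate; relax the rate filter so the
        # SNP survives to the genotype-removal stage
        thresholds = QcThresholds(mendel_error_rate_max=0.05)
        kept, counts, cleaned, _ = qc_pipeline(ped, thresholds)
        assert "snp_good" in kept
        assert counts["genotypes_removed"] == 3
        for s in kept:
            assert find_mendel_errors(cleaned, s) == []

    def test_founder_counts_exclude_children(self):
        ped = make_ped([(("A", "B"), ("A", "A"), ("B", "B"))] * 2)
        assert founder_genotype_counts(ped, "snp1") == (2, 0, 2)
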