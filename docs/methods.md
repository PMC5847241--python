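# Methods

`mirsnp` predicts which allele of a 3'UTR SNP binds mature miRNAs more
strongly, and cleans family genotype data of Mendelian inconsistencies. This
note describes the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical conventions.

## Prediction pipeline

The pipeline follows the pattern-discovery lineage of target predictors that
do not use cross-species conservation: conserved sequence patterns are
extracted from the mature-miRNA corpus itself, pattern-dense regions of the
UTR ("target islands") are treated as candidate binding regions, and miRNAs
are ranked within islands by complementarity alignment. Both alleles of every
SNP are pushed through the full scan so the verdict compares like with like.

### (L,W) pattern discovery

A pattern is a motif over `{A,C,G,U,.}` in which `.` matches any single base.
Validity requires a literal at both ends and the Teiresias density
constraint: any L consecutive literals span at most W positions. Support
counts corpus *sequences* containing at least one match (multiple matches in
one miRNA count once, so long miRNAs cannot dominate). Discovery enumerates
every valid pattern with at least L literals and support ≥ `min_support` by
depth-first occurrence-list growth — appending `'.'*g + literal` to a
growing motif and pruning when support falls below threshold, which is sound
because support is non-increasing under extension.

**Maximality** is defined as one-step irreducibility: a pattern is maximal
iff no single wildcard→literal fill and no single-literal extension of
either end (with any wildcard gap) preserves its support. Chains of
specializations cannot hide behind this rule on the corpora we target,
because every multi-step specialization starts with a one-step one of equal
or smaller support; the one-step formulation has the advantage of being
exactly checkable, and the test suite holds discovery to set-equality with
an exhaustive enumerator over all wildcard-masked substrings on small
corpora. Requiring at least L literals in reported patterns follows the
elementary-pattern convention; without it, single letters would be reported
as "maximal" on almost any corpus.

Defaults: `L=4, W=6`, `min_support = max(2, 1% of corpus)`. Output order is
total (support desc, literal count desc, motif lexicographic), so runs are
byte-reproducible.

### Significance against a Markov background

"Over-represented" is judged against an order-`k` Markov model (default
`k=2`) fitted to the corpus with add-one smoothing. The expected support of
a pattern is `corpus_size × p̂`, with `p̂` the pooled per-sequence match
frequency over `n_null` simulated replicate corpora (default 1000; each
replicate mirrors the observed sequence-length multiset). An add-one count
on the null matches keeps the expectation positive. A pattern is retained
when `ln(observed / expected) ≥ min_log_odds` (default `ln 2`). The Monte
Carlo stream is seeded from the run configuration, so significance calls are
deterministic.

### Allelic scanning and island calling

UTRs are stored as DNA (sense strand), miRNAs as RNA; patterns are mapped
into "target space" by reverse complementation with `U→T` transliteration
(`.` self-maps), and matching happens in DNA space. `N` in a UTR matches
nothing, neither literals nor wildcards. For each SNP both alleles are
substituted (coordinates 0-based, half-open throughout; the 1-based
convention exists only at the VCF boundary) and each allelic sequence is
scanned for every target-space pattern, overlapping matches included.

Islands: any group of at least `min_island_hits` hit-starts falling within a
`window`-nt span (defaults 5 hits / 25 nt, roughly a binding-site footprint)
defines a candidate island from the group's first hit start to its last hit
end; overlapping candidates merge. Anchoring candidate windows at hit starts
is exhaustive — sliding any qualifying span right to its first hit start
keeps its hit set — and the caller is verified against an all-integer-spans
oracle. Only islands containing the SNP offset proceed to alignment;
other islands are reported (BED) but not allele-compared.

### Duplex alignment

miRNA:island affinity is scored by optimal local antiparallel
complementarity alignment (Gotoh affine DP over the miRNA 5'→3' versus the
reversed island): Watson–Crick pairs +5, G:U wobble +1, mismatch −3, gap
open −8 (first gapped base), gap extend −2. This is an alignment score, not
a folding energy: the tool deliberately avoids importing a thermodynamic
model it could not verify, and a DP alignment admits an exact brute-force
oracle (all monotone antiparallel pairings), which the tests use.

An alignment *qualifies* when its score reaches `min_report_score` (default
40, i.e. eight net WC pairs) **and** at least `seed_min_pairs` (default 6)
of miRNA positions 2–8 are paired (wobble counts toward the seed by default;
configurable). Ties in the traceback resolve deterministically (pairing
preferred over gaps, earliest end cell). `best_seeded_score` additionally
exposes a seed-constrained DP — the best score among alignments with at
least the required seed pairs — used wherever one must certify that *no*
qualifying alignment exists in a region, since a qualifying alignment can be
shadowed by a higher-scoring non-qualifying one.

### Verdicts

Per allele, the best qualifying score across SNP-overlapping islands
represents that allele (an allele with islands but no qualifying alignment
contributes 0, so an intact site beats an ablated one). With `Δ = |s_A −
s_B|` and margin `epsilon` (default 0.5):

* `stronger:<allele>` — that allele's score exceeds the other's by more
  than `epsilon`;
* `equal` — both alleles qualify and `Δ ≤ epsilon` (integer-valued pair
  scores make 0.5 a pure tie-margin);
* `island_no_alignment` — an island overlaps the SNP but no miRNA
  qualifies for either allele;
* `no_island` — no island overlaps the SNP in either allelic context.

## Mendelian-error genotype cleaning

Per-SNP filters run in order: completion rate < 0.98 → drop; monomorphic
(≤ 1 observed allele; all-missing counts) → drop; Mendelian-error rate
> 0.01 → drop; then a Hardy–Weinberg exact test on founders (conditional
enumeration of heterozygote counts; two-sided, summing tables no more
probable than the observed, with a 1e-12 relative slack on the float
comparison) drops SNPs at p ≤ 0.001. The error-rate denominator is trios
with a genotyped child — a trio with a missing child can never err.

Trio consistency is evaluated for biallelic autosomal SNPs with missing-data
marginalization: a combination is an error only if no completion of the
missing genotypes is Mendelian. Extended pedigrees are decomposed into
parent-offspring trios; second-degree inconsistencies are out of scope. On
surviving SNPs, the genotypes causing each error are blanked: the default
(`trio`) policy blanks all three members, the `child` policy only the child
— which member the error "belongs" to is not identifiable from a single
trio, so both policies are provided. Either policy leaves the pedigree
error-free, and re-application is the identity.

## Synthetic fixtures

Generators are pure functions of `(spec, seed)` with labeled substreams, so
outputs are byte-identical across runs and adding a generator never perturbs
existing fixtures.

**Planted-family MirSNP fixtures.** A planted 26-nt miRNA is decomposed
into six 6-nt segments (stride 4); each segment is inserted into nine
randomly chosen corpus "carriers" at 3'-region offsets (≥ 10). This
emulates the segment-sharing of miRNA families at exactly the granularity
pattern discovery needs: each segment reaches support 10 against a
background expectation below 0.5, the segments' target-space forms tile the
planted site (the exact reverse complement of the miRNA, embedded in a
random UTR), and island calling fires with 5–6 hits in one window. The SNP
sits in the exclusive footprint of a single segment, so the disrupting
allele removes exactly one island hit; placed at seed position 7, its
alternate allele breaks one seed WC pair (alternate alleles are chosen to
pair neither WC nor wobble). Carriers can only ever pair a site through
their 3' blocks, which the seed gate rejects, so qualification is reserved
for the planted miRNA by construction.

The engineered five-SNP fixture composes one planted miRNA with four
allele treatments — both alleles mismatching (verdict `equal`), WC vs
wobble and WC vs mismatch substitutions (verdicts `stronger:X` with Δ of 4
and 8) — plus a fifth site built from a pseudo-miRNA absent from the
corpus: its segments are carried (the island fires) but no sequence can
align it. Two safeguards make that last outcome deterministic rather than
seed-lucky: the pseudo-miRNA is redrawn until the planted miRNA has no
qualifying duplex against its site, and carriers' free 5' bases are
rerolled (seed-constrained DP as the certificate) until none admits a
qualifying alignment anywhere in the site region.

**Fixture analysis configuration** (`fixtures.fixture_run_config`): the
fixture corpora are tens of sequences, not a genome-scale corpus, so the
matched analysis settings are `L=6, W=6` (contiguous 6-mers — the exact
granularity of the planted sharing; shorter and wildcarded sub-patterns of
the segments otherwise acquire chance support, become maximal in their own
right, and blur island boundaries), `min_support=8`, `n_null=50`, and a
duplex reporting threshold of 80 — far below the planted duplex scores
(112–130) and far above the chance-alignment tail of random 26-mers
(rarely past ~70 even with wobble). All other values are package defaults.

**Pedigrees.** Founders are drawn from per-SNP Hardy–Weinberg proportions
(allele frequency uniform on [0.1, 0.5]), children by Mendelian
transmission; injected errors replace a child genotype with one inconsistent
with its parents (trios with two heterozygous parents admit no detectable
error and are skipped), and missingness is masked afterwards, so an injected
error can legitimately become undetectable — ground truth is written
alongside for exactly this comparison.

**What the generators do not emulate:** real miRNA length and composition
distributions, hairpin biogenesis, multi-site UTRs, linkage disequilibrium
between SNPs, genotyping-platform error profiles, and real pattern/site
divergence (planted sites are perfect complements). Passing tests therefore
demonstrate that the machinery recovers structure it is pointed at and
stays quiet on unstructured input — not that the default thresholds are
calibrated for genome-scale human data.

## Numerical and reproducibility conventions

* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical inputs + config ⇒ byte-identical
  outputs (asserted in tests).
* Alignment scores are small floats built from integer-valued parameters;
  DP and traceback compare them exactly, which is safe because every value
  is a sum of the same few literals.
* Degenerate inputs: empty SNP tables produce header-only reports;
  monomorphic HWE tables give p = 1; an all-missing SNP is monomorphic and
  has completion 0; islands shorter than 8 nt are rejected by the aligner.
* Problem sizes in the validation suite (100 recovery fixtures; 500/1000/200
  oracle cases; pedigrees of 30–40 families) were chosen so the full suite
  and the acceptance script each run in a couple of minutes on one CPU.

## Known limitations

* The alignment model ignores site accessibility and thermodynamics; scores
  are comparable between alleles of one site, not across sites.
* Significance calibration (Markov order, `min_log_odds`) is exposed but
  has only been validated on synthetic corpora.
* The island rule (windowed hit count) is a declared stand-in for an
  enrichment statistic; its defaults are footprint-sized, not fitted.
* Mendelian checking is trio-local; a genotype consistent within every trio
  but impossible across generations is not flagged.
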