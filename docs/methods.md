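# Methods

## The analysis problem

HLA class II loci on 6p21 sit in such strong linkage disequilibrium that the
natural unit of association is not the allele but the extended haplotype —
here DRB3/4/5–DRB1–DQA1–DQB1, where the three DRB paralogs are mutually
exclusive and occupy a single slot (absent paralogs are the countable call
`DRBX*null`). The pipeline compares haplotype-slot frequencies (each subject
contributes two chromosomes) or carrier frequencies (each subject once)
between a case group and a control group, then asks the two questions that
strong LD makes hard: which effects are real once the dominant haplotype is
removed (RPE), and what does the *second* chromosome contribute among
carriers of the dominant one (conditional analyses).

## Phase reconstruction

**By descent (families).** Each member's genotype is split into two
haplotypes in every possible way (2^(h−1) splits for h heterozygous loci);
splits across the family are kept only when every child's unordered pair
combines one intact haplotype from each available parent. Recombination
within the DR–DQ block is disallowed — the block spans well under a
centimorgan and the descent logic presumes intact transmission. For nuclear
families the enumeration factorizes: conditional on the parents' splits,
each child's admissible splits are independent, so the search is exhaustive
yet cheap (parents ≤ 2^(h−1) splits each, h ≤ 8). A member is `descent`-
phased when exactly one unordered pair survives; otherwise it is reported
`unresolved` with the count of admissible pairs. Sibling-through-ungenotyped-
parent constraints are not exploited, which can only overstate ambiguity,
never invent a phase. A family with no recombination-free solution raises a
Mendelian error naming family, subject and locus.

**By anchor assembly (unrelated subjects).** The stepwise scheme seeded by
the designated risk haplotype
`DRB5*01:01:01-DRB1*15:01:01-DQA1*01:02:01-DQB1*06:02:01`:

1. homozygotes phase trivially (both haplotypes enter the known set);
2. subjects carrying every anchor allele phase by subtraction; the
   remainders enter the known set;
3. remaining subjects are decomposed as one known haplotype plus a
   remainder, in passes until a fixed point; when several known haplotypes
   fit, the decomposition using the most frequent one is preferred (ties by
   label);
4. when the candidate decompositions differ *only* in which haplotype
   carries which DRB3/4/5 allele — both candidates are known with the same
   paralog allele — the shared allele stays on the more common haplotype
   and the other haplotype takes the remaining allele (`conflict_rule`).

Subjects whose genotype admits several genuinely different decompositions
stay `unresolved` (the frequency-preferred pair is still recorded, with the
ambiguity count); subjects admitting none get ambiguity count 0. Unresolved
subjects are excluded from haplotype-level denominators but kept in
allele-level ones, so the two table families can have different totals by
design. Every resolved assignment is checked for allele conservation
(hap1 ⊎ hap2 equals the genotype at every slot).

The assembly is a heuristic: its known set and frequency counts depend on
processing order (input order within passes), and ambiguity is judged
against the known set at the moment a subject resolves. On pools with
realistic LD this is immaterial — synthetic cohorts from the default pool
reconstruct essentially perfectly — and the published scheme it mirrors is
itself order-dependent.

## Statistics

All tests are on 2×2 category-vs-rest tables (a, b; c, d), cases in the
first row.

* Odds ratio: cross-product ad/bc. This is the estimator the published
  large-cell rows pin down exactly; small-cell rows computed with a
  conditional maximum-likelihood estimator are available behind
  `estimator="conditional"` (with its exact conditional CI), which is how
  the one published conditional cell (19.89) is reproduced exactly —
  cross-product gives 20.19, within 5%.
* CI: Woolf log-normal, exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); undefined with a
  zero cell, reported blank like the printed tables' degenerate rows.
* p: 1-df Pearson χ², N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), **without**
  continuity correction (a Yates-corrected statistic visibly contradicts
  the published p-values), or a two-sided Fisher exact test summing all
  hypergeometric tables with probability ≤ the observed one. Fisher is
  computed by exact integer enumeration: the weights C(r1,x)·C(r2,c1−x)
  share one denominator, so tie comparison is exact and the result is a
  ratio of integers — no floating-point tie tolerance. scipy's
  implementation serves as an independent cross-check in the tests (they
  agree to ~1e-15 over every table with N ≤ 30).
* Test selection: Fisher when any expected cell is < 5, else χ²
  (`test_rule="expected5"`); `always_chi2` / `always_fisher` are available
  because the published per-row choice is not recoverable. The test used is
  always recorded per cell. Notably the published multi-round RPE columns
  behave like an unconditional χ² even at expected counts < 5, so those
  round-2+ cells reproduce exactly only under `always_chi2`.

## RPE sequential elimination

Each round tests every remaining category against the rest of the shrinking
totals; the smallest p (ties: larger |observed − expected| case-cell
deviation, then label) is the candidate, and it is excluded — its counts
removed from both groups — when p < α (default 0.05) and its case count is
at least `min_case_count` (default 2, encoding the rule that categories
with at most one affected observation are never called significant; they
remain in the background totals). The procedure stops when no eligible
category clears α. The full per-round, per-category p grid is retained and
written one column per round.

Counts-mode fixtures list only a block's published rows, so the unpublished
remainder is aggregated into an `OTHER` category that is counted and tested
but never excludable (`background`): eliminating an aggregate pseudo-
category would distort every later round.

## Synthetic cohorts

The generator produces the structure the analysis assumes, with recorded
truth:

* **Pool**: 16 extended haplotypes. The anchor is pinned at 0.153 and the
  second-risk haplotype
  `DRB4*01:03:01-DRB1*04:01:01-DQA1*03:02//03:03:01-DQB1*03:01:01` at
  0.031 — the observed control-chromosome frequencies — and the rest are
  realistic northern-European DR–DQ haplotypes, one of which absorbs the
  residual so the pool sums to exactly 1 (keeping the pinned values exact).
* **Population sampling**: Hardy–Weinberg — two independent pool draws per
  subject.
* **Families**: founder parents drawn the same way; children inherit one
  intact haplotype per parent uniformly; the first child is the affected
  proband, parents and siblings are the FDR comparison group regardless of
  genotype (the study design's FDR group is not screened-negative). With a
  risk model, families are redrawn until the proband passes acceptance.
* **Ascertainment**: rejection sampling with acceptance proportional to
  multiplicative genotype risk, baseline × RR(h1) × RR(h2), optionally
  boosted when exactly one chromosome is the anchor and the other is a
  designated second-risk haplotype. No incidence or vaccination dynamics
  are modelled — the minimal structure sufficient to exercise every stage.
  The default model uses the observed haplotype odds ratios as per-copy
  relative risks (anchor 6.75, second-risk 2.77, co-inheritance boost 1.7).

Under a multiplicative per-copy model the population haplotype-slot odds
ratio equals the per-copy relative risk, which is what the end-to-end
recovery measurement checks: generate (RR = 6, 1000 cases and 1000 controls
per replicate, 100 replicates), phase by anchor assembly, count, and ask
how often the Woolf 95% CI covers 6.

What the generator does **not** emulate: recombination, population
stratification, genotyping error, rare/private haplotypes outside the pool,
and DPA1/DPB1 (extended haplotypes stop at DQB1 by default, as in the
result tables). Passing tests therefore demonstrate correctness of the
machinery under the stated model, not robustness to real-data artefacts.

## Numerical and formatting conventions

Percentages print to 1 decimal, odds ratios and CI bounds to 2 decimals,
p-values as 3-significant-digit scientific notation. Result rows are
ordered by descending case count, ties by label. Genotype pairs are
canonicalised (sorted) on read; phase is never encoded in input files.
Undefined statistics (zero cells/margins) are reported blank rather than
clamped. All randomness flows from a single integer seed through
`numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

* The anchor-assembly ambiguity count is relative to the known set, not to
  all haplotypes segregating in the population; it can understate true
  ambiguity early in a pass.
* Published conditional-block percentages use internally inconsistent
  denominators; the conditional module therefore reports raw counts plus
  both candidate denominators (all carriers vs heterozygous carriers) and
  the headline second-haplotype p-value is computed on heterozygous-carrier
  denominators.
* The homozygosity comparison on the published carrier counts is clearly
  non-significant here (Fisher p ≈ 0.50) but does not land on the published
  p of 0.749 under any test-selection rule; the discrepancy is documented
  rather than fitted.
* RPE round-2+ values depend on the per-round test choice (see above);
  only round 1 is asserted to equal the single-shot association exactly.
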