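# hlassoc

Case–control association analysis of HLA class II extended haplotypes, built
around the genetics of Pandemrix-vaccination-associated narcolepsy type 1
(NT1): a small family-based patient cohort (31 probands, 66 first-degree
relatives) compared against 636 Swedish general-population controls typed at
high resolution for *DRB3/DRB4/DRB5*, *DRB1*, *DQA1*, *DQB1*, *DPA1* and
*DPB1*.

The package is for immunogeneticists who need the full analysis ladder for
this kind of data, not just single-locus tests:

* **nomenclature** — WHO colon-delimited allele names, non-amplified DRB
  paralogs as first-class `DRBX*null` calls, and merge groups
  (`DQA1*03:02//03:03:01`) that reconcile cohorts typed at different field
  resolutions;
* **phasing** — extended-haplotype reconstruction by descent within nuclear
  families (exhaustive transmission-consistent enumeration), and for
  unrelated subjects the stepwise anchor-seeded assembly: homozygotes, then
  subtraction around the high-LD risk haplotype
  `DRB5*01:01:01-DRB1*15:01:01-DQA1*01:02:01-DQB1*06:02:01`, then iterative
  decomposition against the growing set of known haplotypes, with a
  frequency rule for DRB3/4/5 conflicts;
* **association** — for every category-vs-rest 2×2 table with cells
  (a, b; c, d): cross-product odds ratio OR = ad/bc, Woolf 95% CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), and a two-sided p from the 1-df
  Pearson χ² (no continuity correction) or Fisher's exact test (any expected
  cell < 5), with a conditional-MLE estimator available for small cells;
* **rpe** — relative predispositional effects: sequentially eliminate the
  category with the smallest p, shrink both group totals, and re-test until
  nothing eligible reaches α, exposing secondary associations masked by a
  dominant one;
* **conditional** — analyses restricted to risk-haplotype carriers: which
  *second* haplotype adds risk, and whether homozygosity does;
* **simulate** — synthetic cohorts (LD-structured 16-haplotype pool,
  Hardy–Weinberg sampling, nuclear-family transmission, risk-proportional
  case ascertainment) with recorded ground-truth phase.

## Worked example

The study's subject-level genotypes are not public, but its per-category
counts are; the counts mode runs the identical statistical path from those.
For the DRB3/4/5 locus (62 NT1 chromosomes vs 1272 control chromosomes):

```python
from hlassoc import analyze_counts
from hlassoc.refdata import ALLELE_BLOCKS_NT1_VS_GP

block = ALLELE_BLOCKS_NT1_VS_GP[0]          # DRB3/4/5 alleles, NT1 vs GP
res = analyze_counts(block.case_counts(), block.control_counts())
for r in res.results:
    print(r.category, f"{r.or_:.2f}", f"({r.ci_low:.2f}, {r.ci_high:.2f})",
          f"{r.p:.2E}", r.test_used)
print("RPE exclusion order:", res.trace.significant)
```

prints

```
DRB3*03:01:01 1.50 (0.53, 4.27) 3.57E-01 fisher
DRB4*01:03:01 0.83 (0.45, 1.56) 5.68E-01 chi2
DRB5*01:01:01 6.32 (3.75, 10.65) 8.24E-15 chi2
RPE exclusion order: ['DRB5*01:01:01', 'DRB4*01:03:01', 'DRB3*03:01:01']
```

`DRB5*01:01:01` carries an overwhelming single-shot association (OR 6.32,
p = 8.24E-15). Neither other allele deviates on its own — but once the
DRB5 chromosomes are eliminated, `DRB4*01:03:01` and then `DRB3*03:01:01`
emerge as secondary effects: that is what the RPE rounds measure.

From a shell the same three modes are available as a CLI:

```sh
hlassoc simulate --seed 1 --out sim/                 # synthetic cohort
hlassoc run --genotypes sim/genotypes.tsv --ped sim/families.ped --out out/
hlassoc counts --counts t.csv --case-total 62 --control-total 1272 --out out/
```

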