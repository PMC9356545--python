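# Methods

## Problem and model

Maternal plasma cfDNA is modeled as a two-component mixture: a maternal
fraction (1 − FF) whose allele content at a SNP is the mother's genotype
dosage g_m/2, and a fetal fraction FF whose content is the fetal dosage / 2.
Reads at a site of depth N are treated as N independent Bernoulli draws from
the mixture frequency — a binomial sampling model. Sites are assumed
biallelic, autosomal, and (for the haplotype stage) free of recombination
between the proband's and the fetus's meioses within the target window; the
target regions this method is designed for span a few hundred kilobases
around a disease locus, where a crossover in either meiosis is rare.

### Fetal fraction

At a SNP where the parents are homozygous for opposite alleles, the mother
contributes only her allele and the fetus is an obligate heterozygote, so the
plasma frequency of the paternal-type allele has expectation FF/2. With
per-site counts p (maternal-type allele) and q (paternal-type), the pooled
estimator is

    FF = 2·Σq / Σ(p + q),

summing over sites before dividing. Pooling weights sites by depth and is
the maximum-likelihood estimator under the binomial model with shared FF;
a per-site mean is exposed as a diagnostic only. The raw ratio is clipped to
[0, 1]; a raw value above 1 (pathological counts) is flagged. The orientation
of p/q follows the parents, not ref/alt, so the estimate is invariant to
which parent carries the reference allele.

### Phasing through the proband

At a site where exactly one parent is heterozygous, the homozygous co-parent
transmits its only allele t = dosage/2, so the heterozygous parent's
transmitted allele is (proband dosage − t). Transmitted alleles across sites
form H0, complements H1. Sites where the subtraction leaves {0,1} are
Mendelian-inconsistent and dropped (counted). No recombination model is
applied; a breakpoint diagnostic reports where a phased H0 diverges from a
reference haplotype, and a single crossover shows up as one contiguous
divergent block.

### Expected profiles and the Spearman decision

Under fetal inheritance of allele h from the heterozygous parent, the
expected plasma alt frequency is

    E(h) = (1 − FF)·g_m/2 + FF·(t + h)/2,

with g_m the mother's dosage (1 at maternal-informative sites; 0 or 2 at
paternal-informative sites, where g_m = 2t). This mixture form is the
package's model for the expected profiles; it is the standard relative
haplotype dosage construction. Evaluating E per site with h from H0 gives
E0, from H1 gives E1 (E0 ≠ E1 at every site by construction, the gap being
FF/2). The observed vector O = q/(p+q) over the same sites is compared to
E0 and E1 by Spearman's ρ — Pearson correlation of average ranks, ties
receiving the mean of the ranks they span — and the call is the hypothesis
with the larger ρ. The decision margin defaults to 0 (strict argmax); an
exact tie, or a rank-degenerate vector (constant after ranking, as happens
when FF → 0 collapses E0 onto E1), yields a no-call flagged TIE. The point
FF estimate is used; FF uncertainty is not propagated. Sites are pooled over
the whole window with no block segmentation.

### Quality gates

* Mendelian screen: a site is consistent iff the proband dosage can arise
  from one allele of each parent (validated against exhaustive enumeration
  of all 27 dosage triples). Families above 5% inconsistent sites among
  complete-trio sites are excluded (MENDELIAN_FAIL). The 5% default
  tolerates genotyping error while catching non-paternity and sample swaps;
  the denominator is complete-trio sites.
* Fetal-fraction gate: below 3% the maternal and fetal contributions cannot
  be reliably separated; the comparison is inclusive (FF = 3% is callable).
* Informative-count gate: strictly more than three effective SNPs (phased
  sites with nonzero plasma depth) are required per parent.

Families without a proband are supported only when a pre-phased parental
haplotype table is supplied; the package does not population-phase.

## Tunable parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `ff_threshold` | 0.03 | fraction | separability limit of the mixture |
| `min_informative` | 3 (require > 3) | SNPs | rank correlation meaningless below this |
| `margin` | 0.0 | ρ difference | strict argmax; raise for conservative calls |
| `max_mendel_fraction` | 0.05 | fraction | genotyping-error tolerance vs. pedigree errors |
| panel `min_spacing` | 10 000 | bp | avoids redundant, tightly linked panel SNPs |

Panel filters additionally require MAF ∈ [0.3, 0.5] in both population
databases (an allele-frequency window of [0.3, 0.7] — a minor-allele
frequency cannot exceed 0.5, so the window is implemented on the MAF scale),
GC ∈ [0.4, 0.55], no duplicated regions, homopolymer runs < 5, and a
linkage-disequilibrium parameter with the target > 0.8 (consumed as a
precomputed column; whether it is r² or D′ depends on the annotation source).
Spacing is enforced greedily left-to-right among otherwise-passing SNPs.

## Simulator

`simulate_pedigree` draws parental haplotypes per site (Bernoulli(MAF) in
random mode, or exact per-class site counts in planned mode, with homozygous
co-parent dosages conditioned on Hardy–Weinberg), transmits one haplotype per
parent to proband and fetus, and samples plasma counts binomially around the
mixture frequency at fixed or Poisson per-site depth. Optional artefacts:

* `capture_ref_bias` b ∈ (0,1]: alt-read retention relative to ref,
  π′ = πb/(πb + 1 − π) — emulates probes preferentially capturing
  reference-matching fragments;
* `template_dropout` d: loss of short fetal templates during amplification,
  lowering the effective fetal fraction to FF(1−d)/(FF(1−d) + 1 − FF);
* `mendel_error_rate`: per-site proband genotype corruption;
* `proband_crossover_index`: a single proband crossover, for the phasing
  diagnostic only.

`simulate_cohort` draws per-family FF from a truncated normal (the spread is
parameterised as a standard deviation on the fraction scale) and fetal
inheritance uniformly over H0/H1 per parent, with family seeds derived from
a master seed.

What the simulator does **not** model: read-level errors, fragment-length
distributions, locus-specific amplicon depth structure, maternal somatic
variation, or recombination in the fetal meiosis. Passing tests therefore
demonstrate correctness of the inference under the stated mixture model, not
robustness to every artefact of real targeted cfDNA sequencing; the
capture-bias and dropout switches probe the first-order enrichment artefacts
only, and the inference deliberately applies no correction for them.

## Reference benchmark cohorts

Clinical cohorts are not distributable, so validation uses simulated cohorts
at the fetal-fraction regimes the two enrichment chemistries produce:

* **multiplex_maternal** — 300 families, FF ~ Normal(0.073, 0.03) truncated
  at 0.005, 15 maternal-informative SNPs at depth 5000 (Poisson), plus 20
  FF-informative SNPs;
* **capture_maternal** — 300 families, FF ~ Normal(0.1156, 0.06) truncated
  at 0.03, 40 maternal-informative SNPs at depth 400, plus 10 FF-informative
  SNPs (capture panels yield more haplotype-informative but fewer
  FF-informative sites);
* **paternal** — 200 families, FF ~ Normal(0.09, 0.03) truncated at 0.03,
  15 paternal-informative SNPs at depth 5000, plus 20 FF-informative SNPs.

Each family runs the full pipeline — FF estimated from its own counts, all
gates applied — and the reported metric is the positive prediction rate:
correct calls divided by called (non-excluded) families. These cohort sizes
and depths run in seconds; `scripts/acceptance.py --seed S` derives the three
master seeds as S, S+1, S+2.

## Numerical and design choices

* Ties in ranks use the average-rank convention; the Spearman implementation
  is validated to 1e−12 against a brute-force oracle and scipy.
* The FF gate is inclusive at the threshold; the informative gate is strict
  (> 3).
* Zero-depth plasma sites are retained in tables but excluded from every
  frequency vector and from FF sums.
* Joins between genotype and count tables are exact on (chrom, pos, ref,
  alt); nothing is matched by position alone.
* Genotypes are alt-dosages against an opaque reference build; multiallelic
  records are skipped, never decomposed.
* Double-heterozygous sites are discarded: with both parents heterozygous
  the transmitted alleles are not resolvable from single-site genotypes.

## Limitations

* No recombination handling: a crossover inside the window between the two
  meioses silently degrades the correlation rather than being modeled.
* FF uncertainty and capture reference bias are not propagated or corrected.
* No significance statement accompanies ρ; the decision is argmax with an
  optional margin.
* The maternal call is intrinsically harder than the paternal one — the
  signal is a perturbation of a 50% background rather than of 0%/100% — and
  degrades first as FF or depth falls.
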