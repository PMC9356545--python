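# rhdocall

Noninvasive fetal haplotype inference from maternal-plasma cell-free DNA.

Couples who both carry a recessive disease allele (the motivating setting is
β-thalassemia, *HBB*) can have the fetal genotype assessed without invasive
sampling: maternal plasma contains a minority fraction of placenta-derived
fetal cfDNA, and the allelic imbalance it induces at SNPs linked to the
disease locus reveals which haplotype of each parent the fetus inherited.
`rhdocall` implements the full inference chain for users with trio genotypes
(father, mother, and a previously characterized first child — the proband)
plus per-SNP plasma allele read counts:

1. **Mendelian/paternity QC** — trios with an excessive fraction of
   Mendelian-inconsistent sites (default > 5%) are excluded outright.
2. **Informative-SNP classification** — sites where the parents are
   homozygous for opposite alleles serve fetal-fraction estimation; sites
   where exactly one parent is heterozygous serve haplotype inference for
   that parent.
3. **Fetal fraction (FF)** — at parent-opposite-homozygote sites every fetal
   genome contributes one paternal-type allele, so pooling read counts gives
   `FF = 2·Σq / Σ(p+q)`, with `p`/`q` the reads carrying the maternal-/
   paternal-homozygote allele.
4. **Proband-anchored phasing** — at each informative site the homozygous
   co-parent's transmitted allele is known, so the proband genotype reveals
   which allele the heterozygous parent transmitted; those alleles form
   haplotype **H0**, their complements **H1**.
5. **Spearman haplotype call** — the expected plasma alt-allele frequency
   under fetal inheritance of allele *h* is
   `E(h) = (1−FF)·g_m/2 + FF·(t+h)/2` (`g_m` = maternal dosage, `t` = the
   co-parent's transmitted allele). Evaluating per site under H0 and H1 gives
   profiles E0 and E1; the observed profile O = q/(p+q) is compared to each
   by Spearman's rank correlation ρ (average ranks for ties), and the fetus
   is called to carry whichever hypothesis correlates better. Families with
   FF < 3% or with three or fewer informative SNPs are not called.

A simulator (`rhdocall simulate`, `rhdocall.simulate`) generates complete
synthetic families — parental haplotypes, Mendelian transmission to proband
and fetus, and binomially sampled plasma counts from the (1−FF)/FF mixture —
so the whole pipeline is testable without clinical data.

## Worked example

Simulate a family with FF = 10%, depth 5000×, where the fetus inherited the
paternal H0 and the maternal H1 haplotype, then run the pipeline:

```bash
rhdocall simulate --n-ff-snps 20 --n-paternal-snps 12 --n-maternal-snps 12 \
    --ff 0.10 --depth 5000 --seed 21 --fetus-maternal H1 --out-dir demo
rhdocall ff --trio-vcf demo/trio.vcf --counts demo/plasma.tsv
rhdocall infer --trio-vcf demo/trio.vcf --plasma-counts demo/plasma.tsv \
    --out demo/report.json
```

which prints

```
{
  "ff": 0.1006829346219897,
  "n_sites": 20,
  "total_depth": 100156,
  "gate_passed": true,
  "threshold": 0.03
}
paternal: H0 (rho_h0=0.9791050079237432, rho_h1=0.26493429626171877, n=12, ff=0.1006829346219897, flags=[])
maternal: H1 (rho_h0=-0.06107048165524592, rho_h1=0.8362420100070908, n=12, ff=0.1006829346219897, flags=[])
```

The fetal fraction is recovered at 10.07% from 20 informative sites
(~100k pooled reads), and for each parent the observed plasma profile ranks
almost perfectly with the expected profile of the truly inherited haplotype
(ρ ≈ 0.98 and 0.84) and poorly with the alternative — both calls match the
simulated truth. Low-FF or SNP-poor families come back as `no-call` with the
responsible QC flag (`LOW_FF`, `FEW_SNPS`, `MENDELIAN_FAIL`, `TIE`).

Other subcommands: `rhdocall phase` exports the H0/H1 table, `rhdocall
panel-filter` applies the SNP panel design criteria (MAF, GC, duplication,
homopolymer, spacing, LD) to an annotated candidate table, and `rhdocall
evaluate` runs a named benchmark cohort.

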