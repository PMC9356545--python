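"""Partition SNPs into the informative classes used by the pipeline.

Classification uses parental genotypes only:

* parents homozygous for different alleles -> usable for fetal-fraction
  estimation (the fetus is an obligate heterozygote there);
* exactly one parent heterozygous, the other homozygous -> usable for
  inferring which haplotype of the heterozygous parent the fetus inherited;
* both parents heterozygous, or both homozygous for the same allele, or any
  parental genotype missing -> uninformative (double-het sites are discarded,
  not population-phased).
"""

from __future__ import annotations

from typing import Optional, Sequence

from .types import AlleleCounts, ClassifiedSnp, SnpClass, TrioGenotypes


def classify_site(father: Optional[int], mother: Optional[int]) -> SnpClass:
    if father is None or mother is None:
        return SnpClass.UNINFORMATIVE
    if father in (0, 2) and mother in (0, 2) and father != mother:
        return SnpClass.FF_INFORMATIVE
    if father == 1 and mother in (0, 2):
        return SnpClass.PATERNAL_INFORMATIVE
    if mother == 1 and father in (0, 2):
        return SnpClass.MATERNAL_INFORMATIVE
    return SnpClass.UNINFORMATIVE


def classify(
    trio: Sequence[TrioGenotypes],
    counts: Optional[Sequence[AlleleCounts]] = None,
) -> list[ClassifiedSnp]:
    """Assign each SNP exactly one class; optionally attach plasma counts by site key."""
    by_key = {c.site.key: c for c in counts} if counts else {}
    return [
        ClassifiedSnp(
            site=g.site,
            snp_class=classify_site(g.father, g.mother),
            trio=g,
            counts=by_key.get(g.site.key),
        )
        for g in trio
    ]
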