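"""Fetal-fraction estimation from parent-opposite-homozygote SNPs.

At a site where the mother is homozygous for one allele and the father for the
other, every fetal genome contributes exactly one paternal-type allele, so the
plasma frequency of the paternal allele has expectation FF/2. Pooling read
counts over such sites gives the estimator

    FF = 2 * sum(q) / sum(p + q)

where, per site, ``p`` counts reads carrying the maternal-homozygote allele and
``q`` reads carrying the paternal-homozygote allele (orientation follows the
parents, not ref/alt).
"""

from __future__ import annotations

from typing import Sequence

from .errors import EstimationError, ValidationError
from .types import ClassifiedSnp, FFEstimate, SnpClass

DEFAULT_FF_THRESHOLD = 0.03


def estimate_ff(snps: Sequence[ClassifiedSnp]) -> FFEstimate:
    """Pooled fetal-fraction estimate over FF-informative SNPs with plasma depth.

    Raises
    ------
    EstimationError
        If no FF-informative site with nonzero depth is available.
    """
    sum_q = 0
    sum_depth = 0
    n_sites = 0
    for snp in snps:
        if snp.snp_class is not SnpClass.FF_INFORMATIVE:
            continue
        if snp.counts is None or snp.counts.depth == 0:
            continue
        # Orient p/q by the parents: q counts the paternal-homozygote allele.
        if snp.trio.father == 2:  # father alt-hom, mother ref-hom
            q = snp.counts.alt_count
        else:  # father ref-hom, mother alt-hom
            q = snp.counts.ref_count
        sum_q += q
        sum_depth += snp.counts.depth
        n_sites += 1
    if n_sites == 0 or sum_depth == 0:
        raise EstimationError(
            "no FF-informative SNPs with plasma coverage: check that parental "
            "genotypes and plasma counts share sites and that parents are "
            "opposite homozygotes at some of them"
        )
    raw = 2.0 * sum_q / sum_depth
    return FFEstimate(ff=min(max(raw, 0.0), 1.0), n_sites=n_sites, total_depth=sum_depth, raw_ratio=raw)


def per_site_ff(snps: Sequence[ClassifiedSnp]) -> list[float]:
    """Diagnostic: per-site 2q/(p+q) values underlying the pooled estimate."""
    out = []
    for snp in snps:
        if snp.snp_class is not SnpClass.FF_INFORMATIVE or snp.counts is None or snp.counts.depth == 0:
            continue
        q = snp.counts.alt_count if snp.trio.father == 2 else snp.counts.ref_count
        out.append(2.0 * q / snp.counts.depth)
    return out


def ff_gate(est: FFEstimate, threshold: float = DEFAULT_FF_THRESHOLD) -> bool:
    """True iff the estimate clears the callability threshold (inclusive).

    Below ~3% fetal fraction the fetal and maternal cfDNA contributions cannot
    be reliably separated, so such families are not called.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0,1], got {threshold}")
    return est.ff >= threshold
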