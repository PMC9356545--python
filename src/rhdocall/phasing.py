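"""Proband-anchored parental phasing.

At a site where exactly one parent is heterozygous, the homozygous co-parent
necessarily transmits its only allele (dosage / 2); subtracting that from the
proband's dosage identifies which allele the heterozygous parent passed to the
proband. The transmitted alleles over all such sites form haplotype H0, the
complements H1 — the two inheritance hypotheses later tested for the fetus.

Phasing is per-site and deterministic: the method assumes no recombination in
the target window (a few hundred kilobases), so no crossover model is applied.
A breakpoint diagnostic is provided instead for users who suspect one.
"""

from __future__ import annotations

from typing import Sequence

from .errors import PhasingError
from .types import ClassifiedSnp, Parent, PhasedParent, SnpClass

DEFAULT_MIN_INFORMATIVE = 3  # gate requires strictly more than this many sites

_CLASS_FOR_PARENT = {
    Parent.PATERNAL: SnpClass.PATERNAL_INFORMATIVE,
    Parent.MATERNAL: SnpClass.MATERNAL_INFORMATIVE,
}


def phase_parent(classes: Sequence[ClassifiedSnp], parent: Parent) -> PhasedParent:
    """Build H0/H1 for one parent from its informative SNPs and the proband.

    Sites where the implied transmitted allele falls outside {0,1} are
    Mendelian-inconsistent and dropped (counted in ``n_dropped_inconsistent``).
    """
    wanted = _CLASS_FOR_PARENT[parent]
    sites, h0, h1, co = [], [], [], []
    n_dropped = 0
    n_candidate = 0
    for snp in sorted(
        (s for s in classes if s.snp_class is wanted), key=lambda s: (s.site.chrom, s.site.pos)
    ):
        n_candidate += 1
        if snp.trio.proband is None:
            raise PhasingError(
                "proband genotype missing: proband-anchored phasing requires a "
                "genotyped first child; for families without one, supply a "
                "pre-phased haplotype table (no-proband mode)"
            )
        co_dosage = snp.trio.mother if parent is Parent.PATERNAL else snp.trio.father
        co_allele = co_dosage // 2
        transmitted = snp.trio.proband - co_allele
        if transmitted not in (0, 1):
            n_dropped += 1
            continue
        sites.append(snp.site)
        h0.append(transmitted)
        h1.append(1 - transmitted)
        co.append(co_allele)
    if n_candidate == 0 or not sites:
        raise PhasingError(
            f"no resolvable {parent.value}-informative sites: cannot construct H0/H1"
        )
    return PhasedParent(
        parent=parent, sites=sites, h0=h0, h1=h1, co_parent=co, n_dropped_inconsistent=n_dropped
    )


def informative_gate(phased: PhasedParent, min_sites: int = DEFAULT_MIN_INFORMATIVE) -> bool:
    """True iff strictly more than ``min_sites`` informative SNPs are available.

    Too few effective SNPs make the rank correlation statistically meaningless;
    the default requires more than three sites.
    """
    return phased.n_sites > min_sites


def breakpoint_diagnostic(phased: PhasedParent, truth_h0: Sequence[int]) -> list[int]:
    """Indices where the phased H0 disagrees with a reference haplotype.

    A single contiguous disagreement block running to one end of the window is
    the signature of one crossover between proband and the reference; scattered
    disagreements indicate genotyping error instead. Diagnostic only — no
    correction is applied.
    """
    if len(truth_h0) != phased.n_sites:
        raise PhasingError("reference haplotype length does not match phased sites")
    return [i for i, (a, b) in enumerate(zip(phased.h0, truth_h0)) if a != b]
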