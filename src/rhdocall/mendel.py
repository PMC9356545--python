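"""Mendelian-consistency (paternity) screen run on a trio before any inference.

A site is consistent when the child's dosage can be formed by taking one allele
from each parent: a heterozygous parent can transmit 0 or 1 alt alleles, a
homozygous parent only dosage/2. Families with an excessive inconsistent
fraction (non-paternity, sample swap) are excluded from haplotype inference.
"""

from __future__ import annotations

from typing import Sequence

from .errors import QCError
from .types import MendelianReport, TrioGenotypes

DEFAULT_MAX_MENDEL_FRACTION = 0.05


def _transmissible(dosage: int) -> set[int]:
    """Alt-allele counts (0 or 1) a parent with the given dosage can transmit."""
    return {0, 1} if dosage == 1 else {dosage // 2}


def is_consistent(father: int, mother: int, child: int) -> bool:
    """True iff the child dosage can arise from one allele of each parent."""
    return any(a + b == child for a in _transmissible(father) for b in _transmissible(mother))


def mendelian_check(
    trio: Sequence[TrioGenotypes],
    max_fraction: float = DEFAULT_MAX_MENDEL_FRACTION,
) -> MendelianReport:
    """Screen a trio for Mendelian inconsistencies.

    Only sites with all three genotypes present enter the denominator. The
    family passes when the inconsistent fraction is at most ``max_fraction``
    (default 5%, tolerating genotyping error while catching non-paternity).
    """
    if not 0.0 < max_fraction < 1.0:
        raise QCError(f"max_fraction must be in (0,1), got {max_fraction}")
    tested = [g for g in trio if g.complete]
    if not tested:
        raise QCError("no sites with complete trio genotypes; cannot run Mendelian check")
    bad = [g.site for g in tested if not is_consistent(g.father, g.mother, g.proband)]
    return MendelianReport(
        n_tested=len(tested),
        n_inconsistent=len(bad),
        max_fraction=max_fraction,
        inconsistent_sites=bad,
    )
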