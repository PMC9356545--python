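"""The haplotype classifier: expected plasma profiles and the Spearman decision.

Maternal plasma cfDNA is a mixture of maternal DNA (fraction 1−FF) and fetal
DNA (fraction FF). At an informative SNP the expected plasma alt-allele
frequency under the hypothesis that the fetus inherited allele ``h`` from the
heterozygous parent is therefore

    E(h) = (1 − FF) · g_m / 2  +  FF · (t + h) / 2

where ``g_m`` is the mother's alt dosage (1 at maternal-informative sites,
0 or 2 at paternal-informative ones) and ``t`` the allele the homozygous
co-parent necessarily transmits. Evaluating E per site with ``h`` taken from
H0 gives the profile E0, from H1 the profile E1; the observed profile O is
q/(p+q) per site. The fetus is called to have inherited whichever haplotype's
expected profile ranks more like O under Spearman correlation, subject to the
fetal-fraction and informative-SNP-count gates.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .types import (
    AlleleCounts,
    Call,
    CallResult,
    ExpectedProfiles,
    Parent,
    PhasedParent,
    QcFlag,
    SpearmanResult,
)

DEFAULT_MARGIN = 0.0


def expected_plasma_frequency(mother_dosage: int, co_transmitted: int, h: int, ff: float) -> float:
    """Expected plasma alt frequency for one site under fetal inheritance of allele h."""
    return (1.0 - ff) * mother_dosage / 2.0 + ff * (co_transmitted + h) / 2.0


def expected_profiles(
    phased: PhasedParent,
    counts: Mapping[tuple, AlleleCounts],
    ff: float,
) -> ExpectedProfiles:
    """Build E0/E1/O vectors over the phased sites that have plasma coverage.

    ``counts`` maps site keys (chrom,pos,ref,alt) to plasma counts; zero-depth
    and uncovered sites are excluded.
    """
    if not 0.0 < ff < 1.0:
        raise ValidationError(f"fetal fraction must be in (0,1), got {ff}")
    sites, e0, e1, o = [], [], [], []
    for site, h0, h1, co in zip(phased.sites, phased.h0, phased.h1, phased.co_parent):
        c = counts.get(site.key)
        if c is None or c.depth == 0:
            continue
        if phased.parent is Parent.MATERNAL:
            g_m = 1  # the mother herself is heterozygous here
        else:
            g_m = 2 * co  # homozygous mother's dosage at paternal-informative sites
        e0.append(expected_plasma_frequency(g_m, co, h0, ff))
        e1.append(expected_plasma_frequency(g_m, co, h1, ff))
        o.append(c.alt_frequency)
        sites.append(site)
    if not sites:
        raise ValidationError("no phased site has nonzero plasma depth")
    return ExpectedProfiles(parent=phased.parent, sites=sites, e0=e0, e1=e1, o=o, ff=ff)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation: Pearson's formula applied to average ranks.

    Ties receive the mean of the ranks they span. A constant input vector
    leaves the coefficient undefined and raises ValidationError; callers turn
    this into a no-call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("spearman_rho needs two equal-length vectors of size >= 2")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        raise ValidationError("spearman_rho undefined: a vector is constant after ranking")
    return SpearmanResult(rho=float((dx * dy).sum() / denom), n=x.size)


def call_haplotype(
    profiles: Optional[ExpectedProfiles],
    ff_ok: bool,
    n_ok: bool,
    margin: float = DEFAULT_MARGIN,
    parent: Optional[Parent] = None,
    ff_used: Optional[float] = None,
    n_informative: Optional[int] = None,
) -> CallResult:
    """Decide H0 vs H1 (or no-call) for one parent.

    Gates are checked first: a failed fetal-fraction gate or informative-count
    gate yields a no-call without computing correlations. Otherwise the call is
    the hypothesis with the larger Spearman coefficient against O, requiring a
    difference greater than ``margin`` (default 0: strict argmax; an exact tie
    or a degenerate rank vector yields a no-call flagged TIE).
    """
    if margin < 0:
        raise ValidationError(f"margin must be >= 0, got {margin}")
    if profiles is not None:
        parent = profiles.parent
        ff_used = profiles.ff if ff_used is None else ff_used
        n_informative = profiles.n_sites if n_informative is None else n_informative
    if parent is None:
        raise ValidationError("parent must be known to produce a call")
    n_informative = n_informative or 0
    flags: set[QcFlag] = set()
    if not ff_ok:
        flags.add(QcFlag.LOW_FF)
    if not n_ok:
        flags.add(QcFlag.FEW_SNPS)
    if flags:
        return CallResult(
            parent=parent, call=Call.NO_CALL, rho_h0=None, rho_h1=None,
            n_informative=n_informative, ff_used=ff_used, qc_flags=flags,
        )
    assert profiles is not None
    try:
        r0 = spearman_rho(profiles.o, profiles.e0).rho
        r1 = spearman_rho(profiles.o, profiles.e1).rho
    except ValidationError:
        return CallResult(
            parent=parent, call=Call.NO_CALL, rho_h0=None, rho_h1=None,
            n_informative=n_informative, ff_used=ff_used, qc_flags={QcFlag.TIE},
        )
    if r0 - r1 > margin:
        call = Call.H0
    elif r1 - r0 > margin:
        call = Call.H1
    else:
        call = Call.NO_CALL
        flags.add(QcFlag.TIE)
    return CallResult(
        parent=parent, call=call, rho_h0=r0, rho_h1=r1,
        n_informative=n_informative, ff_used=ff_used, qc_flags=flags,
    )
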