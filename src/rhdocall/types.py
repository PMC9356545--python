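"""Core domain types for noninvasive fetal haplotype inference.

Genotypes are stored as alt-allele dosages (0, 1, 2) relative to the reference
genome, coordinates are 1-based (VCF convention), and only biallelic SNPs are
admitted anywhere in the pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .errors import ValidationError

_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class SnpSite:
    """A biallelic SNP locus; the key every other record joins on."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"alleles must be single bases A/C/G/T, got ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def _check_dosage(value: Optional[int], who: str) -> None:
    if value is not None and value not in (0, 1, 2):
        raise ValidationError(f"{who} dosage must be 0, 1, 2 or missing, got {value}")


@dataclass(frozen=True)
class TrioGenotypes:
    """Alt-allele dosages of father, mother and (optionally) the proband at one SNP."""

    site: SnpSite
    father: Optional[int]
    mother: Optional[int]
    proband: Optional[int] = None

    def __post_init__(self) -> None:
        _check_dosage(self.father, "father")
        _check_dosage(self.mother, "mother")
        _check_dosage(self.proband, "proband")

    @property
    def parents_complete(self) -> bool:
        return self.father is not None and self.mother is not None

    @property
    def complete(self) -> bool:
        return self.parents_complete and self.proband is not None


@dataclass(frozen=True)
class AlleleCounts:
    """Plasma read counts supporting the ref (p) and alt (q) allele at one SNP."""

    site: SnpSite
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(
                f"negative read count at {self.site.chrom}:{self.site.pos}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_frequency(self) -> float:
        """Observed alt-allele frequency O = q / (p + q); requires depth > 0."""
        if self.depth == 0:
            raise ValidationError(
                f"alt frequency undefined at zero depth ({self.site.chrom}:{self.site.pos})"
            )
        return self.alt_count / self.depth


class SnpClass(enum.Enum):
    """Informative-SNP classes defined by the parental genotype configuration."""

    FF_INFORMATIVE = "ff_informative"  # parents homozygous for different alleles
    PATERNAL_INFORMATIVE = "paternal_informative"  # father het, mother hom
    MATERNAL_INFORMATIVE = "maternal_informative"  # mother het, father hom
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ClassifiedSnp:
    site: SnpSite
    snp_class: SnpClass
    trio: TrioGenotypes
    counts: Optional[AlleleCounts] = None


class Parent(enum.Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"


class Call(enum.Enum):
    H0 = "H0"
    H1 = "H1"
    NO_CALL = "no-call"


class QcFlag(enum.Enum):
    LOW_FF = "LOW_FF"
    FEW_SNPS = "FEW_SNPS"
    MENDELIAN_FAIL = "MENDELIAN_FAIL"
    TIE = "TIE"


@dataclass
class FFEstimate:
    """Pooled fetal-fraction estimate over FF-informative SNPs."""

    ff: float
    n_sites: int
    total_depth: int
    raw_ratio: float  # before clipping to [0, 1]; > 1 indicates pathological counts

    @property
    def overflow(self) -> bool:
        return self.raw_ratio > 1.0


@dataclass
class MendelianReport:
    """Trio-consistency screen run before any inference."""

    n_tested: int
    n_inconsistent: int
    max_fraction: float
    inconsistent_sites: list[SnpSite] = field(default_factory=list)

    @property
    def fraction_inconsistent(self) -> float:
        return self.n_inconsistent / self.n_tested if self.n_tested else 0.0

    @property
    def passed(self) -> bool:
        return self.fraction_inconsistent <= self.max_fraction


@dataclass
class PhasedParent:
    """H0/H1 haplotypes of one parent over that parent's informative SNPs.

    ``h0`` holds the alt-dosage (0/1) of the allele the parent transmitted to the
    proband, ``h1`` the untransmitted allele; ``co_parent`` the allele the
    homozygous co-parent necessarily transmits (its dosage / 2).
    """

    parent: Parent
    sites: list[SnpSite]
    h0: list[int]
    h1: list[int]
    co_parent: list[int]
    n_dropped_inconsistent: int = 0

    def __post_init__(self) -> None:
        n = len(self.sites)
        if not (len(self.h0) == len(self.h1) == len(self.co_parent) == n):
            raise ValidationError("phased vectors must have equal length")
        for a, b in zip(self.h0, self.h1):
            if a + b != 1:
                raise ValidationError("h0 and h1 must be complementary at every site")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class ExpectedProfiles:
    """Per-site expected plasma alt frequencies under H0/H1 plus the observed vector."""

    parent: Parent
    sites: list[SnpSite]
    e0: list[float]
    e1: list[float]
    o: list[float]
    ff: float

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class SpearmanResult:
    rho: float
    n: int


@dataclass
class CallResult:
    """Decision for one parent: which haplotype the fetus inherited, with QC."""

    parent: Parent
    call: Call
    rho_h0: Optional[float]
    rho_h1: Optional[float]
    n_informative: int
    ff_used: Optional[float]
    qc_flags: set[QcFlag] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "parent": self.parent.value,
            "call": self.call.value,
            "rho_h0": self.rho_h0,
            "rho_h1": self.rho_h1,
            "n_informative": self.n_informative,
            "ff_used": self.ff_used,
            "qc_flags": sorted(f.value for f in self.qc_flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CallResult":
        return cls(
            parent=Parent(d["parent"]),
            call=Call(d["call"]),
            rho_h0=d["rho_h0"],
            rho_h1=d["rho_h1"],
            n_informative=d["n_informative"],
            ff_used=d["ff_used"],
            qc_flags={QcFlag(f) for f in d["qc_flags"]},
        )
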