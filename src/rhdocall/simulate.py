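"""Synthetic pedigree and plasma-count generator.

Emulates the data-generating process the inference assumes: parental
haplotypes drawn per site, Mendelian transmission to a proband and a fetus,
and plasma read counts drawn binomially around the cfDNA mixture frequency

    pi = (1 - FF) * mother_dosage / 2 + FF * fetus_dosage / 2

at a configurable depth (fixed or Poisson per site). Two enrichment artefacts
seen in real targeted cfDNA data can be switched on: preferential capture of
reference-matching fragments (probe bias, reweighting pi) and loss of short
fetal templates during amplification (which depresses the effective fetal
fraction). Neither is corrected for downstream — they exist to probe the
pipeline's robustness.

Everything is reproducible from the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import truncnorm

from .errors import ValidationError
from .types import AlleleCounts, Parent, SnpClass, SnpSite, TrioGenotypes

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs of one simulated family.

    Either draw ``n_snps`` sites with parental genotypes implied by Hardy-
    Weinberg at ``maf`` (random mode), or request explicit per-class site
    counts (planned mode) via ``n_ff_snps`` / ``n_paternal_snps`` /
    ``n_maternal_snps``.
    """

    n_snps: int = 60
    maf: float = 0.4
    ff_true: float = 0.10
    depth: float = 1000.0
    depth_model: str = "poisson"  # or "fixed"
    seed: int = 0
    fetus_paternal: str = "H0"
    fetus_maternal: str = "H0"
    capture_ref_bias: float = 1.0  # alt-read retention in (0,1]; 1 = unbiased
    template_dropout: float = 0.0  # fraction of fetal templates lost pre-sequencing
    mendel_error_rate: float = 0.0
    n_ff_snps: Optional[int] = None
    n_paternal_snps: Optional[int] = None
    n_maternal_snps: Optional[int] = None
    proband_crossover_index: Optional[int] = None  # phasing-diagnostic switch
    crossover_parent: str = "maternal"
    chrom: str = "chr11"
    start_pos: int = 5_100_000
    spacing: int = 10_000

    def validate(self) -> None:
        if not 0.0 <= self.ff_true <= 1.0:
            raise ValidationError(f"ff_true must be in [0,1], got {self.ff_true}")
        if self.depth <= 0:
            raise ValidationError("depth must be positive")
        if not 0.0 < self.capture_ref_bias <= 1.0:
            raise ValidationError("capture_ref_bias must be in (0,1]")
        if self.depth_model not in ("fixed", "poisson"):
            raise ValidationError(f"unknown depth_model {self.depth_model!r}")
        if self.fetus_paternal not in ("H0", "H1") or self.fetus_maternal not in ("H0", "H1"):
            raise ValidationError("fetal inheritance must be 'H0' or 'H1'")

    @property
    def planned(self) -> bool:
        return any(
            n is not None for n in (self.n_ff_snps, self.n_paternal_snps, self.n_maternal_snps)
        )


@dataclass
class SimTruth:
    """One simulated family with full ground truth."""

    config: SimConfig
    trio: list[TrioGenotypes]
    fetus_genotypes: list[int]
    plasma: list[AlleleCounts]
    transmitted: dict  # Parent -> "H0" | "H1" (fetal inheritance truth)
    ff_true: float
    # Per-site parental haplotypes: (transmitted-to-proband, untransmitted).
    father_haplotypes: list[tuple[int, int]]
    mother_haplotypes: list[tuple[int, int]]

    def truth_h0(self, parent: Parent) -> dict:
        """Map site key -> the allele that parent transmitted to the proband."""
        haps = self.father_haplotypes if parent is Parent.PATERNAL else self.mother_haplotypes
        return {g.site.key: h[0] for g, h in zip(self.trio, haps)}

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "ff_true": self.ff_true,
            "transmitted": {p.value: v for p, v in self.transmitted.items()},
            "seed": self.config.seed,
            "fetus_genotypes": self.fetus_genotypes,
            "sites": [list(g.site.key) for g in self.trio],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _draw_sites(config: SimConfig, rng: np.random.Generator, n: int) -> list[SnpSite]:
    sites = []
    for i in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        sites.append(
            SnpSite(
                chrom=config.chrom,
                pos=config.start_pos + i * config.spacing,
                ref=str(_BASES[ref]),
                alt=str(_BASES[alt]),
            )
        )
    return sites


def _planned_classes(config: SimConfig, rng: np.random.Generator) -> list[SnpClass]:
    plan = (
        [SnpClass.FF_INFORMATIVE] * (config.n_ff_snps or 0)
        + [SnpClass.PATERNAL_INFORMATIVE] * (config.n_paternal_snps or 0)
        + [SnpClass.MATERNAL_INFORMATIVE] * (config.n_maternal_snps or 0)
    )
    if not plan:
        raise ValidationError("planned mode requires at least one per-class count")
    rng.shuffle(plan)
    return plan


def _hom_dosage_given_maf(maf: float, rng: np.random.Generator) -> int:
    """Dosage of a homozygote under Hardy-Weinberg, conditioned on being homozygous."""
    p_alt_hom = maf**2 / (maf**2 + (1 - maf) ** 2)
    return 2 if rng.random() < p_alt_hom else 0


def simulate_pedigree(config: SimConfig) -> SimTruth:
    """Generate one family: trio genotypes, fetal truth and plasma counts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ff = config.ff_true

    if config.planned:
        plan = _planned_classes(config, rng)
        n = len(plan)
    else:
        plan = None
        n = config.n_snps
    sites = _draw_sites(config, rng, n)

    father_haps: list[tuple[int, int]] = []
    mother_haps: list[tuple[int, int]] = []
    for i in range(n):
        if plan is None:
            fh = (int(rng.random() < config.maf), int(rng.random() < config.maf))
            mh = (int(rng.random() < config.maf), int(rng.random() < config.maf))
        else:
            cls = plan[i]
            if cls is SnpClass.FF_INFORMATIVE:
                m = 2 * int(rng.random() < 0.5)
                f = 2 - m
                fh, mh = (f // 2, f // 2), (m // 2, m // 2)
            elif cls is SnpClass.PATERNAL_INFORMATIVE:
                order = int(rng.random() < 0.5)
                fh = (order, 1 - order)
                m_allele = _hom_dosage_given_maf(config.maf, rng) // 2
                mh = (m_allele, m_allele)
            else:  # MATERNAL_INFORMATIVE
                order = int(rng.random() < 0.5)
                mh = (order, 1 - order)
                f_allele = _hom_dosage_given_maf(config.maf, rng) // 2
                fh = (f_allele, f_allele)
        father_haps.append(fh)
        mother_haps.append(mh)

    # Effective fetal fraction after short-template dropout (fetal molecules
    # are shorter and preferentially lost during amplification).
    d = config.template_dropout
    ff_eff = ff * (1 - d) / (ff * (1 - d) + (1 - ff)) if ff > 0 else 0.0

    trio: list[TrioGenotypes] = []
    fetus: list[int] = []
    plasma: list[AlleleCounts] = []
    for i, site in enumerate(sites):
        fh, mh = father_haps[i], mother_haps[i]
        father_dos = fh[0] + fh[1]
        mother_dos = mh[0] + mh[1]

        # Proband receives the transmitted (index-0) haplotype of each parent;
        # an optional single crossover flips one parent's contribution from a
        # given site onward (diagnostic use only).
        f_idx = m_idx = 0
        if config.proband_crossover_index is not None and i >= config.proband_crossover_index:
            if config.crossover_parent == "paternal":
                f_idx = 1
            else:
                m_idx = 1
        proband_dos = fh[f_idx] + mh[m_idx]
        if config.mendel_error_rate > 0 and rng.random() < config.mendel_error_rate:
            proband_dos = int(rng.integers(0, 3))

        fet_pat = fh[0] if config.fetus_paternal == "H0" else fh[1]
        fet_mat = mh[0] if config.fetus_maternal == "H0" else mh[1]
        fetus_dos = fet_pat + fet_mat

        pi = (1 - ff_eff) * mother_dos / 2.0 + ff_eff * fetus_dos / 2.0
        b = config.capture_ref_bias
        if b < 1.0:
            pi = pi * b / (pi * b + (1 - pi))
        depth_i = (
            int(config.depth)
            if config.depth_model == "fixed"
            else int(rng.poisson(config.depth))
        )
        alt = int(rng.binomial(depth_i, pi)) if depth_i > 0 else 0
        trio.append(
            TrioGenotypes(site=site, father=father_dos, mother=mother_dos, proband=proband_dos)
        )
        fetus.append(fetus_dos)
        plasma.append(AlleleCounts(site=site, ref_count=depth_i - alt, alt_count=alt))

    return SimTruth(
        config=config,
        trio=trio,
        fetus_genotypes=fetus,
        plasma=plasma,
        transmitted={
            Parent.PATERNAL: config.fetus_paternal,
            Parent.MATERNAL: config.fetus_maternal,
        },
        ff_true=ff,
        father_haplotypes=father_haps,
        mother_haplotypes=mother_haps,
    )


@dataclass
class FFDistribution:
    """Truncated-normal fetal-fraction spread across a cohort."""

    mean: float
    sd: float
    truncation: float = 0.001  # lower bound; upper bound is 1

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.truncation - self.mean) / self.sd
        b = (1.0 - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


def simulate_cohort(
    n_families: int,
    template: SimConfig,
    ff_distribution: FFDistribution,
    master_seed: int = 0,
) -> list[SimTruth]:
    """Simulate a cohort: per-family FF from a truncated normal, fetal
    inheritance uniform over H0/H1 per parent, family seeds derived from the
    master seed."""
    if n_families < 1:
        raise ValidationError("n_families must be >= 1")
    rng = np.random.default_rng(master_seed)
    ffs = ff_distribution.sample(n_families, rng)
    seeds = rng.integers(0, 2**31 - 1, size=n_families)
    cohort = []
    for i in range(n_families):
        cfg = dataclasses.replace(
            template,
            ff_true=float(ffs[i]),
            seed=int(seeds[i]),
            fetus_paternal="H0" if rng.random() < 0.5 else "H1",
            fetus_maternal="H0" if rng.random() < 0.5 else "H1",
        )
        cohort.append(simulate_pedigree(cfg))
    return cohort
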