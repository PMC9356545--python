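"""SNP panel selection filters applied to a pre-annotated candidate table.

Candidates (already annotated with population frequencies, GC content,
duplication status, homopolymer runs and linkage to the target locus — the
annotation lookup itself is external) are screened by:

  a. minor allele frequency in [0.3, 0.5] in both population databases
     (i.e. allele frequency in [0.3, 0.7]);
  b. GC content of the enrichment segment in [0.4, 0.55];
  c. not in a duplicated region;
  d. no run of five or more identical bases in the segment;
  e. at least ``min_spacing`` bp (default 10 kb) from the previous kept SNP;
  f. linkage-disequilibrium parameter with the target > 0.8.

All failed criteria are recorded per site (no short-circuiting). Spacing is
enforced greedily left-to-right among SNPs passing every other criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .errors import ValidationError
from .types import SnpSite

DEFAULT_MIN_SPACING = 10_000

CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "maf_1kg", "maf_gnomad", "gc_content",
    "in_duplicated_region", "max_homopolymer_run", "ld_with_target",
]


@dataclass(frozen=True)
class CandidateSnp:
    site: SnpSite
    maf_1kg: float
    maf_gnomad: float
    gc_content: float
    in_duplicated_region: bool
    max_homopolymer_run: int
    ld_with_target: float

    def __post_init__(self) -> None:
        for name, maf in (("maf_1kg", self.maf_1kg), ("maf_gnomad", self.maf_gnomad)):
            if not 0.0 <= maf <= 0.5:
                raise ValidationError(f"{name} must be a minor-allele frequency in [0,0.5], got {maf}")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValidationError(f"gc_content must be in [0,1], got {self.gc_content}")


@dataclass
class FilterDecision:
    site: SnpSite
    failed_criteria: set[str] = field(default_factory=set)

    @property
    def kept(self) -> bool:
        return not self.failed_criteria


def filter_panel(
    candidates: Sequence[CandidateSnp],
    min_spacing: int = DEFAULT_MIN_SPACING,
) -> list[FilterDecision]:
    """Apply criteria (a)-(f); input must be position-sorted within chromosome."""
    last_chrom, last_pos = None, None
    for c in candidates:
        if c.site.chrom == last_chrom and last_pos is not None and c.site.pos < last_pos:
            raise ValidationError("candidates must be sorted by position within chromosome")
        last_chrom, last_pos = c.site.chrom, c.site.pos

    decisions = []
    last_kept: dict[str, int] = {}  # per-chromosome position of previous kept SNP
    for c in candidates:
        failed: set[str] = set()
        if not (0.3 <= c.maf_1kg <= 0.5 and 0.3 <= c.maf_gnomad <= 0.5):
            failed.add("a")
        if not (0.4 <= c.gc_content <= 0.55):
            failed.add("b")
        if c.in_duplicated_region:
            failed.add("c")
        if c.max_homopolymer_run >= 5:
            failed.add("d")
        if not c.ld_with_target > 0.8:
            failed.add("f")
        if not failed:
            prev = last_kept.get(c.site.chrom)
            if prev is not None and c.site.pos - prev < min_spacing:
                failed.add("e")
            else:
                last_kept[c.site.chrom] = c.site.pos
        decisions.append(FilterDecision(site=c.site, failed_criteria=failed))
    return decisions


def read_candidates(path: Union[str, Path]) -> list[CandidateSnp]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"candidate table {path} is missing columns {missing}")
    return [
        CandidateSnp(
            site=SnpSite(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt),
            maf_1kg=float(r.maf_1kg),
            maf_gnomad=float(r.maf_gnomad),
            gc_content=float(r.gc_content),
            in_duplicated_region=bool(r.in_duplicated_region),
            max_homopolymer_run=int(r.max_homopolymer_run),
            ld_with_target=float(r.ld_with_target),
        )
        for r in df.itertuples(index=False)
    ]


def write_decisions(path: Union[str, Path], decisions: Sequence[FilterDecision]) -> None:
    pd.DataFrame(
        [
            (d.site.chrom, d.site.pos, d.site.ref, d.site.alt, d.kept,
             "".join(sorted(d.failed_criteria)))
            for d in decisions
        ],
        columns=["chrom", "pos", "ref", "alt", "kept", "failed_criteria"],
    ).to_csv(path, sep="\t", index=False)
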