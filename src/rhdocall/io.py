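"""Readers and writers: genotype VCFs, plasma allele-count tables, reports.

VCF handling goes through pysam; tabular formats through pandas. Multiallelic
and indel records are skipped (with a logged count), never decomposed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import pysam

from .errors import ValidationError
from .types import AlleleCounts, Call, CallResult, Parent, PhasedParent, SnpSite, TrioGenotypes

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
PHASED_COLUMNS = ["chrom", "pos", "ref", "alt", "parent", "h0_allele", "h1_allele", "co_parent_allele"]

_BASES = frozenset("ACGT")


def _gt_to_dosage(gt: tuple) -> Optional[int]:
    """Decode a pysam GT tuple into an alt dosage, or None if any allele is missing."""
    if gt is None or any(a is None for a in gt):
        return None
    return sum(int(a) for a in gt)


def read_trio_vcf(
    path: PathLike,
    father: str,
    mother: str,
    proband: Optional[str] = None,
) -> list[TrioGenotypes]:
    """Read biallelic SNP genotypes for a father/mother(/proband) trio from a VCF.

    Parameters
    ----------
    path : VCF file (plain or bgzipped) with GT in FORMAT.
    father, mother : sample names; must be present in the header.
    proband : optional sample name for the first child.

    Multiallelic records, indels and non-ACGT alleles are skipped; the skip
    count is logged.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    for name, role in ((father, "father"), (mother, "mother"), (proband, "proband")):
        if name is not None and name not in samples:
            raise ValidationError(
                f"sample {name!r} ({role}) not found in VCF header; samples are {samples}"
            )
    records: list[TrioGenotypes] = []
    n_skipped = 0
    for rec in vcf:
        if (
            rec.alts is None
            or len(rec.alts) != 1
            or rec.ref is None
            or len(rec.ref) != 1
            or len(rec.alts[0]) != 1
            or rec.ref.upper() not in _BASES
            or rec.alts[0].upper() not in _BASES
        ):
            n_skipped += 1
            continue
        site = SnpSite(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref.upper(),
            alt=rec.alts[0].upper(),
            id=rec.id,
        )
        try:
            f_dos = _gt_to_dosage(rec.samples[father].get("GT"))
            m_dos = _gt_to_dosage(rec.samples[mother].get("GT"))
            p_dos = _gt_to_dosage(rec.samples[proband].get("GT")) if proband else None
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}")
        records.append(TrioGenotypes(site=site, father=f_dos, mother=m_dos, proband=p_dos))
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    read_trio_vcf.last_skip_count = n_skipped  # type: ignore[attr-defined]
    return records


def write_trio_vcf(
    path: PathLike,
    trio: Sequence[TrioGenotypes],
    father: str = "FATHER",
    mother: str = "MOTHER",
    proband: Optional[str] = "PROBAND",
) -> None:
    """Write trio genotypes as an uncompressed VCF (GT only)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(g.site.chrom for g in trio):
        header.contigs.add(chrom)
    names = [father, mother] + ([proband] if proband else [])
    for name in names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for g in trio:
            rec = out.new_record(
                contig=g.site.chrom,
                start=g.site.pos - 1,
                alleles=(g.site.ref, g.site.alt),
                id=g.site.id,
            )
            dosages = [g.father, g.mother] + ([g.proband] if proband else [])
            for name, dos in zip(names, dosages):
                if dos is None:
                    rec.samples[name]["GT"] = (None, None)
                else:
                    rec.samples[name]["GT"] = (0, 1) if dos == 1 else (dos // 2, dos // 2)
            out.write(rec)


def read_plasma_counts(path: PathLike) -> list[AlleleCounts]:
    """Read a plasma allele-count table (TSV: chrom,pos,ref,alt,ref_count,alt_count).

    Duplicated sites are an error; negative counts are a validation error.
    Zero-depth records are retained (downstream stages exclude them from
    frequency vectors).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"count table {path} is missing columns {missing}")
    keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
    if len(set(keys)) != len(keys):
        raise ValidationError(f"count table {path} contains duplicated sites")
    out = []
    for row in df.itertuples(index=False):
        site = SnpSite(chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt)
        out.append(AlleleCounts(site=site, ref_count=int(row.ref_count), alt_count=int(row.alt_count)))
    return out


def write_plasma_counts(path: PathLike, counts: Sequence[AlleleCounts]) -> None:
    df = pd.DataFrame(
        [
            (c.site.chrom, c.site.pos, c.site.ref, c.site.alt, c.ref_count, c.alt_count)
            for c in counts
        ],
        columns=COUNT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class JoinResult:
    """Trio records paired with plasma counts by exact (chrom,pos,ref,alt) key."""

    joined: list[tuple[TrioGenotypes, AlleleCounts]]
    unjoinable_trio: list[SnpSite]
    unjoinable_counts: list[SnpSite]


def join_trio_counts(trio: Sequence[TrioGenotypes], counts: Sequence[AlleleCounts]) -> JoinResult:
    """Join trio genotypes and plasma counts; the key is exact, no positional fuzz."""
    by_key = {c.site.key: c for c in counts}
    joined, un_trio = [], []
    seen = set()
    for g in trio:
        c = by_key.get(g.site.key)
        if c is None:
            un_trio.append(g.site)
        else:
            joined.append((g, c))
            seen.add(g.site.key)
    un_counts = [c.site for c in counts if c.site.key not in seen]
    if un_trio or un_counts:
        log.info(
            "join: %d trio sites and %d count sites had no partner",
            len(un_trio),
            len(un_counts),
        )
    return JoinResult(joined=joined, unjoinable_trio=un_trio, unjoinable_counts=un_counts)


def write_report(results: Sequence[CallResult], path: PathLike) -> None:
    """Write calls as JSON (``path``) and TSV (same stem, ``.tsv``)."""
    if not results:
        raise ValidationError("write_report requires at least one result")
    path = Path(path)
    payload = {"results": [r.to_dict() for r in results]}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    rows = [r.to_dict() for r in results]
    for row in rows:
        row["qc_flags"] = ",".join(row["qc_flags"])
    pd.DataFrame(rows).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)


def read_report(path: PathLike) -> list[CallResult]:
    payload = json.loads(Path(path).read_text())
    return [CallResult.from_dict(d) for d in payload["results"]]


def write_phased_table(path: PathLike, phased: Sequence[PhasedParent]) -> None:
    rows = []
    for ph in phased:
        for site, h0, h1, co in zip(ph.sites, ph.h0, ph.h1, ph.co_parent):
            rows.append((site.chrom, site.pos, site.ref, site.alt, ph.parent.value, h0, h1, co))
    pd.DataFrame(rows, columns=PHASED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phased_table(path: PathLike) -> dict[Parent, PhasedParent]:
    """Load pre-phased parental haplotypes (used in the no-proband mode)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in PHASED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phased table {path} is missing columns {missing}")
    out: dict[Parent, PhasedParent] = {}
    for parent_value, sub in df.groupby("parent", sort=False):
        parent = Parent(parent_value)
        sub = sub.sort_values(["chrom", "pos"])
        out[parent] = PhasedParent(
            parent=parent,
            sites=[
                SnpSite(chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt)
                for r in sub.itertuples(index=False)
            ],
            h0=[int(v) for v in sub["h0_allele"]],
            h1=[int(v) for v in sub["h1_allele"]],
            co_parent=[int(v) for v in sub["co_parent_allele"]],
        )
    return out
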