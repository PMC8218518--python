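"""Variant records and site-level VCF input/output.

The pipeline works on expressed single-nucleotide variants (eSNVs) called
from RNA-seq. Each record carries the three annotations the inclusion
filters consume: a variant-quality score in [0, 1] (e.g. an RVboost Q
score), the read depth at the site, and the population allele frequency
(1000 Genomes style; absent for novel variants).

VCFs are site-level (no genotype columns) with INFO keys ``QS``, ``DP``
and ``AF1KG``; the key names are configurable on read for externally
produced files. Reading goes through pysam; writing is a deterministic
text emitter so that identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from pathlib import Path

import pysam

from .channels import BASES
from .errors import DataError

#: A panel-of-normals entry / hotspot coordinate: (chrom, pos, ref, alt).
SiteKey = tuple[str, int, str, str]


@dataclasses.dataclass(frozen=True, slots=True)
class VariantRecord:
    """One expressed single-nucleotide variant.

    Positions are 1-based. ``population_af`` is ``None`` when the variant
    is absent from the population reference panel (treated as novel, i.e.
    rarer than any frequency cutoff).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    quality_score: float
    depth: int
    population_af: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise DataError(f"ref/alt must be single A/C/G/T bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def site_key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=QS,Number=1,Type=Float,Description="Variant quality score in [0,1]">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at the site">
##INFO=<ID=AF1KG,Number=1,Type=Float,Description="Population allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    chrom: str,
    chrom_length: int,
) -> None:
    """Write site-level VCF 4.2, sorted by position then alt base.

    Deterministic: the same record set always yields the same bytes.
    """
    lines = [_VCF_HEADER.format(chrom=chrom, length=chrom_length)]
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        info = f"QS={rec.quality_score:.4f};DP={rec.depth}"
        if rec.population_af is not None:
            info += f";AF1KG={rec.population_af:.5f}"
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n")
    Path(path).write_text("".join(lines))


def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    qs_key: str = "QS",
    dp_key: str = "DP",
    af_key: str = "AF1KG",
) -> list[VariantRecord]:
    """Read SNV records from a VCF file.

    Multi-allelic rows are split into biallelic records; non-SNV alleles
    (indels, symbolic alleles) are ignored. ``sample_id`` defaults to the
    file stem.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem.removesuffix(".vcf")
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            ref = row.ref
            if ref is None or len(ref) != 1 or ref not in BASES:
                continue
            qs = row.info.get(qs_key)
            dp = row.info.get(dp_key)
            af = row.info.get(af_key)
            if qs is None or dp is None:
                raise DataError(
                    f"{path.name}:{row.pos}: missing required INFO key "
                    f"{qs_key if qs is None else dp_key}"
                )
            for alt in row.alts or ():
                if len(alt) != 1 or alt not in BASES:
                    continue
                # round away float32 noise from the htslib INFO representation
                records.append(
                    VariantRecord(
                        sample_id=sample_id,
                        chrom=row.chrom,
                        pos=row.pos,
                        ref=ref,
                        alt=alt,
                        quality_score=round(float(qs), 6),
                        depth=int(dp),
                        population_af=None if af is None else round(float(af), 6),
                    )
                )
    return records


def read_site_table(path: str | Path) -> set[SiteKey]:
    """Read a (chrom, pos, ref, alt) TSV — e.g. a panel of normals."""
    sites: set[SiteKey] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or (i == 1 and line.lower().startswith("chrom")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                from .errors import ParseError

                raise ParseError(f"expected 4 columns in site table {path}", line_number=i)
            sites.add((fields[0], int(fields[1]), fields[2], fields[3]))
    return sites


def write_site_table(sites: Iterable[SiteKey], path: str | Path) -> None:
    """Write a sorted (chrom, pos, ref, alt) TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in sorted(sites):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
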