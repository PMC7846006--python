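"""VCF 4.2 writers/readers for per-pool calls and classified variants.

The files are plain-text, single-contig VCFs.  INFO fields:

* per-pool calls: ``DP`` (depth), ``AF`` (allele frequency), ``POOL``;
  FILTER carries the caller verdict (PASS / low_maf / low_depth / low_qual).
* classified variants: ``AF`` (combined), ``AF_A``/``AF_B``, ``DP_A``/
  ``DP_B``, ``ZYG`` (homoplasmy|heteroplasmy), ``CAT``
  (haplogroup_defining|private|unique), ``CLASS``
  (transition|transversion), ``LOWFREQ`` (flag, combined AF < 0.40).
"""

from __future__ import annotations

from pathlib import Path

from .duplex_concordance import RejectedArtifact
from .errors import FormatError, ValidationError
from .reference_panel import MtReference
from .strand_caller import StrandVariantCall
from .variant_classification import ClassifiedVariant

_VCF_VERSION = "##fileformat=VCFv4.2"


def _header(reference: MtReference, info_lines: list[str], filter_lines: list[str]) -> str:
    lines = [_VCF_VERSION]
    lines.append(f"##contig=<ID={reference.name},length={len(reference)}>")
    lines.extend(info_lines)
    lines.extend(filter_lines)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return "\n".join(lines) + "\n"


_CLASSIFIED_INFO = [
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Combined allele frequency (depth-weighted mean of the two pools)">',
    '##INFO=<ID=AF_A,Number=1,Type=Float,Description="Allele frequency in pool A">',
    '##INFO=<ID=AF_B,Number=1,Type=Float,Description="Allele frequency in pool B">',
    '##INFO=<ID=DP_A,Number=1,Type=Integer,Description="Depth in pool A">',
    '##INFO=<ID=DP_B,Number=1,Type=Integer,Description="Depth in pool B">',
    '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity: homoplasmy or heteroplasmy">',
    '##INFO=<ID=CAT,Number=1,Type=String,Description="Category: haplogroup_defining, private or unique">',
    '##INFO=<ID=CLASS,Number=1,Type=String,Description="Substitution class: transition or transversion">',
    '##INFO=<ID=LOWFREQ,Number=0,Type=Flag,Description="Combined allele frequency below 40%">',
]

_POOL_INFO = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pool depth at the site">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele frequency in the pool">',
    '##INFO=<ID=POOL,Number=1,Type=String,Description="Primer pool (strand): A or B">',
]

_FILTERS = [
    '##FILTER=<ID=low_maf,Description="Alt frequency below the reporting floor">',
    '##FILTER=<ID=low_depth,Description="Depth below the minimum">',
    '##FILTER=<ID=low_qual,Description="Phred quality below the minimum">',
]


def write_variants_vcf(
    variants: list[ClassifiedVariant], reference: MtReference, path: str | Path
) -> None:
    """Write classified variants as a VCF 4.2 file (input must be sorted)."""
    positions = [v.position for v in variants]
    if positions != sorted(positions):
        raise ValidationError("variants must be sorted by position")
    with open(path, "w") as fh:
        fh.write(_header(reference, _CLASSIFIED_INFO, []))
        for v in variants:
            info = (
                f"AF={v.combined_freq:.6g};AF_A={v.freq_A:.6g};AF_B={v.freq_B:.6g};"
                f"DP_A={v.depth_A};DP_B={v.depth_B};ZYG={v.zygosity};CAT={v.category};"
                f"CLASS={v.mutation_class}"
            )
            if v.low_frequency_flag:
                info += ";LOWFREQ"
            fh.write(
                f"{reference.name}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n"
            )


def read_variants_vcf(path: str | Path) -> list[ClassifiedVariant]:
    """Round-trip reader for :func:`write_variants_vcf` output."""
    out: list[ClassifiedVariant] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _VCF_VERSION:
            raise FormatError(f"not a VCF 4.2 file: first line {first!r}")
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _qual, _filter, info = line.rstrip("\n").split("\t")
            fields: dict[str, str] = {}
            flags: set[str] = set()
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    fields[k] = v
                else:
                    flags.add(item)
            out.append(
                ClassifiedVariant(
                    position=int(pos),
                    ref=ref,
                    alt=alt,
                    freq_A=float(fields["AF_A"]),
                    freq_B=float(fields["AF_B"]),
                    depth_A=int(fields["DP_A"]),
                    depth_B=int(fields["DP_B"]),
                    combined_freq=float(fields["AF"]),
                    zygosity=fields["ZYG"],
                    category=fields["CAT"],
                    mutation_class=fields["CLASS"],
                    low_frequency_flag="LOWFREQ" in flags,
                )
            )
    return out


def write_pool_calls_vcf(
    calls: list[StrandVariantCall], reference: MtReference, path: str | Path
) -> None:
    """Write one pool's candidate calls as VCF 4.2."""
    with open(path, "w") as fh:
        fh.write(_header(reference, _POOL_INFO, _FILTERS))
        for c in sorted(calls, key=lambda c: (c.position, c.alt)):
            info = f"DP={c.depth};AF={c.frequency:.6g};POOL={c.pool}"
            fh.write(
                f"{reference.name}\t{c.position}\t.\t{c.ref}\t{c.alt}\t"
                f"{c.qual:.4g}\t{c.filter}\t{info}\n"
            )


def write_artifacts_tsv(artifacts: list[RejectedArtifact], path: str | Path) -> None:
    """Sidecar table of duplex-rejected candidates with their reasons."""
    with open(path, "w") as fh:
        fh.write("position\tref\talt\tpool_seen\tfrequency\treason\n")
        for a in sorted(artifacts, key=lambda a: (a.position, a.alt)):
            fh.write(
                f"{a.position}\t{a.ref}\t{a.alt}\t{a.pool_seen}\t{a.frequency:.6g}\t{a.reason}\n"
            )
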