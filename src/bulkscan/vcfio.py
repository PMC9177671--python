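"""Reading and writing site-count tables as VCF 4.2 and TSV.

All file coordinates are 1-based inclusive.  VCF records carry per-bulk
allele depths in the AD FORMAT field (ref,alt); only biallelic SNPs are
read back, multi-allelic or non-SNP records are dropped and counted.
"""

from __future__ import annotations

import logging

import pandas as pd
import pysam

log = logging.getLogger("bulkscan")

__all__ = [
    "write_bulk_vcf",
    "read_bulk_counts_vcf",
    "read_parent_variants_vcf",
    "write_counts_tsv",
    "read_counts_tsv",
]

_COORD_COMMENT = "# coordinates: 1-based inclusive (VCF/GFF convention)"


def _vcf_header(sample_names, chrom_lengths: dict) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=int(length))
    header.formats.add("AD", "R", "Integer", "Allele read depths (ref,alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for name in sample_names:
        header.add_sample(name)
    return header


def write_bulk_vcf(
    sites: pd.DataFrame,
    path,
    high_name: str = "HIGH",
    low_name: str = "LOW",
    chrom_lengths: dict | None = None,
) -> None:
    """Write a high/low site-count table as an uncompressed VCF."""
    if chrom_lengths is None:
        chrom_lengths = (
            sites.groupby("chrom")["pos"].max().astype(int).to_dict()
        )
    header = _vcf_header([high_name, low_name], chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in sites.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.samples[high_name]["AD"] = (int(row.high_ref), int(row.high_alt))
            rec.samples[high_name]["DP"] = int(row.high_ref + row.high_alt)
            rec.samples[low_name]["AD"] = (int(row.low_ref), int(row.low_alt))
            rec.samples[low_name]["DP"] = int(row.low_ref + row.low_alt)
            vf.write(rec)


def read_bulk_counts_vcf(path, high_sample: str, low_sample: str) -> pd.DataFrame:
    """Read per-bulk AD counts from a VCF into a site-count table.

    Multi-allelic records and non-SNP alleles are dropped (logged).
    """
    rows, dropped = [], 0
    with pysam.VariantFile(str(path)) as vf:
        for name in (high_sample, low_sample):
            if name not in list(vf.header.samples):
                raise KeyError(f"sample {name!r} not in VCF {path}")
        for rec in vf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in "ACGT"
                or alts[0] not in "ACGT"
            ):
                dropped += 1
                continue
            ad_h = rec.samples[high_sample]["AD"]
            ad_l = rec.samples[low_sample]["AD"]
            rows.append(
                (rec.contig, rec.pos, rec.ref, alts[0],
                 int(ad_h[0]), int(ad_h[1]), int(ad_l[0]), int(ad_l[1]))
            )
    if dropped:
        log.info("read_bulk_counts_vcf: dropped %d non-biallelic-SNP records", dropped)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt",
                 "high_ref", "high_alt", "low_ref", "low_alt"],
    )


def read_parent_variants_vcf(path, sample: str | None = None) -> pd.DataFrame:
    """Read a single-sample parent VCF into a variant table.

    Returns chrom, pos, ref, alt, ref_count, alt_count (from AD when
    present) and gt (from GT when present); multi-allelic records dropped.
    """
    rows, dropped = [], 0
    with pysam.VariantFile(str(path)) as vf:
        names = list(vf.header.samples)
        name = sample if sample is not None else names[0]
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                dropped += 1
                continue
            smp = rec.samples[name]
            ad = smp.get("AD", (0, 0))
            gt = smp.get("GT", None)
            gt_str = (
                "/".join("." if g is None else str(g) for g in gt)
                if gt is not None
                else ""
            )
            rows.append(
                (rec.contig, rec.pos, rec.ref, alts[0],
                 int(ad[0] or 0), int(ad[1] or 0), gt_str)
            )
    if dropped:
        log.info("read_parent_variants_vcf: dropped %d multi-allelic records", dropped)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "ref_count", "alt_count", "gt"],
    )


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    """Write any table as TSV with a coordinate-convention header comment."""
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
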