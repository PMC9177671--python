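"""Reference-guided pseudo-reference construction.

The bulks of a QTL-seq experiment are scored against the genome of one
parent.  When only a public reference assembly for the species exists, a
stand-in for that parent is built by substituting the parent's confident
homozygous SNP alleles into the reference sequence ("reference-guided
assembly").  Only single-nucleotide substitutions are applied; indels and
low-confidence calls are rejected and reported.

Coordinates are 1-based inclusive (VCF convention) at every interface.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "filter_confident_parent_variants",
    "apply_snp_substitutions",
]

_SNP_BASES = set("ACGT")


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {name: uppercase sequence str} dict."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict, path, width: int = 60) -> None:
    """Write sequences uppercase, 60 columns, preserving input order."""
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def filter_confident_parent_variants(
    variants: pd.DataFrame,
    min_depth: int = 7,
    min_alt_fraction: float = 0.9,
) -> pd.DataFrame:
    """Reduce a parent variant table to a confident substitution set.

    ``variants`` needs columns chrom, pos, ref, alt and either read counts
    (ref_count, alt_count) or a genotype string column ``gt``.  A record is
    retained when it is a biallelic SNP (single A/C/G/T ref and alt), its
    depth is >= min_depth, and it is homozygous-alternate: alt fraction
    >= min_alt_fraction when counts are present, genotype 1/1 or 1|1
    otherwise.

    Returns the substitution set (chrom, pos, ref, alt), sorted, one row per
    position.
    """
    df = variants.copy()
    is_snp = df["ref"].str.len().eq(1) & df["alt"].str.len().eq(1)
    is_snp &= df["ref"].isin(_SNP_BASES) & df["alt"].isin(_SNP_BASES)
    df = df[is_snp]
    if {"ref_count", "alt_count"}.issubset(df.columns):
        depth = df["ref_count"] + df["alt_count"]
        keep = depth >= min_depth
        frac = df["alt_count"].where(depth > 0, 0) / depth.replace(0, 1)
        keep &= frac >= min_alt_fraction
        df = df[keep]
    elif "gt" in df.columns:
        df = df[df["gt"].isin(("1/1", "1|1"))]
    else:
        raise KeyError("variant table needs ref_count/alt_count or gt")
    df = (
        df[["chrom", "pos", "ref", "alt"]]
        .drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    return df


def apply_snp_substitutions(reference: dict, subs: pd.DataFrame):
    """Substitute SNP alleles into reference sequences.

    Returns ``(pseudo_reference, report)`` where the report is a DataFrame
    with one row per substitution and a ``status`` column: ``applied``, or a
    rejection reason (``ref_mismatch``, ``not_snp``, ``unknown_chrom``,
    ``out_of_range``).  Rejected records are never applied silently; output
    sequences keep their input lengths.
    """
    seqs = {name: bytearray(seq.upper(), "ascii") for name, seq in reference.items()}
    status = []
    for row in subs.itertuples(index=False):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_BASES or alt not in _SNP_BASES:
            status.append("not_snp")
            continue
        if row.chrom not in seqs:
            status.append("unknown_chrom")
            continue
        seq = seqs[row.chrom]
        pos0 = int(row.pos) - 1
        if not 0 <= pos0 < len(seq):
            status.append("out_of_range")
            continue
        if chr(seq[pos0]) != ref:
            status.append("ref_mismatch")
            continue
        seq[pos0] = ord(alt)
        status.append("applied")
    report = subs.copy()
    report["status"] = status
    pseudo = {name: seq.decode("ascii") for name, seq in seqs.items()}
    return pseudo, report


def substitution_report_summary(report: pd.DataFrame) -> dict:
    counts = report["status"].value_counts().to_dict()
    return {
        "applied": int(counts.get("applied", 0)),
        "skipped": int(len(report) - counts.get("applied", 0)),
        "by_reason": {k: int(v) for k, v in counts.items() if k != "applied"},
    }
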