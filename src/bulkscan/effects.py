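"""Variant effect classification against gene models.

Candidate SNPs are classified genic/intergenic, exon/intron, and — for
positions inside a coding sequence — by their codon change under the
standard nuclear genetic code: synonymous (sSNP) when the amino acid is
unchanged, non-synonymous (nsSNP) otherwise.  Codons are reported in
transcript orientation with the variant base upper-cased (e.g. aCg -> aTg
for a middle-position C>T on the coding strand).

Gene models come from GFF3 (1-based inclusive coordinates); only the
canonical (first) transcript per gene is used, matching reports that give
one effect per SNP.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "read_gff3",
    "write_gff3",
    "locate_variant",
    "codon_change",
    "annotate_variants",
    "summarize_region_effects",
]


@dataclass
class GeneModel:
    """One gene with the exon/CDS structure of its canonical transcript."""

    gene_id: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)  # [(start, end)] 1-based inclusive
    cds: list = field(default_factory=list)    # [(start, end)] 1-based inclusive

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for name, ivals in (("exon", self.exons), ("CDS", self.cds)):
            for (s, e) in ivals:
                if s > e:
                    raise ValueError(f"{name} interval {s}-{e} inverted")
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {name} intervals in {self.gene_id}")
        for (cs, ce) in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(
                    f"CDS {cs}-{ce} of {self.gene_id} not contained in an exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def complete_cds(self) -> bool:
        return self.cds_length % 3 == 0 and self.cds_length > 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)


_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _attrs(text: str) -> dict:
    return dict(_ATTR_RE.findall(text))


def read_gff3(path) -> dict:
    """Parse GFF3 gene models into {gene_id: GeneModel}.

    Recognises gene, mRNA (or transcript), exon and CDS features; the
    canonical transcript is the first mRNA of each gene by sorted id.  CDS
    rows parented directly to a gene are accepted.  Exonless transcripts use
    their CDS intervals as exons.
    """
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"]
    df = pd.read_csv(
        path, sep="\t", comment="#", names=cols, header=None,
        dtype={"chrom": str}, na_filter=False,
    )
    genes: dict = {}
    tx_parent: dict = {}
    tx_order: dict = {}
    for row in df.itertuples(index=False):
        a = _attrs(row.attributes)
        if row.type == "gene":
            gid = a.get("ID", a.get("Name"))
            genes[gid] = {"chrom": row.chrom, "strand": row.strand, "tx": {}}
        elif row.type in ("mRNA", "transcript"):
            tid, parent = a.get("ID"), a.get("Parent")
            tx_parent[tid] = parent
            if parent in genes:
                genes[parent]["tx"].setdefault(tid, {"exon": [], "CDS": []})
        elif row.type in ("exon", "CDS"):
            parent = a.get("Parent")
            gid = tx_parent.get(parent, parent)
            if gid not in genes:
                continue
            tid = parent if parent in tx_parent else f"{gid}.t"
            genes[gid]["tx"].setdefault(tid, {"exon": [], "CDS": []})
            genes[gid]["tx"][tid][row.type].append((int(row.start), int(row.end)))

    models: dict = {}
    for gid, info in genes.items():
        if not info["tx"]:
            continue
        tid = sorted(info["tx"])[0]  # canonical transcript
        parts = info["tx"][tid]
        exons = parts["exon"] or parts["CDS"]
        models[gid] = GeneModel(
            gene_id=gid, chrom=info["chrom"], strand=info["strand"],
            exons=exons, cds=parts["CDS"],
        )
    return models


def write_gff3(models: dict, path) -> None:
    """Write gene models as GFF3 (gene, mRNA, exon, CDS rows)."""
    lines = ["##gff-version 3"]
    for gid in sorted(models):
        m = models[gid]
        tid = f"{gid}.1"
        lines.append(
            "\t".join([m.chrom, "bulkscan", "gene", str(m.start), str(m.end),
                       ".", m.strand, ".", f"ID={gid}"])
        )
        lines.append(
            "\t".join([m.chrom, "bulkscan", "mRNA", str(m.start), str(m.end),
                       ".", m.strand, ".", f"ID={tid};Parent={gid}"])
        )
        for s, e in m.exons:
            lines.append("\t".join([m.chrom, "bulkscan", "exon", str(s), str(e),
                                    ".", m.strand, ".", f"Parent={tid}"]))
        # phase bookkeeping for CDS rows, transcript orientation
        ordered = m.cds if m.strand == "+" else m.cds[::-1]
        done = 0
        for s, e in ordered:
            phase = (3 - done % 3) % 3
            lines.append("\t".join([m.chrom, "bulkscan", "CDS", str(s), str(e),
                                    ".", m.strand, str(phase), f"Parent={tid}"]))
            done += e - s + 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def locate_variant(models: dict, chrom: str, pos: int):
    """Locate a site against gene models.

    Returns (gene_id or None, region_class, hits): region_class is 'exon'
    when the position lies in an exon of some gene, 'intron' when inside a
    gene span but in no exon, 'intergenic' otherwise.  ``hits`` lists every
    overlapping gene as (gene_id, class) sorted by gene id; the primary hit
    (first by id, exon preferred over intron) is returned up front.
    """
    hits = []
    for gid in sorted(models):
        m = models[gid]
        if m.chrom == chrom and m.contains(pos):
            hits.append((gid, "exon" if m.in_exon(pos) else "intron"))
    if not hits:
        return None, "intergenic", []
    hits.sort(key=lambda h: (h[1] != "exon", h[0]))
    return hits[0][0], hits[0][1], sorted(hits)


def _highlight(codon: str, offset: int) -> str:
    return "".join(
        b.upper() if i == offset else b.lower() for i, b in enumerate(codon)
    )


def codon_change(sequences: dict, model: GeneModel, pos: int, alt: str):
    """Codon and amino-acid change for a CDS position.

    ``sequences`` maps chromosome name to sequence (the assembly the variant
    was called against, normally the pseudo-reference).  The codon is
    extracted in transcript orientation: for minus-strand genes the spliced
    CDS is reverse-complemented and the alternate base complemented before
    substitution.  Returns (codon_ref, codon_alt, aa_ref, aa_alt) with the
    variant base upper-cased inside the codon strings, or None when the
    affected codon is incomplete (partial terminal codon).
    """
    if not model.in_cds(pos):
        raise ValueError(f"{model.gene_id}: position {pos} not in CDS")
    alt = alt.upper()
    if len(alt) != 1 or alt not in "ACGT":
        raise ValueError(f"alternate allele must be a single base, got {alt!r}")
    seq = sequences[model.chrom]
    spliced = "".join(seq[s - 1 : e] for s, e in model.cds).upper()
    offset = 0
    for s, e in model.cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    if model.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
        offset = len(spliced) - 1 - offset
        alt_t = str(Seq(alt).complement())
    else:
        alt_t = alt
    if spliced[offset] == alt_t:
        raise ValueError("alternate allele equals the reference base")
    ci, co = divmod(offset, 3)
    codon_ref = spliced[ci * 3 : ci * 3 + 3]
    if len(codon_ref) < 3:
        warnings.warn(
            f"{model.gene_id}: position {pos} falls in an incomplete terminal codon"
        )
        return None
    codon_alt = codon_ref[:co] + alt_t + codon_ref[co + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return _highlight(codon_ref, co), _highlight(codon_alt, co), aa_ref, aa_alt


def annotate_variants(
    sites: pd.DataFrame, models: dict, sequences: dict | None = None
) -> pd.DataFrame:
    """Annotate a site table (chrom, pos, ref, alt) against gene models.

    Adds gene, region (exon/intron/intergenic), codon_ref/codon_alt,
    aa_ref/aa_alt and effect (nsSNP / sSNP / non-coding).  UTR exon
    positions (exon outside any CDS) and intronic/intergenic positions are
    'non-coding'; codon columns are filled only for CDS positions.  When
    ``sequences`` is None codon-level classification is skipped.
    """
    rows = []
    for site in sites.itertuples(index=False):
        gid, region, _ = locate_variant(models, site.chrom, int(site.pos))
        rec = {
            "chrom": site.chrom, "pos": int(site.pos),
            "ref": site.ref, "alt": site.alt,
            "gene": gid, "region": region,
            "codon_ref": "", "codon_alt": "", "aa_ref": "", "aa_alt": "",
            "effect": "non-coding",
        }
        if (
            gid is not None
            and region == "exon"
            and sequences is not None
            and models[gid].in_cds(int(site.pos))
        ):
            change = codon_change(sequences, models[gid], int(site.pos), site.alt)
            if change is not None:
                cref, calt, aref, aalt = change
                rec.update(
                    codon_ref=cref, codon_alt=calt, aa_ref=aref, aa_alt=aalt,
                    effect="sSNP" if aref == aalt else "nsSNP",
                )
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize_region_effects(effects: pd.DataFrame, region=None) -> dict:
    """Summarise effect annotations, optionally within one region.

    Counts SNPs, unique genes hit, exon/intron/intergenic positions, and
    nsSNP/sSNP calls.  ``region`` may be a CandidateRegion (or anything with
    chrom/start/end attributes) to restrict the table first.
    """
    df = effects
    if region is not None:
        df = df[
            (df["chrom"] == region.chrom)
            & (df["pos"] >= region.start)
            & (df["pos"] <= region.end)
        ]
    genic = df["gene"].notna()
    return {
        "n_snps": int(len(df)),
        "n_genes": int(df.loc[genic, "gene"].nunique()),
        "n_genic_snps": int(genic.sum()),
        "n_exon": int((df["region"] == "exon").sum()),
        "n_intron": int((df["region"] == "intron").sum()),
        "n_intergenic": int((df["region"] == "intergenic").sum()),
        "n_nsSNP": int((df["effect"] == "nsSNP").sum()),
        "n_sSNP": int((df["effect"] == "sSNP").sum()),
    }
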