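from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from bulkscan.effects import GeneModel

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def df_candidate_table() -> pd.DataFrame:
    """Published candidate-SNP list for the days-to-flowering region."""
    return pd.read_csv(DATA / "df_candidate_snps.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def leaf_candidate_table() -> pd.DataFrame:
    """Published candidate-SNP list for the leaf-shape region."""
    return pd.read_csv(DATA / "leafshape_candidate_snps.tsv", sep="\t", comment="#")


@pytest.fixture(scope="session")
def toy_genome():
    """A deterministic 6 kb sequence with one plus- and one minus-strand
    two-exon gene (complete CDS), for effect-annotation tests."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    plus = GeneModel(
        "geneA", "chr1", "+",
        exons=[(1001, 1150), (1301, 1450)],
        cds=[(1052, 1150), (1301, 1402)],  # 99 + 102 = 201 bp
    )
    minus = GeneModel(
        "geneB", "chr1", "-",
        exons=[(2001, 2200), (2401, 2600)],
        cds=[(2101, 2199), (2401, 2502)],  # 99 + 102 = 201 bp
    )
    assert plus.complete_cds and minus.complete_cds
    return {"chr1": seq}, {"geneA": plus, "geneB": minus}


def oracle_effect(seq: str, model: GeneModel, pos: int, alt: str) -> str:
    """Reference oracle: mutate the chromosome, re-splice, re-translate the
    whole CDS and compare proteins — independent of codon indexing."""

    def protein(s):
        spliced = "".join(s[a - 1 : b] for a, b in model.cds)
        if model.strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
        return str(Seq(spliced).translate())

    mutated = seq[: pos - 1] + alt + seq[pos:]
    return "sSNP" if protein(seq) == protein(mutated) else "nsSNP"
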