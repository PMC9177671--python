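"""Synthetic F2 populations, extreme bulks and pooled allele counts.

The generator emulates a biparental F2 mapping design of the kind used for
QTL-seq in pigeonpea: two inbred parents differing at a major quantitative
locus for days to flowering (parental means 105 and 67 days) and at a
recessive Mendelian leaf-shape locus (3 lanceolate : 1 obcordate in the F2),
a population of 179 individuals, 15-plant extreme bulks, and short-read
allele-depth sampling at a mean depth of ~14x per bulk.

Genotypes are simulated as two independent F1 gametes per individual; gamete
alleles follow a Markov chain along each chromosome with inter-marker
recombination fractions given by the Haldane map function (no crossover
interference).  Genotype *dosage* throughout this module counts alleles of
the reference parent (the late-flowering, obcordate-leaf parent whose genome
serves as the pseudo-reference), so dosage 2 means homozygous for the
reference parent and the alternate-allele frequency at a site is
``1 - dosage / 2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromosomeSpec",
    "QTLSpec",
    "SimConfig",
    "F2Population",
    "haldane",
    "expected_pve",
    "simulate_f2",
    "sample_bulk_counts",
    "paired_site_counts",
    "study_config",
    "write_truth_json",
]

_BASES = np.array(list("ACGT"))


def haldane(d_morgans):
    """Recombination fraction for a genetic distance in Morgans.

    Haldane's map function r = (1 - exp(-2d)) / 2, assuming independent
    crossovers (no interference).
    """
    d = np.asarray(d_morgans, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def expected_pve(additive: float, dominance: float, noise_sd: float) -> float:
    """Fraction of F2 phenotypic variance explained by one biallelic QTL.

    In an F2 (allele frequency 1/2) the genetic variance splits into an
    additive part a^2/2 and a dominance part d^2/4; environmental noise adds
    noise_sd^2.
    """
    vg = additive**2 / 2.0 + dominance**2 / 4.0
    return vg / (vg + noise_sd**2)


@dataclass(frozen=True)
class ChromosomeSpec:
    """One simulated chromosome: physical length, marker count, map length."""

    name: str
    length_bp: int
    n_markers: int
    cm_length: float


@dataclass(frozen=True)
class QTLSpec:
    """A causal locus.

    For a quantitative trait, ``additive`` is the effect in trait units of
    each reference-parent allele and ``dominance`` the heterozygote
    deviation.  ``recessive_class`` marks a Mendelian trait scored as a
    class: individuals homozygous for the reference-parent allele (dosage 2)
    show the recessive phenotype.
    """

    chrom: str
    pos_bp: int
    trait: str
    additive: float = 0.0
    dominance: float = 0.0
    recessive_class: bool = False
    recessive_label: str = "obcordate"
    dominant_label: str = "lanceolate"


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic F2 experiment."""

    chromosomes: tuple = ()
    qtls: tuple = ()
    n_individuals: int = 179
    trait_baseline: float = 86.0
    trait_noise_sd: float = 14.0
    bulk_size: int = 15
    mean_depth: float = 14.0
    fixed_depth: bool = False
    seq_error_rate: float = 0.001
    misclassification_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome must be declared")
        if self.n_individuals < 2 * self.bulk_size:
            raise ValueError(
                f"n_individuals ({self.n_individuals}) must be >= "
                f"2 * bulk_size ({2 * self.bulk_size})"
            )
        if not 0.0 <= self.seq_error_rate < 0.5:
            raise ValueError("seq_error_rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        by_name = {c.name: c for c in self.chromosomes}
        if len(by_name) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for q in self.qtls:
            if q.chrom not in by_name:
                raise ValueError(f"QTL chromosome {q.chrom!r} not declared")
            if not 1 <= q.pos_bp <= by_name[q.chrom].length_bp:
                raise ValueError(
                    f"QTL position {q.pos_bp} outside {q.chrom} "
                    f"(length {by_name[q.chrom].length_bp})"
                )


def study_config(seed: int = 0) -> SimConfig:
    """Default configuration mirroring the pigeonpea F2 study design.

    179 F2s; a days-to-flowering QTL on CcLG03 with additive effect 19 days
    (half the 105 - 67 day parental difference, baseline at the midparent 86)
    and residual noise of 14 days (single-QTL PVE ~48%, the size of a major
    flowering-time QTL); a recessive obcordate-leaf locus on CcLG08; 15-plant
    bulks sequenced at mean depth 14x.
    """
    return SimConfig(
        chromosomes=(
            ChromosomeSpec("CcLG03", 23_500_000, 160, 120.0),
            ChromosomeSpec("CcLG08", 16_900_000, 120, 100.0),
        ),
        qtls=(
            QTLSpec("CcLG03", 20_000_000, "DF", additive=19.0),
            QTLSpec("CcLG08", 7_800_000, "leaf_shape", recessive_class=True),
        ),
        seed=seed,
    )


def _marker_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Evenly spaced markers per chromosome, snapped onto causal positions."""
    frames = []
    for chrom in config.chromosomes:
        pos = np.linspace(1, chrom.length_bp, chrom.n_markers).round().astype(np.int64)
        pos = np.unique(pos)
        for q in config.qtls:
            if q.chrom == chrom.name:
                pos[np.argmin(np.abs(pos - q.pos_bp))] = q.pos_bp
        pos = np.unique(pos)
        cm = pos / chrom.length_bp * chrom.cm_length
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom.name,
                    "pos": pos,
                    "cm": cm,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class F2Population:
    """A simulated F2 population.

    Attributes
    ----------
    markers : DataFrame with chrom, pos, cm, ref, alt (one row per marker).
    dosages : int8 array (n_individuals, n_markers); count of the
        reference-parent allele, 0/1/2.
    phenotypes : DataFrame indexed by individual id with one column per
        quantitative trait (trait units) and per class trait (labels).
    truth : list of per-trait ground-truth dicts (trait, chrom, causal
        position, effects, expected PVE, bulk membership once assigned).
    config : the SimConfig that produced the population.
    """

    markers: pd.DataFrame
    dosages: np.ndarray
    phenotypes: pd.DataFrame
    truth: list
    config: SimConfig

    @property
    def ids(self) -> pd.Index:
        return self.phenotypes.index

    def marker_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.markers["chrom"].to_numpy() == chrom)
            & (self.markers["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(hit[0])


def _simulate_gametes(
    cm: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """Alleles (0/1) of F1 gametes along one chromosome, Haldane model."""
    m = cm.size
    first = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    if m == 1:
        return first[:, None]
    r = haldane(np.diff(cm) / 100.0)
    switches = (rng.random((n_gametes, m - 1)) < r).astype(np.int8)
    # cumulative XOR of switch indicators gives the chain state
    flips = np.cumsum(switches, axis=1) % 2
    alleles = np.empty((n_gametes, m), dtype=np.int8)
    alleles[:, 0] = first
    alleles[:, 1:] = (first[:, None] + flips) % 2
    return alleles


def simulate_f2(config: SimConfig) -> F2Population:
    """Simulate an F2 population under the given design.

    Each individual is the union of two independent F1 gametes; dosages at a
    single marker therefore segregate 1:2:1 in expectation.  Quantitative
    phenotypes are baseline + additive*(dosage-1) + dominance*[dosage==1]
    summed over that trait's QTLs, plus Gaussian noise; Mendelian class
    traits follow the recessive rule (optionally with a misclassification
    probability).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_map, rng_geno, rng_pheno = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    markers = _marker_table(config, rng_map)
    n = config.n_individuals

    blocks = []
    for chrom in config.chromosomes:
        cm = markers.loc[markers["chrom"] == chrom.name, "cm"].to_numpy()
        g1 = _simulate_gametes(cm, n, rng_geno)
        g2 = _simulate_gametes(cm, n, rng_geno)
        blocks.append(g1 + g2)
    dosages = np.concatenate(blocks, axis=1)

    ids = pd.Index([f"F2_{i + 1:04d}" for i in range(n)], name="id")
    pheno = pd.DataFrame(index=ids)
    truth: list = []
    pop = F2Population(markers, dosages, pheno, truth, config)

    quant_traits: dict = {}
    for q in config.qtls:
        if q.recessive_class:
            continue
        quant_traits.setdefault(q.trait, []).append(q)
    for trait, qtls in quant_traits.items():
        value = np.full(n, config.trait_baseline, dtype=float)
        for q in qtls:
            dos = dosages[:, pop.marker_index(q.chrom, q.pos_bp)]
            value += q.additive * (dos - 1) + q.dominance * (dos == 1)
        value += rng_pheno.normal(0.0, config.trait_noise_sd, size=n)
        pheno[trait] = value
        truth.append(
            {
                "trait": trait,
                "chrom": qtls[0].chrom,
                "causal_pos": int(qtls[0].pos_bp),
                "additive": qtls[0].additive,
                "dominance": qtls[0].dominance,
                "expected_pve": expected_pve(
                    qtls[0].additive, qtls[0].dominance, config.trait_noise_sd
                ),
                "high_bulk": [],
                "low_bulk": [],
            }
        )

    for q in config.qtls:
        if not q.recessive_class:
            continue
        dos = dosages[:, pop.marker_index(q.chrom, q.pos_bp)]
        is_recessive = dos == 2
        if config.misclassification_rate > 0:
            flip = rng_pheno.random(n) < config.misclassification_rate
            is_recessive = is_recessive ^ flip
        pheno[q.trait] = np.where(
            is_recessive, q.recessive_label, q.dominant_label
        )
        truth.append(
            {
                "trait": q.trait,
                "chrom": q.chrom,
                "causal_pos": int(q.pos_bp),
                "mode": "recessive",
                "recessive_label": q.recessive_label,
                "dominant_label": q.dominant_label,
                "high_bulk": [],
                "low_bulk": [],
            }
        )
    return pop


def sample_bulk_counts(
    population: F2Population,
    bulk_members,
    rng: np.random.Generator,
    mean_depth: float | None = None,
    seq_error_rate: float | None = None,
    fixed_depth: bool | None = None,
) -> pd.DataFrame:
    """Pooled read counts for one bulk at every marker.

    Each bulk member contributes equal DNA (the equimolar-pooling protocol),
    so the true alternate-allele frequency at a site is
    f = 1 - sum(dosage) / (2 * bulk_size).  Depth is Poisson around the
    configured mean (or exactly the mean when ``fixed_depth``), and the
    alternate read count is Binomial(depth, f(1-e) + (1-f)e) with e the
    symmetric per-read error rate (two-allele fold-in; no third allele).

    Returns a DataFrame chrom, pos, ref, alt, ref_count, alt_count.
    """
    cfg = population.config
    mean_depth = cfg.mean_depth if mean_depth is None else mean_depth
    seq_error_rate = (
        cfg.seq_error_rate if seq_error_rate is None else seq_error_rate
    )
    fixed_depth = cfg.fixed_depth if fixed_depth is None else fixed_depth

    members = list(bulk_members)
    if not members:
        raise ValueError("empty bulk")
    idx = population.ids.get_indexer(members)
    if (idx < 0).any():
        missing = [m for m, i in zip(members, idx) if i < 0]
        raise KeyError(f"unknown bulk members: {missing}")

    dos = population.dosages[idx]  # (bulk, markers), reference-parent allele
    f_alt = 1.0 - dos.sum(axis=0) / (2.0 * len(members))
    p_alt_read = f_alt * (1.0 - seq_error_rate) + (1.0 - f_alt) * seq_error_rate

    m = f_alt.size
    if fixed_depth:
        depth = np.full(m, int(round(mean_depth)), dtype=np.int64)
    else:
        depth = rng.poisson(mean_depth, size=m)
    alt = rng.binomial(depth, p_alt_read)
    out = population.markers[["chrom", "pos", "ref", "alt"]].copy()
    out["ref_count"] = depth - alt
    out["alt_count"] = alt
    return out


def paired_site_counts(
    population: F2Population,
    high_bulk,
    low_bulk,
    rng: np.random.Generator,
    **kwargs,
) -> pd.DataFrame:
    """Site-count table for a high/low bulk pair.

    Columns: chrom, pos, ref, alt, high_ref, high_alt, low_ref, low_alt.
    The high bulk is the one whose trait state matches the reference parent
    (late-flowering / obcordate), so linked sites show index ~0 in it.
    """
    hi = sample_bulk_counts(population, high_bulk, rng, **kwargs)
    lo = sample_bulk_counts(population, low_bulk, rng, **kwargs)
    out = hi.rename(columns={"ref_count": "high_ref", "alt_count": "high_alt"})
    out["low_ref"] = lo["ref_count"]
    out["low_alt"] = lo["alt_count"]
    return out


def write_truth_json(truth: list, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")


def write_phenotypes_tsv(population: F2Population, path) -> None:
    df = population.phenotypes.reset_index()
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
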