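"""End-to-end orchestration: simulate, bulk, pseudo-reference, scan, annotate.

``run_pipeline`` ties the stages together in the order of a QTL-seq
experiment — bulk construction from phenotypes, pseudo-reference from
parent variants, SNP-index scan with null bands, candidate regions, effect
annotation — writing per-stage outputs and a final report into one output
directory.  A single run seed fans out to per-stage child seeds by stable
hashing of stage names, and the whole run is deterministic under a fixed
seed.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bulks, effects, pseudoref, simulate, vcfio
from .model import QTLSeqScan

log = logging.getLogger("bulkscan")

__all__ = ["RunConfig", "run_pipeline", "write_report", "generate_dataset", "child_rng"]


def child_seed(seed: int, stage: str) -> np.random.SeedSequence:
    """Stable per-stage seed derived from the run seed and the stage name."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])


def child_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


def generate_dataset(config: simulate.SimConfig, out_dir) -> dict:
    """Simulate an F2 experiment and write its files.

    For every trait in the configuration: selects extreme bulks (quantitative
    traits by phenotype extremes, Mendelian class traits by class), samples
    pooled read counts for the bulk pair, and writes a counts TSV plus a VCF
    with per-bulk AD fields.  Also writes the phenotype TSV and the
    ground-truth JSON (with bulk memberships filled in).  Returns paths and
    in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop = simulate.simulate_f2(config)
    simulate.write_phenotypes_tsv(pop, out / "phenotypes.tsv")

    chrom_lengths = {c.name: c.length_bp for c in config.chromosomes}
    counts: dict = {}
    for truth in pop.truth:
        trait = truth["trait"]
        if truth.get("mode") == "recessive":
            spec = bulks.BulkSpec(
                trait=trait,
                mode="categorical",
                n_per_bulk=config.bulk_size,
                high_label=truth["recessive_label"],
                low_label=truth["dominant_label"],
            )
        else:
            spec = bulks.BulkSpec(trait=trait, n_per_bulk=config.bulk_size)
        rng_bulk = child_rng(config.seed, f"bulk:{trait}")
        high, low = bulks.select_extreme_bulks(pop.phenotypes, spec, rng_bulk)
        truth["high_bulk"], truth["low_bulk"] = list(high), list(low)
        rng_counts = child_rng(config.seed, f"counts:{trait}")
        sites = simulate.paired_site_counts(pop, high, low, rng_counts)
        counts[trait] = sites
        vcfio.write_counts_tsv(sites, out / f"counts_{trait}.tsv")
        vcfio.write_bulk_vcf(
            sites, out / f"bulks_{trait}.vcf",
            high_name="HIGH", low_name="LOW", chrom_lengths=chrom_lengths,
        )
    simulate.write_truth_json(pop.truth, out / "truth.json")
    return {
        "population": pop,
        "counts": counts,
        "out_dir": str(out),
        "phenotypes": str(out / "phenotypes.tsv"),
        "truth": str(out / "truth.json"),
    }


@dataclass
class RunConfig:
    """File paths and parameters for one pipeline run."""

    out_dir: str
    # inputs (any subset; stages lacking inputs are skipped)
    counts_tsv: str | None = None
    vcf: str | None = None
    high_sample: str = "HIGH"
    low_sample: str = "LOW"
    phenotypes: str | None = None
    trait: str = ""
    bulk_mode: str = "quantitative"
    n_per_bulk: int = 15
    high_label: str | None = None
    low_label: str | None = None
    parent_vcf: str | None = None
    reference_fasta: str | None = None
    gff3: str | None = None
    # scan parameters
    min_depth: int = 7
    min_index: float = 0.3
    hom_threshold: float = 0.1
    depth_rule: str = "either"
    index_rule: str = "both"
    window_size: int = 1_000_000
    step: int = 10_000
    bulk_size: int = 15
    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.counts_tsv is None and self.vcf is None:
            raise ValueError("need counts_tsv or vcf")
        for name in ("counts_tsv", "vcf", "phenotypes", "parent_vcf",
                     "reference_fasta", "gff3"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RunResult:
    config: RunConfig
    results: object  # QTLSeqScanResults
    bulks: dict | None
    pseudo_report: pd.DataFrame | None
    effects: pd.DataFrame | None
    report: dict
    paths: dict


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the pipeline stages declared by the configuration."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(
        json.dumps(asdict(config), indent=2) + "\n"
    )
    paths: dict = {}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return result

    bulk_members = None
    if config.phenotypes:
        def _bulk():
            pheno = pd.read_csv(config.phenotypes, sep="\t", comment="#")
            spec = bulks.BulkSpec(
                trait=config.trait, mode=config.bulk_mode,
                n_per_bulk=config.n_per_bulk,
                high_label=config.high_label, low_label=config.low_label,
            )
            rng = child_rng(config.seed, "bulking")
            high, low = bulks.select_extreme_bulks(pheno, spec, rng)
            members = {"high": high, "low": low}
            (out / "bulks.json").write_text(json.dumps(members, indent=2) + "\n")
            log.info("stage=bulking in=%d out=%d+%d", len(pheno), len(high), len(low))
            return members
        bulk_members = stage("bulking", _bulk)
        paths["bulks"] = str(out / "bulks.json")

    pseudo_report = None
    pseudo_seqs = None
    if config.parent_vcf and config.reference_fasta:
        def _pseudo():
            ref = pseudoref.read_fasta(config.reference_fasta)
            parent = vcfio.read_parent_variants_vcf(config.parent_vcf)
            subs = pseudoref.filter_confident_parent_variants(
                parent, min_depth=config.min_depth
            )
            pseudo, report = pseudoref.apply_snp_substitutions(ref, subs)
            pseudoref.write_fasta(pseudo, out / "pseudo_reference.fasta")
            vcfio.write_counts_tsv(report, out / "substitutions.tsv")
            log.info(
                "stage=pseudo_reference in=%d applied=%d",
                len(parent), int((report["status"] == "applied").sum()),
            )
            return pseudo, report
        pseudo_seqs, pseudo_report = stage("pseudo_reference", _pseudo)
        paths["pseudo_reference"] = str(out / "pseudo_reference.fasta")

    def _scan():
        if config.counts_tsv:
            sites = vcfio.read_counts_tsv(config.counts_tsv)
        else:
            sites = vcfio.read_bulk_counts_vcf(
                config.vcf, config.high_sample, config.low_sample
            )
        model = QTLSeqScan(
            sites,
            min_depth=config.min_depth,
            min_index=config.min_index,
            hom_threshold=config.hom_threshold,
            depth_rule=config.depth_rule,
            index_rule=config.index_rule,
            window_size=config.window_size,
            step=config.step,
            bulk_size=config.bulk_size,
            n_reps=config.n_reps,
            trait=config.trait,
        )
        band_seed = int(child_seed(config.seed, "null_bands").generate_state(1)[0] % (2**31))
        res = model.fit(seed=band_seed, alpha=config.alpha)
        log.info(
            "stage=scan in=%d pass=%d causal=%d regions=%d",
            len(res.sites), int(res.sites["pass_filters"].sum()),
            int(res.sites["causal"].sum()), len(res.regions),
        )
        return res
    results = stage("scan", _scan)
    paths.update(results.save(out))

    effect_table = None
    seqs_for_effects = pseudo_seqs
    if config.gff3 and (seqs_for_effects or config.reference_fasta):
        def _annotate():
            seqs = seqs_for_effects or pseudoref.read_fasta(config.reference_fasta)
            models = effects.read_gff3(config.gff3)
            table = effects.annotate_variants(results.causal_sites, models, seqs)
            if len(table):
                table = table.merge(
                    results.causal_sites[
                        ["chrom", "pos", "index_high", "index_low", "delta"]
                    ],
                    on=["chrom", "pos"],
                )
            vcfio.write_counts_tsv(table, out / "effects.tsv")
            log.info("stage=annotate in=%d genic=%d",
                     len(table), int(table["gene"].notna().sum()) if len(table) else 0)
            return table
        effect_table = stage("effect_annotation", _annotate)
        paths["effects"] = str(out / "effects.tsv")

    report = write_report(results, effect_table, out)
    paths["report"] = str(out / "report.json")
    (out / "summary.txt").write_text(results.summary() + "\n")
    paths["summary"] = str(out / "summary.txt")
    return RunResult(
        config=config, results=results, bulks=bulk_members,
        pseudo_report=pseudo_report, effects=effect_table,
        report=report, paths=paths,
    )


def write_report(results, effect_table, out_dir) -> dict:
    """Final per-trait report: regions, spans, causal-SNP and effect counts."""
    regions = []
    for r in results.regions:
        entry = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "span_mb": r.span_mb,
            "alpha": r.alpha,
            "n_causal_snps": r.n_causal_snps,
        }
        if effect_table is not None and len(effect_table):
            summ = effects.summarize_region_effects(effect_table, r)
            entry.update(
                n_genic_snps=summ["n_genic_snps"],
                n_genes=summ["n_genes"],
                n_exon=summ["n_exon"],
                n_intron=summ["n_intron"],
                n_nsSNP=summ["n_nsSNP"],
                n_sSNP=summ["n_sSNP"],
            )
        regions.append(entry)
    report = {
        "trait": results.model.trait,
        "alpha": results.alpha,
        "n_regions": len(regions),
        "regions": regions,
        "filter_accounting": results.filter_accounting(),
    }
    path = Path(out_dir) / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
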