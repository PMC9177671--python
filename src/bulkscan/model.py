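"""Model/results surface for a QTL-seq bulked-segregant scan.

``QTLSeqScan`` is built from a per-site table of pooled allele counts for a
high and a low bulk; ``fit()`` computes SNP-indices, applies the site
filters, flags candidate causal SNPs (delta = -1), forms sliding-window
means, simulates depth-matched null confidence bands, and calls candidate
regions.  The returned ``QTLSeqScanResults`` carries the per-site records,
window statistics, bands and regions, and offers ``summary()``, ``plot()``
and ``save()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nullci, snpindex, vcfio

__all__ = ["QTLSeqScan", "QTLSeqScanResults"]


class QTLSeqScan:
    """A two-bulk QTL-seq scan model.

    Parameters
    ----------
    sites : DataFrame with chrom, pos, ref, alt, high_ref, high_alt,
        low_ref, low_alt.  The *high* bulk is the one matching the
        reference parent's trait state.
    min_depth, min_index, hom_threshold, depth_rule, index_rule :
        site-filter settings (see ``snpindex.apply_site_filters``).
    causal_criterion : rule for flagging causal SNPs ('neg' = delta == -1).
    window_size, step : sliding-window geometry in bp.
    bulk_size : individuals per bulk (null simulation).
    n_reps : null replicates per distinct depth pair.
    alphas : band levels to simulate (default P<0.05 and P<0.01).
    chrom_lengths : optional {chrom: bp} so windows tile whole chromosomes.
    trait : label carried into regions and reports.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        min_depth: int = 7,
        min_index: float = 0.3,
        hom_threshold: float = 0.1,
        depth_rule: str = "either",
        index_rule: str = "both",
        causal_criterion: str = "neg",
        window_size: int = 1_000_000,
        step: int = 10_000,
        bulk_size: int = 15,
        n_reps: int = 10_000,
        alphas=(0.05, 0.01),
        chrom_lengths: dict | None = None,
        trait: str = "",
    ):
        missing = [c for c in snpindex.SITE_COLUMNS if c not in sites.columns]
        if missing:
            raise KeyError(f"site table missing columns: {missing}")
        self.sites = sites.reset_index(drop=True)
        self.min_depth = min_depth
        self.min_index = min_index
        self.hom_threshold = hom_threshold
        self.depth_rule = depth_rule
        self.index_rule = index_rule
        self.causal_criterion = causal_criterion
        self.window_size = window_size
        self.step = step
        self.bulk_size = bulk_size
        self.n_reps = n_reps
        self.alphas = tuple(alphas)
        self.chrom_lengths = chrom_lengths
        self.trait = trait

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "QTLSeqScan":
        return cls(df, **kwargs)

    @classmethod
    def from_vcf(
        cls, path, high_sample: str, low_sample: str, **kwargs
    ) -> "QTLSeqScan":
        sites = vcfio.read_bulk_counts_vcf(path, high_sample, low_sample)
        return cls(sites, **kwargs)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "QTLSeqScan":
        return cls(vcfio.read_counts_tsv(path), **kwargs)

    def fit(
        self,
        seed: int = 0,
        alpha: float = 0.05,
        band_cache: nullci.NullBandCache | None = None,
    ) -> "QTLSeqScanResults":
        """Run the scan.  ``seed`` drives the null-band simulation only
        (everything else is deterministic); pass a shared ``band_cache`` to
        reuse bands across fits with identical bulk size and filters."""
        if alpha not in self.alphas:
            raise ValueError(f"alpha {alpha} not among configured levels {self.alphas}")
        records = snpindex.compute_indices(self.sites)
        records = snpindex.apply_site_filters(
            records,
            min_depth=self.min_depth,
            min_index=self.min_index,
            hom_threshold=self.hom_threshold,
            depth_rule=self.depth_rule,
            index_rule=self.index_rule,
        )
        records = snpindex.flag_causal(records, criterion=self.causal_criterion)
        windows = snpindex.sliding_window_means(
            records,
            window_size=self.window_size,
            step=self.step,
            chrom_lengths=self.chrom_lengths,
        )
        if band_cache is None:
            band_cache = nullci.NullBandCache(
                bulk_size=self.bulk_size,
                n_reps=self.n_reps,
                alphas=self.alphas,
                seed=seed,
                min_index=self.min_index,
                index_rule=self.index_rule,
            )
        regions, windows = nullci.call_regions(
            windows,
            band_cache,
            alpha=alpha,
            step=self.step,
            sites=records,
            trait=self.trait,
        )
        return QTLSeqScanResults(
            model=self,
            sites=records,
            windows=windows,
            regions=regions,
            bands=band_cache,
            alpha=alpha,
            seed=seed,
        )


@dataclass
class QTLSeqScanResults:
    """Fitted scan: per-site records, windows, null bands and regions."""

    model: QTLSeqScan
    sites: pd.DataFrame
    windows: pd.DataFrame
    regions: list
    bands: nullci.NullBandCache
    alpha: float
    seed: int

    @property
    def regions_frame(self) -> pd.DataFrame:
        return nullci.regions_to_frame(self.regions)

    @property
    def causal_sites(self) -> pd.DataFrame:
        return self.sites[self.sites["causal"]]

    def filter_accounting(self) -> dict:
        s = self.sites
        return {
            "n_sites": int(len(s)),
            "fail_depth": int(s["flag_low_depth"].sum()),
            "fail_low_index": int(s["flag_low_index"].sum()),
            "fail_homozygosity": int(s["flag_not_homozygous"].sum()),
            "pass_all": int(s["pass_filters"].sum()),
            "causal": int(s["causal"].sum()),
        }

    def summary(self) -> str:
        acc = self.filter_accounting()
        m = self.model
        lines = [
            "QTL-seq bulked-segregant scan",
            "=" * 64,
            f"trait: {m.trait or '(unnamed)'}    alpha: {self.alpha}",
            f"filters: depth >= {m.min_depth} ({m.depth_rule}), "
            f"index < {m.min_index} ({m.index_rule}), "
            f"homozygosity threshold {m.hom_threshold}",
            f"window {m.window_size} bp / step {m.step} bp; "
            f"bulk size {m.bulk_size}; null reps {m.n_reps}",
            "-" * 64,
            f"sites: {acc['n_sites']}   low depth: {acc['fail_depth']}   "
            f"low index: {acc['fail_low_index']}   "
            f"not homozygous: {acc['fail_homozygosity']}",
            f"passing all filters: {acc['pass_all']}   "
            f"causal (delta = -1): {acc['causal']}",
            f"windows: {len(self.windows)}   "
            f"significant: {int(self.windows['significant'].sum()) if len(self.windows) else 0}",
            "-" * 64,
        ]
        rf = self.regions_frame
        if len(rf):
            lines.append("candidate regions:")
            lines.append(
                rf[["chrom", "start", "end", "span_mb", "n_causal_snps"]]
                .to_string(index=False)
            )
        else:
            lines.append("candidate regions: none")
        return "\n".join(lines)

    def plot(self, chrom: str, ax=None):
        """Index and delta tracks for one chromosome with the confidence
        bands (green P<0.05, orange P<0.01) and called regions shaded."""
        import matplotlib.pyplot as plt

        win = self.windows[self.windows["chrom"] == chrom]
        if ax is None:
            fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 7))
        else:
            axes = ax
            fig = axes[0].figure
        x = win["start"] / 1e6
        axes[0].plot(x, win["mean_index_high"], lw=1, color="tab:blue")
        axes[0].set_ylabel("SNP-index (high)")
        axes[1].plot(x, win["mean_index_low"], lw=1, color="tab:blue")
        axes[1].set_ylabel("SNP-index (low)")
        axes[2].plot(x, win["mean_delta"], lw=1, color="black")
        axes[2].fill_between(
            x, win["band_lower"], win["band_upper"],
            color="green", alpha=0.25, label="P < 0.05",
        )
        if 0.01 in self.model.alphas:
            lo01 = [
                self.bands.band(int(round(dh)), int(round(dl)), 0.01)
                if np.isfinite(dh) and np.isfinite(dl) else (np.nan, np.nan)
                for dh, dl in zip(win["median_depth_high"], win["median_depth_low"])
            ]
            axes[2].fill_between(
                x, [b[0] for b in lo01], [b[1] for b in lo01],
                color="orange", alpha=0.2, label="P < 0.01",
            )
        for r in self.regions:
            if r.chrom == chrom:
                for a in axes:
                    a.axvspan(r.start / 1e6, r.end / 1e6, color="grey", alpha=0.2)
        axes[2].set_ylabel("delta SNP-index")
        axes[2].set_xlabel(f"{chrom} position (Mb)")
        axes[2].set_ylim(-1.05, 1.05)
        axes[2].legend(loc="upper right", fontsize=8)
        return fig

    def save(self, out_dir) -> dict:
        """Write sites, windows, bands and regions as TSV/BED into out_dir."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "sites": out / "sites.tsv",
            "windows": out / "windows.tsv",
            "bands": out / "bands.tsv",
            "regions": out / "regions.tsv",
            "regions_bed": out / "regions.bed",
        }
        vcfio.write_counts_tsv(self.sites, paths["sites"])
        vcfio.write_counts_tsv(self.windows, paths["windows"])
        vcfio.write_counts_tsv(self.bands.to_frame(), paths["bands"])
        vcfio.write_counts_tsv(self.regions_frame, paths["regions"])
        with open(paths["regions_bed"], "w") as fh:
            fh.write("# coordinates: 0-based half-open (BED convention)\n")
            for r in self.regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.trait or 'region'}\n")
        return {k: str(v) for k, v in paths.items()}
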