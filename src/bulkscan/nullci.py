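"""Null confidence bands for delta-SNP-index and candidate-region calling.

Under the null hypothesis of no QTL, each bulk is a random draw of F2
individuals, so a bulk's allele count at a site is Binomial(2 * bulk_size,
1/2) (each of the 2*bulk_size F1 gametes carries either parental allele with
probability 1/2 — equivalently bulk genotype contributions 0, 1/2, 1 with
probabilities 1/4, 1/2, 1/4), and sequencing resamples that frequency
binomially at the site's read depth.  Monte-Carlo replicates of this
two-stage draw give the null distribution of delta at a given depth pair;
its alpha/2 and 1-alpha/2 empirical quantiles are the plotted confidence
band (P < 0.05 and P < 0.01 in genome-wide delta plots).  Replicates that
would fail the observed-data low-index site filter are redrawn so the band
refers to the same record set as the windows.

Windows whose mean delta escapes the band at their median depth are
significant; overlapping or adjacent significant windows merge into
candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "simulate_null_delta",
    "ci_bounds",
    "NullBandCache",
    "CandidateRegion",
    "call_regions",
    "regions_to_frame",
]


def simulate_null_delta(
    depth_high: int,
    depth_low: int,
    bulk_size: int = 15,
    n_reps: int = 10_000,
    rng=None,
    min_index: float = 0.3,
    index_rule: str = "both",
) -> np.ndarray:
    """Sample the null distribution of delta-SNP-index.

    Returns exactly ``n_reps`` accepted replicates; rejection sampling
    enforces the low-index filter (default: redraw only when the index is
    below ``min_index`` in both bulks).  Deterministic for a fixed rng seed.
    """
    if depth_high < 1 or depth_low < 1:
        raise ValueError("depths must be >= 1")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if index_rule not in ("both", "either", "none"):
        raise ValueError("index_rule must be 'both', 'either' or 'none'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    out = np.empty(n_reps, dtype=float)
    filled = 0
    n_alleles = 2 * bulk_size
    batch = max(n_reps, 10_000)
    while filled < n_reps:
        f_high = rng.binomial(n_alleles, 0.5, size=batch) / n_alleles
        f_low = rng.binomial(n_alleles, 0.5, size=batch) / n_alleles
        idx_high = rng.binomial(depth_high, f_high) / depth_high
        idx_low = rng.binomial(depth_low, f_low) / depth_low
        if index_rule == "both":
            keep = ~((idx_high < min_index) & (idx_low < min_index))
        elif index_rule == "either":
            keep = ~((idx_high < min_index) | (idx_low < min_index))
        else:
            keep = np.ones(batch, dtype=bool)
        delta = idx_high[keep] - idx_low[keep]
        take = min(delta.size, n_reps - filled)
        out[filled : filled + take] = delta[:take]
        filled += take
    return out


def ci_bounds(null_sample, alpha: float):
    """Empirical (alpha/2, 1 - alpha/2) quantiles of a null delta sample."""
    sample = np.asarray(null_sample, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if sample.size < 10.0 / alpha:
        raise ValueError(
            f"sample of {sample.size} too small for alpha={alpha}; "
            f"need >= {int(np.ceil(10.0 / alpha))}"
        )
    lo, hi = np.quantile(sample, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


class NullBandCache:
    """Null delta bands memoised by (depth_high, depth_low).

    Each distinct depth pair is simulated once (``n_reps`` replicates) with
    an rng derived from the cache seed and the pair itself, so results do
    not depend on query order.  Bands are returned as (lower, upper) for the
    requested alpha.
    """

    def __init__(
        self,
        bulk_size: int = 15,
        n_reps: int = 10_000,
        alphas=(0.05, 0.01),
        seed: int = 0,
        min_index: float = 0.3,
        index_rule: str = "both",
    ):
        self.bulk_size = bulk_size
        self.n_reps = n_reps
        self.alphas = tuple(alphas)
        self.seed = seed
        self.min_index = min_index
        self.index_rule = index_rule
        self._cache: dict = {}

    def band(self, depth_high: int, depth_low: int, alpha: float):
        key = (int(depth_high), int(depth_low))
        if key not in self._cache:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, key[0], key[1]])
            )
            sample = simulate_null_delta(
                key[0],
                key[1],
                bulk_size=self.bulk_size,
                n_reps=self.n_reps,
                rng=rng,
                min_index=self.min_index,
                index_rule=self.index_rule,
            )
            self._cache[key] = {a: ci_bounds(sample, a) for a in self.alphas}
        bands = self._cache[key]
        if alpha not in bands:
            raise KeyError(f"alpha {alpha} not among cached levels {self.alphas}")
        return bands[alpha]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "depth_high": dh,
                "depth_low": dl,
                "alpha": a,
                "lower": lo,
                "upper": hi,
            }
            for (dh, dl), bands in sorted(self._cache.items())
            for a, (lo, hi) in sorted(bands.items(), reverse=True)
        ]
        return pd.DataFrame(
            rows, columns=["depth_high", "depth_low", "alpha", "lower", "upper"]
        )


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of significant windows.

    start/end are 1-based inclusive bp; span_mb is reported to two decimals,
    matching the convention of QTL-seq region reports (e.g. boundaries at
    19.22 and 20.80 Mb give a 1.58 Mb region).
    """

    chrom: str
    start: int
    end: int
    alpha: float
    n_windows: int = 0
    n_causal_snps: int = 0
    trait: str = ""

    @property
    def span_mb(self) -> float:
        return round((self.end - self.start) / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def regions_to_frame(regions) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "span_mb": r.span_mb,
            "alpha": r.alpha,
            "n_windows": r.n_windows,
            "n_causal_snps": r.n_causal_snps,
            "trait": r.trait,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "span_mb", "alpha", "n_windows",
            "n_causal_snps", "trait",
        ],
    )


def call_regions(
    windows: pd.DataFrame,
    bands,
    alpha: float = 0.05,
    step: int = 10_000,
    sites: pd.DataFrame | None = None,
    trait: str = "",
):
    """Call candidate regions from window statistics and null bands.

    ``bands`` is a NullBandCache or a callable (depth_high, depth_low,
    alpha) -> (lower, upper).  A window is significant when its mean delta
    lies outside the band evaluated at the window's median bulk depths.
    Significant windows on one chromosome separated by at most one step
    merge into a region spanning the outermost window edges.  When a
    causal-flagged site table is given, each region carries the count of
    causal SNPs it contains.

    Returns (regions, windows) where regions is a list of CandidateRegion
    and windows is the input with a ``significant`` column added.
    """
    band_of = bands.band if isinstance(bands, NullBandCache) else bands
    win = windows.copy()
    sig = np.zeros(len(win), dtype=bool)
    lowers = np.full(len(win), np.nan)
    uppers = np.full(len(win), np.nan)
    for i, row in enumerate(win.itertuples(index=False)):
        if row.n_snps <= 0 or not np.isfinite(row.mean_delta):
            continue
        lo, hi = band_of(
            int(round(row.median_depth_high)),
            int(round(row.median_depth_low)),
            alpha,
        )
        lowers[i], uppers[i] = lo, hi
        sig[i] = row.mean_delta < lo or row.mean_delta > hi
    win["band_lower"] = lowers
    win["band_upper"] = uppers
    win["significant"] = sig

    regions: list[CandidateRegion] = []
    for chrom, grp in win[win["significant"]].groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="stable")
        cur_start = cur_end = None
        cur_n = 0

        def emit(s, e, k):
            n_causal = 0
            if sites is not None and "causal" in sites.columns:
                in_reg = (
                    (sites["chrom"] == chrom)
                    & (sites["pos"] >= s)
                    & (sites["pos"] <= e)
                    & sites["causal"]
                )
                n_causal = int(in_reg.sum())
            regions.append(
                CandidateRegion(
                    chrom=chrom, start=int(s), end=int(e), alpha=alpha,
                    n_windows=k, n_causal_snps=n_causal, trait=trait,
                )
            )

        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_n = row.start, row.end, 1
            elif row.start <= cur_end + step + 1:
                cur_end = max(cur_end, row.end)
                cur_n += 1
            else:
                emit(cur_start, cur_end, cur_n)
                cur_start, cur_end, cur_n = row.start, row.end, 1
        if cur_start is not None:
            emit(cur_start, cur_end, cur_n)
    return regions, win
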