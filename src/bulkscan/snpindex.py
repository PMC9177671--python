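"""Per-site SNP-index / delta-SNP-index statistics, filters and windows.

The SNP-index at a site is the fraction of aligned reads carrying the
alternate (non-reference-parent) allele:

    SNP-index = alt_count / (ref_count + alt_count)

An index of 0 means every read matches the reference parent, 1 means every
read matches the other parent.  The delta-SNP-index contrasts the two bulks:

    delta = SNP-index(high bulk) - SNP-index(low bulk)

where by convention the *high* bulk is the one matching the reference
parent's trait state, so a trait-linked locus shows delta near -1.

Site tables are pandas DataFrames with columns
chrom, pos, ref, alt, high_ref, high_alt, low_ref, low_alt; positions are
1-based.  ``compute_indices`` adds depths, indices and delta;
``apply_site_filters`` adds boolean filter flags and a ``pass_filters``
column without ever mutating counts or dropping rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "snp_index",
    "delta_snp_index",
    "compute_indices",
    "classify_zygosity",
    "apply_site_filters",
    "flag_causal",
    "sliding_window_means",
]

SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "high_ref", "high_alt", "low_ref", "low_alt",
]


def snp_index(alt_count, depth):
    """alt_count / depth, elementwise; NaN where depth is 0."""
    alt = np.asarray(alt_count, dtype=float)
    dp = np.asarray(depth, dtype=float)
    if np.any((alt < 0) | (dp < 0)) or np.any(alt > dp):
        raise ValueError("need 0 <= alt_count <= depth")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(dp > 0, alt / np.where(dp > 0, dp, 1), np.nan)
    return out if out.ndim else float(out)


def delta_snp_index(index_high, index_low):
    """SNP-index of the high bulk minus SNP-index of the low bulk."""
    out = np.asarray(index_high, dtype=float) - np.asarray(index_low, dtype=float)
    return out if out.ndim else float(out)


def compute_indices(sites: pd.DataFrame) -> pd.DataFrame:
    """Add high_depth, low_depth, index_high, index_low and delta columns."""
    df = sites.copy()
    df["high_depth"] = df["high_ref"] + df["high_alt"]
    df["low_depth"] = df["low_ref"] + df["low_alt"]
    df["index_high"] = snp_index(df["high_alt"], df["high_depth"])
    df["index_low"] = snp_index(df["low_alt"], df["low_depth"])
    df["delta"] = delta_snp_index(df["index_high"], df["index_low"])
    return df


def classify_zygosity(index, hom_threshold: float = 0.1):
    """Bulk zygosity call from a SNP-index.

    hom_ref when index <= hom_threshold, hom_alt when index >=
    1 - hom_threshold, het otherwise ('undef' for NaN).  The threshold
    stands in for a caller genotype when only allele depths are available.
    """
    idx = np.asarray(index, dtype=float)
    out = np.full(idx.shape, "het", dtype=object)
    out[idx <= hom_threshold] = "hom_ref"
    out[idx >= 1.0 - hom_threshold] = "hom_alt"
    out[np.isnan(idx)] = "undef"
    return out if out.ndim else str(out)


def apply_site_filters(
    sites: pd.DataFrame,
    min_depth: int = 7,
    min_index: float = 0.3,
    hom_threshold: float = 0.1,
    depth_rule: str = "either",
    index_rule: str = "both",
) -> pd.DataFrame:
    """Flag sites against the depth, low-index and homozygosity filters.

    Depth filter: with ``depth_rule='either'`` (default, the stricter
    convention) a site fails when its depth is below ``min_depth`` in either
    bulk; ``'both'`` is the literal reading that fails a site only when both
    bulks are thin.  Low-index filter: with ``index_rule='both'`` (default,
    the spurious-SNP rule) a site fails when its index is below ``min_index``
    in *both* bulks; ``'either'`` is the literal reading, which would discard
    every delta = -1 site and is provided for reproducibility only.
    Homozygosity: both bulks must be homozygous (hom_ref or hom_alt) under
    ``classify_zygosity``.

    Adds flag_low_depth / flag_low_index / flag_not_homozygous,
    zygosity_high / zygosity_low, a ``filters`` summary string and
    ``pass_filters``; never removes or mutates rows.  The three flags are
    computed independently, so their application order is immaterial.
    """
    if depth_rule not in ("either", "both") or index_rule not in ("either", "both"):
        raise ValueError("depth_rule and index_rule must be 'either' or 'both'")
    df = sites if "delta" in sites.columns else compute_indices(sites)
    df = df.copy()

    thin_high = df["high_depth"] < min_depth
    thin_low = df["low_depth"] < min_depth
    if depth_rule == "either":
        df["flag_low_depth"] = thin_high | thin_low
    else:
        df["flag_low_depth"] = thin_high & thin_low

    lo_high = df["index_high"] < min_index
    lo_low = df["index_low"] < min_index
    if index_rule == "both":
        df["flag_low_index"] = lo_high & lo_low
    else:
        df["flag_low_index"] = lo_high | lo_low

    df["zygosity_high"] = classify_zygosity(df["index_high"], hom_threshold)
    df["zygosity_low"] = classify_zygosity(df["index_low"], hom_threshold)
    hom = {"hom_ref", "hom_alt"}
    df["flag_not_homozygous"] = ~(
        df["zygosity_high"].isin(hom) & df["zygosity_low"].isin(hom)
    )

    flags = np.array(["LOW_DEPTH", "LOW_INDEX", "NOT_HOMOZYGOUS"], dtype=object)
    mask = df[["flag_low_depth", "flag_low_index", "flag_not_homozygous"]].to_numpy()
    df["filters"] = [";".join(flags[row]) or "PASS" for row in mask]
    df["pass_filters"] = ~mask.any(axis=1)
    return df


def flag_causal(
    sites: pd.DataFrame,
    criterion: str = "neg",
    threshold: float = 1.0,
    atol: float = 0.0,
) -> pd.DataFrame:
    """Mark candidate causal SNPs.

    A site is causal-eligible when it passes every site filter and its delta
    meets the criterion: ``'neg'`` (default) requires delta == -1 exactly
    (the allele in the high bulk matching the reference parent and the low
    bulk fixed for the other parent), ``'abs'`` requires |delta| == 1, and
    ``'threshold'`` requires |delta| >= threshold.  ``atol`` relaxes exact
    comparison if needed.
    """
    df = sites if "pass_filters" in sites.columns else apply_site_filters(sites)
    df = df.copy()
    delta = df["delta"].to_numpy()
    if criterion == "neg":
        hit = np.abs(delta - (-1.0)) <= atol
    elif criterion == "abs":
        hit = np.abs(np.abs(delta) - 1.0) <= atol
    elif criterion == "threshold":
        hit = np.abs(delta) >= threshold
    else:
        raise ValueError(f"unknown causal criterion {criterion!r}")
    df["causal"] = hit & df["pass_filters"].to_numpy()
    return df


def sliding_window_means(
    sites: pd.DataFrame,
    window_size: int = 1_000_000,
    step: int = 10_000,
    chrom_lengths: dict | None = None,
    restrict_to: str | None = "window",
) -> pd.DataFrame:
    """Sliding-window means of the bulk indices and delta.

    Windows advance by ``step`` from the start of each chromosome; a SNP at
    1-based position p belongs to window [start0, start0 + window_size) with
    start0 0-based iff start0 <= p - 1 < start0 + window_size.  Reported
    coordinates are 1-based inclusive.  Means are arithmetic over member
    SNPs; empty windows report n_snps 0 and NaN means.  Per-window median
    bulk depths are carried for null-band lookup.

    ``restrict_to='window'`` (default) averages over sites passing the depth
    and low-index filters — the record set shown in genome-wide index plots —
    while the homozygosity filter only gates causal-SNP calls.  Use
    ``'pass'`` for fully filtered sites or None for all sites.
    """
    if window_size < step:
        raise ValueError("window_size must be >= step")
    df = sites if "delta" in sites.columns else compute_indices(sites)
    if restrict_to == "window":
        if "flag_low_depth" not in df.columns:
            df = apply_site_filters(df)
        df = df[~(df["flag_low_depth"] | df["flag_low_index"])]
    elif restrict_to == "pass":
        if "pass_filters" not in df.columns:
            df = apply_site_filters(df)
        df = df[df["pass_filters"]]
    elif restrict_to is not None:
        raise ValueError("restrict_to must be 'window', 'pass' or None")

    rows = []
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos0 = grp["pos"].to_numpy(dtype=np.int64) - 1
        length = None if chrom_lengths is None else chrom_lengths.get(chrom)
        span = length if length is not None else (int(pos0[-1]) + 1 if pos0.size else 0)
        if span <= 0:
            continue
        starts = np.arange(0, span, step, dtype=np.int64)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, starts + window_size, side="left")
        n = hi - lo

        def win_stat(values, reducer):
            out = np.full(starts.size, np.nan)
            vals = values.to_numpy(dtype=float)
            if reducer == "mean":
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                with np.errstate(invalid="ignore"):
                    out = np.where(n > 0, (csum[hi] - csum[lo]) / np.where(n > 0, n, 1), np.nan)
            else:  # median, per window (windows are small)
                for i in range(starts.size):
                    if n[i] > 0:
                        out[i] = np.median(vals[lo[i]:hi[i]])
            return out

        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts + 1,
                    "end": np.minimum(starts + window_size, span),
                    "n_snps": n,
                    "mean_index_high": win_stat(grp["index_high"], "mean"),
                    "mean_index_low": win_stat(grp["index_low"], "mean"),
                    "mean_delta": win_stat(grp["delta"], "mean"),
                    "median_depth_high": win_stat(grp["high_depth"], "median"),
                    "median_depth_low": win_stat(grp["low_depth"], "median"),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_snps", "mean_index_high",
                "mean_index_low", "mean_delta", "median_depth_high",
                "median_depth_low",
            ]
        )
    return pd.concat(rows, ignore_index=True)
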