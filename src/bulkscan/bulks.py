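"""Extreme-phenotype bulk construction and Mendelian segregation tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BulkSpec", "select_extreme_bulks", "segregation_chi_square"]


@dataclass(frozen=True)
class BulkSpec:
    """How to build a pair of bulks for one trait.

    mode "quantitative": the n_per_bulk highest-value individuals form the
    high bulk and the n_per_bulk lowest the low bulk.  mode "categorical":
    members of ``high_label`` form the high bulk and ``low_label`` the low
    bulk; an over-sized class is down-sampled with the run seed.  The high
    bulk is by convention the one matching the reference parent's trait
    state (late-flowering / obcordate leaf).
    """

    trait: str
    mode: str = "quantitative"
    n_per_bulk: int = 15
    high_label: str | None = None
    low_label: str | None = None

    def __post_init__(self):
        if self.mode not in ("quantitative", "categorical"):
            raise ValueError(f"unknown bulk mode {self.mode!r}")
        if self.n_per_bulk < 1:
            raise ValueError("n_per_bulk must be >= 1")
        if self.mode == "categorical" and not (self.high_label and self.low_label):
            raise ValueError("categorical mode needs high_label and low_label")


def select_extreme_bulks(
    phenotypes: pd.DataFrame,
    spec: BulkSpec,
    rng: np.random.Generator | None = None,
):
    """Select (high_bulk_ids, low_bulk_ids) from a phenotype table.

    ``phenotypes`` must carry individual ids in an ``id`` column or as its
    index, and a column named for the trait.  Selection is invariant to row
    order: rows are stably sorted on (value, id), so boundary ties resolve
    deterministically by id.
    """
    df = phenotypes.reset_index() if "id" not in phenotypes.columns else phenotypes
    if "id" not in df.columns or spec.trait not in df.columns:
        raise KeyError(f"phenotype table needs 'id' and {spec.trait!r} columns")
    df = df[["id", spec.trait]].dropna()
    n = spec.n_per_bulk

    if spec.mode == "quantitative":
        if len(df) < 2 * n:
            raise ValueError(
                f"need >= {2 * n} phenotyped individuals, have {len(df)}"
            )
        ordered = df.sort_values([spec.trait, "id"], kind="stable")
        low = ordered["id"].head(n).tolist()
        high = ordered["id"].tail(n).tolist()
        return high, low

    # categorical
    rng = np.random.default_rng(0) if rng is None else rng
    bulks = []
    for label in (spec.high_label, spec.low_label):
        members = sorted(df.loc[df[spec.trait] == label, "id"])
        if len(members) < n:
            raise ValueError(
                f"class {label!r} has {len(members)} members, need {n}"
            )
        if len(members) > n:
            members = sorted(rng.choice(members, size=n, replace=False))
        bulks.append(list(members))
    return bulks[0], bulks[1]


def segregation_chi_square(observed, expected_ratio=(3, 1)):
    """Pearson goodness-of-fit of two class counts to a Mendelian ratio.

    Returns (chi2, df, p_value) with df = 1.
    """
    a, b = observed
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    total = a + b
    if total == 0:
        raise ValueError("zero total count")
    ra, rb = expected_ratio
    expected = np.array([ra, rb], dtype=float) / (ra + rb) * total
    chi2, p = stats.chisquare([a, b], f_exp=expected)
    return float(chi2), 1, float(p)
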