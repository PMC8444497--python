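"""The four processed datasets, |k-3| deviation, binning, and summaries.

The raw solved table is processed into four variants that differ in how
asymmetric forks and extreme exponents are handled:

* **V1** — every fork with a computable exponent (degenerate and
  uncomputable forks dropped and counted);
* **V2** — V1 minus mixed (asymmetric) forks;
* **V3** — V2 with k truncated to the interval [-14, 20];
* **V4** — V1 minus mixed minus both-wider forks, k truncated above at 20.

The deviation statistic is |k - 3|, distance from the Murray optimum,
recomputed from the (possibly truncated) k of each variant.  Scatter
summaries sort by a key (d0 or angle) and average consecutive groups of
20 forks; analyses downstream of the variants run on the unbinned rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Variant",
    "VariantTable",
    "BinnedSeries",
    "make_variant",
    "bin_means",
    "summarize_threshold_slice",
    "VariantFilter",
]

MURRAY_K = 3.0
TRUNCATE_LOW = -14.0
TRUNCATE_HIGH = 20.0


class Variant(str, Enum):
    V1 = "V1"  # raw: all computable k
    V2 = "V2"  # asymmetric (mixed) removed
    V3 = "V3"  # mixed removed, k truncated to [-14, 20]
    V4 = "V4"  # standard forks only, k truncated above at 20

    @classmethod
    def coerce(cls, value) -> "Variant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unknown variant {value!r}; expected one of {[v.value for v in cls]}"
            )


@dataclass
class VariantTable:
    """One processed dataset with per-row k and deviation, plus provenance.

    ``rows`` keeps the original index of the solved table so nesting
    (V4 within V2 within V1) can be checked by record identity.
    ``provenance`` counts rows dropped by each rule and rows truncated.
    """

    variant: Variant
    rows: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self):
        return len(self.rows)


def _computable(frame: pd.DataFrame) -> pd.Series:
    return frame["k"].notna() & frame["case"].isin(
        ["standard", "both_wider", "mixed"]
    )


def make_variant(solved: pd.DataFrame, variant_id) -> VariantTable:
    """Build one of the four processed datasets from a solved table.

    The input must carry ``k`` and ``case`` columns (``k`` NaN for
    uncomputable forks).  Deviation |k-3| is recomputed after truncation.
    """
    variant = Variant.coerce(variant_id)
    for col in ("k", "case"):
        if col not in solved.columns:
            raise ValueError(f"solved table lacks required column {col!r}")

    n_in = len(solved)
    keep = _computable(solved)
    n_uncomputable = int((~keep).sum())
    rows = solved.loc[keep].copy()

    n_mixed_dropped = 0
    n_both_wider_dropped = 0
    if variant in (Variant.V2, Variant.V3, Variant.V4):
        mixed = rows["case"] == "mixed"
        n_mixed_dropped = int(mixed.sum())
        rows = rows.loc[~mixed]
    if variant is Variant.V4:
        wider = rows["case"] == "both_wider"
        n_both_wider_dropped = int(wider.sum())
        rows = rows.loc[~wider]

    n_truncated = 0
    if variant is Variant.V3:
        clipped = rows["k"].clip(lower=TRUNCATE_LOW, upper=TRUNCATE_HIGH)
        n_truncated = int((clipped != rows["k"]).sum())
        rows["k"] = clipped
    elif variant is Variant.V4:
        clipped = rows["k"].clip(upper=TRUNCATE_HIGH)
        n_truncated = int((clipped != rows["k"]).sum())
        rows["k"] = clipped

    rows["deviation"] = (rows["k"] - MURRAY_K).abs()
    provenance = {
        "n_input": n_in,
        "n_retained": len(rows),
        "n_uncomputable_dropped": n_uncomputable,
        "n_mixed_dropped": n_mixed_dropped,
        "n_both_wider_dropped": n_both_wider_dropped,
        "n_truncated": n_truncated,
    }
    assert (
        provenance["n_retained"]
        + n_uncomputable
        + n_mixed_dropped
        + n_both_wider_dropped
        == n_in
    )
    return VariantTable(variant=variant, rows=rows, provenance=provenance)


@dataclass
class BinnedSeries:
    """Means over consecutive groups of ``bin_size`` forks after a stable
    sort by ``sort_key``; the trailing remainder is dropped and counted."""

    sort_key: str
    bin_size: int
    table: pd.DataFrame  # columns: mean sort key, mean_k, mean_deviation, n
    n_dropped_remainder: int


def bin_means(
    variant: VariantTable,
    sort_key: str = "d0",
    bin_size: int = 20,
) -> BinnedSeries:
    """Sorted group-of-``bin_size`` means of k and |k-3|.

    Rows are stable-sorted by the key (ties keep input order), split into
    consecutive full bins, and averaged; a remainder shorter than
    ``bin_size`` is dropped from the series (it stays in all unbinned
    analyses).
    """
    rows = variant.rows
    if sort_key not in rows.columns:
        raise ValueError(f"sort key {sort_key!r} not present in variant table")
    usable = rows.loc[rows[sort_key].notna()]
    n = len(usable)
    n_bins = n // bin_size
    if n_bins == 0:
        import warnings

        warnings.warn(
            f"fewer than bin_size={bin_size} rows ({n}); empty binned series",
            stacklevel=2,
        )
        empty = pd.DataFrame(
            columns=[f"mean_{sort_key}", "mean_k", "mean_deviation", "n"]
        )
        return BinnedSeries(sort_key, bin_size, empty, n)

    ordered = usable.sort_values(sort_key, kind="stable")
    head = ordered.iloc[: n_bins * bin_size]
    group = np.repeat(np.arange(n_bins), bin_size)
    agg = head.groupby(group).agg(
        **{
            f"mean_{sort_key}": (sort_key, "mean"),
            "mean_k": ("k", "mean"),
            "mean_deviation": ("deviation", "mean"),
        }
    )
    agg["n"] = bin_size
    return BinnedSeries(sort_key, bin_size, agg.reset_index(drop=True), n - n_bins * bin_size)


def summarize_threshold_slice(
    variant: VariantTable,
    d0_min: Optional[float] = None,
    top_n: Optional[int] = None,
    n_boot: int = 10_000,
    seed: Optional[int] = None,
    ci_method: str = "bootstrap",
) -> dict:
    """Mean k with a 95% CI over a large-diameter slice of a variant.

    The slice is either every fork with ``d0 >= d0_min`` or the ``top_n``
    forks with the largest parent diameters.  The CI is a seeded
    nonparametric bootstrap percentile interval by default; a
    t-interval is available via ``ci_method='t'``.
    """
    if (d0_min is None) == (top_n is None):
        raise ValueError("specify exactly one of d0_min or top_n")
    rows = variant.rows
    if d0_min is not None:
        sliced = rows.loc[rows["d0"] >= d0_min]
        label = f"d0 >= {d0_min}"
    else:
        sliced = rows.nlargest(top_n, "d0")
        label = f"top {top_n} d0"
    if sliced.empty:
        raise ValueError(f"empty slice for {label}")

    k = sliced["k"].to_numpy(float)
    mean = float(k.mean())
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, k.size, size=(n_boot, k.size))
        boots = k[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    elif ci_method == "t":
        from scipy import stats

        se = k.std(ddof=1) / np.sqrt(k.size)
        tcrit = stats.t.ppf(0.975, k.size - 1)
        lo, hi = mean - tcrit * se, mean + tcrit * se
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return {
        "slice": label,
        "n": int(k.size),
        "mean_k": mean,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "d0_range": (float(sliced["d0"].min()), float(sliced["d0"].max())),
    }


class VariantFilter(BaseEstimator, TransformerMixin):
    """Sklearn transformer building one processed dataset from a solved table.

    ``fit`` records the drop/truncate provenance as ``provenance_``;
    ``transform`` returns the filtered rows with the recomputed deviation.
    """

    def __init__(self, variant: str = "V1"):
        self.variant = variant

    def fit(self, X: pd.DataFrame, y=None) -> "VariantFilter":
        vt = make_variant(X, self.variant)
        self.provenance_ = vt.provenance
        self.variant_ = vt.variant
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return make_variant(X, self.variant).rows
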