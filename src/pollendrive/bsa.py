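"""Bulk segregant analysis: pooled allele frequencies and the dSNP index.

Two phenotype-contrasted progeny pools are sequenced in bulk; per-marker
alt-allele frequencies are consolidated into 100 kb bins, smoothed in a
sliding window, and the per-window frequency difference (the dSNP index)
is tested with a two-proportion z-test on window-aggregated read counts,
Benjamini-Hochberg corrected across windows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

__all__ = ["delta_snp_index", "bsa_significance"]

log = logging.getLogger(__name__)

POOL_COLUMNS = ("chrom", "pos", "ref_count", "alt_count")


def _check_pool(pool: pd.DataFrame, name: str) -> pd.DataFrame:
    missing = [c for c in POOL_COLUMNS if c not in pool.columns]
    if missing:
        raise ValueError(f"pool {name} missing columns {missing}")
    if (pool[["ref_count", "alt_count"]] < 0).any().any():
        raise ValueError(f"pool {name} has negative counts")
    return pool.reset_index(drop=True)


def delta_snp_index(
    pool_a: pd.DataFrame,
    pool_b: pd.DataFrame,
    bin_size: int = 100_000,
    window: int = 1_000_000,
    step: int = 200_000,
) -> pd.DataFrame:
    """Windowed dSNP index, freq(pool_a) - freq(pool_b).

    Per-marker frequencies alt/(ref+alt) (zero-depth markers excluded) are
    averaged in ``bin_size`` bins, bins averaged in sliding windows; raw
    counts are aggregated per window for the significance test.  Returns a
    frame with chrom, start, end, mid, freq_a, freq_b, delta and the
    aggregated counts.
    """
    a = _check_pool(pool_a, "A")
    b = _check_pool(pool_b, "B")
    if not a[["chrom", "pos"]].equals(b[["chrom", "pos"]]):
        raise ValueError("pools must share the same marker set")
    if window < step:
        raise ValueError("window must be >= step")

    markers = a[["chrom", "pos"]].copy()
    for tag, pool in (("a", a), ("b", b)):
        depth = pool["ref_count"] + pool["alt_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            markers[f"freq_{tag}"] = np.where(depth > 0, pool["alt_count"] / depth, np.nan)
        markers[f"alt_{tag}"] = pool["alt_count"]
        markers[f"tot_{tag}"] = depth
    markers["bin"] = (markers["pos"] - 1) // bin_size

    binned = (
        markers.groupby(["chrom", "bin"], sort=False)
        .agg(
            freq_a=("freq_a", "mean"),
            freq_b=("freq_b", "mean"),
            alt_a=("alt_a", "sum"),
            tot_a=("tot_a", "sum"),
            alt_b=("alt_b", "sum"),
            tot_b=("tot_b", "sum"),
        )
        .reset_index()
    )
    binned["mid"] = binned["bin"] * bin_size + bin_size / 2

    rows = []
    for chrom, sub in binned.groupby("chrom", sort=False):
        span_end = int((sub["bin"].max() + 1) * bin_size)
        start = 0
        while start < span_end:
            end = start + window
            inw = sub[(sub["mid"] >= start) & (sub["mid"] < end)]
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "mid": (start + end) // 2,
                    "freq_a": inw["freq_a"].mean(),
                    "freq_b": inw["freq_b"].mean(),
                    "alt_a": inw["alt_a"].sum(),
                    "tot_a": inw["tot_a"].sum(),
                    "alt_b": inw["alt_b"].sum(),
                    "tot_b": inw["tot_b"].sum(),
                }
            )
            start += step
    track = pd.DataFrame(rows)
    track["delta"] = track["freq_a"] - track["freq_b"]
    return track


def bsa_significance(track: pd.DataFrame, fdr: float = 0.01) -> pd.DataFrame:
    """Flag windows whose pooled allele frequencies differ significantly.

    Two-proportion z-test on window-aggregated alt/total counts, BH across
    windows; windows with q <= fdr are flagged.  Degenerate windows (zero
    depth in either pool, or both frequencies pinned at 0 or 1) are skipped
    with a log entry.
    """
    out = track.copy()
    pvals = np.full(len(out), np.nan)
    for i, row in out.iterrows():
        tot = np.array([row["tot_a"], row["tot_b"]], dtype=float)
        alt = np.array([row["alt_a"], row["alt_b"]], dtype=float)
        pooled = alt.sum() / tot.sum() if tot.min() > 0 else np.nan
        if tot.min() <= 0 or pooled in (0.0, 1.0) or np.isnan(pooled):
            log.info("skipping degenerate window %s:%s", row["chrom"], row["start"])
            continue
        _, p = proportions_ztest(alt, tot)
        pvals[i] = p
    out["p"] = pvals
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] <= fdr
    return out
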