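"""Single-pollen-grain genotype analysis.

Sparse, error-prone genotype calls from whole-genome-amplified single
pollen grains are binned, smoothed, imputed with a two-state haploid HMM,
and aggregated into per-marker transmission frequencies; intervals
transmitted in excess of the Mendelian 0.5 expectation are called as
driven.  Pollen grains are haploid, so ancestry imputation reduces to a
two-state (recurrent-parent vs donor) hidden Markov chain whose transition
probabilities are the Haldane recombination fractions of the marker gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetics import MarkerSet, haldane_r

__all__ = [
    "SparseGenotypeMatrix",
    "BinTrack",
    "AncestryPosterior",
    "bin_signal",
    "sliding_window_smooth",
    "impute_ancestry_hmm",
    "aggregate_allele_frequency",
    "call_driven_intervals",
]


@dataclass(frozen=True)
class SparseGenotypeMatrix:
    """Markers x grains call matrix; 1 = alt (donor), -1 = ref, 0 = missing."""

    data: np.ndarray
    markers: MarkerSet

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.int8)
        if arr.ndim != 2 or arr.shape[0] != self.markers.n_markers:
            raise ValueError("data must be (n_markers, n_grains)")
        if not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError("calls must be in {1, -1, 0}")
        object.__setattr__(self, "data", arr)

    @property
    def n_grains(self) -> int:
        return int(self.data.shape[1])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"grain{i}" for i in range(self.n_grains)]
        df = pd.DataFrame(self.data, columns=cols)
        return pd.concat(
            [self.markers.table[["chrom", "pos"]].reset_index(drop=True), df], axis=1
        )


@dataclass
class BinTrack:
    """Per-bin mean signal; bins are 0-based half-open and tile each chromosome."""

    bins: pd.DataFrame  # chrom, start, end
    values: np.ndarray  # (n_bins,) or (n_bins, n_grains); NaN = missing
    bin_size: int

    def per_grain(self) -> bool:
        return self.values.ndim == 2


def _bin_edges(markers: MarkerSet, bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom in markers.chroms:
        sl = markers.chrom_slice(chrom)
        last = int(markers.pos[sl][-1])
        n_bins = (last - 1) // bin_size + 1
        for b in range(n_bins):
            rows.append({"chrom": chrom, "start": b * bin_size, "end": (b + 1) * bin_size})
    return pd.DataFrame(rows)


def bin_signal(matrix: SparseGenotypeMatrix, bin_size: int = 100_000) -> BinTrack:
    """Mean of non-missing calls per bin per grain; empty bins are NaN."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    bins = _bin_edges(matrix.markers, bin_size)
    n_bins, n_grains = len(bins), matrix.n_grains
    values = np.full((n_bins, n_grains), np.nan)
    bin_row0 = {c: int(bins.index[bins["chrom"] == c][0]) for c in matrix.markers.chroms}
    for chrom in matrix.markers.chroms:
        sl = matrix.markers.chrom_slice(chrom)
        pos = matrix.markers.pos[sl]
        calls = matrix.data[sl]
        which = (pos - 1) // bin_size + bin_row0[chrom]
        nonzero = calls != 0
        sums = np.zeros((n_bins, n_grains))
        counts = np.zeros((n_bins, n_grains))
        np.add.at(sums, which, np.where(nonzero, calls, 0))
        np.add.at(counts, which, nonzero)
        with np.errstate(invalid="ignore"):
            vals = sums / counts
        rows = np.unique(which)
        values[rows] = vals[rows]
    return BinTrack(bins, values, bin_size)


def sliding_window_smooth(
    track: BinTrack, window: int = 1_000_000, step: int = 200_000
) -> pd.DataFrame:
    """Sliding-window mean of non-missing bins, reported at window midpoints.

    Returns a frame with chrom, start, end, mid and one value column per
    grain (or a single 'value' column for aggregate tracks).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if window < track.bin_size:
        raise ValueError("window must be at least one bin wide")
    vals = track.values if track.per_grain() else track.values[:, None]
    out_rows = []
    out_vals = []
    mids = (track.bins["start"].to_numpy() + track.bins["end"].to_numpy()) / 2.0
    for chrom in track.bins["chrom"].unique():
        mask = (track.bins["chrom"] == chrom).to_numpy()
        cmids = mids[mask]
        cvals = vals[mask]
        span_end = int(track.bins.loc[mask, "end"].max())
        start = 0
        while start < span_end:
            end = start + window
            inw = (cmids >= start) & (cmids < end)
            sub = cvals[inw]
            called = (~np.isnan(sub)).sum(axis=0)
            with np.errstate(invalid="ignore"):
                mean = np.where(called > 0, np.nansum(sub, axis=0) / np.maximum(called, 1), np.nan)
            out_rows.append({"chrom": chrom, "start": start, "end": end, "mid": (start + end) // 2})
            out_vals.append(mean)
            start += step
    res = pd.DataFrame(out_rows)
    arr = np.vstack(out_vals)
    if track.per_grain():
        for g in range(arr.shape[1]):
            res[f"grain{g}"] = arr[:, g]
    else:
        res["value"] = arr[:, 0]
    return res


@dataclass
class AncestryPosterior:
    """Posterior donor-ancestry per marker for one grain."""

    p_alt: np.ndarray  # P(donor ancestry) per marker
    decoded: np.ndarray  # int8: 1 alt, -1 ref, 0 below-threshold
    switch_points: list[int]  # marker indices where the decoded state changes
    threshold: float


def _hmm_forward_backward(
    obs: np.ndarray, cm: np.ndarray, eps: float
) -> np.ndarray:
    """Scaled forward-backward for the 2-state haploid ancestry chain.

    obs in {1,-1,0}; state 0 = ref ancestry, 1 = alt.  Returns P(state=1)
    per marker.
    """
    m = obs.size
    # emission[i, s]
    emit = np.ones((m, 2))
    emit[obs == 1, 1] = 1 - eps
    emit[obs == 1, 0] = eps
    emit[obs == -1, 0] = 1 - eps
    emit[obs == -1, 1] = eps
    r = haldane_r(np.diff(cm))
    fwd = np.empty((m, 2))
    scale = np.empty(m)
    fwd[0] = 0.5 * emit[0]
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for i in range(1, m):
        stay, sw = 1 - r[i - 1], r[i - 1]
        pred0 = fwd[i - 1, 0] * stay + fwd[i - 1, 1] * sw
        pred1 = fwd[i - 1, 0] * sw + fwd[i - 1, 1] * stay
        fwd[i, 0] = pred0 * emit[i, 0]
        fwd[i, 1] = pred1 * emit[i, 1]
        scale[i] = fwd[i].sum()
        fwd[i] /= scale[i]
    bwd = np.empty((m, 2))
    bwd[-1] = 1.0
    for i in range(m - 2, -1, -1):
        stay, sw = 1 - r[i], r[i]
        b0 = bwd[i + 1, 0] * emit[i + 1, 0]
        b1 = bwd[i + 1, 1] * emit[i + 1, 1]
        bwd[i, 0] = stay * b0 + sw * b1
        bwd[i, 1] = sw * b0 + stay * b1
        bwd[i] /= bwd[i].sum()
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1]


def impute_ancestry_hmm(
    calls: np.ndarray,
    markers: MarkerSet,
    eps: float = 0.05,
    threshold: float = 0.9,
) -> AncestryPosterior:
    """Forward-backward ancestry imputation for one grain.

    Transitions between adjacent markers use the Haldane recombination
    fraction of their cM gap (chromosomes are independent chains); a call
    matches the underlying ancestry with probability 1-eps and missing
    calls are uninformative.  Posteriors above ``threshold`` (below
    1-threshold) give hard alt (ref) calls; the rest stay missing.
    """
    calls = np.asarray(calls, dtype=np.int8)
    if calls.shape != (markers.n_markers,):
        raise ValueError("calls must be a per-marker vector")
    if np.count_nonzero(calls) < 2:
        raise ValueError("need at least two informative markers")
    p_alt = np.empty(markers.n_markers)
    for chrom in markers.chroms:
        sl = markers.chrom_slice(chrom)
        p_alt[sl] = _hmm_forward_backward(calls[sl], markers.cm[sl], eps)
    decoded = np.zeros(markers.n_markers, dtype=np.int8)
    decoded[p_alt >= threshold] = 1
    decoded[p_alt <= 1 - threshold] = -1
    hard = np.flatnonzero(decoded != 0)
    switches = [int(hard[i]) for i in range(1, hard.size) if decoded[hard[i]] != decoded[hard[i - 1]]]
    return AncestryPosterior(p_alt, decoded, switches, threshold)


def aggregate_allele_frequency(matrix: SparseGenotypeMatrix) -> np.ndarray:
    """Per-marker donor-allele frequency across grains, ignoring missing calls."""
    if matrix.n_grains < 1:
        raise ValueError("need at least one grain")
    alt = (matrix.data == 1).sum(axis=1)
    ref = (matrix.data == -1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(alt + ref > 0, alt / np.maximum(alt + ref, 1), np.nan)


def call_driven_intervals(
    matrix: SparseGenotypeMatrix,
    bin_size: int = 100_000,
    alpha: float = 0.05,
    min_grains: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call genomic intervals over-transmitted relative to Mendelian 0.5.

    Each grain contributes one ancestry vote per bin (the sign of its mean
    bin signal); the per-bin test is an exact one-sided binomial against
    p=0.5, corrected across bins by Benjamini-Hochberg; adjacent significant
    bins merge into intervals.  Returns (intervals, per-bin table).
    """
    if matrix.n_grains < min_grains:
        raise ValueError(f"need at least {min_grains} grains")
    track = bin_signal(matrix, bin_size)
    sign = np.sign(np.nan_to_num(track.values, nan=0.0))
    k = (sign > 0).sum(axis=1)
    n = (sign != 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = np.where(n > 0, stats.binom.sf(k - 1, np.maximum(n, 1), 0.5), np.nan)
    bins = track.bins.copy()
    bins["n_alt"] = k
    bins["n_called"] = n
    bins["p"] = pvals
    tested = bins["p"].notna()
    bins["q"] = np.nan
    if tested.any():
        bins.loc[tested, "q"] = multipletests(bins.loc[tested, "p"], method="fdr_bh")[1]
    bins["significant"] = bins["q"] <= alpha

    intervals = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        cur = None
        for _, row in sub.iterrows():
            if row["significant"]:
                if cur is None:
                    cur = [row["start"], row["end"], row["q"]]
                else:
                    cur[1] = row["end"]
                    cur[2] = min(cur[2], row["q"])
            elif cur is not None:
                intervals.append({"chrom": chrom, "start": cur[0], "end": cur[1], "min_q": cur[2]})
                cur = None
        if cur is not None:
            intervals.append({"chrom": chrom, "start": cur[0], "end": cur[1], "min_q": cur[2]})
    cols = ["chrom", "start", "end", "min_q"]
    return pd.DataFrame(intervals, columns=cols), bins
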