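"""Selection-scan statistics and admixture-interval correlation.

Implements extended haplotype homozygosity (EHH) and the integrated
haplotype score (iHS) with derived-frequency-bin standardisation; the
windowed extreme-|iHS|-count statistic with SNP-count-decile empirical
p-values and Bonferroni adjustment across populations; windowed
Weir-Cockerham F_ST; minimum-p assignment to gene regions; and pairwise
Spearman correlation of donor-allele frequencies across populations for a
set of introgression intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import HaplotypePanel

__all__ = [
    "ehh",
    "ihs",
    "standardize_ihs",
    "window_extreme_count",
    "quantile_binned_empirical_p",
    "bonferroni_adjust",
    "wc_fst",
    "gene_region_p",
    "interval_admixture_correlation",
]

log = logging.getLogger(__name__)


def ehh(panel: HaplotypePanel, core: int, allele: int) -> np.ndarray:
    """Extended haplotype homozygosity around a core SNP for one allele.

    EHH(x) is the probability that two random carriers of ``allele`` at the
    ``core`` SNP are identical over every SNP between the core and x
    (inclusive).  EHH at the core is 1 and EHH is non-increasing outward in
    both directions.  Requires >= 2 carriers.
    """
    carriers = panel.matrix[panel.matrix[:, core] == allele]
    n = carriers.shape[0]
    if n < 2:
        raise ValueError("need at least two carriers of the core allele")
    denom = n * (n - 1) / 2.0
    out = np.empty(panel.n_snp)
    out[core] = 1.0
    for direction in (1, -1):
        groups = np.zeros(n, dtype=np.int64)
        j = core + direction
        while 0 <= j < panel.n_snp:
            groups = groups * 2 + carriers[:, j]
            _, counts = np.unique(groups, return_counts=True)
            out[j] = (counts * (counts - 1) / 2.0).sum() / denom
            # re-encode group ids compactly to avoid overflow on long runs
            _, groups = np.unique(groups, return_inverse=True)
            j += direction
    return out


def _ihh_one_side(
    carriers: np.ndarray, cm: np.ndarray, core: int, direction: int, truncation: float
) -> tuple[float, bool]:
    """Trapezoid integral of EHH over cM outward until EHH < truncation.

    Walks outward computing EHH incrementally and stops at the truncation
    threshold, so the cost stays proportional to the homozygosity tract.
    Returns (integral, decayed); ``decayed`` is False when the chromosome
    edge is reached before EHH falls below the cutoff, in which case the
    integral is biased and the SNP should be skipped.
    """
    n = carriers.shape[0]
    denom = n * (n - 1) / 2.0
    total = 0.0
    prev_e, prev_x = 1.0, cm[core]
    groups = np.zeros(n, dtype=np.int64)
    j = core + direction
    while 0 <= j < cm.size:
        groups = groups * 2 + carriers[:, j]
        _, groups, counts = np.unique(groups, return_inverse=True, return_counts=True)
        e = (counts * (counts - 1) / 2.0).sum() / denom
        x = cm[j]
        total += 0.5 * (prev_e + e) * abs(x - prev_x)
        if e < truncation:
            return total, True
        prev_e, prev_x = e, x
        j += direction
    return total, prev_e < truncation


@dataclass
class IhsResult:
    table: pd.DataFrame  # snp, pos_bp, freq_derived, ihh_anc, ihh_der, ihs_raw, ihs


def ihs(
    panel: HaplotypePanel,
    maf_min: float = 0.05,
    truncation: float = 0.05,
    n_bins: int = 50,
    include_edges: bool = False,
) -> IhsResult:
    """Integrated haplotype score, standardised in derived-frequency bins.

    Per SNP: iHH is the trapezoid integral of EHH over the genetic map
    (both directions, truncated where EHH drops below ``truncation``) for
    ancestral and derived core alleles; the unstandardised score is
    ln(iHH_ancestral / iHH_derived), standardised to mean 0 / sd 1 within
    derived-allele-frequency bins.  SNPs below the MAF floor, with < 2
    carriers of either allele, with a zero iHH, or (unless
    ``include_edges``) whose EHH has not decayed below ``truncation`` when
    the chromosome edge is reached, are skipped with a log entry.
    """
    rows = []
    freqs = panel.matrix.mean(axis=0)
    for snp in range(panel.n_snp):
        f = freqs[snp]
        if min(f, 1 - f) < maf_min:
            continue
        car_d = panel.matrix[panel.matrix[:, snp] == 1]
        car_a = panel.matrix[panel.matrix[:, snp] == 0]
        if car_d.shape[0] < 2 or car_a.shape[0] < 2:
            continue
        parts = [
            _ihh_one_side(car, panel.pos_cm, snp, d, truncation)
            for car in (car_d, car_a)
            for d in (1, -1)
        ]
        if not include_edges and not all(decayed for _, decayed in parts):
            log.info("skipping SNP %d: EHH did not decay before the chromosome edge", snp)
            continue
        ihh_d = parts[0][0] + parts[1][0]
        ihh_a = parts[2][0] + parts[3][0]
        if ihh_d <= 0 or ihh_a <= 0:
            log.info("skipping SNP %d: zero integrated homozygosity", snp)
            continue
        rows.append(
            {
                "snp": snp,
                "pos_bp": int(panel.pos_bp[snp]),
                "freq_derived": f,
                "ihh_anc": ihh_a,
                "ihh_der": ihh_d,
                "ihs_raw": np.log(ihh_a / ihh_d),
            }
        )
    tab = pd.DataFrame(rows, columns=["snp", "pos_bp", "freq_derived", "ihh_anc", "ihh_der", "ihs_raw"])
    return IhsResult(standardize_ihs(tab, n_bins=n_bins))


def standardize_ihs(table: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """(Re-)standardise raw iHS scores within derived-frequency bins.

    Operates on any table with ``ihs_raw`` and ``freq_derived`` columns -
    in particular on several per-chromosome tables concatenated together,
    which is how a genome-wide scan is standardised (a sweep then occupies
    a small fraction of each frequency bin instead of dominating it).
    """
    tab = table.copy()
    tab["ihs"] = np.nan
    if len(tab):
        bins = np.clip((tab["freq_derived"] * n_bins).astype(int), 0, n_bins - 1)
        for b in np.unique(bins):
            idx = (bins == b).to_numpy()
            if idx.sum() < 2:
                continue
            v = tab.loc[idx, "ihs_raw"]
            sd = v.std(ddof=0)
            if sd > 0:
                tab.loc[idx, "ihs"] = (v - v.mean()) / sd
    return tab


def window_extreme_count(
    pos_bp: np.ndarray,
    scores: np.ndarray,
    window: int = 10_000,
    extreme_quantile: float = 0.95,
    genome_span: int | None = None,
) -> pd.DataFrame:
    """Count extreme (top-quantile) |score| SNPs per genomic window.

    The extreme threshold is the genome-wide ``extreme_quantile`` of
    |scores| (NaNs excluded); windows are 0-based half-open tiles.
    """
    pos = np.asarray(pos_bp)
    sc = np.abs(np.asarray(scores, dtype=float))
    if pos.size == 0:
        raise ValueError("empty genome: no scored SNPs")
    ok = np.isfinite(sc)
    threshold = float(np.quantile(sc[ok], extreme_quantile)) if ok.any() else np.inf
    span = genome_span if genome_span is not None else int(pos.max()) + 1
    n_windows = (span - 1) // window + 1
    which = np.minimum((pos - 1) // window, n_windows - 1)
    n_snps = np.bincount(which, minlength=n_windows)
    extreme = np.bincount(which[ok & (sc > threshold)], minlength=n_windows)
    return pd.DataFrame(
        {
            "start": np.arange(n_windows) * window,
            "end": (np.arange(n_windows) + 1) * window,
            "n_snps": n_snps,
            "n_extreme": extreme,
        }
    ).assign(threshold=threshold)


def quantile_binned_empirical_p(
    windows: pd.DataFrame, n_bins: int = 10, stat: str = "n_extreme"
) -> pd.DataFrame:
    """Empirical p-values within SNP-count quantile bins.

    Windows are partitioned into ``n_bins`` quantiles of their SNP count;
    within each bin the p-value of a window is the fraction of windows in
    the bin whose statistic is >= its own (descending rank / bin size), so
    ties share the most conservative rank and p is in (0, 1].
    """
    if len(windows) < n_bins:
        raise ValueError("need at least as many windows as bins")
    out = windows.reset_index(drop=True).copy()
    ranks = out["n_snps"].rank(method="first")
    out["snp_bin"] = pd.qcut(ranks, n_bins, labels=False)
    p = np.empty(len(out))
    for b, sub in out.groupby("snp_bin"):
        vals = sub[stat].to_numpy()
        geq = (vals[:, None] <= vals[None, :]).sum(axis=1)  # count >= own
        p[sub.index.to_numpy()] = geq / len(sub)
    out["p_empirical"] = p
    return out


def bonferroni_adjust(p: np.ndarray | pd.Series, n_populations: int) -> np.ndarray:
    """Bonferroni adjustment for testing the same windows in several populations."""
    if n_populations < 1:
        raise ValueError("n_populations must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_populations)


def wc_fst(
    alt_counts: np.ndarray,
    n_alleles: np.ndarray,
    pos_bp: np.ndarray | None = None,
    window: int = 10_000,
) -> tuple[pd.DataFrame | float, pd.Series]:
    """Weir-Cockerham F_ST from per-population allele counts.

    ``alt_counts`` and ``n_alleles`` are (n_snps, n_pops).  Per SNP the
    among/within mean squares give variance components; the windowed
    weighted estimate is the ratio of summed components
    sum(MSP - MSG) / sum(MSP + (n_c - 1) MSG).  Monomorphic windows are
    missing.  Returns (window table or the genome-wide ratio when
    ``pos_bp`` is None, per-SNP theta).
    """
    alt = np.asarray(alt_counts, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    if alt.shape != n.shape or alt.ndim != 2 or alt.shape[1] < 2:
        raise ValueError("need (n_snps, n_pops) counts for >= 2 populations")
    r = alt.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
    nsum = n.sum(axis=1)
    pbar = alt.sum(axis=1) / nsum
    msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (n * p * (1 - p)).sum(axis=1) / (n - 1).sum(axis=1)
    n_c = (nsum - (n**2).sum(axis=1) / nsum) / (r - 1)
    num = msp - msg
    den = msp + (n_c - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / den, np.nan)
    theta_snp = pd.Series(theta, name="theta")

    if pos_bp is None:
        d = den.sum()
        return (float(num.sum() / d) if d > 0 else float("nan")), theta_snp
    pos = np.asarray(pos_bp)
    n_windows = (int(pos.max()) - 1) // window + 1
    which = (pos - 1) // window
    rows = []
    for w in range(n_windows):
        m = which == w
        d = den[m].sum()
        rows.append(
            {
                "start": w * window,
                "end": (w + 1) * window,
                "n_snps": int(m.sum()),
                "fst": num[m].sum() / d if m.any() and d > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows), theta_snp


def gene_region_p(
    genes: pd.DataFrame, windows: pd.DataFrame, flank: int = 1_000
) -> pd.DataFrame:
    """Assign each gene the minimum p of windows intersecting it +/- flank.

    ``genes``: name, start, end (0-based half-open); ``windows``: start,
    end, and a ``p`` column.  Genes touching no window get NaN.
    """
    out = []
    ws = windows["start"].to_numpy()
    we = windows["end"].to_numpy()
    wp = windows["p"].to_numpy(dtype=float)
    for _, g in genes.iterrows():
        lo, hi = g["start"] - flank, g["end"] + flank
        hit = (ws < hi) & (we > lo)
        out.append(
            {
                "name": g["name"],
                "p": float(np.nanmin(wp[hit])) if hit.any() and np.isfinite(wp[hit]).any() else np.nan,
            }
        )
    return pd.DataFrame(out)


def interval_admixture_correlation(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of interval donor-allele frequencies.

    Rows are populations, columns are introgression intervals.  Returns the
    correlation matrix (unit diagonal, NaN for constant intervals) and the
    BH-adjusted p-value matrix (adjusted over the upper triangle).
    """
    if len(table) < 4:
        raise ValueError("need at least 4 populations")
    cols = list(table.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    qmat = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    raw = []
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            x, y = table[cols[i]], table[cols[j]]
            if x.nunique() <= 1 or y.nunique() <= 1:
                rho.iloc[i, j] = rho.iloc[j, i] = np.nan
                continue
            r, p = stats.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            raw.append(p)
            pairs.append((i, j))
    if raw:
        qs = multipletests(raw, method="fdr_bh")[1]
        for (i, j), qv in zip(pairs, qs):
            qmat.iloc[i, j] = qmat.iloc[j, i] = qv
    for i, c in enumerate(cols):
        if table[c].nunique() <= 1:
            rho.iloc[i, i] = np.nan
    return rho, qmat
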