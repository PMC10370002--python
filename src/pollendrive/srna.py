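"""Small-RNA cluster discovery, hairpin-locus identification, and
differential cluster accumulation.

Clusters are read islands (merge gap <= ``max_gap``) retained when they
pass a CPM cutoff and show a clear size bias toward one of the canonical
Dicer sizes (21, 22 or 24 nt).  Hairpin (inverted-repeat) loci are called
from strand bias, 22nt bias, reverse-complement self-alignment of the
underlying sequence, and a base-pairing fraction from a Nussinov-style
maximum-matching fold.  Differential accumulation between replicated
conditions uses a negative-binomial exact test with a moment-estimated
common dispersion and Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "call_clusters",
    "identify_hairpins",
    "differential_clusters",
    "dsrna_template_check",
    "nussinov_max_pairs",
    "self_complement_alignment",
]

SIZE_RANGE = tuple(range(20, 26))
DICER_SIZES = (21, 22, 24)
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def call_clusters(
    reads: pd.DataFrame,
    library_size: int | None = None,
    min_cpm: float = 5.0,
    max_gap: int = 75,
    min_modal_fraction: float = 0.5,
    keep_all: bool = False,
) -> pd.DataFrame:
    """De novo small-RNA cluster calling from alignment records.

    ``reads`` columns: chrom, start (0-based), length, strand, count; must
    be sorted by (chrom, start).  Reads closer than ``max_gap`` merge into
    one island.  Retained clusters have CPM >= ``min_cpm`` and a modal read
    size in {21, 22, 24} holding >= ``min_modal_fraction`` of reads.
    """
    req = ["chrom", "start", "length", "strand", "count"]
    if any(c not in reads.columns for c in req):
        raise ValueError(f"reads must have columns {req}")
    for _, sub in reads.groupby("chrom", sort=False):
        if np.any(np.diff(sub["start"].to_numpy()) < 0):
            raise ValueError("alignment records must be sorted by start within chromosome")
    if library_size is None:
        library_size = int(reads["count"].sum())

    rows = []
    for chrom, sub in reads.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = starts + sub["length"].to_numpy()
        cummax_end = np.maximum.accumulate(ends)
        new_island = np.r_[True, starts[1:] > cummax_end[:-1] + max_gap]
        island = np.cumsum(new_island) - 1
        for isl in np.unique(island):
            part = sub[island == isl]
            total = int(part["count"].sum())
            cpm = total * 1e6 / library_size if library_size > 0 else 0.0
            sizes = part.groupby("length")["count"].sum()
            by_size = {f"n{k}": int(sizes.get(k, 0)) for k in SIZE_RANGE}
            modal = int(sizes.idxmax())
            modal_frac = float(sizes.max() / total)
            plus = int(part.loc[part["strand"] == "+", "count"].sum())
            strand_frac = max(plus, total - plus) / total
            retained = (
                cpm >= min_cpm
                and modal in DICER_SIZES
                and modal_frac >= min_modal_fraction
            )
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(part["start"].min()),
                    "end": int((part["start"] + part["length"]).max()),
                    "count": total,
                    "cpm": cpm,
                    "dominant_size": modal,
                    "modal_fraction": modal_frac,
                    "plus_count": plus,
                    "minus_count": total - plus,
                    "strand_fraction": strand_frac,
                    "frac22": by_size["n22"] / total,
                    **by_size,
                    "retained": retained,
                }
            )
    clusters = pd.DataFrame(rows)
    if clusters.empty or keep_all:
        return clusters
    return clusters[clusters["retained"]].reset_index(drop=True)


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested Watson-Crick/wobble pairs (Nussinov DP).

    A position may pair with another at distance > ``min_loop``; pairs are
    non-crossing.  O(n^3) with the bifurcation loop vectorised per
    diagonal.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return 0
    arr = np.frombuffer(s.encode(), dtype="S1")
    code = np.zeros(n, dtype=np.int8)
    for i, b in enumerate("ACGU"):
        code[arr == b.encode()] = i
    # pairable matrix
    can = np.zeros((n, n), dtype=bool)
    pairs = [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]  # AU UA CG GC GU UG
    for a, b in pairs:
        can |= (code[:, None] == a) & (code[None, :] == b)
    N = np.zeros((n + 1, n + 1), dtype=np.int32)  # N[i, j] over s[i:j]
    for span in range(min_loop + 2, n + 1):
        i = np.arange(0, n - span + 1)
        j = i + span
        best = N[i, j - 1].copy()  # j-1 unpaired
        # bifurcation: s[i:k] + s[k:j]; pairing of j-1 with k-1 is covered
        # because N[k-1:j] includes that pair via the recursion below
        pairij = can[i, j - 1] & (span - 1 > min_loop)
        cand = np.where(pairij, N[i + 1, j - 1] + 1, -1)
        best = np.maximum(best, cand)
        for k in range(1, span):
            inner = can[i + k, j - 1] & (span - k - 1 > min_loop)
            cand = np.where(inner, N[i, i + k] + N[i + k + 1, j - 1] + 1, -1)
            best = np.maximum(best, cand)
        N[i, j] = best
    return int(N[0, n])


def self_complement_alignment(seq: str, window: int = 50) -> tuple[int, float]:
    """Best local alignment of a sequence against its reverse complement.

    Returns (aligned length, identity), where identity is evaluated over
    the best ``window``-column stretch of the alignment so that an inverted
    repeat's arms are not diluted by the loop the alignment spans.
    """
    comp = str.maketrans("ACGTU", "TGCAA")
    rc = seq.upper().translate(comp)[::-1]
    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=-2, open_gap_score=-6, extend_gap_score=-2
    )
    aln = aligner.align(seq.upper(), rc)
    if len(aln) == 0:
        return 0, 0.0
    best = aln[0]
    a, b = best[0], best[1]
    match = np.array([x == y and x != "-" for x, y in zip(a, b)], dtype=float)
    length = len(a)
    if length == 0:
        return 0, 0.0
    if length <= window:
        return length, float(match.mean())
    sums = np.convolve(match, np.ones(window), mode="valid")
    return length, float(sums.max() / window)


def identify_hairpins(
    clusters: pd.DataFrame,
    genome: dict[str, str],
    min_strand_fraction: float = 0.8,
    min_frac22: float = 0.5,
    min_align_len: int = 50,
    min_identity: float = 0.8,
    min_pairing_fraction: float = 0.6,
    max_fold_len: int = 600,
) -> pd.DataFrame:
    """Call hairpin (hp-siRNA) loci among retained clusters.

    A cluster is a hairpin iff reads are single-strand biased
    (>= ``min_strand_fraction``), disproportionately 22 nt
    (>= ``min_frac22``), its sequence aligns to its own reverse complement
    over >= ``min_align_len`` bp at >= ``min_identity``, and the
    Nussinov-fold pairing fraction is >= ``min_pairing_fraction``.  The
    thresholds quantify the qualitative criteria (strand bias, 22nt bias,
    self-complementarity, thermodynamic stability proxy) and are all
    configurable.  Sequences longer than ``max_fold_len`` are folded over
    their central window.
    """
    rows = []
    for _, cl in clusters.iterrows():
        chrom_seq = genome[cl["chrom"]]
        if cl["end"] > len(chrom_seq):
            raise ValueError(f"cluster {cl['chrom']}:{cl['start']}-{cl['end']} exceeds sequence")
        seq = chrom_seq[int(cl["start"]) : int(cl["end"])]
        if len(seq) > max_fold_len:
            mid = len(seq) // 2
            seq_fold = seq[mid - max_fold_len // 2 : mid + max_fold_len // 2]
        else:
            seq_fold = seq
        if cl["strand_fraction"] < min_strand_fraction or cl["frac22"] < min_frac22:
            continue
        aln_len, ident = self_complement_alignment(seq, window=min_align_len)
        if aln_len < min_align_len or ident < min_identity:
            continue
        pairing = 2.0 * nussinov_max_pairs(seq_fold) / len(seq_fold)
        if pairing < min_pairing_fraction:
            continue
        rows.append(
            {
                "chrom": cl["chrom"],
                "start": cl["start"],
                "end": cl["end"],
                "cpm": cl["cpm"],
                "strand_fraction": cl["strand_fraction"],
                "frac22": cl["frac22"],
                "align_len": aln_len,
                "align_identity": ident,
                "pairing_fraction": pairing,
            }
        )
    cols = [
        "chrom", "start", "end", "cpm", "strand_fraction", "frac22",
        "align_len", "align_identity", "pairing_fraction",
    ]
    return pd.DataFrame(rows, columns=cols)


def _common_dispersion(pseudo: np.ndarray, groups: list[np.ndarray]) -> float:
    """Moment estimator of the NB dispersion pooled over clusters/conditions."""
    ests = []
    for idx in groups:
        sub = pseudo[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = (v[ok] - m[ok]) / m[ok] ** 2
        ests.append(phi)
    allphi = np.concatenate(ests)
    allphi = allphi[np.isfinite(allphi)]
    if allphi.size == 0:
        return 1e-4
    return float(max(np.mean(allphi), 1e-4))


def _nb_exact_p(ya: int, yb: int, na: int, nb_: int, phi: float) -> float:
    """Exact conditional NB test of equal means given the total ya+yb.

    Group sums are NB with mean n*mu and dispersion phi/n; the two-sided
    p-value sums the probabilities of all splits of the total no more
    likely than the observed one (the doubling-free exact-test construction
    used for sequence count data).
    """
    t = ya + yb
    if t == 0:
        return 1.0
    mu = t / (na + nb_)
    k = np.arange(t + 1)

    def logpmf(y, n):
        mean = n * mu
        disp = phi / n
        if disp <= 1e-12:
            return stats.poisson.logpmf(y, mean)
        size = 1.0 / disp
        p = size / (size + mean)
        return stats.nbinom.logpmf(y, size, p)

    logp = logpmf(k, na) + logpmf(t - k, nb_)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[ya]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-10)].sum()))


def differential_clusters(
    counts_a: pd.DataFrame | np.ndarray,
    counts_b: pd.DataFrame | np.ndarray,
    lfc: float = 2.0,
    q: float = 0.01,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Differential small-RNA cluster accumulation between two conditions.

    Counts are clusters x replicates.  Libraries are CPM-normalised to the
    mean library size, a common NB dispersion is moment-estimated (or
    supplied), and each cluster gets an exact conditional NB test.  Flagged
    clusters satisfy |log2FC| >= ``lfc`` and BH q <= ``q``.  All-zero
    clusters are excluded; a single replicate per condition is refused
    unless ``dispersion`` is given.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("counts must be clusters x replicates with matching clusters")
    if (a.shape[1] < 2 or b.shape[1] < 2) and dispersion is None:
        raise ValueError("need >=2 replicates per condition unless a dispersion is supplied")

    lib = np.concatenate([a.sum(axis=0), b.sum(axis=0)])
    if np.any(lib == 0):
        raise ValueError("a library has zero total counts")
    target = lib.mean()
    pa = a / a.sum(axis=0, keepdims=True) * target
    pb = b / b.sum(axis=0, keepdims=True) * target

    nonzero = (a.sum(axis=1) + b.sum(axis=1)) > 0
    na, nb_ = a.shape[1], b.shape[1]
    if dispersion is None:
        both = np.hstack([pa, pb])
        dispersion = _common_dispersion(both, [np.arange(na), na + np.arange(nb_)])

    mean_a = pa.mean(axis=1)
    mean_b = pb.mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    pvals = np.full(a.shape[0], np.nan)
    for i in np.flatnonzero(nonzero):
        ya = int(round(pa[i].sum()))
        yb = int(round(pb[i].sum()))
        pvals[i] = _nb_exact_p(ya, yb, na, nb_, dispersion)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p": pvals,
            "tested": nonzero,
        }
    )
    out["q"] = np.nan
    if nonzero.any():
        out.loc[nonzero, "q"] = multipletests(out.loc[nonzero, "p"], method="fdr_bh")[1]
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["flagged"] = nonzero & (np.abs(out["log2fc"]) >= lfc) & (out["q"] <= q)
    out.attrs["dispersion"] = dispersion
    return out


def dsrna_template_check(
    plus_count: int, minus_count: int, max_dominant_fraction: float = 0.6
) -> bool:
    """True when strand balance is consistent with a dsRNA template.

    Clusters processed from double-stranded precursors show negligible
    strand bias; the dominant-strand fraction must not exceed
    ``max_dominant_fraction``.
    """
    total = plus_count + minus_count
    if total == 0:
        raise ValueError("no strand counts")
    return max(plus_count, minus_count) / total <= max_dominant_fraction
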