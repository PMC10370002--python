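"""Small-RNA target prediction, Argonaute sorting, and degradome support.

Guide/target complementarity is scored with the widely used plant scheme:
each mismatch costs 1.0, each G:U wobble 0.5, bulges 2.0, and penalties
double over guide positions 2-13 (the seed-proximal core); sites at or
below the expectation cutoff (default 5.0) are reported.  Argonaute-mediated
cleavage falls between the target nucleotides opposite guide positions 10
and 11, so degradome (5'-monophosphate capture) read pileups at that
coordinate validate a predicted site; a central mismatch or bulge
(positions 9-11) instead predicts translational repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "GuideRNA",
    "TargetSite",
    "CleavageProfile",
    "score_target",
    "ago_sorting",
    "extract_cleavage_profile",
    "cleavage_support",
    "classify_responder_haplotype",
]

RNA = set("ACGU")
_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
AGO_BY_5P = {"A": "Ago2", "C": "Ago5", "U": "Ago1", "G": "unclassified"}


def _as_rna(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    if set(s) - RNA:
        raise ValueError(f"{what} contains non-RNA characters: {sorted(set(s) - RNA)}")
    return s


@dataclass(frozen=True)
class GuideRNA:
    """A small-RNA guide strand (20-25 nt, RNA alphabet)."""

    sequence: str

    def __post_init__(self) -> None:
        s = _as_rna(self.sequence, "guide")
        if not 20 <= len(s) <= 25:
            raise ValueError("guide length must be 20-25 nt")
        object.__setattr__(self, "sequence", s)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def five_prime(self) -> str:
        return self.sequence[0]


@dataclass
class TargetSite:
    """A predicted guide binding site on a transcript (0-based half-open)."""

    transcript_pos: tuple[int, int]
    score: float
    states: list[tuple[int, int | None, str]]  # (guide pos 1-based, target pos, state)
    cleavage_coord: int  # target position opposite guide nt 10
    mode: str  # "cleavage" or "translational"

    @property
    def seed_span(self) -> tuple[int, int]:
        """Target positions opposite guide nts 2-8 (half-open)."""
        tp = [t for g, t, _ in self.states if t is not None and 2 <= g <= 8]
        return (min(tp), max(tp) + 1)

    def positions_opposite(self, guide_positions: tuple[int, ...] = (10, 11)) -> list[int]:
        return [t for g, t, _ in self.states if t is not None and g in guide_positions]


def _pair_state(g: str, t: str) -> str:
    if (g, t) in _PAIR:
        return "match"
    if (g, t) in _WOBBLE:
        return "wobble"
    return "mismatch"


def _position_weight(gpos: int, core: tuple[int, int]) -> float:
    return 2.0 if core[0] <= gpos <= core[1] else 1.0


def _align_site(
    guide: str,
    window: str,
    win_start: int,
    mismatch: float,
    gu: float,
    gap: float,
    core: tuple[int, int],
) -> tuple[float, list[tuple[int, int | None, str]]]:
    """Needleman-Wunsch of the guide against a target window.

    Guide position p (1-based, 5'->3') pairs antiparallel with the target,
    so the guide is matched against the reversed window; gaps in the guide
    row are target bulges.  End gaps in the target are free so the window
    may be slightly longer than the guide.
    """
    g = guide
    t = window[::-1]  # align guide 5'->3' against target 3'->5'
    n, m = len(g), len(t)
    INF = float("inf")
    D = np.full((n + 1, m + 1), INF)
    D[0, :] = 0.0  # free leading target overhang
    for i in range(1, n + 1):
        w = _position_weight(i, core)
        for j in range(m + 1):
            best = INF
            if j >= 1:
                st = _pair_state(g[i - 1], t[j - 1])
                cost = {"match": 0.0, "wobble": gu * w, "mismatch": mismatch * w}[st]
                best = D[i - 1, j - 1] + cost
            if j >= 1:
                best = min(best, D[i, j - 1] + gap)  # target bulge
            best = min(best, D[i - 1, j] + gap * w)  # guide bulge
            D[i, j] = best
    j_end = int(np.argmin(D[n]))
    score = float(D[n, j_end])
    # traceback
    states: list[tuple[int, int | None, str]] = []
    i, j = n, j_end
    while i > 0:
        w = _position_weight(i, core)
        if j >= 1:
            st = _pair_state(g[i - 1], t[j - 1])
            cost = {"match": 0.0, "wobble": gu * w, "mismatch": mismatch * w}[st]
            if abs(D[i, j] - (D[i - 1, j - 1] + cost)) < 1e-9:
                tpos = win_start + (m - j)  # target coordinate of t[j-1]
                states.append((i, tpos, st))
                i, j = i - 1, j - 1
                continue
        if j >= 1 and abs(D[i, j] - (D[i, j - 1] + gap)) < 1e-9:
            states.append((i, win_start + (m - j), "target-bulge"))
            j -= 1
            continue
        states.append((i, None, "guide-bulge"))
        i -= 1
    states.reverse()
    return score, states


def score_target(
    guide: GuideRNA,
    transcript: str,
    cutoff: float = 5.0,
    mismatch: float = 1.0,
    gu: float = 0.5,
    gap: float = 2.0,
    core: tuple[int, int] = (2, 13),
) -> list[TargetSite]:
    """Scan a transcript for guide binding sites at or below the cutoff.

    Overlapping candidate windows are reduced to local best hits.  The
    predicted cleavage coordinate is the transcript position opposite guide
    nt 10; a mismatch or bulge at guide positions 9-11 switches the mode to
    translational repression.
    """
    t = _as_rna(transcript, "transcript")
    g = guide.sequence
    if len(t) < len(g):
        raise ValueError("transcript shorter than guide")
    slack = 2
    hits: list[TargetSite] = []
    for start in range(0, len(t) - len(g) + 1):
        end = min(start + len(g) + slack, len(t))
        score, states = _align_site(g, t[start:end], start, mismatch, gu, gap, core)
        if score > cutoff:
            continue
        opp10 = [tp for gp, tp, _ in states if gp == 10 and tp is not None]
        if not opp10:
            continue
        tpos = [tp for _, tp, _ in states if tp is not None]
        # a mismatch or bulge over the cleavage-flanking positions predicts
        # translational repression; a G:U wobble still permits slicing
        central = [st for gp, _, st in states if 9 <= gp <= 11]
        mode = "cleavage" if all(s in ("match", "wobble") for s in central) else "translational"
        hits.append(
            TargetSite(
                transcript_pos=(min(tpos), max(tpos) + 1),
                score=score,
                states=states,
                cleavage_coord=opp10[0],
                mode=mode,
            )
        )
    # de-overlap: keep the best-scoring site among mutually overlapping hits
    hits.sort(key=lambda h: (h.score, h.transcript_pos))
    kept: list[TargetSite] = []
    for h in hits:
        if all(
            h.transcript_pos[1] <= k.transcript_pos[0] or h.transcript_pos[0] >= k.transcript_pos[1]
            for k in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.transcript_pos)
    return kept


def ago_sorting(guide: GuideRNA) -> str:
    """Predicted Argonaute effector from the guide 5' nucleotide.

    5'-A guides load Ago2, 5'-C Ago5, 5'-U Ago1; 5'-G is unclassified.
    """
    return AGO_BY_5P[guide.five_prime]


@dataclass
class CleavageProfile:
    """Per-transcript-position counts of degradome read 5' ends."""

    counts: np.ndarray
    library_size: int
    cpm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.cpm = counts * 1e6 / self.library_size if self.library_size > 0 else counts * 0.0


def extract_cleavage_profile(
    positions: np.ndarray | list[int], transcript_length: int, library_size: int
) -> CleavageProfile:
    """Histogram of read 5' ends (the cloned 5' monophosphates), CPM-normalised."""
    pos = np.asarray(positions, dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= transcript_length):
        raise ValueError("read 5' position outside transcript bounds")
    counts = np.bincount(pos, minlength=transcript_length).astype(float)
    return CleavageProfile(counts, library_size)


def cleavage_support(
    site: TargetSite,
    profile: CleavageProfile,
    tolerance: int = 1,
    floor_cpm: float = 1.0,
    quantile: float = 0.9,
) -> bool:
    """Does the degradome profile support cleavage at the predicted site?

    Supported iff the maximum CPM within ``tolerance`` nt of the predicted
    cleavage coordinate reaches the background floor and strictly exceeds
    the ``quantile``-th quantile of the transcript-wide profile (a flat
    profile therefore supports nothing).
    """
    c = site.cleavage_coord
    lo, hi = max(0, c - tolerance), min(profile.cpm.size, c + tolerance + 1)
    peak = float(profile.cpm[lo:hi].max()) if hi > lo else 0.0
    return peak >= floor_cpm and peak > float(np.quantile(profile.cpm, quantile))


def classify_responder_haplotype(
    allele: str,
    reference: str,
    sites: list[TargetSite],
    min_aligned_fraction: float = 0.5,
) -> dict[int, dict]:
    """Classify each reference target site on an alternative allele.

    The allele is globally aligned to the reference transcript; per site the
    status is one of:

    - ``deleted``: a deletion removes the site's seed region (with an
      ``in_frame`` flag, total deleted length divisible by 3);
    - ``position-11-SNP``: a substitution at the target nucleotides opposite
      guide positions 10/11 (the cleavage-flanking pair);
    - ``seed-disrupted``: a substitution or small gap within the seed;
    - ``intact`` otherwise.
    """
    ref = _as_rna(reference, "reference")
    alt = _as_rna(allele, "allele")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=2,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-0.5,
    )
    aln = aligner.align(ref, alt)
    if len(aln) == 0:
        raise ValueError("allele could not be aligned to the reference")
    best = aln[0]
    a_ref, a_alt = best[0], best[1]
    identity = sum(x == y and x != "-" for x, y in zip(a_ref, a_alt)) / len(ref)
    if identity < min_aligned_fraction:
        raise ValueError("allele aligns too poorly to the reference")

    # per-reference-position: substituted? deleted?
    substituted = np.zeros(len(ref), dtype=bool)
    deleted = np.zeros(len(ref), dtype=bool)
    ri = 0
    for x, y in zip(a_ref, a_alt):
        if x != "-":
            if y == "-":
                deleted[ri] = True
            elif y != x:
                substituted[ri] = True
            ri += 1

    out: dict[int, dict] = {}
    for k, site in enumerate(sites):
        s0, s1 = site.transcript_pos
        seed0, seed1 = site.seed_span
        cleave = site.positions_opposite((10, 11))
        info: dict = {"in_frame": None}
        if deleted[seed0:seed1].any() or deleted[s0:s1].sum() >= (s1 - s0) // 2:
            runs = int(deleted.sum())
            info["status"] = "deleted"
            info["in_frame"] = runs % 3 == 0
            info["deleted_bp"] = runs
        elif any(substituted[c] for c in cleave):
            info["status"] = "position-11-SNP"
        elif substituted[seed0:seed1].any() or deleted[s0:s1].any():
            info["status"] = "seed-disrupted"
        else:
            info["status"] = "intact"
        out[k] = info
    return out
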