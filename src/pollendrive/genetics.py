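"""Genome representation, genetic maps, and meiosis.

Coordinates follow the usual mixed convention of the field: base-pair
positions are 1-based (VCF), bins and windows elsewhere in the package are
0-based half-open (BED).  Genetic positions are in centimorgans and crossing
over follows the Haldane (Poisson, no-interference) model, so the
recombination fraction between two loci d cM apart is (1 - exp(-2d/100))/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "GeneticMap",
    "Haplotype",
    "DiploidGenotype",
    "haldane_r",
    "haldane_inverse_cm",
    "crossover_positions",
    "meiosis",
    "meiosis_batch",
    "estimate_map_distance",
]

REF = 0  # recurrent-parent (W22) allele
ALT = 1  # donor (mexicana) allele


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Map distance (cM) -> recombination fraction under Haldane."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_inverse_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction -> Haldane map distance in cM."""
    r = np.asarray(r, dtype=float)
    if np.any(r >= 0.5):
        raise ValueError("recombination fraction must be < 0.5 for Haldane inverse")
    return -50.0 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class MarkerSet:
    """Ordered marker loci with physical (bp) and genetic (cM) coordinates.

    ``table`` columns: chrom, pos (1-based bp), cm, ref, alt.  Markers must be
    sorted with strictly increasing bp and non-decreasing cM within each
    chromosome, and ref/alt labels must differ at every site.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "cm", "ref", "alt"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker table missing columns: {missing}")
        tab = self.table.reset_index(drop=True)
        if (tab["ref"].astype(str) == tab["alt"].astype(str)).any():
            raise ValueError("ref and alt labels must differ at every marker")
        for chrom, sub in tab.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: bp positions must be strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"{chrom}: cM must be non-decreasing with bp")
            if np.any(cm < 0):
                raise ValueError(f"{chrom}: negative cM position")
        object.__setattr__(self, "table", tab)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.table["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy(dtype=float)

    def index_of(self, chrom: str, pos: int) -> int:
        sub = self.table[(self.table["chrom"] == chrom) & (self.table["pos"] == pos)]
        if sub.empty:
            raise KeyError(f"no marker at {chrom}:{pos}")
        return int(sub.index[0])


class GeneticMap:
    """Piecewise-linear bp<->cM interpolation per chromosome.

    Anchored at (bp 0, 0 cM); chromosome length in cM is the last marker's
    genetic position unless ``terminal_pad_cm`` extends it.
    """

    def __init__(self, markers: MarkerSet, terminal_pad_cm: float = 0.0):
        if terminal_pad_cm < 0:
            raise ValueError("terminal_pad_cm must be >= 0")
        self.markers = markers
        self._bp: dict[str, np.ndarray] = {}
        self._cm: dict[str, np.ndarray] = {}
        self.length_cm: dict[str, float] = {}
        for chrom in markers.chroms:
            sl = markers.chrom_slice(chrom)
            self._bp[chrom] = markers.pos[sl].astype(float)
            self._cm[chrom] = markers.cm[sl]
            self.length_cm[chrom] = float(markers.cm[sl][-1]) + terminal_pad_cm

    @property
    def chroms(self) -> list[str]:
        return list(self.length_cm)

    def bp_to_cm(self, chrom: str, bp: float | np.ndarray) -> np.ndarray:
        return np.interp(bp, np.r_[0.0, self._bp[chrom]], np.r_[0.0, self._cm[chrom]])

    def cm_to_bp(self, chrom: str, cm: float | np.ndarray) -> np.ndarray:
        # non-decreasing cM can plateau; interp picks the left edge of plateaus
        return np.interp(cm, np.r_[0.0, self._cm[chrom]], np.r_[0.0, self._bp[chrom]])

    def marker_cm(self, chrom: str) -> np.ndarray:
        return self._cm[chrom]


@dataclass(frozen=True)
class Haplotype:
    """Allele vector over a MarkerSet; 0 = ref (W22), 1 = alt (mexicana)."""

    alleles: np.ndarray
    markers: MarkerSet

    def __post_init__(self) -> None:
        arr = np.asarray(self.alleles, dtype=np.int8)
        if arr.shape != (self.markers.n_markers,):
            raise ValueError("haplotype length must equal marker count")
        if not np.isin(arr, (REF, ALT)).all():
            raise ValueError("alleles must be 0 (ref) or 1 (alt)")
        object.__setattr__(self, "alleles", arr)

    def carries(self, idx: int) -> bool:
        return bool(self.alleles[idx] == ALT)


@dataclass(frozen=True)
class DiploidGenotype:
    """Two phased haplotypes plus named designated loci (e.g. Tpd1, Tpd2).

    ``loci`` maps a locus name to its marker index in the shared MarkerSet.
    """

    maternal: Haplotype
    paternal: Haplotype
    loci: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.maternal.markers is not self.paternal.markers and not self.maternal.markers.table.equals(
            self.paternal.markers.table
        ):
            raise ValueError("haplotypes must share a MarkerSet")
        for name, idx in self.loci.items():
            if not 0 <= idx < self.maternal.markers.n_markers:
                raise KeyError(f"locus {name!r} index {idx} outside marker set")

    @property
    def markers(self) -> MarkerSet:
        return self.maternal.markers

    def locus_index(self, name: str) -> int:
        try:
            return self.loci[name]
        except KeyError:
            raise KeyError(f"designated locus {name!r} not defined on this genotype") from None

    def alleles_at(self, name: str) -> tuple[int, int]:
        i = self.locus_index(name)
        return int(self.maternal.alleles[i]), int(self.paternal.alleles[i])

    def carries(self, name: str) -> bool:
        """True if at least one haplotype carries the alt allele."""
        return ALT in self.alleles_at(name)

    def is_het(self, name: str) -> bool:
        a, b = self.alleles_at(name)
        return a != b

    def dosage(self) -> np.ndarray:
        return self.maternal.alleles.astype(np.int16) + self.paternal.alleles


def crossover_positions(chrom_length_cm: float, rng: np.random.Generator) -> np.ndarray:
    """Draw crossover positions under the no-interference model.

    Count ~ Poisson(length/100), positions i.i.d. uniform on [0, length],
    returned sorted.
    """
    if chrom_length_cm < 0:
        raise ValueError("chromosome length must be non-negative")
    if chrom_length_cm == 0:
        return np.empty(0)
    n = rng.poisson(chrom_length_cm / 100.0)
    return np.sort(rng.uniform(0.0, chrom_length_cm, size=n))


def meiosis(parent: DiploidGenotype, gmap: GeneticMap, rng: np.random.Generator) -> Haplotype:
    """Produce one gamete haplotype as a crossover mosaic of the parent.

    The starting haplotype on each chromosome is chosen with probability 1/2;
    allele phase flips at each crossover.
    """
    markers = parent.markers
    if set(gmap.chroms) != set(markers.chroms):
        raise ValueError("genetic map and parent marker set disagree on chromosomes")
    out = np.empty(markers.n_markers, dtype=np.int8)
    for chrom in markers.chroms:
        sl = markers.chrom_slice(chrom)
        cm = gmap.marker_cm(chrom)
        xo = crossover_positions(gmap.length_cm[chrom], rng)
        start = rng.integers(2)
        phase = (start + np.searchsorted(xo, cm)) % 2
        out[sl] = np.where(phase == 0, parent.maternal.alleles[sl], parent.paternal.alleles[sl])
    return Haplotype(out, markers)


def meiosis_batch(
    parent: DiploidGenotype, gmap: GeneticMap, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Vectorised meiosis: (n, n_markers) gamete allele matrix.

    Uses the Markov equivalence of the Haldane model: phase switches between
    adjacent markers independently with the interval's recombination fraction.
    Statistically identical to ``meiosis`` (see the property tests).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    markers = parent.markers
    out = np.empty((n, markers.n_markers), dtype=np.int8)
    for chrom in markers.chroms:
        sl = markers.chrom_slice(chrom)
        cm = gmap.marker_cm(chrom)
        r = haldane_r(np.diff(cm))
        m = cm.size
        switches = np.empty((n, m), dtype=np.int8)
        switches[:, 0] = rng.integers(2, size=n)
        if m > 1:
            switches[:, 1:] = rng.random((n, m - 1)) < r
        phase = np.cumsum(switches, axis=1) % 2
        out[:, sl] = np.where(phase == 0, parent.maternal.alleles[sl], parent.paternal.alleles[sl])
    return out


def estimate_map_distance(
    progeny: Sequence[DiploidGenotype],
    locus_a: str,
    locus_b: str,
    transmitting_parent: str = "male",
    map_function: str = "direct",
) -> tuple[float, int]:
    """Estimate the map distance between two loci from scored progeny.

    The gamete contributed by ``transmitting_parent`` ("male" or "female") is
    scored at both loci; a gamete is recombinant when the two ancestries
    differ (the transmitting parent is assumed heterozygous in coupling).
    Returns (cM estimate, recombinant count).  ``map_function`` "direct"
    reports 100*r, matching small-distance usage; "haldane" applies the
    Haldane inverse.
    """
    if len(progeny) == 0:
        raise ValueError("no progeny supplied")
    if transmitting_parent not in ("male", "female"):
        raise ValueError("transmitting_parent must be 'male' or 'female'")
    rec = 0
    for g in progeny:
        ia, ib = g.locus_index(locus_a), g.locus_index(locus_b)
        hap = g.paternal if transmitting_parent == "male" else g.maternal
        rec += int(hap.alleles[ia] != hap.alleles[ib])
    r = rec / len(progeny)
    if map_function == "direct":
        cm = 100.0 * r
    elif map_function == "haldane":
        cm = float(haldane_inverse_cm(r))
    else:
        raise ValueError("map_function must be 'direct' or 'haldane'")
    return cm, rec
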