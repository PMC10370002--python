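"""Synthetic-data generators.

Every analysis stage in this package can be exercised end-to-end on data
produced here: haploid pollen genomes from the drive simulator observed
through a sparse, error-prone single-grain sequencing model; pooled
segregant read counts; small-RNA read pileups from hairpin, dsRNA-derived
and background loci on a genome with planted inverted repeats; haplotype
panels from a forward Wright-Fisher simulation with or without a sweep;
and degradome-style 5' cleavage profiles.  Generators take an explicit
numpy Generator and record their spec and seed as provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .drive import PhenotypeClass, ViabilityRule
from .genetics import (
    ALT,
    REF,
    DiploidGenotype,
    GeneticMap,
    Haplotype,
    MarkerSet,
    haldane_inverse_cm,
)
from .pollen import SparseGenotypeMatrix

__all__ = [
    "ObservationModel",
    "SRNALocus",
    "SRNASimSpec",
    "HaplotypePanel",
    "DriveScenario",
    "drive_scenario",
    "observe_pollen_genotypes",
    "generate_bsa_pools",
    "generate_srna_reads",
    "generate_haplotype_panel",
    "generate_ipare_profile",
]

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# study-condition scenario: the two-chromosome drive cross
# ---------------------------------------------------------------------------


@dataclass
class DriveScenario:
    """Marker layout and founder genotypes emulating the drive cross.

    Two drive chromosomes (chr5-like with the toxin, linked antidote and a
    fully linked kernel marker inside the inversion; chr6-like with the
    unlinked antidote and a 21.5 cM kernel marker) plus one neutral
    chromosome.  The heterozygous drive parent carries donor-ancestry blocks
    around the drive loci on its paternal haplotype.
    """

    markers: MarkerSet
    gmap: GeneticMap
    loci: dict[str, int]
    drive_parent: DiploidGenotype  # Tpd1/+; Tpd2/+ heterozygote
    w22: DiploidGenotype  # recurrent parent, all ref (doubles as bt1;y1 tester)
    homozygote: DiploidGenotype  # Tpd1;Tpd2 homozygous (selfed) line
    rule: ViabilityRule


def drive_scenario(
    antidote_cm: float = 0.0,
    baseline_abortion: float = 0.0602,
    marker_step_cm: float = 2.0,
    chrom_length_cm: float = 100.0,
    haplotype_integrity: bool = True,
) -> DriveScenario:
    """Build the canonical drive-cross study conditions.

    ``antidote_cm`` is the toxin/linked-antidote distance as geneticists
    report it from progeny counts: 100 x the recombinant fraction (0 for
    the effective linked unit used in abortion-rate expectations; 18.7 for
    the mapped Dicer-allele distance used in the pseudolinkage analyses).
    The underlying map gap is its Haldane inverse, so a female-transmission
    estimate recovers ``antidote_cm`` directly.  Kernel markers (Bt1, y1)
    are heterozygous with the dominant functional allele in coupling with
    the drive haplotype, as in a tester cross.  Physical positions use
    1 Mb per cM.
    """
    if not 0.0 <= antidote_cm < 50.0:
        raise ValueError("antidote_cm is 100x a recombinant fraction and must be in [0, 50)")
    gap = float(haldane_inverse_cm(antidote_cm / 100.0))
    rows = []
    loci_cm = {
        "chr5": {"dcl2T": 40.0 - gap, "Tpd1": 40.0, "Bt1": 40.0},
        "chr6": {"Tpd2": 50.0, "y1": 71.5},
        "chr1": {},
    }
    blocks = {"chr5": (40.0 - max(gap, 10.0) - 5.0, 50.0), "chr6": (40.0, 60.0)}
    for chrom in ("chr1", "chr5", "chr6"):
        grid = list(np.arange(0.0, chrom_length_cm + 1e-9, marker_step_cm))
        named = loci_cm[chrom]
        cms = sorted(set(grid) | set(named.values()))
        used = set()
        for cm in cms:
            here = [nm for nm, c in named.items() if c == cm and nm not in used]
            used.update(here)
            if not here:
                here = [None]
            for nm in here:
                rows.append({"chrom": chrom, "cm": cm, "name": nm})
    # assign strictly increasing bp at 1 Mb/cM, nudging co-located named loci
    tab = pd.DataFrame(rows)
    tab["pos"] = 0
    for chrom, sub in tab.groupby("chrom", sort=False):
        bp = (sub["cm"].to_numpy() * 1_000_000).astype(int) + 1
        for i in range(1, len(bp)):
            if bp[i] <= bp[i - 1]:
                bp[i] = bp[i - 1] + 1
        tab.loc[sub.index, "pos"] = bp
    tab["ref"] = "W22"
    tab["alt"] = "mex"
    order = [c for c in ("chr1", "chr5", "chr6")]
    tab["chrom"] = pd.Categorical(tab["chrom"], categories=order, ordered=True)
    tab = tab.sort_values(["chrom", "pos"]).reset_index(drop=True)
    tab["chrom"] = tab["chrom"].astype(str)
    markers = MarkerSet(tab[["chrom", "pos", "cm", "ref", "alt"]])
    loci = {nm: int(i) for i, nm in enumerate(tab["name"]) if isinstance(nm, str)}
    gmap = GeneticMap(markers)

    donor = np.zeros(markers.n_markers, dtype=np.int8)
    for chrom, (lo, hi) in blocks.items():
        sl = markers.chrom_slice(chrom)
        cm = markers.cm[sl]
        donor[sl][(cm >= lo) & (cm <= hi)] = ALT
    donor[loci["y1"]] = ALT  # dominant Y1 in coupling with the Tpd2 haplotype
    ref_hap = Haplotype(np.zeros(markers.n_markers, dtype=np.int8), markers)
    donor_hap = Haplotype(donor, markers)
    rule = ViabilityRule(baseline_abortion=baseline_abortion, haplotype_integrity=haplotype_integrity)
    return DriveScenario(
        markers=markers,
        gmap=gmap,
        loci=loci,
        drive_parent=DiploidGenotype(ref_hap, donor_hap, loci),
        w22=DiploidGenotype(ref_hap, ref_hap, loci),
        homozygote=DiploidGenotype(donor_hap, donor_hap, loci),
        rule=rule,
    )


# ---------------------------------------------------------------------------
# single-grain observation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationModel:
    """Sparse single-grain sequencing noise: per-marker i.i.d. by default.

    ``dropout_rate`` models whole-genome-amplification allele dropout; for
    haploid grains it simply adds to the missing rate.  ``block_dropout_cm``
    optionally drops contiguous blocks (amplification-bias stress test).
    """

    missing_rate: float = 0.8
    dropout_rate: float = 0.0
    error_rate: float = 0.05
    mean_depth: float = 1.0
    block_dropout_cm: float = 0.0

    def __post_init__(self) -> None:
        for nm in ("missing_rate", "dropout_rate", "error_rate"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")


def observe_pollen_genotypes(
    gametes: np.ndarray | Sequence[Haplotype],
    markers: MarkerSet,
    model: ObservationModel,
    rng: np.random.Generator,
) -> SparseGenotypeMatrix:
    """Observe true gamete haplotypes through the noise model.

    Returns markers x grains calls in {1, -1, 0}; each observed call equals
    the truth with probability 1 - error_rate.
    """
    if not isinstance(gametes, np.ndarray):
        gametes = np.array([h.alleles for h in gametes], dtype=np.int8)
    if gametes.shape[0] < 1:
        raise ValueError("need at least one gamete")
    truth = np.where(gametes.T == ALT, 1, -1).astype(np.int8)  # markers x grains
    m, g = truth.shape
    miss = 1.0 - (1.0 - model.missing_rate) * (1.0 - model.dropout_rate)
    observed = rng.random((m, g)) >= miss
    if model.block_dropout_cm > 0:
        for chrom in markers.chroms:
            sl = markers.chrom_slice(chrom)
            cm = markers.cm[sl]
            starts = rng.uniform(0, max(cm[-1], 1e-9), size=g)
            block = (cm[:, None] >= starts) & (cm[:, None] < starts + model.block_dropout_cm)
            observed[sl] &= ~block
    flips = rng.random((m, g)) < model.error_rate
    calls = np.where(flips, -truth, truth).astype(np.int8)
    calls[~observed] = 0
    mat = SparseGenotypeMatrix(calls, markers)
    return mat


# ---------------------------------------------------------------------------
# bulk segregant pools
# ---------------------------------------------------------------------------


def generate_bsa_pools(
    pools: Mapping[str, Sequence[DiploidGenotype]],
    depth: int,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Binomial pooled-sequencing read counts per marker for each pool.

    Counts ~ Binomial(depth, pool alt-allele frequency).  Returns one frame
    per pool label with chrom, pos, ref_count, alt_count.
    """
    if not pools or any(len(v) == 0 for v in pools.values()):
        raise ValueError("all pools must be non-empty")
    out = {}
    for label, members in pools.items():
        markers = members[0].markers
        freq = np.mean([g.dosage() for g in members], axis=0) / 2.0
        alt = rng.binomial(depth, freq)
        out[label] = pd.DataFrame(
            {
                "chrom": markers.table["chrom"],
                "pos": markers.table["pos"],
                "ref_count": depth - alt,
                "alt_count": alt,
            }
        )
    return out


# ---------------------------------------------------------------------------
# small RNA reads over a genome with planted inverted repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SRNALocus:
    start: int  # 0-based
    end: int
    kind: Literal["hairpin", "dsrna", "te", "background"]
    cpm: float = 50.0
    size_dist: Mapping[int, float] = field(
        default_factory=lambda: {22: 0.8, 21: 0.1, 20: 0.05, 23: 0.05}
    )
    strand_bias: float = 0.95  # dominant-strand fraction, in [0.5, 1]
    arm_len: int = 100  # hairpin only
    arm_identity: float = 0.95  # hairpin only

    def __post_init__(self) -> None:
        if not 0.5 <= self.strand_bias <= 1.0:
            raise ValueError("strand_bias is the dominant-strand fraction in [0.5, 1]")
        if abs(sum(self.size_dist.values()) - 1.0) > 1e-6:
            raise ValueError("size distribution must sum to 1")


@dataclass(frozen=True)
class SRNASimSpec:
    loci: tuple[SRNALocus, ...]
    genome_length: int = 50_000
    library_size: int = 200_000
    background_per_kb: float = 0.5  # expected background reads per kb

    def __post_init__(self) -> None:
        loci = sorted(self.loci, key=lambda l: l.start)
        for a, b in zip(loci, loci[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping loci at {a.end}/{b.start}")
        object.__setattr__(self, "loci", tuple(loci))


def generate_srna_reads(
    spec: SRNASimSpec, rng: np.random.Generator, chrom: str = "chr1"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Emit small-RNA alignment records and a genome with planted hairpins.

    Hairpin loci carry an embedded inverted repeat (two ``arm_len`` arms at
    ``arm_identity``, short loop) in the genome sequence and emit
    strand-biased, 22nt-dominated reads; dsRNA-derived loci emit nearly
    strand-balanced reads.  Records are (chrom, start, length, strand,
    count), sorted by start.  Also returns provenance in frame.attrs.
    """
    genome = rng.choice(BASES, size=spec.genome_length)
    for loc in spec.loci:
        if loc.kind == "hairpin":
            span = loc.end - loc.start
            loop = max(span - 2 * loc.arm_len, 10)
            if 2 * loc.arm_len + loop > span:
                raise ValueError("hairpin locus too short for its arms")
            arm = rng.choice(BASES, size=loc.arm_len)
            arm2 = np.array(list(_revcomp("".join(arm))))
            mut = rng.random(loc.arm_len) > loc.arm_identity
            arm2[mut] = rng.choice(BASES, size=int(mut.sum()))
            genome[loc.start : loc.start + loc.arm_len] = arm
            genome[loc.start + loc.arm_len + loop : loc.start + 2 * loc.arm_len + loop] = arm2
    seq = "".join(genome)

    rows = []
    for loc in spec.loci:
        n_reads = rng.poisson(loc.cpm * spec.library_size / 1e6)
        if n_reads == 0:
            continue
        sizes = np.array(list(loc.size_dist))
        probs = np.array(list(loc.size_dist.values()))
        lens = rng.choice(sizes, p=probs, size=n_reads)
        dominant = rng.choice(["+", "-"])
        strands = np.where(rng.random(n_reads) < loc.strand_bias, dominant, "+-"[dominant == "+"])
        hi = np.maximum(loc.end - lens.max(), loc.start + 1)
        starts = rng.integers(loc.start, hi, size=n_reads)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "length": lens, "strand": strands}))
    n_bg = rng.poisson(spec.background_per_kb * spec.genome_length / 1000.0)
    if n_bg:
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": rng.integers(0, spec.genome_length - 25, size=n_bg),
                    "length": rng.integers(20, 26, size=n_bg),
                    "strand": rng.choice(["+", "-"], size=n_bg),
                }
            )
        )
    reads = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "length", "strand"]
    )
    reads["count"] = 1
    reads = (
        reads.groupby(["chrom", "start", "length", "strand"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    reads.attrs["spec"] = dataclasses.asdict(spec) | {
        "loci": [dataclasses.asdict(l) for l in spec.loci]
    }
    return reads, {chrom: seq}


# ---------------------------------------------------------------------------
# haplotype panels: forward Wright-Fisher, neutral or sweep
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix with physical/genetic positions.

    0 = ancestral, 1 = derived; polarity is explicit by construction (the
    founding population is monomorphic ancestral).
    """

    matrix: np.ndarray  # (n_hap, n_snp) uint8
    pos_bp: np.ndarray
    pos_cm: np.ndarray
    sweep_site: int | None = None  # column index of the selected site, if any

    @property
    def n_hap(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_snp(self) -> int:
        return int(self.matrix.shape[1])


def _wf_generation(
    pop: np.ndarray, r_adj: np.ndarray, fitness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n, L = pop.shape
    w = fitness / fitness.sum()
    p1 = rng.choice(n, size=n, p=w)
    p2 = rng.choice(n, size=n, p=w)
    switches = np.empty((n, L), dtype=np.int8)
    switches[:, 0] = rng.integers(2, size=n)
    switches[:, 1:] = rng.random((n, L - 1)) < r_adj
    phase = np.cumsum(switches, axis=1) % 2
    return np.where(phase == 0, pop[p1], pop[p2]).astype(np.uint8)


def generate_haplotype_panel(
    n_hap: int,
    n_snp: int,
    model: Literal["neutral", "sweep"] = "neutral",
    s: float = 1.5,
    rng: np.random.Generator | None = None,
    pop_size: int = 200,
    generations: int = 300,
    sweep_generations: int = 60,
    mu: float = 1e-3,
    total_cm: float = 200.0,
    chrom_bp: int = 1_000_000,
    maf_min: float = 0.05,
    max_tries: int = 30,
) -> HaplotypePanel:
    """Forward Wright-Fisher haplotype panel at desk scale.

    A haploid population of ``pop_size`` recombining genomes accumulates
    mutations (ancestral 0 -> derived 1) for ``generations``; under the
    sweep model a beneficial allele (haploid selection 1+s) is then seeded
    at the central segregating site and selected for ``sweep_generations``,
    retrying until it is at intermediate-to-high frequency.  ``n_hap``
    haplotypes are sampled and sites below ``maf_min`` dropped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_snp <= 0:
        raise ValueError("n_snp must be positive")
    if n_hap < 20 or n_hap % 2:
        raise ValueError("n_hap must be even and >= 20")
    L = int(3 * n_snp)
    cm = np.sort(rng.uniform(0, total_cm, size=L))
    r_adj = 0.5 * (1 - np.exp(-2 * np.diff(cm) / 100.0))
    neutral_fit = np.ones(pop_size)

    for attempt in range(max_tries):
        pop = np.zeros((pop_size, L), dtype=np.uint8)
        for _ in range(generations):
            pop = _wf_generation(pop, r_adj, neutral_fit, rng)
            muts = rng.random((pop_size, L)) < mu
            pop ^= muts
        if model == "sweep":
            # hard sweep: a new beneficial mutation at the central site
            site = int(np.argmin(np.abs(cm - total_cm / 2)))
            pop[:, site] = 0
            pop[int(rng.integers(pop_size)), site] = 1
            lost = False
            for _ in range(sweep_generations):
                fit = np.where(pop[:, site] == 1, 1.0 + s, 1.0)
                pop = _wf_generation(pop, r_adj, fit, rng)
                f = pop[:, site].mean()
                if f == 0.0:
                    lost = True
                    break
                if f >= 0.75:  # stop well short of fixation
                    break
            if lost:
                continue
        else:
            site = None
        idx = rng.choice(pop_size, size=n_hap, replace=False)
        sample = pop[idx]
        freqs = sample.mean(axis=0)
        keep = (freqs >= maf_min) & (freqs <= 1 - maf_min)
        if site is not None:
            if not 0.5 <= freqs[site] <= 0.95:
                continue
            keep[site] = True
        if keep.sum() < min(20, n_snp // 2):
            continue
        cols = np.flatnonzero(keep)
        if cols.size > n_snp:  # thin to the requested SNP count
            chosen = np.linspace(0, cols.size - 1, n_snp).astype(int)
            if site is not None:
                si = int(np.searchsorted(cols, site))
                chosen = np.unique(np.r_[chosen, si])
            cols = cols[chosen]
        sweep_col = int(np.searchsorted(cols, site)) if site is not None else None
        pos_cm = cm[cols]
        pos_bp = np.maximum(1, (pos_cm / total_cm * chrom_bp).astype(int))
        pos_bp = np.maximum.accumulate(pos_bp + np.arange(pos_bp.size))  # strictly increasing
        return HaplotypePanel(sample[:, cols], pos_bp, pos_cm, sweep_site=sweep_col)
    raise RuntimeError("failed to generate a panel satisfying the model conditions")


# ---------------------------------------------------------------------------
# degradome-style 5' cleavage profiles
# ---------------------------------------------------------------------------


def generate_ipare_profile(
    transcript_length: int,
    sites: Sequence[int],
    signal_to_background: float,
    rng: np.random.Generator,
    background_rate: float = 1.0,
) -> np.ndarray:
    """Per-position 5'-end read counts: Poisson background plus site peaks.

    Peak intensity is ``signal_to_background`` times the background rate
    (or that ratio directly when the background rate is zero).
    """
    for s in sites:
        if not 0 <= s < transcript_length:
            raise ValueError(f"site {s} outside transcript")
    counts = rng.poisson(background_rate, size=transcript_length).astype(float)
    peak = signal_to_background * (background_rate if background_rate > 0 else 1.0)
    for s in sites:
        counts[s] += rng.poisson(peak)
    return counts
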