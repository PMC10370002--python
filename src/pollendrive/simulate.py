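"""Forward Monte-Carlo simulation of pollen populations, crosses, and
backcross programs under the toxin-antidote drive model."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .drive import PhenotypeClass, ViabilityRule, classify_plant_phenotype, survival_probability
from .genetics import ALT, DiploidGenotype, GeneticMap, Haplotype, meiosis_batch

__all__ = [
    "PollenPopulation",
    "CrossDesign",
    "CrossResult",
    "simulate_pollen_population",
    "simulate_cross",
    "score_kernel_markers",
    "simulate_backcross_program",
]


def _batch_survival(
    gametes: np.ndarray, sporophyte: DiploidGenotype, rule: ViabilityRule
) -> np.ndarray:
    """Per-gamete drive-survival probability (baseline excluded)."""
    rule.check_loci(sporophyte)
    n = gametes.shape[0]
    if not sporophyte.carries(rule.toxin):
        return np.ones(n)
    cols = {nm: gametes[:, sporophyte.locus_index(nm)] == ALT for nm in rule.loci}
    probs = np.empty(n)
    # patterns are few; evaluate survival per unique pattern
    keymat = np.column_stack([cols[nm] for nm in rule.loci])
    uniq, inv = np.unique(keymat, axis=0, return_inverse=True)
    for k, row in enumerate(uniq):
        pattern = {nm: bool(v) for nm, v in zip(rule.loci, row)}
        probs_k = survival_probability(rule, pattern)
        probs[inv == k] = probs_k
    return probs


@dataclass
class PollenPopulation:
    """A simulated pollen cohort: gamete alleles, viability flags, provenance."""

    gametes: np.ndarray  # (n, n_markers) int8
    viable: np.ndarray  # (n,) bool
    sporophyte: DiploidGenotype
    rule: ViabilityRule
    seed: int | None = None

    @property
    def n(self) -> int:
        return int(self.gametes.shape[0])

    @property
    def abortion_rate(self) -> float:
        return float(1.0 - self.viable.mean())

    def viable_gametes(self) -> np.ndarray:
        return self.gametes[self.viable]

    def haplotypes(self, viable_only: bool = False) -> list[Haplotype]:
        mat = self.viable_gametes() if viable_only else self.gametes
        return [Haplotype(row, self.sporophyte.markers) for row in mat]

    def summary(self) -> dict:
        return {
            "n": self.n,
            "n_viable": int(self.viable.sum()),
            "abortion_percent": 100.0 * self.abortion_rate,
            "seed": self.seed,
        }


@dataclass
class CrossDesign:
    """One cross (or a multi-generation backcross program)."""

    mother: DiploidGenotype
    father: DiploidGenotype
    n_progeny: int = 100
    generations: int = 1
    recurrent_parent: DiploidGenotype | None = None
    recurrent_role: str = "mother"  # which side the recurrent parent takes
    select_class: PhenotypeClass | None = PhenotypeClass.DRIVE

    def __post_init__(self) -> None:
        if self.n_progeny < 1:
            raise ValueError("progeny count must be >= 1")
        if self.recurrent_role not in ("mother", "father"):
            raise ValueError("recurrent_role must be 'mother' or 'father'")


@dataclass
class CrossResult:
    progeny: list[DiploidGenotype]
    failed: bool
    viable_pollen_fraction: float


def simulate_pollen_population(
    sporophyte: DiploidGenotype,
    rule: ViabilityRule,
    n: int,
    rng: np.random.Generator,
    gmap: GeneticMap | None = None,
    seed: int | None = None,
) -> PollenPopulation:
    """Simulate n gametes by meiosis and apply the viability rule."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if gmap is None:
        gmap = GeneticMap(sporophyte.markers)
    gametes = meiosis_batch(sporophyte, gmap, rng, n)
    p = _batch_survival(gametes, sporophyte, rule) * (1.0 - rule.baseline_abortion)
    viable = rng.random(n) < p
    return PollenPopulation(gametes, viable, sporophyte, rule, seed=seed)


def simulate_cross(
    design: CrossDesign,
    gmap: GeneticMap,
    rule: ViabilityRule,
    rng: np.random.Generator,
) -> CrossResult:
    """Simulate progeny of one cross.

    Male gametes are sampled from viable pollen only (uniformly - no pollen
    competition); female gametes are unselected.  A father shedding zero
    viable pollen yields an explicit failed cross; a viable fraction below
    1% triggers a warning, mirroring crosses by sterile-class plants that
    often fail outright.
    """
    n = design.n_progeny
    female = meiosis_batch(design.mother, gmap, rng, n)

    # rejection-sample viable male gametes in batches
    male_rows: list[np.ndarray] = []
    attempts = 0
    drawn = 0
    viable_total = 0
    while sum(len(b) for b in male_rows) < n:
        batch = max(n, 256)
        g = meiosis_batch(design.father, gmap, rng, batch)
        p = _batch_survival(g, design.father, rule) * (1.0 - rule.baseline_abortion)
        keep = rng.random(batch) < p
        drawn += batch
        viable_total += int(keep.sum())
        male_rows.append(g[keep])
        attempts += 1
        if attempts >= 40 and viable_total == 0:
            return CrossResult([], failed=True, viable_pollen_fraction=0.0)
    male = np.concatenate(male_rows)[:n]
    frac = viable_total / drawn
    if frac < 0.01:
        warnings.warn(f"father viable-pollen fraction {frac:.3%} is below 1%", stacklevel=2)

    markers = design.mother.markers
    loci = dict(design.mother.loci) or dict(design.father.loci)
    progeny = [
        DiploidGenotype(Haplotype(female[i], markers), Haplotype(male[i], markers), loci)
        for i in range(n)
    ]
    return CrossResult(progeny, failed=False, viable_pollen_fraction=float(frac))


def score_kernel_markers(
    progeny: Sequence[DiploidGenotype], marker_loci: Sequence[str]
) -> pd.DataFrame:
    """Count progeny carrying the dominant (alt) allele at scored kernel markers.

    Returns a table with carrier counts and fractions per locus (e.g. Bt1 vs
    bt1, Y1 vs y1 kernel phenotypes on a homozygous-recessive tester).
    """
    if len(progeny) == 0:
        raise ValueError("no progeny to score")
    rows = []
    for name in marker_loci:
        carriers = sum(g.carries(name) for g in progeny)  # KeyError if unscored
        rows.append(
            {
                "locus": name,
                "carriers": carriers,
                "n": len(progeny),
                "fraction": carriers / len(progeny),
            }
        )
    return pd.DataFrame(rows)


def simulate_backcross_program(
    design: CrossDesign,
    rule: ViabilityRule,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[list[list[DiploidGenotype]], pd.DataFrame]:
    """Run a multi-generation backcross program.

    Each generation crosses the current selected line against the recurrent
    parent (in ``recurrent_role``); among progeny, the next line parent is
    drawn from the ``select_class`` phenotype (or any progeny if None).
    Returns per-generation progeny plus a per-marker alt-allele retention
    table (one column per generation).
    """
    if design.generations < 0:
        raise ValueError("generations must be >= 0")
    recurrent = design.recurrent_parent
    if recurrent is None:
        recurrent = design.mother if design.recurrent_role == "mother" else design.father
    line = design.father if design.recurrent_role == "mother" else design.mother
    markers = line.markers

    if design.generations == 0:
        freq = line.dosage() / 2.0
        tab = pd.DataFrame({"chrom": markers.table["chrom"], "pos": markers.table["pos"], "g0": freq})
        return [[line]], tab

    per_gen: list[list[DiploidGenotype]] = []
    retention = {}
    for g in range(1, design.generations + 1):
        mother, father = (recurrent, line) if design.recurrent_role == "mother" else (line, recurrent)
        res = simulate_cross(
            CrossDesign(mother=mother, father=father, n_progeny=design.n_progeny),
            gmap,
            rule,
            rng,
        )
        if res.failed:
            raise RuntimeError(f"backcross generation {g} failed: no viable pollen")
        per_gen.append(res.progeny)
        dose = np.mean([p.dosage() for p in res.progeny], axis=0) / 2.0
        retention[f"g{g}"] = dose
        if design.select_class is not None:
            sel = [p for p in res.progeny if classify_plant_phenotype(p, rule) == design.select_class]
            if not sel:
                raise RuntimeError(f"no {design.select_class.value} progeny to select in generation {g}")
            line = sel[int(rng.integers(len(sel)))]
        else:
            line = res.progeny[int(rng.integers(len(res.progeny)))]
    tab = pd.DataFrame({"chrom": markers.table["chrom"], "pos": markers.table["pos"], **retention})
    return per_gen, tab
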