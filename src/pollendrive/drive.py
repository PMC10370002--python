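"""The toxin-antidote pollen-killing model.

A sporophyte carrying at least one copy of the toxin locus (Tpd1, a
hairpin-siRNA producer) poisons its entire pollen cohort before meiosis.
Only gametes that inherit the full antidote set - by default the
toxin-linked hypomorphic Dicer allele (dcl2T) plus the unlinked Tpd2 locus -
survive.  Under the default haplotype-integrity rule the toxin and its
linked antidote must be co-inherited (or co-absent): recombinant pollen that
separates them is eliminated, which reproduces the observed male
pseudolinkage (0 cM) between loci that recombine freely through the female.

A baseline abortion probability composes independently with drive killing
(survival = drive survival x (1 - baseline)), accounting for the ~6%
background abortion seen in wild-type pollen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .genetics import ALT, DiploidGenotype, GeneticMap, Haplotype, haldane_r

__all__ = [
    "PhenotypeClass",
    "ViabilityRule",
    "gamete_viability",
    "survival_probability",
    "expected_gamete_classes",
    "classify_plant_phenotype",
    "expected_progeny_ratio",
]

MAX_ENUMERATED_LOCI = 12


class PhenotypeClass(str, Enum):
    FERTILE = "fertile"
    DRIVE = "drive"  # semi-sterile: canonical ~75% pollen abortion
    STERILE = "sterile"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ViabilityRule:
    """Who dies and who survives in the pollen of a toxin carrier.

    survival_table optionally maps a frozenset of carried antidote locus
    names to a survival probability, overriding the default all-or-nothing
    rule (used for partial antidotes such as dcl2-mu1 stacking).
    """

    toxin: str = "Tpd1"
    antidotes: tuple[str, ...] = ("dcl2T", "Tpd2")
    linked_antidote: str = "dcl2T"
    haplotype_integrity: bool = True
    baseline_abortion: float = 0.0
    survival_table: Mapping[frozenset, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_abortion <= 1.0:
            raise ValueError("baseline_abortion must be a probability")
        if not self.antidotes:
            raise ValueError("at least one antidote locus is required")
        if self.linked_antidote not in self.antidotes:
            raise ValueError("linked_antidote must be one of the antidote loci")
        if self.survival_table is not None:
            table = {frozenset(k): float(v) for k, v in self.survival_table.items()}
            if any(not 0.0 <= v <= 1.0 for v in table.values()):
                raise ValueError("survival probabilities must lie in [0, 1]")
            object.__setattr__(self, "survival_table", table)

    @property
    def loci(self) -> tuple[str, ...]:
        return (self.toxin,) + self.antidotes

    def check_loci(self, genotype: DiploidGenotype) -> None:
        for name in self.loci:
            genotype.locus_index(name)  # raises KeyError if absent


def survival_probability(rule: ViabilityRule, pattern: Mapping[str, bool]) -> float:
    """Drive-survival probability (baseline excluded) for a gamete pattern.

    ``pattern`` maps each rule locus name to whether the gamete carries the
    alt allele there.  Applies only when the sporophyte carries the toxin.
    """
    carried = frozenset(a for a in rule.antidotes if pattern[a])
    if rule.survival_table is not None and carried in rule.survival_table:
        return rule.survival_table[carried]
    if carried != frozenset(rule.antidotes):
        return 0.0
    if rule.haplotype_integrity and pattern[rule.linked_antidote] != pattern[rule.toxin]:
        return 0.0
    return 1.0


def gamete_viability(
    gamete: Haplotype,
    sporophyte: DiploidGenotype,
    rule: ViabilityRule,
    rng: np.random.Generator,
) -> bool:
    """Stochastic viability of one gamete; True = viable, False = aborted."""
    rule.check_loci(sporophyte)
    p = 1.0
    if sporophyte.carries(rule.toxin):  # sporophytic toxin action
        pattern = {name: bool(gamete.alleles[sporophyte.locus_index(name)] == ALT) for name in rule.loci}
        p = survival_probability(rule, pattern)
    p *= 1.0 - rule.baseline_abortion
    return bool(rng.random() < p)


def _gamete_pattern_distribution(
    parent: DiploidGenotype, gmap: GeneticMap, loci: tuple[str, ...]
) -> pd.DataFrame:
    """Exact meiotic distribution over alt-carriage patterns at named loci.

    Enumerates parental-origin vectors per chromosome; adjacent-locus
    transitions use Haldane recombination fractions of the cM gaps.
    """
    if len(loci) > MAX_ENUMERATED_LOCI:
        raise ValueError(f"refusing to enumerate more than {MAX_ENUMERATED_LOCI} loci")
    markers = parent.markers
    by_chrom: dict[str, list[str]] = {}
    for name in loci:
        idx = parent.locus_index(name)
        chrom = str(markers.table["chrom"].iloc[idx])
        by_chrom.setdefault(chrom, []).append(name)

    chrom_dists: list[list[tuple[dict[str, int], float]]] = []
    for chrom, names in by_chrom.items():
        names = sorted(names, key=lambda nm: markers.cm[parent.locus_index(nm)])
        cm = np.array([markers.cm[parent.locus_index(nm)] for nm in names])
        r = haldane_r(np.diff(cm))
        m = len(names)
        dist: dict[tuple[int, ...], float] = {}
        for origins in itertools.product((0, 1), repeat=m):
            p = 0.5
            for j in range(m - 1):
                p *= r[j] if origins[j] != origins[j + 1] else 1.0 - r[j]
            alleles = tuple(
                int(
                    (parent.maternal if o == 0 else parent.paternal).alleles[
                        parent.locus_index(nm)
                    ]
                )
                for nm, o in zip(names, origins)
            )
            dist[alleles] = dist.get(alleles, 0.0) + p
        chrom_dists.append([(dict(zip(names, a)), p) for a, p in dist.items()])

    rows = []
    for combo in itertools.product(*chrom_dists):
        pattern: dict[str, int] = {}
        p = 1.0
        for d, pc in combo:
            pattern.update(d)
            p *= pc
        rows.append({**{nm: bool(pattern[nm]) for nm in loci}, "meiotic_freq": p})
    df = pd.DataFrame(rows).groupby(list(loci), as_index=False)["meiotic_freq"].sum()
    return df


def expected_gamete_classes(
    sporophyte: DiploidGenotype,
    rule: ViabilityRule,
    gmap: GeneticMap,
    extra_loci: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Analytic gamete-class distribution with viability weighting.

    Returns one row per carriage pattern over the rule loci (plus any
    ``extra_loci``) with columns: meiotic_freq, survival (drive survival x
    (1-baseline)), and surviving_freq renormalised over survivors.  The
    implied abortion rate is ``1 - sum(meiotic_freq * survival)``.
    """
    loci = rule.loci + tuple(x for x in extra_loci if x not in rule.loci)
    if len(loci) > MAX_ENUMERATED_LOCI:
        raise ValueError(f"refusing to enumerate more than {MAX_ENUMERATED_LOCI} loci")
    rule.check_loci(sporophyte)
    df = _gamete_pattern_distribution(sporophyte, gmap, loci)
    toxic = sporophyte.carries(rule.toxin)
    surv = []
    for _, row in df.iterrows():
        s = survival_probability(rule, {nm: bool(row[nm]) for nm in rule.loci}) if toxic else 1.0
        surv.append(s * (1.0 - rule.baseline_abortion))
    df["survival"] = surv
    total = float((df["meiotic_freq"] * df["survival"]).sum())
    df["surviving_freq"] = (df["meiotic_freq"] * df["survival"]) / total if total > 0 else np.nan
    df.attrs["abortion_rate"] = 1.0 - total
    return df


def classify_plant_phenotype(genotype: DiploidGenotype, rule: ViabilityRule) -> PhenotypeClass:
    """Phenotype of a diploid plant from its toxin/antidote carriage.

    No toxin -> fertile; toxin plus the full antidote set -> drive
    (semi-sterile); toxin without the full set -> sterile.
    """
    try:
        rule.check_loci(genotype)
    except KeyError:
        return PhenotypeClass.UNKNOWN
    if not genotype.carries(rule.toxin):
        return PhenotypeClass.FERTILE
    if all(genotype.carries(a) for a in rule.antidotes):
        return PhenotypeClass.DRIVE
    return PhenotypeClass.STERILE


def _classify_pattern(rule: ViabilityRule, f: Mapping[str, bool], m: Mapping[str, bool]) -> PhenotypeClass:
    carries = {nm: f[nm] or m[nm] for nm in rule.loci}
    if not carries[rule.toxin]:
        return PhenotypeClass.FERTILE
    if all(carries[a] for a in rule.antidotes):
        return PhenotypeClass.DRIVE
    return PhenotypeClass.STERILE


def expected_progeny_ratio(
    mother: DiploidGenotype,
    father: DiploidGenotype,
    rule: ViabilityRule,
    gmap: GeneticMap,
) -> dict[PhenotypeClass, float]:
    """Analytic phenotype-class distribution of a cross.

    Female transmission is unselected; male transmission is weighted by
    gamete viability (drive killing happens in pollen of toxin carriers).
    The baseline abortion rate cancels on renormalisation and is ignored.
    """
    rule.check_loci(mother)
    rule.check_loci(father)
    fem = _gamete_pattern_distribution(mother, gmap, rule.loci)
    male = _gamete_pattern_distribution(father, gmap, rule.loci)
    if father.carries(rule.toxin):
        w = np.array(
            [
                survival_probability(rule, {nm: bool(row[nm]) for nm in rule.loci})
                for _, row in male.iterrows()
            ]
        )
        tot = float((male["meiotic_freq"] * w).sum())
        if tot == 0:
            raise ValueError("father produces no viable pollen under this rule")
        male = male.assign(meiotic_freq=male["meiotic_freq"] * w / tot)
    out: dict[PhenotypeClass, float] = {}
    for _, fr in fem.iterrows():
        for _, mr in male.iterrows():
            cls = _classify_pattern(
                rule,
                {nm: bool(fr[nm]) for nm in rule.loci},
                {nm: bool(mr[nm]) for nm in rule.loci},
            )
            out[cls] = out.get(cls, 0.0) + float(fr["meiotic_freq"] * mr["meiotic_freq"])
    return out
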