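# pollendrive

Forward simulation and analysis of a **toxin–antidote pollen killer** (gene
drive) segregating in maize x teosinte (*Zea mays* ssp. *mexicana*)
introgression lines, for geneticists studying segregation distortion,
RNAi-based gamete killing, and their population-genomic footprints.

In this system a toxin locus (*Tpd1*, a hairpin-siRNA precursor) acts
**sporophytically**: one copy in the diploid parent poisons the entire
pollen cohort. Rescue is **gametophytic**: a pollen grain survives only if
it inherits every antidote — a toxin-linked hypomorphic Dicer allele
(*dcl2^T^*) and the unlinked *Tpd2*. A heterozygote therefore aborts

\[ 1 - \tfrac14(1-b) \approx 76.5\% \]

of its pollen (with baseline abortion *b* ≈ 6%), yet transmits the drive
haplotypes to *all* surviving grains. Eliminating recombinants that
separate the toxin from its linked antidote produces **pseudolinkage**:
0 cM between loci through the male, the true map distance through the
female.

The package provides, as importable modules behind a thin `pollendrive`
CLI:

| module | contents |
|---|---|
| `genetics` | marker sets, genetic maps, Haldane meiosis, map-distance estimation |
| `drive` | the viability rule, analytic gamete/progeny expectations, phenotype classes |
| `simulate` | Monte-Carlo pollen populations, crosses, backcross programs |
| `synth` | generators: sparse single-pollen observations, segregant pools, small-RNA reads over genomes with planted inverted repeats, Wright–Fisher haplotype panels (± sweep), degradome profiles |
| `pollen` | single-grain binning/smoothing, 2-state haploid ancestry HMM, driven-interval caller |
| `bsa` | dSNP index and window significance for bulk segregant analysis |
| `srna` | sRNA cluster calling, hairpin identification (Nussinov fold + self-complementarity), NB exact differential test |
| `targets` | plant-style siRNA target scoring, Argonaute sorting by 5' nt, degradome cleavage support, responder-haplotype classification |
| `popgen` | EHH/iHS, windowed extreme-score statistics with decile empirical p, Weir–Cockerham F_ST, interval-admixture Spearman correlation |

## Worked example

```python
import numpy as np
from pollendrive import drive_scenario
from pollendrive.simulate import CrossDesign, simulate_cross, simulate_pollen_population
from pollendrive.genetics import estimate_map_distance
from pollendrive.drive import classify_plant_phenotype

rng = np.random.default_rng(7)
sc = drive_scenario()  # Tpd1/+;Tpd2/+ vs recurrent parent, 6.02% baseline

pop = simulate_pollen_population(sc.drive_parent, sc.rule, 10_000, rng, sc.gmap)
print(f"heterozygote abortion: {100 * pop.abortion_rate:.1f}%")

wt = simulate_pollen_population(sc.w22, sc.rule, 10_000, rng, sc.gmap)
print(f"wild-type abortion:    {100 * wt.abortion_rate:.1f}%")

cross = simulate_cross(
    CrossDesign(mother=sc.drive_parent, father=sc.w22, n_progeny=1_000),
    sc.gmap, sc.rule, rng,
)
counts = {}
for p in cross.progeny:
    cls = classify_plant_phenotype(p, sc.rule).value
    counts[cls] = counts.get(cls, 0) + 1
print("maternal progeny:", counts)

sc_mapped = drive_scenario(antidote_cm=18.7)
male = simulate_cross(
    CrossDesign(mother=sc_mapped.w22, father=sc_mapped.drive_parent, n_progeny=214),
    sc_mapped.gmap, sc_mapped.rule, rng,
)
cm, rec = estimate_map_distance(male.progeny, "dcl2T", "Tpd1", "male")
print(f"male dcl2T-Tpd1 distance: {cm:.1f} cM ({rec} recombinants / 214)")
```

prints

```
heterozygote abortion: 77.3%
wild-type abortion:    5.8%
maternal progeny: {'drive': 253, 'sterile': 244, 'fertile': 503}
male dcl2T-Tpd1 distance: 0.0 cM (0 recombinants / 214)
```

Read: the drive heterozygote aborts ~3/4 of its pollen while its wild-type
sibling sits at the ~6% background; the reciprocal (maternal) cross
segregates fertile : drive : sterile at 2:1:1 because female transmission
is unselected; and male transmission eliminates every recombinant between
the toxin and its linked antidote — apparent complete linkage between loci
that are 18.7 cM apart through the female.

See `docs/methods.md` for the model, its assumptions, every tunable
threshold, and what the synthetic data do and do not emulate.

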