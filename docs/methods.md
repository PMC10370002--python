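# Methods

## The system being modelled

`pollendrive` models a sporophytic-toxin / gametophytic-antidote pollen
killer of the kind found in maize x teosinte (*Zea mays* ssp. *mexicana*)
introgression lines. A diploid plant carrying at least one copy of a toxin
locus (*Tpd1*, a hairpin-siRNA-producing non-coding RNA) poisons its whole
pollen cohort before meiosis; after meiosis, only the haploid pollen grains
that inherit the complete antidote set survive. The default antidote set is
a toxin-linked hypomorphic Dicer allele (*dcl2^T^*) plus an unlinked second
locus (*Tpd2*). Because the killing is sporophytic and the rescue
gametophytic, a heterozygous plant aborts the ~3/4 of its pollen that lacks
one or both antidotes, while transmitting the toxin-plus-antidote haplotypes
to essentially every surviving grain — gene drive.

## The viability rule

`drive.ViabilityRule` encodes the model:

| parameter | default | meaning |
|---|---|---|
| `toxin` | `Tpd1` | locus whose presence in the *sporophyte* triggers killing |
| `antidotes` | `(dcl2T, Tpd2)` | loci the *gamete* must carry to survive |
| `linked_antidote` | `dcl2T` | the antidote subject to the integrity requirement |
| `haplotype_integrity` | `True` | surviving gametes must co-inherit toxin and linked antidote (or neither) |
| `baseline_abortion` | 0 (scenario default 0.0602) | drive-independent abortion probability |
| `survival_table` | `None` | per-antidote-combination survival overrides (partial antidotes) |

Survival composes as `drive survival x (1 - baseline)`; the ~6% baseline
reproduces the background abortion of wild-type pollen and is applied to
every gamete independently of drive status.

The haplotype-integrity requirement is a phenomenological stand-in for the
elimination of recombinants that separate the toxin from its linked
antidote (mechanistically attributed to excess secondary siRNAs in such
recombinants). It reproduces the signature male pseudolinkage: zero
recombinants between loci that recombine freely through the female.

## Meiosis and map arithmetic

Crossovers follow the Haldane model: counts Poisson(L/100) per chromosome,
positions uniform, no interference. The vectorised `meiosis_batch` uses the
exact Markov equivalence of this model (independent phase switches between
adjacent markers with probability `r = (1 - e^(-2d/100))/2`); a property
test confirms the two code paths agree in distribution.

`estimate_map_distance` reports `100 x recombinant fraction` by default —
the way map distances are computed from progeny counts in a cross — with
the Haldane inverse available as an option. Consequently
`drive_scenario(antidote_cm=18.7)` interprets 18.7 as the *reported*
distance and places the linked antidote at its Haldane-inverse map gap
(~23.4 cM), so that a female-transmission estimate recovers 18.7. With the
default `antidote_cm=0` the toxin and linked antidote form a single
effective unit, which is what the heterozygote abortion-rate expectation
(1 - 0.25 x (1 - baseline) ≈ 76.5%) assumes.

Coordinates: bp are 1-based; bins and windows are 0-based half-open. The
built-in scenario uses 1 Mb per cM, two drive chromosomes and one neutral
chromosome, markers every 2 cM, and donor-ancestry blocks around the drive
loci on the non-recurrent haplotype. The kernel markers *Bt1* (inside the
inversion, fully linked to the toxin) and *y1* (21.5 cM from *Tpd2*) are
heterozygous with the dominant functional allele in coupling with the
drive haplotype, as in a tester cross.

## Synthetic observations

* **Single-pollen sequencing** (`ObservationModel`): per-marker i.i.d.
  missingness (default 80%), allele-dropout folded into missingness
  (haploid grains), genotype error 5%. A block-dropout option exists for
  amplification-bias stress tests but is off by default; passing tests
  under the i.i.d. model say nothing about spatially correlated dropout in
  real WGA data.
* **Pooled segregants**: read counts are Binomial(depth, pool allele
  frequency) per marker — no mapping bias or overdispersion.
* **Small RNA**: loci emit reads with configurable CPM, size distribution
  over 20–25 nt and dominant-strand fraction; hairpin loci additionally
  plant an inverted repeat (default 100 bp arms at 95% identity) in the
  genome sequence. Background reads are uniform Poisson. Real sRNA data
  have UMI structure, multimapping and structural-RNA contamination that
  are out of scope here (a blocklist hook covers the last).
* **Haplotype panels**: a haploid Wright–Fisher population (N = 200,
  recurrent 0↔1 mutation at 1e-3/site/generation, 200 cM map, 300
  generations of burn-in from a monomorphic ancestral state, so polarity
  is known by construction). The sweep model seeds a new beneficial
  mutation at the central site (haploid selection 1 + s, default s = 1.5)
  and stops at 75% frequency — a hard, partial sweep. Desk-scale panels
  have far less haplotype diversity than real population data; sweep tests
  are positive controls, not power estimates.
* **Degradome profiles**: Poisson background plus Poisson peaks of
  `signal:background` times the background rate at true cleavage sites.

## Single-pollen analysis

Calls (1/-1/0) are averaged in 100 kb bins, smoothed in 1 Mb / 200 kb
sliding windows, and imputed per grain with a two-state haploid HMM
(states: recurrent vs donor ancestry; transitions: Haldane fractions of
the marker cM gaps; emissions: correct with probability 1-ε, missing
uninformative). The external diploid-panel imputation tool used on the
real data is deliberately replaced by this HMM because pollen grains are
haploid; forward–backward posteriors are verified against exhaustive path
enumeration. Posteriors are hard-called at 0.9 (conservative; below that
the marker stays missing).

Driven intervals: each grain votes once per bin (the sign of its bin
mean), the per-bin one-sided exact binomial test against 0.5 is corrected
by Benjamini–Hochberg across bins, and adjacent significant bins merge.
The binomial null assumes independent grains and fair transmission.

## Bulk segregant analysis

Per-marker alt frequencies → 100 kb bin means → sliding-window means; the
dSNP index is the window difference between pools. Significance uses a
two-proportion z-test on window-aggregated raw counts with BH correction
(the simplest test consistent with count data; a simulation null is
available by feeding permuted pools). Under exact 2:1:1 maternal
segregation the depth→∞ oracle gives +0.5 at the toxin and -0.25 at the
unlinked antidote, which the tests assert from pool-composition
arithmetic.

## Small-RNA analysis

Clusters are read islands (gap ≤ 75 bp) kept at CPM ≥ 5 with a modal size
in {21, 22, 24} holding ≥ 50% of reads. Hairpin calls additionally require
single-strand fraction ≥ 0.8, 22 nt fraction ≥ 0.5, a reverse-complement
self-alignment with a ≥ 50 bp window at ≥ 80% identity, and a pairing
fraction ≥ 0.6 from an internal Nussinov-style maximum-matching fold
(min loop 3, verified against exhaustive enumeration ≤ 12 nt). The
identity criterion is evaluated over the best 50 bp window of the local
alignment so the loop the alignment spans does not dilute the arms. The
pairing fraction is a proxy for thermodynamic stability — an external
folder can be substituted where installed. All four thresholds quantify
qualitative criteria and are config-exposed.

Differential accumulation replaces the published R-based tool with a
documented negative-binomial exact test: libraries are scaled to the mean
library size, a common dispersion is moment-estimated across clusters
(floor 1e-4), and the two group sums are compared conditionally on their
total (two-sided, summing splits no more likely than the observed one),
with BH across clusters and the log2FC ≥ 2 / q ≤ 0.01 flagging rule.

## Target prediction and degradome support

Guide/target scoring uses the standard plant scheme: mismatch 1.0, G:U
0.5, bulge 2.0, penalties doubled over guide positions 2–13, expectation
cutoff 5.0 (the exact cutoff used on the real data is not published; 5.0
is the community default and is exposed). Alignment is a small
Needleman–Wunsch with free target end-gaps per candidate window. The
cleavage coordinate is the target position opposite guide nt 10; a
mismatch or bulge anywhere in guide positions 9–11 reassigns the site to
translational-repression mode (a wobble does not). Argonaute sorting is by
5' nucleotide: A→Ago2, C→Ago5, U→Ago1, G→unclassified.

Degradome support requires the CPM within ±1 nt of the predicted cleavage
coordinate to reach a 1-CPM floor and strictly exceed the 0.9 quantile of
the transcript profile; the strict inequality makes a flat profile support
nothing. The floor is meaningful when CPM is computed against the full
library (millions of reads), where stray background reads fall below it.

Responder-haplotype classification aligns an allele to the reference
transcript (global, affine gaps) and reports per reference site:
`deleted` (a deletion covering the seed — target positions opposite guide
nts 2–8 — or most of the site; with an in-frame flag, total gap length
divisible by 3), `position-11-SNP` (substitution opposite guide nt 10/11),
`seed-disrupted`, or `intact`.

## Selection scans

EHH is the fraction of carrier pairs identical over [core, x]; iHH is its
trapezoid integral over the genetic map, truncated where EHH < 0.05, per
allele and direction. SNPs below 5% MAF, with fewer than two carriers of
either allele, or whose EHH has not decayed below the cutoff at a
chromosome edge are skipped (edge integrals are biased). The
unstandardised score ln(iHH_anc/iHH_der) is standardised within
derived-frequency bins (50 by default; 10 at desk scale where bins would
otherwise be nearly empty). `standardize_ihs` re-standardises concatenated
per-chromosome tables so that genome-wide scans pool frequency bins across
chromosomes — without this, the hitchhikers of a desk-scale sweep dominate
their own bins and cancel their own signal.

Windowed statistics: the count of top-5% |iHS| SNPs per 10 kb window;
windows are binned into SNP-count deciles and the empirical p of a window
is its conservative descending rank within its decile divided by the
decile size (ties share the worst rank, so p ∈ (0, 1]); Bonferroni
multiplies by the number of populations tested. Weir–Cockerham F_ST is
computed from allele counts as variance components (MSP, MSG, n_c) with
the windowed weighted form Σ(MSP−MSG)/Σ(MSP+(n_c−1)MSG); the per-SNP and
windowed estimators are verified against longhand arithmetic. Gene-region
assignment takes the minimum window p over the gene ± 1 kb. Interval
correlations are pairwise Spearman over populations with BH over the
upper triangle; constant intervals (e.g. a monomorphic responder locus)
are reported missing rather than zero.

## Problem sizes and numerical choices

Simulations in the tests and the acceptance script use 10,000 gametes for
abortion rates, 1,000–2,000 progeny for segregation and mapping, 178
grains (x ~50 markers/chromosome) for the single-pollen positive control,
400–1,000 replicates for null calibrations, 60-haplotype/250-SNP panels
for the scans. These sizes were chosen so every stochastic check sits
several standard errors inside its tolerance while the whole suite stays
desk-scale. Stochastic positive controls run under fixed seeds;
distributional checks assert within 3 standard errors. Degenerate inputs
(zero-depth markers, empty bins, monomorphic windows, all-zero clusters)
are propagated as missing values, never as zeros.

## Known limitations

* No pollen competition: viable pollen fertilises uniformly (an optional
  fitness weight is the extension point); recombinant-pollen competition
  observed in the real system is not modelled.
* The integrity rule is all-or-nothing by default; graded survival needs a
  `survival_table`.
* No molecular model of siRNA dose, transitivity or silencing spread; the
  drive model is purely genetic.
* The B73-like "immune responder" cross outcome is representable via a
  `survival_table` scenario stub but is not validated against data.
* The Wright–Fisher generator uses recurrent symmetric mutation, so rare
  back-mutation can blur ancestral polarity at desk scale.
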