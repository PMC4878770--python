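# pedrecomb

Crossover and non-crossover recombination mapping from whole-genome
sequencing of a three-generation pedigree, with a synthetic-pedigree
simulator that provides ground truth for every analysis stage.

## The problem

Sequencing a complete three-generation family (4 grandparents, 2 F1
parents, their offspring) makes individual meiotic recombination events
directly observable.  At any SNP where an F1 parent is heterozygous and
its own parents' genotypes differ, each F1 allele can be traced to one
grandparent; following those alleles into the F2 generation yields, for
every transmitted gamete, a sequence of grandparent-of-origin labels
along each chromosome.  Runs of identical labels form *haploblocks*:

* a **crossover (CO)** appears as a switch between two adjacent
  haploblocks, localised to the interval between their outermost SNPs;
* a **non-crossover gene conversion (NCO)** appears as a single
  informative site whose label disagrees with the surrounding block.

Because a single miscalled genotype mimics an NCO exactly, candidate
conversions pass a stringent filter cascade (recalibration tranche,
indel distance, SNP-cluster density, allele balance, read support, and a
sex-linked contamination pattern) before being accepted.

Downstream, the package computes the genetic statistics such a dataset
supports: sex-specific map lengths (d = 100 · n<sub>events</sub> /
n<sub>meioses</sub> cM) and cM/Mb rates, agreement with an external
linkage map, crossover interference as the coefficient of coincidence
(CoC = observed/expected double COs in 1 Mb windows), a permutation
test for event clustering (hot-spots), proportional-overlap association
of events with gene anatomy (promoter, first exon/intron, ...), region
overlap odds ratios, paired GC comparison, and GC-biased gene
conversion: among conversions at weak(A/T):strong(G/C) sites, the
strong-transmission proportion p̂ gives the transmission distortion
*c* = 2p̂ − 1, tested with an exact binomial test against 0.5.

The sex chromosome is handled with avian ZW semantics: females are
hemizygous outside the pseudoautosomal region (PAR), the non-PAR Z
recombines only in male meiosis, and female Z genotypes there are
haploid calls.

## The simulator

Real pedigree data of this kind are large and access-controlled, so the
package includes a first-class simulator: founder haplotypes at a
configurable SNP density, gametes from a stationary gamma-renewal
crossover process (shape ν ≥ 1; ν = 1 is the Poisson, no-interference
limit) with sex-specific rates and an optional obligate crossover per
chromosome, geometric conversion tracts with the strong allele
transmitted at probability (1 + c)/2, Z/PAR inheritance, and an error
model (depth, genotype errors, missing calls, low GQ, W-read
contamination).  Every simulation carries its truth tables — crossover
breakpoints, conversion tracts, per-site origins — so recall, precision
and estimator calibration are measurable, not assumed.

## Worked example

```python
from pedrecomb.pipeline import run_simulated_pipeline

result = run_simulated_pipeline(seed=1)   # desk-scale 3-chromosome genome
print(result.report["counts"])
print(result.report["map"])
```

prints (seed 1):

```
{'sites_in': 4272, 'sites_surviving': 4272, 'z_het_females_removed': 0,
 'informative_site_sides': 2865, 'untraceable': 2704, 'co_events': 25,
 'nco_events': 1, 'nco_candidates': 1, 'truth_co': 26,
 'truth_nco_conversions': 1}
{'total_autosomal_cM': 200.0, 'female_autosomal_cM': 180.0,
 'male_autosomal_cM': 220.0}
```

All 4,272 clean simulated sites survive filtering; 25 of the 26 true
crossovers are detectable (one falls outside the informative-site span)
and all 25 are recovered, each interval containing its true breakpoint.
The single simulated gene conversion that hits an informative site
survives the filter cascade.  The implied autosomal map (events × 100 /
10 meioses) is 200 cM, split 180 cM maternal / 220 cM paternal.

The same pipeline is available as a CLI:

```bash
pedrecomb simulate --seed 1 --out sim/
pedrecomb filter --vcf sim/pedigree.vcf --pedigree sim/pedigree.tsv \
    --mean-cov 42 --out filt/
pedrecomb phase --vcf filt/filtered.vcf --pedigree sim/pedigree.tsv --out ph/
pedrecomb detect-co --phased ph/phased.tsv --out co/
pedrecomb detect-nco --phased ph/phased.tsv --vcf filt/filtered.vcf \
    --pedigree sim/pedigree.tsv --out nco/
pedrecomb stats --co co/co_events.tsv --nco nco/nco_events.tsv --out stats/
# or everything at once:
pedrecomb all --seed 1 --out run/
```

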