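# Methods

## Pedigree design and phasing model

The package analyses a 4 + 2 + n three-generation pedigree (default
n = 5 F2 offspring, one of them female).  Each F2 genome decomposes into
a paternally and a maternally transmitted gamete; the ten F1 → F2
meioses (five per sex) are the observation units.

A site is *informative* for a transmission side when the F1 parent of
that side is heterozygous and exactly one assignment maps each F1 allele
to a distinct grandparent — one grandparent homozygous for one allele,
the other homozygous for the alternative allele or heterozygous.  The
transmitted allele is resolvable in an offspring unless the F1's partner
and the offspring are both heterozygous; such transmissions are counted
as untraceable and excluded from label sequences.  A site may be
informative for both sides at once and is then emitted independently
for each.  A missing genotype in any of the five individuals relevant
to a side makes the site uninformative for that side.  Origin labels
are integer codes (0 grandfather, 1 grandmother, −1 untraceable) so
downstream comparisons are exact.

## Event calling

Label runs become haploblocks.  Pruning assumes at most one
recombination event per megabase: an interior block with fewer than
`min_sites` (default 3) sites whose two flanking switches fall within
1 Mb (last site of the left neighbour to first site of the right
neighbour) is removed, equal-label neighbours merge, and the scan
restarts leftmost until a fixed point — which makes the result
deterministic and lets a brute-force re-implementation serve as a test
oracle.  Removed single-site blocks become NCO candidates; removed
multi-site blocks are logged as suspect and not forwarded (conversion
tracts spanning two or more adjacent informative sites are deliberately
left unclassified rather than guessed).  Terminal blocks are never
pruned: they participate in only one switch, so the one-event-per-Mb
argument does not apply to them.

A crossover is called between each adjacent pruned-block pair with
differing labels, localised to the half-open interval
(last site of left block, first site of right block] with
resolution = interval length; events are binned at <5 kb / <10 kb and
summarised with and without assembly-gap overlap.  No event is called
before the first or after the last informative site; crossovers outside
the informative span are a stated power limitation.

NCO candidates pass a pure-conjunction filter cascade (every filter is
evaluated and recorded in a fixed-order trace): usable allele depths;
the stricter 90 % recalibration tranche; ≥10 bp from any indel; not in
a >3-SNPs-per-30-bp cluster of the full call set (window anchored to
contain the candidate); no more than two deviating sites within any
5 kb window of the same offspring/side label sequence; no reads on a
third allele; minor-allele read fraction ≥ 0.25 in every heterozygote;
and not matching the all-females-heterozygous /
all-males-homozygous-reference pattern that W-linked reads produce on a
male-derived assembly.  Surviving events at weak:strong sites are
classified W>S or S>W by the transmitted versus background base.

## Statistics

* **Maps.** d = 100 · n/meioses cM.  Sex-average per-chromosome
  distances divide total events by all 10 meioses; the Z divides
  paternal events by 10 (a male map, since the non-PAR Z recombines
  only in males); sex-specific genome totals divide same-sex autosomal
  events by the 5 same-sex meioses.  Both conventions are exposed and
  labelled.
* **Linkage agreement.** Pearson r between per-chromosome observed and
  external linkage distances; invariant to positive rescaling, so
  counts and count-proportional distances give identical r.
* **Chromosome ends.** Distance of each event midpoint to the nearest
  end, binned at 10 Mb and 1 Mb; male versus female terminal distances
  compared with a one-sided Mann–Whitney U (normal-approximation z
  reported alongside the exact-distribution p).
* **Interference.** Chromosomes are tiled with 1 Mb windows; for every
  window pair at separation d, observed = meioses with ≥1 event in both
  windows, expected = product of the windows' marginal occupancy
  probabilities × meioses; pooled over pairs and chromosomes,
  CoC(d) = O/E, reported as NaN (not 0) where E = 0.
* **Hot-spots.** Statistic: pairs of events from different meioses on
  the same chromosome closer than 100 kb (midpoints).  Permutations
  redraw each event's midpoint uniformly on its own chromosome,
  preserving per-chromosome and per-meiosis counts;
  p = (1 + #{null ≥ obs}) / (1 + n\_perm).  A variant excluding
  gap-overlapping events is available.
* **Gene anatomy.** The genome is partitioned into promoter (2 kb
  upstream of the TSS, strand-aware), first exon, first intron, other
  exons, other introns and intergenic, with overlaps resolved by that
  precedence.  Each event distributes weight overlap/length across
  categories; density = summed weight per category bp; each category is
  tested against intergenic with Fisher's exact test on rounded event
  counts and kb margins (Fisher requires integers; the kb scaling is
  noted in the output).
* **Region overlap.** Midpoint-in-region counts versus region/non-region
  area; odds ratio (in/out)/(area ratio) plus Fisher p on the events ×
  kb table.
* **GC.** Per-chromosome mean event-region GC paired with background
  GC, paired t-test; chromosomes without events are dropped and
  counted; all-zero differences short-circuit to t = 0, p = 1.
* **gBGC.** p̂ = n(W>S)/(n(W>S)+n(S>W)); exact two-sided binomial test
  against 0.5 (opposite-tail-summing convention); Clopper–Pearson 95 %
  CI; c = 2p̂ − 1.  No multiple-testing correction is applied anywhere.

## Simulator

Founders carry biallelic SNPs at Poisson-distributed positions
(default density 10⁻⁴/bp at desk scale; the empirical diversity of the
flycatcher system is π ≈ 3.6 × 10⁻³, which desk-scale runs deliberately
undersample for speed).  All eight founder haplotype alleles are drawn
independently with monomorphic sites rejected, giving a natural mixture
of weak:strong and weak:weak / strong:strong site types.

Crossovers per gamete follow a stationary gamma-renewal process: shape
ν (default 5), mean spacing 100/rate Mb, warm-started far left of the
chromosome so the first in-window event is at renewal equilibrium.
ν = 1 recovers a Poisson process (CoC ≈ 1 at all separations); larger ν
depresses CoC at short range, reproducing distance-dependent positive
interference.  Default rates are the flycatcher sex-specific autosomal
rates (female 2.28, male 3.56 cM/Mb).  The obligate crossover is
implemented by rejection-resampling a chromosome's event set until
non-empty — an approximation of one obligate chiasma.  On the Z, female
meiosis restricts crossovers and conversion tracts to the PAR; the
obligate-crossover conditioning is *not* applied there, since forcing
an event into a 0.6 Mb window every meiosis would imply a ≥83 cM/Mb PAR
map, far above the configured female rate.  Female gametes transmit
either the Z or the W (the W modelled as a Z homologue with no non-PAR
sequence), which fixes offspring sex.

Conversion tracts start at Poisson rate `nco_rate_per_Mb` (default
0.1/Mb — the true initiation rate in birds is unknown; this default is
a placeholder of plausible order, not an estimate) with geometric
lengths (mean 500 bp; single-site detection makes the exact mean
non-critical).  At weak:strong heterozygous sites inside a tract the
strong allele is transmitted with probability (1 + c)/2, at other
heterozygous sites either allele with probability ½; a change relative
to the background haplotype is recorded as a truth conversion.  Tracts
landing within 1 bp of a crossover breakpoint are re-drawn.

The error model perturbs emitted records: Poisson depth, binomial
allele depths, uniform wrong-genotype replacement, missing calls, a
low-GQ fraction, and a W-contamination channel that rewrites autosomal
sites to the all-females-het / all-males-hom-ref pattern (tagged in the
truth so filter recall is checkable).  A null error model emits
idealised records — constant depth, balanced allele depths, GQ 99 — so
that "clean data passes every filter" holds identically rather than
with high probability.

### What the simulator does not emulate

Linked-read structure, base-qualities, indels and structural variation,
reference bias, repeat-driven mis-mapping (beyond the W-contamination
channel), population LD among founders, and realistic SNP density.
Passing recovery tests therefore demonstrates correctness of the
detection logic under the stated generative model, not robustness to
every real-data artifact; the filter cascade's real-data thresholds are
carried as configuration, not re-derived.

## Numerical and design choices

* Intervals are 0-based half-open internally; VCF positions (1-based)
  convert at the I/O boundary.  Crossover intervals are reported as
  1-based (left, right].
* Event location for point statistics is the interval midpoint
  (configurable in principle; positions for NCO events are exact).
* Missing genotype calls count against the coverage filter stage: a
  no-call carries no usable reads, and the five-stage report order
  (mask → biallelic → coverage → GQ → Mendelian) stays fixed.
* Mendelian checks treat a haploid (female Z) child as inheriting its
  single allele from the father; trios with missing members are
  uninformative rather than violations.
* Recalibration-tranche membership travels as VCF INFO flags
  (`T90FAIL`, `T999FAIL`); absence means pass.
* A conversion landing on the informative site adjacent to a crossover
  breakpoint shifts the apparent label switch by one marker interval.
  Exact breakpoint-containment is therefore only guaranteed in
  tract-free simulations; at the default conversion rate the collision
  is rare (none observed in 30 clean pedigrees), and at 20× that rate
  roughly one call in fifty relocates by one marker.  Real analyses at
  ~1000× higher marker density are affected proportionally less.
* Desk-scale problem sizes: the default genome is 3 chromosomes
  (20 Mb, 8 Mb, and a 15 Mb Z with a 0.6 Mb PAR) at density 10⁻⁴,
  chosen so a full simulate–detect cycle runs in ~0.25 s and the
  100-pedigree recovery studies finish in well under a minute.
* Double crossovers falling inside one marker interval are invisible
  (an even number of co-located breakpoints cancels, an odd number
  looks like one); recovery scoring collapses them into a single
  expected event.

## Known limitations

Detection power for conversions is bounded by the probability that a
tract covers an informative site, so simulated conversion counts are
not calibrated to any empirical NCO rate.  The haploid re-call path for
female non-PAR-Z sites accepts pre-made haploid genotypes; it does not
re-genotype from reads.  VQSR itself, alignment, and variant calling
are out of scope — the pipeline consumes a called VCF.
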