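# Methods

This note documents the models implemented in `sweepscan`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing
its output.

## Data model and coordinates

All stages share three containers: a marker map (1-based physical
positions, strictly increasing per chromosome, unique ids, two alleles
per marker), a diploid dosage matrix over {0, 1, 2, missing} counting
copies of allele2/ALT, and a phased binary haplotype panel (two rows per
sample, no missing entries). Positions are 1-based inclusive everywhere
internally; BED exports convert to 0-based half-open at the boundary.
Readers validate dimensions and map sortedness and refuse inconsistent
input rather than repairing it. Ancestral/derived recoding is an explicit
step (`infer_ancestral`), never implicit: the ancestral allele is the
majority allele over the full cohort's haplotypes, and exact 50:50 ties
are flagged and excluded from iHS (they remain usable for the EHHS-based
tests, which need no polarization).

## Quality control

The filter chain runs in a fixed order — marker call rate ≥ 0.95, marker
MAF ≥ 0.05, sample missingness ≤ 0.10 (strictly-greater removal), then LD
pruning — and each step is idempotent. Pruning follows indep-pairwise
semantics (window 50 SNPs, step 5, r² > 0.60) with r² computed as the
squared Pearson correlation of dosages over pairwise-complete samples
(composite LD). Within an offending pair the later marker on the map is
removed; this tie-break is deterministic, and a `lower_maf` victim rule
is available for users who prefer PLINK's choice.

## EHH statistics

EHH and EHHS are computed by walking outward from the focal marker and
refining haplotype identity classes one marker at a time; the pooled
pair-identity fraction Σ n_k(n_k−1)/(n(n−1)) at each step is exact, and
the walk stops once the curve falls below the decay cutoff (identity
classes only refine, so the curves are monotone non-increasing — a
property asserted in the tests and checked against exhaustive pairwise
enumeration to 1e−12).

Integration is trapezoidal over physical distance in bp, per side, up to
and including the first marker below the cutoff (default 0.05). A side
whose curve never decays before the chromosome end is an edge case: the
default `discard` rule suppresses the site's statistic (status
`edge_truncated`) to avoid downward-biased integrals; `truncate`
integrates to the last marker and notes the status. Physical distance is
used throughout — no genetic map is assumed.

Standardization conventions:

* iHS: 20 equal-width derived-frequency bins over (0, 1); each bin is
  centered and scaled with the population (divide-by-n) standard
  deviation, so small exact test cases reproduce mean 0 / sd 1 to 1e−9.
  Bins with fewer than two finite values leave their members
  `unstandardizable`.
* Rsb: normalized EHHS integrals, median-centered (robust);
* XP-EHH: unnormalized EHHS integrals, mean-centered. Both scale by the
  genome-wide population sd. Centering is configurable in both tests.

A within-scan MAF ≥ 0.05 screen is re-applied because the cohort-wide QC
does not guarantee group subsets stay polymorphic: per group panel for
iHS, and on the pooled two-group frequency for Rsb/XP-EHH — pooling
rather than per-group filtering deliberately retains sites fixed in one
group, which are exactly the signal XP-EHH exists to detect.

The p-transform `p_score = −log10(1 − 2|Φ(z) − 0.5|)` equals −log10 of
the two-sided Gaussian p-value; p_score ≥ 4 corresponds to
|z| ≥ Φ⁻¹(1 − 5·10⁻⁵) ≈ 3.8906, verified numerically in the tests.

## Window classification

Windows are 250 kb, starting at 0 on each chromosome and stepping by
240 kb so that consecutive windows share 10 kb ("10-kb overlaps" read
literally; the step is configurable for the alternative 10-kb-step
reading). The last window truncates at the final marker. Boundaries are
inclusive on both ends, so a SNP on a shared boundary counts in both
windows. A window is flagged when it contains at least 3 SNPs with
p_score ≥ 4 (reaching the threshold counts; a strict mode exists).
Overlapping or book-ended flagged windows merge into candidate regions;
lengths are reported as (end − start)/1000 kb. Region sets from Rsb and
XP-EHH are intersected pairwise (positive-length overlaps only), and
intersections are annotated when they also overlap a within-group iHS
region.

## Runs of homozygosity

Segment detection applies the seven-criterion sliding-window protocol:
50-SNP windows are "acceptable" with ≤ 1 heterozygote and ≤ 2 missing
calls; a SNP is in-ROH when ≥ 5% of the windows covering it are
acceptable, with the denominator being the number of windows that *can*
cover it given chromosome ends (so edge SNPs remain reachable); maximal
in-ROH runs are split at inter-SNP gaps > 1 Mb; surviving runs must hold
≥ 100 SNPs, span ≥ 1 Mb, have ≤ 100 kb per SNP (span/n), and — as final
segment properties — again ≤ 1 heterozygote and ≤ 2 missing. Reported
segments are the maximal sub-runs satisfying all criteria, verified
against exhaustive enumeration on small chromosomes.

Locus homozygosity is the fraction of a group's animals whose segments
cover a SNP (each animal counted once). The island threshold is the
genome-wide empirical quantile at 0.999 within the group, computed with
the next-higher order statistic so the selected set is the upper 0.1%
tail even when n·q is integral; threshold ties are included (≥). SNPs at
or above threshold merge into islands when consecutive on the map. The
threshold is genome-wide per group, not per chromosome.

## Distance-based AMOVA

Hamming distances count allele differences |g_i − g_j| over pairwise
non-missing markers (a 0/2 pair contributes 2); the normalized variant
divides by twice the comparable-marker count, and a genotype-mismatch
mode is available. The partition uses the standard machinery: Gower
centering of −½D², sequential (Type I) sums of squares by projecting on
the growing design (order as written, BW then GEO; the groupings are
close to orthogonal so order effects are small, and the order is
configurable), pseudo-F against the residual, and R² = SS/SS_total. SS
additivity holds to 1e−9 by construction and is asserted.

Significance comes from random permutations of factor levels at the
population level by default — the factors are population attributes, so
whole populations exchange labels; sample-level permutation is available
for synthetic calibration work. The p-value uses the add-one correction
(1 + #{F* ≥ F})/(1 + n_perm), so 1000 permutations bound p below at
≈ 0.001. Permutation F statistics are compared with a 1e−8 relative
tolerance so that tied statistics are counted as ties regardless of
floating-point summation order. Because per-permutation designs are
constant within populations, the quadratic forms are evaluated on the
population-aggregated Gower matrix — an exact algebraic reduction, not an
approximation. Classical MDS (principal coordinates) of the same matrix
is provided for structure checks; negative-eigenvalue mass is dropped
and logged.

## Synthetic cohorts

The generator emulates the kind of data the pipeline targets — a
23-population, 541-bird SNP-array cohort with heavy/light and
north/south contrast groups — without claiming coalescent exactness:

* **Founders and mosaics.** K founder haplotypes (default 40) carry
  per-site frequencies ≥ the MAF floor (0.05). Haplotypes are
  founder mosaics: the copied founder switches between adjacent sites
  with probability 1 − exp(−switch_rate·gap), so LD decays over
  ~1/switch_rate bp (default 100 kb); alleles then mutate independently
  at 10⁻³.
* **Hierarchical drift.** Every group level (heavy, light, north, south)
  and every population draws a mean-1 gamma multiplier per founder;
  group-level multipliers have variance 2 × drift, population-level
  0.5 × drift, and a population's mosaics copy founders with probability
  proportional to the product of its own and its group multipliers.
  Populations in a group therefore drift in a shared direction —
  the structure the AMOVA measures — while drift 0 gives one
  exchangeable pool. The default drift 2.0 was calibrated once so the
  full study design yields group variance fractions in the ~10–25% band
  with permutation p at the attainable minimum, the two anchors reported
  for the real cohort.
* **Sweeps.** Hard sweeps are implanted deterministically: a chosen
  fraction of the target populations' haplotypes (round half up) becomes
  a copy of one template over focal ± span, with the derived allele
  forced at the focal site — exact ground truth for power studies.
* **Autozygosity.** With probability `ibd_rate` (default 0.25) an
  individual's second haplotype is overwritten by its first over a
  1.5–4 Mb stretch, producing genuine ROH; segments are recorded in the
  truth set.
* **Missingness** is injected uniformly at 0.002 per genotype (array-like
  post-QC call rates); the phased panel stays complete.

Everything derives from explicit integer seeds through spawned seed
sequences; identical configuration and seed give byte-identical PED/MAP,
VCF, labels and truth files.

What the generator does **not** emulate: recombination hotspots, genetic
maps, sex chromosomes, genotyping error beyond uniform missingness,
ascertainment bias of array design, mutation-drift equilibrium, or
realistic site-frequency spectra. Passing tests therefore demonstrate
that the statistics, window rules, ROH criteria and variance partition
behave correctly on data with the right LD, structure and sweep geometry
— not that any particular biological conclusion about a real cohort
would be reproduced.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
the study-design cohort uses all 23 populations and 541 diploids but two
6-Mb chromosomes at ~1 SNP/6 kb (2,000 markers before QC); power
replicates use one 9-Mb chromosome at 1 SNP/3 kb (~3,000 markers) with a
95%-carrier, 400-kb sweep; PERMANOVA calibration uses 50 drift-free
cohorts of 10 × 6 diploids with 199 permutations. These sizes keep every
property measurable (oracle equivalence is exact at any size; power and
calibration are rate estimates over seeded replicates) while a full run
stays in the minutes range on one CPU.

## Known limitations

* EHH integrals use physical distance; cohorts with strong recombination
  -rate variation would need a genetic map, which the model omits.
* The edge rule suppresses statistics near chromosome ends; short
  chromosomes with long-range LD lose a border region of sites.
* Permutation at the population level limits attainable p-values when
  few populations exist (with 4 populations per factor level the null
  distribution has only dozens of distinct relabelings).
* The Hamming/AMOVA stage treats all markers as exchangeable; no
  weighting by allele frequency or LD pruning beyond the shared QC chain
  is applied inside the partition.
* fastPHASE-style phasing is out of scope: phased input (or the
  simulator's phased output) is required for the haplotype tests.
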