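# Methods

`radsexscan` implements the desk-side statistics of a sex-association study
in an F2 intercross between two inbred-like fish strains, genotyped by
RAD-seq: genotype calling from read counts, a per-SNP differentiation scan,
a binary-trait linkage scan, recombination-rate profiling, and region
enrichment, plus a forward simulator of the whole design.  This note
records the models, the numerical choices, and what the simulator does and
does not emulate.

## Genotype likelihood with a bounded error-rate profile

Reads at a site in one individual are a multinomial sample over the four
nucleotides.  With per-read error rate ε, a homozygote *ii* emits base *i*
with probability 1−ε and each other base with ε/3; a heterozygote *ij*
emits each genotype base with (1−2ε/3)/2 and the others with ε/3.  Rather
than fixing ε, each of the 10 unordered diploid genotypes gets a *profile*
likelihood: the multinomial likelihood maximized over ε within
[ε_min, ε_max] = [0.001, 0.1].  The interior maximizers are closed form —
ε̂ = (n−n_i)/n for homozygote *ii* and ε̂ = 3(n−n_i−n_j)/(2n) for
heterozygote *ij* — clipped to the bound; the unit tests verify the closed
form against a dense ε-grid search to 10⁻⁶.  The multinomial coefficient is
omitted throughout: it is common to all genotypes at a site and cancels
from every ratio.

The upper bound is the scientifically important part.  Illumina RAD data
shows heterozygotes with strongly uneven allele counts; an unbounded
maximum-likelihood fit can absorb that skew into an implausibly large ε and
call the site homozygous.  Capping ε at 0.1 provably reduces that error
mode — the test suite demonstrates it by exhaustive enumeration of the read
space at depth 16.

A genotype is assigned only when 2(lnL_best − lnL_second) exceeds the
χ²₁ quantile at 1−α (6.6349 at the default α = 0.01; df = 1 is the standard
choice for this two-hypothesis comparison and is configurable).  Zero depth
and exact first-place ties give NO_CALL; ties are never broken arbitrarily,
because a tie means the data cannot distinguish the genotypes.  There is no
explicit depth filter: low-coverage sites simply cannot reach a significant
ratio.  This makes the call rate *approximately*, not strictly, increasing
in depth — callability of k-error outcomes switches on at discrete depths,
so the exact call probability for a true homozygote at ε_true = 0.01 is
0 up to depth 4, ≈0.95 at depth 5, dips to ≈0.90 by depth 10, and only then
climbs toward 1.  An optional `min_depth` post-hoc filter mirrors the
stricter coverage criterion sometimes applied to map markers; it defaults
to off.

## G-test scan with FDR control

For each called SNP the scan builds a sexes-by-genotypes contingency table
from called genotypes only, after removing SNPs genotyped in fewer than 20
males or 20 females (both thresholds strict ≥).  The statistic is
G = 2·Σ O·ln(O/E) with expectations from independence of the margins,
referred to χ² with (r−1)(c−1) df; no continuity or Williams correction.
Cells with O = 0 contribute 0 (the x·ln x limit) and genotype classes with
zero margin are dropped before computing df, which keeps G finite and df
well defined.  Genotypic tables are the default because the study's
supplementary scan tables report per-genotype counts by sex; an allelic
2×2 mode is available behind a flag for comparison.

P-values become q-values by the Benjamini–Hochberg step-up rule,
q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j clipped at 1, computed within each family and
never pooled across families.  SNPs with q < 0.001 sit above the scan's
"0.1 percent FDR" significance line.  The implementation is checked against
statsmodels' `fdr_bh` to 10⁻¹² and is order-invariant by construction.
Under a complete null the G-test p-values are close to, but not exactly,
uniform (the χ² reference is asymptotic; at 82/63 fish per sex the
Kolmogorov–Smirnov distance to uniform is ≈0.015), which is conservative in
combination with BH.

## Binary-trait LOD scan

Sex is the binary trait; markers are phase-known four-way classes (the
ordered pair of grandparental origins of the maternal and paternal
gametes).  The alternative model gives each class its own penetrance
p̂_g = m_g/(m_g+f_g); the null pools all classes; LOD is the base-10 log of
the maximized binomial likelihood ratio with 0·ln 0 = 0.  This is a
*single-marker* scan: with dense, fully informative phase-known markers the
hidden-genotype EM of interval mapping degenerates to exactly this
likelihood at each typed marker, so the package implements the likelihood
itself rather than wrapping a QTL package.  On the published
genotype-by-sex table at the chr-4 peak (70/0, 12/63) the single-marker LOD
is 28.79 against the reported interval-mapped 28.78; the declared agreement
budget for that comparison is ±0.05.

Genome-wide significance comes from permutation: the sex vector is shuffled
among individuals (genotype correlation preserved), the genome-wide maximum
LOD recorded per permutation — vectorized as one matrix product per
permutation batch — and the 5 % / 10 % thresholds taken as the 95th/90th
percentiles with type-7 linear interpolation, fixed for bit-reproducibility
given a seed.  The calibration suite confirms the observed maximum exceeds
its own 5 % threshold in ≈5 % of null replicates.

Support intervals extend from a peak over the contiguous run of markers
within `drop` (default 1.5) LOD of it, then one marker beyond as a
conservative flank, clamped at chromosome ends — the flank rule matches how
such intervals are reported by flanking markers.

Haplotype-by-sex tables cross-tabulate one- or two-marker genotype classes
against sex with percent-male per class; Fisher's exact test (two-sided,
point-probability method, via scipy) covers small candidate-gene tables.

## Recombination rates

In this design every F2 individual's maternal gamete observes one female
meiosis and its paternal gamete one male meiosis, so the recombination
fraction between adjacent markers is the fraction of origin switches among
individuals informative for both markers (pairwise deletion of missing
entries).  Fractions convert to map distance with the Kosambi function
d = 25·ln((1+2r)/(1−2r)) cM, inverse r = tanh(2d)/2 (d in Morgans).
Estimates at or above 0.5 are capped at 0.4999 before conversion, since the
function diverges at 0.5.  Local rate profiles use a sliding window of 3
markers moving 1 marker per estimate: (cM span)/(Mb span), anchored at the
middle marker (the anchoring point is a documented choice; the window
definition does not fix it), with non-positive Mb spans skipped.

## Region enrichment

For an element class with n genome-wide copies, the expected count in a
region covering fraction f of the assembly under uniform placement is n·f,
the percent-in-region is 100·observed/n, and an upper-tail binomial test
gives P(X ≥ observed).  The region fraction is an input (for the chr-4q
heterochromatic region of Zv9 it is 2.26 %), never recomputed from assembly
sizes.  Element membership uses the start-point rule (an element belongs to
the region containing its 0-based start), configurable to any-overlap.
Display rounding follows the published table's convention: one decimal,
half away from zero, except values ≥ 10 shown as integers; raw values are
kept at full precision.

## The simulator

The generator emulates the study design, not the raw sequence data:

* **Pedigree.** F0 founders are opposite homozygotes at every
  strain-diagnostic marker (a configurable fraction of markers; default
  all), F1 are phase-known heterozygotes, and each F2 draws a maternal
  gamete on the female map and a paternal gamete on the male map.
* **Crossovers.** No interference: each inter-marker interval recombines
  independently with probability equal to the Kosambi inverse of its
  sex-specific cM span.  The mapping function fixes interval distances; it
  does not impose an interference model, and interval-wise recombination
  fractions are the testable contract (the recovery suite confirms them).
* **Maps.** Default: four chromosomes (50–62 Mb, 40–50 evenly spaced
  markers, 90–100 female cM), male map scaled to 0.6 of the female map
  (male fish maps are consistently shorter), the distal 10 % of each
  chromosome carrying 20 % of its cM (telomere-elevated recombination, as
  in fish linkage maps), and male recombination additionally suppressed
  5-fold in the terminal region of the sex chromosome.  All of it is
  configurable, including fully explicit per-marker cM maps.
* **Sex.** A penetrance table at one or two marker loci maps collapsed
  genotype classes (or joint two-locus classes) to P(male); draws are
  independent given genotype.  The default single locus near the distal
  telomere uses 1.0 / 0.16 / 0.0, the pattern observed at the mapped peak
  (all grandsire-homozygotes male, 84 % of heterozygotes female).
* **Reads.** Depth is negative-binomial (mean 30, dispersion 5 — the study
  reports a 20× criterion for map markers but no depth distribution, so
  these are chosen as RAD-typical), zeroed with a missingness probability
  (default 0.02), and counts are multinomial under the same error model the
  caller assumes, at ε_true = 0.01 (the true error rate of the original
  data is unknown; this default is flagged here deliberately).

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: read-level artefacts (PCR duplicates,
allele-specific bias, base-quality variation), model misspecification
between the generator and the caller, partially informative markers of an
outbred cross, genotyping error correlated across individuals, marker-order
error, and segregation distortion.  Power and calibration results are
therefore best-case for the statistical machinery, not claims about any
particular sequencing run.

## Problem sizes and determinism

The calibration studies run at the study's design point (82 males, 63
females): 200 replicates × 10,000 SNPs for FDR control under the null, 200
replicates × 500 unlinked markers × 1,000 permutations for threshold
type-I error, and 100 replicates each for locus detection/localization and
suppression recovery.  The permutation type-I criterion (5 % ± 2 % over 200
replicates) has ≈1.5 % Monte-Carlo standard error, so it is run from a
fixed master seed.  Every stochastic stage takes an explicit seed; the
pipeline derives one independent stream per stage from the master seed by
fixed spawn keys, so changing e.g. the permutation count never perturbs the
simulation draws, and repeated runs are byte-identical.

## Known limitations

* The LOD scan is single-marker; between sparse or partially missing
  markers it does not interpolate genotype probabilities, and its peak can
  differ from an interval-mapping peak by more than the declared budget
  when markers are far apart.
* The G-test relies on the asymptotic χ² tail; with few fish per genotype
  class the p-values are conservative rather than exact.
* The enrichment null is uniform placement only; no GC-, repeat- or
  gap-aware null models.
* Multi-allelic sites beyond the 10-genotype enumeration and base-quality
  aware likelihoods are out of scope.
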