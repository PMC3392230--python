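# radsexscan

Sex-association genome scans for F2 intercrosses genotyped from RAD-seq
read counts.

Many fish have no heteromorphic sex chromosomes, and gonadal sex in a cross
segregates like a partially penetrant binary trait.  Finding the genomic
regions associated with sex in an F2 intercross between two strains takes a
chain of statistics that this package implements as a tested, reusable
library for geneticists working with such crosses:

* **Genotype calling** from per-site nucleotide read counts by maximum
  likelihood under a multinomial read model, with the per-read sequencing
  error rate ε profiled over a bounded interval (default [0.001, 0.1]) and
  a χ²₁ likelihood-ratio test (α = 0.01) between the two best genotypes
  deciding whether to call at all.  The bound keeps heterozygotes with
  uneven read counts from being miscalled homozygous.
* **Per-SNP differentiation scan**: a G-test, G = 2·Σ O·ln(O/E), of the
  sexes-by-genotypes table at every SNP genotyped in ≥ 20 fish of each sex,
  with Benjamini–Hochberg q-values per family and a q < 0.001 significance
  line.
* **Binary-trait LOD scan** on phase-known four-way genotypes,
  LOD = log₁₀ of the maximized binomial likelihood ratio (per-class
  penetrance p̂_g = m_g/(m_g+f_g) vs pooled), with genome-wide 5 %/10 %
  thresholds from sex-label permutations and 1.5-LOD-drop support
  intervals.
* **Recombination-rate profiles**: sex-specific recombination fractions
  from gametic origin switches, Kosambi conversion
  d = 25·ln((1+2r)/(1−2r)) cM, and 3-marker sliding-window cM/Mb rates —
  the profile in which recombination suppression around a sex-determining
  region shows up.
* **Region enrichment** of genomic element classes: observed vs expected
  (n · region fraction) counts, percent-in-region, binomial upper-tail test.
* **A forward simulator** of the whole design — F0→F1→F2 pedigree with
  sex-specific maps, no-interference crossovers, penetrance-based sex at
  one or two loci, negative-binomial depth and multinomial read error — so
  every stage is testable without sequence data.

## Worked example

```python
import numpy as np
from radsexscan import SimulationConfig, run_sexscan, simulate_cross
from radsexscan.genotyper import call_matrix

config = SimulationConfig()          # 145 F2 fish, distal sex locus on chr4
sim = simulate_cross(config, np.random.default_rng(3))
calls, _ = call_matrix(sim.read_counts)
scan = run_sexscan(calls, sim.sample_sheet, family="A", min_per_sex=20, fdr=0.001)
print(scan.nsmallest(3, "p")[["marker_id", "chrom", "pos_bp", "G", "p", "q"]])
```

prints

```
 marker_id chrom   pos_bp          G            p            q
 chr4_m048  chr4 60760000 126.038857 4.275727e-28 7.268737e-26
 chr4_m047  chr4 59520000 104.581596 1.951618e-23 1.658876e-21
 chr4_m045  chr4 57040000 102.027256 6.999433e-23 3.966345e-21
```

The strongest differentiation between males and females sits exactly at the
simulated sex locus (chr4:60,760,000): G is the log-likelihood-ratio
statistic of the genotype-by-sex table and q its BH-adjusted p-value, far
below the 0.001 line.  On the published genotype-by-sex table at a real
chr-4 peak (70 C/C fish all male, 12 of 75 C/G male) the binary-trait
likelihood gives LOD 28.79:

```python
from radsexscan import binary_lod
lod, penetrance = binary_lod(["C/C"] * 70 + ["C/G"] * 75,
                             ["male"] * 70 + ["male"] * 12 + ["female"] * 63)
print(round(lod, 2), {k: round(v, 2) for k, v in penetrance.items()})
# 28.79 {'C/C': 1.0, 'C/G': 0.16}
```

The `examples/` directory has one short script per capability (simulation,
calling, both scans, recombination profiles, enrichment), each printing the
numbers it computes and what they mean.  A thin CLI wraps the same
functions: `radsexscan simulate|genotype|sexscan|qtl|haplo|recomb|enrich|run`,
e.g. `radsexscan run --seed 7 --out out/` for the full simulate→report
pipeline.

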