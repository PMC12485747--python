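# invstruct

Inference of complex structural haplotypes at an inversion +
segmental-duplication locus from short-read-derived data, modelled on
the human 17q21.31 region.

## The problem

The 17q21.31 locus carries a ~970 kb inversion polymorphism (the H1
and H2 orientation clades) flanked by segmental duplications,
including independent partial duplications of the *KANSL1* gene — the
β duplicon on H1 backgrounds and the α duplicon on H2 backgrounds —
and copy-number-variable *NSF* duplicons. Long-read assemblies resolve
these structures directly, but population-scale and ancient-DNA
cohorts are short-read: structure there must be inferred from proxy
signals. `invstruct` implements that inference as a tested, reusable
pipeline for anyone genotyping an inversion + duplication locus from
cohort VCFs and read-depth tracks:

1. **Inversion genotyping** (`invstruct.inversion`) — each sample's
   0/1/2 genotype vector over a panel of inversion tag SNPs is
   compared by Euclidean distance to the three expected vectors
   (all-0 = H1/H1, all-1 = H1/H2, all-2 = H2/H2); the argmin wins,
   with no-calls on missingness or exact ties.
2. **Duplication copy number** (`invstruct.depth`) — read depth
   averaged in 1,000 bp windows stepped by 100 bp, normalized to a
   copy-number-invariant control region; diploid CN = 2 × mean
   normalized depth over a duplicon's unique sector (summed over the
   two reference *NSF* regions), with QC caps (CN > 20 for *KANSL1*,
   > 50 for *NSF*) removing unrealistic samples.
3. **Complex genotypes** (`invstruct.complexgt`) — inversion call and
   α/β copy numbers are integrated against an expectation table over
   haplotype pairs; ambiguous copy-number configurations (e.g. β CN 4
   on H1/H1: β2/β2 vs β1/β3) resolve toward commoner haplotypes, and
   trios validate Mendelian consistency.
4. **Recombination scan** (`invstruct.recomb`) — PC1 of the local
   genotype matrix in non-overlapping 10 kb windows separates the
   three inversion genotypes; per-genotype 5–95% quantile envelopes,
   exclusion of overlapping-envelope windows, and reassignment of runs
   of ≥ 2 adjacent outlier windows expose tracts where a chromosome
   locally matches the opposite clade. Interior runs are double
   crossover / gene-conversion events; runs reaching the region edge
   are single events.
5. **Frequency trajectories** (`invstruct.trajectory`) — a multinomial
   logistic model of the four reportable haplotype categories (H1.β1,
   H1.β2+, H2.α1, H2.α2+) against sample age, `log(f_c/f_ref) = a_c +
   b_c·t` with t in kiloyears oriented toward the present, fitted by
   the package's own Newton solver; fold changes between times carry
   delta-method intervals.
6. **Structure clustering and dating** (`invstruct.structures`,
   `invstruct.trees`) — haplotypes as ordered, oriented block
   decompositions: singleton/short-block filtering, strand-invariant
   grouping into unique structures, length-weighted jaccard distances,
   neighbor joining, Robinson–Foulds matrices over windowed trees,
   LD-guided window selection against the duplication-proximal anchor
   window, and node-age calibration by fixed split times (orangutan
   18.13 mya, human–chimpanzee 7.74 mya).
7. **Synthetic cohorts** (`invstruct.simulate`) — a generator with
   known truth (haplotype pairs, sector copy numbers, implanted
   recombination tracts, time-stamped samples from a logit trajectory)
   emitting the standard formats the pipeline consumes, so every stage
   is testable end to end without external data.

## Worked example

Simulate a 200-sample cohort at the generator's default conditions
(modern-European-like haplotype frequencies, 500 tag SNPs with 1%
error, 30× coverage) and run the genotyping stages:

```python
import collections
import invstruct as iv
from invstruct.depth import DepthConfig, SectorDef, estimate_all, windows_from_table

cfg = iv.SimConfig(n_individuals=200, seed=1)
truth, tags, panel, depth, snps = iv.simulate_cohort(cfg)

calls = iv.genotype_inversion(tags)
print(dict(collections.Counter(c.genotype for c in calls)))

sectors = {n: SectorDef(n, ivl) for n, ivl in iv.default_sim_sectors().items()}
genotypes = []
for i, sid in enumerate(truth.sample_ids):
    ests = estimate_all(windows_from_table(depth[sid]), sectors, DepthConfig())
    genotypes.append(iv.integrate(calls[i], ests["alpha"], ests["beta"]))
print(dict(collections.Counter(
    l for g in genotypes if g.resolved for l in iv.simplify(g))))
```

prints

```
{'H1/H2': 82, 'H1/H1': 108, 'H2/H2': 10}
{'H1.β2+': 109, 'H2.α2+': 79, 'H1.β1': 189, 'H2.α1': 23}
```

— the cohort's inversion genotypes and the simplified haplotype counts
(400 haplotypes from 200 resolved individuals; against the generator's
truth this run recovers 100.0% of diploid genotypes). Fitting the
trajectory model to 600 aged haplotype observations simulated from a
duplication-set rise of 0.08 (12 kya) → 0.50 (today):

```
Haplotype trajectory: multinomial logistic regression
  observations (haplotypes): 600
  reference category:        H1.β1
  log-likelihood:            -574.7782
  converged:                 True

  category    intercept     (se)   slope/ky     (se)
  H1.β2+        -0.3347 (0.2483)     0.3435 (0.0558)
  H2.α1         -1.7910 (0.3136)     0.0502 (0.0457)
  H2.α2+        -0.7361 (0.2189)     0.1018 (0.0337)

KANSL1-duplication set fold change 12 kya -> today: 4.12 (95% CI 2.51-6.76)
```

Positive slopes (per kiloyear, toward the present) mean the category
has risen; here both *KANSL1*-duplication categories rise and their
combined frequency multiplies several-fold, with the sampling
uncertainty of a 600-haplotype cohort visible in the interval.

A command-line interface mirrors the library:
`invstruct simulate`, `genotype-inversion`, `copy-number`,
`complex-genotype`, `trio-check`, `scan-recomb`, `fit-trajectory`,
`cluster-structures`, `select-ld-windows`, `calibrate-tree`
(see `invstruct --help`).

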