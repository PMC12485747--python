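# Methods

This note documents the models and procedures `invstruct` implements,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Locus model and nomenclature

A structural haplotype is a triple: inversion clade (H1 direct, H2
inverted), extra copies of the clade-specific *KANSL1* duplicon (β on
H1, α on H2 — the β duplication occurs only on H1 backgrounds and α
only on H2), and per-haplotype *NSF* duplicon copies (reference
baseline 2). Labels follow the field's nomenclature: `H1.β2` carries
one extra β copy; an optional `.γk` suffix records non-reference *NSF*
content. Short reads cannot phase *NSF* duplications onto haplotypes,
so the reportable categories collapse to H1.β1, H1.β2+, H2.α1, H2.α2+
and *NSF* is reported only as a diploid copy number — a deliberate
limitation, not an omission.

Coordinates are 0-based half-open internally; VCF I/O is 1-based per
the standard.

## Inversion genotyping

Genotypes at the tag-SNP panel are coded 0/1/2 as alternate-allele
dosage, polarity-corrected per SNP so 2 always means two H2-tagging
alleles. Distances to the three expected vectors are computed per
sample over its non-missing sites only, against the expected vectors
restricted to those sites; this keeps distances comparable without
imputing. Defaults: `min_call_fraction = 0.5` (fewer usable sites →
no-call), exact distance ties → no-call. Distances are reported raw
and divided by √n for cross-sample QC; the margin (runner-up minus
best) supports confidence filtering.

## Copy number from read depth

Depth is averaged in 1,000 bp windows advanced by 100 bp, normalized
per sample to the mean of the control-region windows (a median option
exists for contamination robustness), and averaged over the windows of
each duplicon's unique sector; diploid CN = 2 × that mean, and the
*NSF* estimate sums the two reference regions before scaling (diploid
baseline 4). Integer calls round half away from zero (no rounding rule
is canonical; this one is symmetric and documented). QC caps default
to CN 20 for the *KANSL1* sectors and 50 for *NSF*.

Two deliberate choices:

- **Sector means use fully contained windows.** Windows straddling a
  sector boundary average sector and flanking copy number and bias the
  estimate toward 2 (up to −0.17 CN at true CN 6 with any-overlap
  inclusion); containment removes the bias at negligible cost in
  window count.
- **The control statistic is the mean across windows** (per-window
  means weight bases unevenly at gaps; with gap windows excluded the
  two readings coincide for complete coverage).

## Complex genotype integration

The expectation table is data, not code: for every unordered pair of
configured haplotype labels it lists the implied α CN, β CN and
inversion genotype (β CN = 2 + extra β copies across the pair, α
likewise, inversion genotype = H2 count). Integration selects, among
entries matching the inversion call, the pair minimizing the L1
distance between expected and observed integer CN calls; distance 0 is
high confidence, 1 low, > 1 unresolved (including copy numbers that
contradict the inversion call, which are flagged with a diagnostic).

Exact-distance ties resolve toward commoner haplotypes. The rarity
ranking orders each clade's series by extra-copy count (β1 > β2 > β3,
α1 > α2 > α3, the observed frequency order) and compares pairs by
(rarest member, rank sum): a pair avoiding any very rare haplotype
(β2/β2) beats one containing it (β1/β3) even when rank sums tie, which
is the assignment practitioners make at β CN 4 on an H1/H1 background.
Pairs are unordered; phase is never claimed.

## Recombination scan

Within windows where the H1 and H2 SNP pools are divergent, PC1 of the
centered genotype matrix (no variance standardization; switchable)
separates H1/H1, H1/H2 and H2/H2. Per window the PC1 sign is fixed by
requiring the H2/H2 group mean ≥ the H1/H1 group mean (heterozygotes
as fallback) — some explicit rule is mandatory for cross-window runs
to be meaningful, and this one also absorbs allele-coding flips.
Windows with < 3 variants, zero variance, or overlapping per-genotype
5–95% quantile envelopes are ambiguous and excluded.

Outlier assignment partitions PC1 space by the midpoints of the gaps
between adjacent group envelopes: a sample is an outlier in a window
only when it crosses into another group's slot. Merely exiting one's
own envelope cannot be the criterion — 10% of samples do so per window
by construction, which on a 200-sample, 36-window cohort would
manufacture ~17 spurious two-window runs, and conversely a genuinely
converted tract strays outside the *target* group's envelope in 10% of
windows, fragmenting true runs. Only maximal runs of ≥ 2 adjacent
outlier windows toward the same target are reassigned; runs may bridge
a single ambiguous window (logged). A run flanked on both sides by
usable windows is a double event (double crossover or long gene
conversion — the two are not distinguishable here); a run reaching the
analyzed region's boundary is single. Replacing manual curation with
these machine-readable filters makes the scan reproducible; the
per-event report (sample, interval, direction, class) remains
reviewable.

## Haplotype-frequency trajectories

Each resolved individual contributes two haplotype observations at its
sample age. The model is a multinomial logit, `log(f_c(t)/f_ref(t)) =
a_c + b_c t`, t in kiloyears oriented toward the present (t =
−age/1000, so positive slope = rising toward the present; the
covariate scale is a documented choice). Within-individual correlation
of the two observations is ignored — a simplification matching how
haplotype frequencies are plotted and counted. The fit is the
package's own Newton ascent with analytic gradient and Hessian and
step-halving, so the likelihood machinery is part of the tested
surface (cross-checked against statsmodels' MNLogit in the suite);
convergence at |Δ log L| < 1e-8 within 100 iterations, non-convergence
reported. A constant time covariate is collinear with the intercept;
it is dropped and slopes pinned at exactly 0. A category absent from
the data is held at frequency 0 (separation guard); a single observed
category raises a separation error. Standard errors come from the
observed information; fold changes between two times are ratios of
summed predicted frequencies with delta-method intervals on the log
ratio (denominators < 1e-6 report as unbounded).

## Structure clustering and trees

Block decompositions are filtered by a fitted two-stage rule: the
non-singleton block set and the length cutoff (the 0.25 quantile of
surviving block lengths, emulating a data-derived shortest-quartile
boundary) are resolved once from the cohort, then applied as a fixed
rule. Fitting once matters: a quantile recomputed from already
filtered blocks keeps tightening, so only the fitted transform is
idempotent.

Structures are grouped by the ordered sequence of (block id,
orientation), canonicalized as the lexicographic minimum of the
sequence and its reverse-complement so strand choice cannot split a
group. Unique structures are related by a length-weighted jaccard
distance, `1 − Σ w·min(c_A, c_B) / Σ w·max(c_A, c_B)` over block
copy counts with w the block's mean observed length — a self-contained
approximation of base-level graph similarity that ignores block order
(two structures sharing content but differing in arrangement appear
closer than a base-level graph would place them; grouping, which is
order-sensitive, happens first). Summary structures are an
average-linkage dendrogram cut at a configurable threshold.

Neighbor joining is implemented directly (Q-criterion, ties broken
toward the lowest original taxon-index pair, negative branch lengths
clamped to zero and logged) so the determinism contract is explicit;
the suite cross-checks topologies against scikit-bio and verifies
exact recovery of additive matrices. Robinson–Foulds distances
(unrooted symmetric difference of nontrivial bipartitions, polytomies
allowed) delegate to dendropy behind the module surface and are
verified against a brute-force bipartition oracle. LD-window selection
sorts windows by RF distance to the right-most (duplication-proximal)
anchor window, breaking ties toward the genomically nearer window.
Node ages scale linearly against a calibration clade's fixed age
(defaults 18.13 mya orangutan split, 7.74 mya human–chimpanzee split);
the tree is assumed approximately clock-like, with root-to-tip spread
beyond 10% logged as a warning. The RF-matrix ordination offered for
visualization is classical MDS.

## The synthetic cohort generator

The generator emulates exactly the signals the pipeline consumes, at a
compact scale (a 500 kb contig with the real locus's geometry: control
region, β/α sectors, two NSF sectors, inversion interior) so whole
cohorts simulate in seconds:

- haplotype pairs i.i.d. from configured frequencies (defaults emulate
  a present-day European cohort: H1.β1 0.45, H1.β2 0.29, H2.α1 0.05,
  H2.α2 0.21), or from the logit trajectory at each sample's age;
- tag genotypes equal to the H2 count, each haplotype allele flipping
  independently at the configured error rate (default 1%);
- windowed depth Poisson around coverage × CN/2 × window size
  (default 30×), control region CN 2 by construction;
- inversion-interior SNPs from two pools whose allele frequencies
  differ by the configured divergence (default 0.8; the real H1/H2
  divergence is not asserted anywhere and the parameter is free), with
  implanted tracts drawing from the donor clade's pool on exactly one
  haplotype;
- trajectory defaults in the tests and acceptance script follow a
  duplication-set rise from 0.08 at 12 kya to 0.50 today (6.25-fold).

Not emulated: read-level noise, mapping bias, GC effects, linkage
between neighbouring SNPs beyond pool membership, correlated depth
between overlapping windows, genotype imputation error structure.
Passing tests therefore demonstrate correctness of the *computations*
under the stated noise models, not robustness to every artifact of
real short-read data; the QC surfaces (margins, envelopes, caps,
confidence flags) are the intended handles for real-data noise.

## Problem sizes and numerics

The test suite and acceptance script use cohorts of 120–200
individuals, 500 tag SNPs, ~720 inversion SNPs (2/kb), 36 scan
windows, 100 trajectory replicates of 600 haplotypes, and 200 random
tree pairs of ≤ 7 leaves — sizes at which every stage's accuracy
statistics are stable while a full run completes in seconds. Seeds
derive from a single user seed; identical configuration is
byte-identical output. PCA uses deterministic SVD; the trajectory
solver's ascent property is asserted on every fit. The fold-change
estimator at n = 600 carries ±20–35% per-draw sampling noise around an
essentially unbiased center, so accuracy checks compare its replicate
median against the simulated truth.

## Known limitations

- The expectation table's decision boundaries are a reconstruction of
  standard integration logic and are configuration, not ground truth.
- Single events are only recognized when a run touches the analyzed
  region's boundary; events entirely inside an ambiguous stretch are
  invisible.
- The trajectory model pools populations by default and treats
  haplotypes as independent observations.
- The jaccard measure is block-level, not base-level; NSF phasing and
  γ-subtyping from short reads are out of scope by design.
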