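# Methods

## The selfing model

Everything is built on the two-locus genotype distribution of an F_k
single-seed-descent (SSD) line.  The F1 is fully heterozygous in coupling
phase (AB/ab).  One meiosis turns a diplotype (h1, h2) into gametes: the
parental haplotypes at (1−r)/2 each and the two recombinants at r/2 each,
where r ∈ [0, 0.5] is the per-meiosis recombination fraction.  Selfing is
iterated on the 16 ordered diplotype states for k−1 rounds and collapsed to
the nine two-locus genotype classes.  Checks that pin the implementation:

* one-locus marginals are (1−(1/2)^(k−1))/2, (1/2)^(k−1), … — exactly
  7/16 : 1/8 : 7/16 at F4 (verified in rational arithmetic);
* at k = 2 the recursion equals exhaustive gamete enumeration;
* as k → ∞ the recombinant-line frequency converges to the
  Haldane–Waddington value 2r/(1+2r), which is also the closed form used
  for fully inbred ("riself") populations.

The recombination fraction of a marker pair is the r maximising the
multinomial log-likelihood of its 9-class contingency table under this
model; the linkage LOD is log10 L(r̂) − log10 L(0.5).  Markers scored with
no heterozygote class in a non-inbred population (a common artefact of
two-cluster KASP scoring) keep a collapsed 2×3 likelihood (AA vs non-AA)
for rf estimation and are excluded from the distortion and estRF
translocation scans.  The matrix-level estimator maximises on an r grid of
step 0.001 (fully vectorised across all pairs); the scalar API refines by
golden section to 1e−6.  Both are exercised against each other in tests.

Per-meiosis r (not the F_k-inflated observed recombinant fraction) is
passed through Kosambi's map function, matching multipoint practice.

## Map construction

Grouping is single-linkage transitive closure over pairs with LOD ≥ 3.0
and r̂ ≤ 0.3 (both constraints; defaults configurable).  Ordering is greedy
seriation: seed with the smallest-r̂ pair, insert each remaining marker at
the SARF-minimising position (ties broken by marker name, then position,
for determinism), then progressive rippling with an exhaustive window of 3
(configurable) accepted only on strict SARF decrease — so the objective
never increases and terminates.  Positions are cumulative Kosambi
distances of adjacent r̂ (adjacent intervals are capped just below r = 0.5;
any such interval exceeds the split threshold and is cut anyway).  Groups
are split at adjacent gaps ≥ 35 cM (inclusive), fragments re-anchored at 0
and suffixed.  Chromosome labels are the majority of a-priori assignments,
re-derived per fragment.

Single-linkage at LOD 3 with ~300 markers and n ≈ 94 occasionally chains
two chromosomes through one borderline pair (the null exceedance of LOD 3
is ~1e−4 per pair).  This is left as-is: it is exactly the signal class the
mapped-translocation caller consumes, and distinguishing it from a real
rearrangement is that caller's job, not the grouper's.

## Consensus merging

Component groups for one chromosome are orientation-normalised first: any
group whose mean Spearman correlation of common-marker ranks against the
others is negative is reversed; groups sharing no markers are discarded
with a warning.  The merge is an L1 linear program over consensus
positions: for each component and each marker pair at most K intervals
apart, an order constraint x_j − x_i ≥ 0; the objective minimises
Σ w |(x_j − x_i) − d| over adjacent component pairs with equal total weight
per component (w = 1/#pairs), linearised with slack variables and solved
with HiGHS (`scipy.optimize.linprog`).  Contradictory order constraints —
cycles in the union order graph — are removed greedily by lowest support
(number of component maps backing the edge) before solving; exact minimum
feedback sets are NP-hard and not attempted.  Candidates for K = 1, 2, 3
are scored by per-component RMSE after a least-squares affine rescaling of
the component onto the consensus; the lowest mean RMSE wins, ties broken
by lower SD then lower K.  Ties in consensus position are ordered by the
topological order of the surviving constraint graph, then by name.

## Map comparison

The marker-distance ratio compares a biparental group to the consensus on
their common markers only: MD = (span of common markers)/(n_common − 1) on
each map's own scale and MDR = MD_bip/MD_cons.  Zero-length biparental
groups are excluded; a zero consensus span with positive biparental span
is recorded as infinite and kept out of the fences.  Outliers per
chromosome use Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) with quantiles by
linear interpolation (type 7) — the method matters because fence
membership can flip with it, so it is fixed and documented.  "Expanded"
groups are high outliers with ≥ 6 common markers.

Order agreement is Spearman's ρs on common-marker ranks; groups with
< 7 common markers are "insufficient".  Classification uses |ρs| because
orientation is normalised upstream — a pure reversal is a flip, not a
rearrangement: |ρs| ≤ 0.6 incongruent, (0.6, 0.7] near-incongruent, else
congruent.  The boundary assignment at exactly 0.6/0.7 is a package
decision.

## Imputation and segregation distortion

Imputation is a three-state forward–backward pass per individual along
each mapped group: initial probabilities are the generation-k marginals;
transitions are conditionals of the two-locus distribution at the
adjacent-interval r (from inverse Kosambi); emissions give 1−ε to the
observed state (ε = 1e−4 by default), uniform for missing.  Hard calls are
max-marginal; below a 0.95 posterior floor the call is left missing
(configurable).  A caveat the tests document: with ε = 1e−4 the F4 chain
assigns an isolated flip between 1 cM flanks substantial probability of
being a real double junction (the O(r) junction path beats the 5e−5 error
emission), so such calls are blanked rather than corrected; a realistic
ε ≈ 0.01 corrects them.

The distortion scan is a per-marker χ² goodness-of-fit of hard-call counts
against the generation expectation (df = 2; fully inbred populations test
AA:BB = 1:1, df = 1), BH-adjusted within the population, significant at
adjusted p < 0.05.  Direction comes from the homozygote counts only.
Population-level QC flags a population whose mean reference-parent
homozygote ratio is ≥ 0.54 or whose other-parent ratio is ≤ 0.37; flagged
populations stay in per-population tables but leave the panel aggregates.
Hotspots are counted per marker and per 10 cM consensus bin (binning added
for sparse-marker robustness; both are reported).

## Translocations

Mapped calls: markers whose a-priori chromosome differs from their group's
majority produce one call per (population, chromosome pair); one minority
marker suffices by default (configurable); reciprocal when the
mirror-image conflict exists.  estRF calls: marker pairs on different
chromosomes with LOD strictly above 7.0, aggregated per chromosome pair
with the max LOD; an optional stricter screening threshold (LOD 10)
supports a two-stage workflow — both thresholds are exposed because both
appear in practice and the package does not adjudicate between them.
Methods merge by union on (population, chromosome pair).  Type enrichment
across ancestral groups uses χ² on the carrier/non-carrier × group table;
with any expected cell < 5 a seeded Monte-Carlo permutation p (10⁴ draws)
is reported alongside the asymptotic one.

## Crossover QTL

The trait is the obligate crossover count: along each mapped group, the
sum over consecutive non-missing calls of |g_{t+1} − g_t| (AA↔BB counts
2, the intercross convention).  It is a lower bound on the true junction
count, exact in the dense-marker noiseless limit (a property the tests
verify against simulator truth).  The scan regresses the trait on expected
additive dosage P(BB) − P(AA) from the imputation posteriors
(Haley–Knott); LOD = (n/2) log10(RSS0/RSS1).  Putative QTL are local
maxima with LOD ≥ 2.0, support intervals by 1.5-LOD drop, overlapping
peaks collapsed to the strongest.  The multiple-QTL model fits all
putative dosages jointly and retains peaks whose drop-one LOD clears a
threshold: a seeded permutation 95th percentile of genome-wide max LODs
when requested, else the fixed 2.0 — both selection rules are available
because neither is canonical.  Common QTL are maximal consensus-marker
runs covered by support intervals from ≥ 4 populations.

## The synthetic panel generator

The generator emulates an SSD NAM panel: biallelic founders, F1
heterozygous everywhere, per-chromosome crossover counts Poisson with mean
length/100 (Haldane — no interference), uniform crossover positions,
exactly one offspring per line per generation, k−1 meioses to F_k (fully
inbred lines run 25 rounds, residual heterozygous sites — frequency
~6e−8 — resolved by a fair coin).  Observation noise is independent
per-call dropout and uniform miscalls.  The default wheat-like layout has
21 chromosomes (1A–7D), 8–31 markers on A/B chromosomes, 2–8 on the
sparse D genome, lengths 80–160 cM.

Design choices worth stating:

* **No interference** in simulation although maps use Kosambi.
  Parameter-recovery tests therefore compare recombination fractions (or
  marker orders), not cM, and estimated maps are not expected to equal
  true lengths.
* **Structural variants rearrange the population's physical marker
  layout**: markers in a translocated or inverted segment segregate at
  their new location for the whole population while keeping their original
  a-priori assignment.  This produces exactly the detection signature
  (assignment conflicts, inter-chromosome linkage, reversed local order)
  without modelling meiotic pairing in heterozygotes; unbalanced-gamete
  loss can only be imposed through the selection spec.
* **SDL selection is zygote viability**: offspring survive with
  probability w(genotype)/max(w) at each SDL each generation, by rejection
  sampling (an error is raised if 1000 consecutive offspring are
  rejected).
* **The crossover modifier adds its effect to every chromosome's Poisson
  mean per copy of the non-reference allele**, using the parent's genotype
  at each meiosis.  The realised additive effect on the measured trait is
  smaller than the meiotic boost because early-generation crossovers are
  only partly correlated with the line's final genotype and sparse markers
  miss junctions.
* The truth record (true layout, pre-noise genotypes, realised junction
  counts, variant/SDL/modifier positions) is serialised with the
  genotypes so downstream tests never re-derive truth.

What the generator does not emulate: crossover interference, segregation
of heterozygous rearrangements (pairing loops, gamete loss), genotyping
batch effects, marker ascertainment bias, residual heterozygosity
structure in real F4 seed lots.  Passing tests therefore demonstrate the
estimators' correctness under the stated model, not robustness to every
artefact of real array data.

## Study conditions of the stochastic acceptance checks

Problem sizes were chosen so each check isolates one property at
desk scale:

* rf recovery: 500 two-marker F4 populations, n = 94, true per-meiosis
  r = 0.1 (markers placed at the Haldane distance).
* Map reconstruction: one noiseless panel, 5 chromosomes × 12 markers
  (110 cM), n = 500.
* Incongruence power: 100 noiseless replicates, 12 markers on one
  chromosome, inversion spanning the central 8 markers, n = 94.  (Note:
  reversing a block of m of n markers gives ρs = 1 − 2m(m²−1)/(n(n²−1));
  reversing exactly half of 12 markers yields ρs ≈ 0.755, which is still
  "congruent", so a detectable inversion must span about two-thirds of the
  markers — the chosen 8/12.)
* Distortion calibration: 80 neutral F4 panels of 21 × 6 markers
  (> 10⁴ marker tests, raw type-I within 0.05 ± 0.01 despite residual
  within-chromosome correlation); power: 200 replicates of an SDL with
  weights 1 : 1 : 0.4 at n = 94.
* Translocations: 100 replicates of a reciprocal 30 cM exchange in a
  3 × 10-marker genome (detection) and 100 null panels of 21 sparse
  chromosomes (specificity) at n = 94.
* Crossover QTL: 5 chromosomes × 12 markers over 40 cM, n = 94,
  modifier effect +2 per chromosome per allele copy.  The short, densely
  marked chromosomes keep the obligate count close to the true junction
  count (power) while limiting the effective number of independent tests,
  so the fixed genome-wide LOD 2.0 threshold keeps its type-I rate
  (~8–10% per genome scan) — with long sparse chromosomes the same
  threshold exceeds 10% and the same modifier is often missed.

## Numerical notes

* Golden-section tolerance 1e−6 on r (scalar path); grid step 1e−3
  (matrix path); observed-zero classes contribute zero to the likelihood
  even where the model probability vanishes.
* The LP uses sparse constraint matrices; positions are anchored by
  subtracting the minimum, and consensus positions are made monotone by a
  cumulative maximum (guards ~1e−12 solver slack).
* Seriation insertion and rippling tie-breaks are deterministic (marker
  name, then position); maps are invariant under individual permutation
  and marker relabelling.
* All stochastic stages consume a numpy `default_rng` seeded from the
  configuration; a panel-level seed fans out per population
  deterministically.

## Known limitations

* Two-point maps only — no multipoint EM refinement of orders; ordering
  quality at n ≈ 94 with > 25 markers per group depends on rippling and
  can leave local inversions.
* Single-linkage grouping can chain chromosomes through one borderline
  pair at panel scale (see above); downstream callers, not the grouper,
  disambiguate.
* The consensus conflict resolution is a greedy heuristic; pathological
  cyclic inputs may remove more constraints than the minimum.
* χ² distortion tests at n = 94 have limited power for mild distortion,
  and BH is applied within population only, as is conventional.
* The crossover trait undercounts junctions at realistic marker density;
  QTL effect sizes are attenuated accordingly.
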