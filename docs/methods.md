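# Methods

## The model

A time-ordered gene co-expression network (TO-GCN) organizes the TFs
of a developmental time course into levels whose expression peaks tile
the time axis. The package's working assumptions are those of the
underlying method: (i) regulation is reflected in co-expression with a
roughly one-stage lag, so a regulator and its targets are strongly
positively correlated over stage means; (ii) the cascade is anchored
by a seed TF maximally expressed at the first stage with monotone
decline; (iii) level in the breadth-first layering of the positive
TF–TF graph is a proxy for regulatory depth, so biologically plausible
regulator chains have strictly increasing levels; and (iv) predicted
promoter binding sites are an independent line of evidence that
filters co-expression-compatible chains down to plausible ones.

Correlations are computed on stage means (replicates collapsed by
arithmetic mean), because the network is time-ordered over stages and
per-replicate variation is nuisance at that resolution. Negative
edges (below the negative cutoff) are recorded and exported but do not
drive leveling; with a single seed they would conflate
opposite-phase programs.

## Differential expression

The NB Wald test is intentionally transparent rather than a DESeq2
re-implementation: median-of-ratios size factors; per-gene
method-of-moments dispersion (variance = μ + αμ²) pooled across the
two groups; per-gene α floored at the matrix-wide mean α (dispersion
moderation — with 2–3 replicates the raw moment estimator
underestimates variance often enough that an unmoderated Wald test is
grossly anti-conservative); log2 fold change of normalized group means
with a 0.5 pseudocount; Wald statistic referred to a t distribution
with `nA + nB − 2 + 4` degrees of freedom, the extra 4 a moderation
credit for the pooled prior. On 20 null simulations of 2,000 genes
(dispersion 0.1, 3 vs 3 replicates) this yields zero BH discoveries at
FDR 0.05 while detecting a planted 4-fold change at dispersion 0.01
with ~99% power — adequate for building a DEG universe, though the
fold-change-shrinkage and outlier handling of dedicated DE packages
are out of scope. "Between any two time points" means all unordered
stage pairs. BH adjustment is the standard step-up procedure
(statsmodels backend).

## The synthetic cascade generator

The generator emulates what the method exploits in real data, with
planted ground truth for every downstream claim.

**Level profiles.** Simple shifted unimodal bumps cannot reproduce a
TO-GCN's correlation structure over five mean-centered stages: two
bumps one stage apart have Pearson r ≲ 0.4, and any profile family
with adjacent-level correlation r₁ forces level-gap-2 correlation
≥ 2r₁² − 1 (spherical geometry), so "adjacent ≈ 0.85, gap-2 small" is
unattainable. The designer therefore targets a *wide-separation*
geometry: adjacent-level correlation ≈ 0.55 (the seed→level-2 link
tightened to ≈ 0.75 because the first breadth-first hop has no
redundancy against the seed's own count noise) and non-adjacent
correlation ≤ −0.3. Profiles are found numerically: geodesic
initialization in centered-profile space, then a penalized L-BFGS fit
enforcing, on the min–max scale the count means live on, a dominant
peak per level (margin 0.30), steep rising edges (the stage before the
peak ≤ 0.5 of span; ≤ 0.35 for level 2), a strictly decreasing
first-stage-spike seed (first stage ≥ 0.85 of the centered-unit-norm
profile, second stage ≤ 0.45 of span), and the correlation targets.
The construction is deterministic and validated at build time (peak
stages must be non-decreasing, the seed strictly decreasing).

**Genes.** Level 1 holds only the seed TF(s): with a single
breadth-first seed, any other first-stage-peaked TF would necessarily
be assigned level 2, so a populated level 1 would be internally
inconsistent. Levels 2..L hold `tfs_per_level` TFs and
`structural_per_level` enzyme genes each; per-gene profiles are small
random rotations (0.04 rad) of the level shape, affinely mapped to
[baseline, baseline × peak_fold] (defaults 50, 8) with a log-normal
per-gene magnitude. A large stage-flat background (2,500 genes,
log-normal magnitudes, σ = 1) keeps per-sample totals stable so TPM
normalization does not couple the cascade genes — with a small
background, library-composition shifts across stages distort every
correlation.

**Regulatory truth.** The seed parents every level-2 TF; each deeper
TF has one planted parent in the level above; each enzyme one planted
same-level driver. One level-2 TF is a *hub*: it parents a
configurable share of level-3 TFs (default 0.7) and directly drives a
share of level-2 enzymes (default 0.3) — regulatory out-degree in real
GRNs is heavy-tailed, and master regulators drive enzyme batteries
directly. The designated focal order-3 chain runs seed → hub →
level-3 TF → enzyme; its root, the most upstream regulator, is what
top-regulator ranking should recover. Binding sites are exactly the
planted edges plus decoys drawn uniformly from non-planted TF→gene
pairs; `decoy_site_rate` is the contamination fraction of the final
table (promoter scans report false positives at a rate relative to
their output, not to all possible pairs), and decoys never coincide
with planted pairs so validation precision is measurable.

**Noise.** Counts are NB with variance μ + αμ² (α = 0.1 by default,
Poisson at α = 0), per-sample log-normal library factors (CV 0.1).
Planted DE sets are defined from the noiseless means at |log2FC| ≥ 1.

**Matched analysis cutoffs.** The published correlation cutoffs
(0.8/0.85) belong to the real datasets they were calibrated on and
remain the `PipelineConfig` defaults. For a simulated cascade the
discriminative cutoff lies between the designed adjacent-level
correlation and the (negative) non-adjacent ceiling;
`CascadeParams.analysis_config()` places it at 0.4 × adjacent_r
(≈ 0.22) — below the midpoint because measured correlations attenuate
under count noise, and a missed planted edge (which strands or shifts
whole downstream strata in the breadth-first leveling) costs more than
a spurious one, which the wide separation makes vanishingly rare.

**What passing tests do and do not show.** The generator reproduces
staged bump profiles, NB noise, library-size variation, background
compositional stability, decoy-contaminated binding sites and
multi-megabase genomic enzyme clusters. It does not emulate
replicate-level batch effects, correlated gene-gene noise,
isoform-level signal, unbalanced designs, or the annotation noise of
real TF/enzyme catalogs; recovery rates measured here are upper bounds
on what identically configured real data would give.

## Numerical and design choices

- Seed selection z-scores use the population standard deviation of the
  TF's own stage profile; monotonicity tolerates per-step increases up
  to 30% of the profile's dynamic range (replicate noise produces
  transient bounces even in genuinely declining profiles), and
  `build_togcn` escalates the tolerance once before giving up.
  Deterministic tie-break by gene id.
- Constant-profile genes are excluded from correlation (undefined r)
  rather than assigned 0.
- Structural attachment takes the maximum-r supporting TF, ties broken
  by TF id; all supporting edges are retained in exports.
- Chain enumeration is exact depth-limited search over level-increasing
  paths with a per-network adjacency cache; ordering is deterministic
  (root id, then path). `--adjacent-only` restricts hops to exactly one
  level; the default allows any level gap, since the published chains
  span levels 3–6 for targets attached at level 6.
- Permutation calibration of cutoffs (opt-in) shuffles each gene's
  stage order independently; with very few stages the null is coarse
  and the fixed cutoffs are the fallback.
- The run manifest contains config, seed, input and output digests but
  no timings (those go to `run.log`), so identical config + inputs +
  seed reproduce it byte for byte.
- Cluster detection measures gaps between successive gene starts;
  defaults 2 Mb / 3 genes reflect the loosely linked multi-megabase
  clusters reported for this pathway, and the output is descriptive —
  no significance test is attached.
- Enrichment requires the study set to be contained in the universe and
  intersects terms with the universe; no GO-DAG propagation.

## Problem sizes

The default simulated study is 5 stages × 3 replicates, 5 levels,
10 TFs and 40 enzymes per downstream level, 2,500 background genes
(2,701 genes total). Acceptance-style checks use 20 random 50 × 6
matrices for the correlation oracle, every hypergeometric instance up
to N = 15, 100 random ≤ 12-node graphs for chain enumeration, 10
simulation seeds for regulator-ranking recovery and 20 null
simulations of 2,000 genes for FDR control.

## Known limitations

- Level assignment is only as good as the seed: a wrong seed shifts
  strata wholesale. The first-stage-spike design makes this rare in
  simulation but real courses may lack so clean an anchor.
- With five stages, single-gene profile corruption (a ~2σ joint swing
  on two stages) occasionally misplaces individual TFs or enzymes;
  recovery targets are met in distribution, not per gene.
- The NB test does not shrink fold changes; near-threshold |log2FC|
  decisions are noisy at 2–3 replicates.
- Cross-tissue comparative network classes (shared/condition-specific
  edge types) are out of scope; tissues are analyzed independently.
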