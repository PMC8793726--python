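# Methods

## Distances on the genetic map

Genetic position is estimated from Marey maps: per-chromosome marker tables
of cumulative genetic position (cM) against physical position (bp). The
package interpolates **piecewise-linearly** between flanking markers — the
standard local Marey-map estimate — and converts to Morgans at the API
boundary (cM only ever appears in files). Positions outside the marker range
**clamp** to the terminal marker's genetic value rather than extrapolate,
which avoids manufacturing negative or runaway recombination rates at
telomeres.

Real maps are noisy and occasionally dip; markers whose genetic values
decrease are repaired by isotonic regression (pool-adjacent-violators, L2
projection onto non-decreasing series), with the number of adjusted markers
logged. Duplicate physical positions are an error, not repaired.
Chromosomes with fewer than two markers are flagged *unmapped*.

The pairwise distance between two loci uses the floor midpoint of each gene
span (strand-free; files are 1-based inclusive, internally 0-based
half-open, converted once in `genome_io`):

* different chromosomes → exactly **0.5 Morgans**, the unlinked convention;
* same mapped chromosome → |Δ genetic position|, by default **uncapped**
  (intrachromosomal distances above 0.5 M are possible on long chromosomes
  and are reported as computed; `cap_half=True` clips them to 0.5 so intra-
  and interchromosomal distances share a ceiling);
* same unmapped chromosome → **0**, with a warning: a chromosome without a
  usable map is treated as non-recombining (the natural reading for dot-like
  chromosomes), and the warning surfaces the assumption.

## Statistics and scope

* **X1** — count of (X-linked parent, retrogene on another chromosome)
  pairs, over surviving retrogenes. The out-of-the-X excess is a
  well-replicated pattern, so X1 doubles as a data-quality check: a dataset
  that fails to show it is suspect.
* **X2** — mean of dist(parent, retrogene) over retrogenes; every retrogene
  weighted equally; n is the retrogene count in scope.
* **X3, reported as μ̂** — mean over parental genes of the per-parent mean
  distance to its retrocopy set C. Parents differ widely in how many copies
  they spawn; two-level averaging removes that weight. By default C holds
  surviving retrogenes only (`include_pseudogenes=True` widens it to all
  retrocopies); parents whose C is empty drop out of the average.
* **X4, reported as μ̂** — per retrogene, the minimum distance over
  {parental gene} ∪ {located network partners of the parent}; averaged over
  retrogenes. Network edges are symmetrized (direction discarded, self-edges
  and duplicates removed) since partner databases mix direction conventions.
  Partners without coordinates are excluded with a logged count; the set can
  never empty because the parent is always a member, so X4 ≤ dist(retrogene,
  parent) identically.

X2–X4 are computed **after the out-of-the-X filter**: every X-linked
parental gene leaves the table together with its whole retrocopy group, so
the linkage question is asked on strictly autosomal parents and is not
confounded by the X1 effect. The filter is idempotent, and X1 after
filtering is identically zero.

## Monte Carlo nulls and the p-value

All nulls embody the same hypothesis: retrogene insertion points are i.i.d.
uniform over the genome — a chromosome drawn with probability proportional
to physical length, then a base uniform within it — independent of parental
location. (Resampling observed pseudogene positions instead was considered
and rejected as a null: the observed pseudogene distribution need not
reflect the insertion distribution, and is approximately uniform anyway.)
Per statistic:

* **X1**: n independent uniform (parent, retrogene) point pairs per
  realization; the out-of-the-X count is recorded. Its null mean follows
  the binomial closed form n·p_X·(1−p_X), used as an analytic oracle in the
  tests.
* **X2**: n independent pairs; parents are drawn from **autosomes only** by
  default, matching the post-filter scope of the observed statistic
  (`parent_restrict="all"` is available); retrogenes genome-wide. On
  uniform maps the null mean has the closed form
  P(diff chrom)·0.5 + Σᵢ wᵢ²·Gᵢ/3, the second analytic oracle.
* **X3**: preserves the empirical multiset of group sizes |C| — the
  heterogeneity the statistic exists to correct for — drawing one parent
  per group and |C| genome-wide retrocopies. X2 is implemented as the
  all-groups-of-size-one special case of this sampler, so the advertised
  reduction is an exact sample-for-sample identity.
* **X4**: default `fixed-partners` mode keeps the empirical parent/partner
  coordinates fixed and redraws only retrogene positions — the minimal
  permutation consistent with the hypothesis, since the network geometry is
  not what is being tested. A `random-partners` mode that redraws candidate
  sets of matching size each realization is provided; pooling fixed-mode
  runs over fresh candidate configurations reproduces the random-mode
  distribution exactly, which the test suite verifies by KS.

Default iteration count is 1,000, configurable.

The p-value is the **two-tailed add-one permutation estimator**
p = min(1, 2·min(#{s ≤ obs}+1, #{s ≥ obs}+1)/(N+1)). It can never return 0
from a finite null sample; its floor at N = 1000 is 2/1001 ≈ 0.002. Under
exchangeability P(p ≤ t) ≤ t at every attainable level, which yields the
nominal type-I error the acceptance suite measures.

Reproducibility: one root seed; each test derives an independent child
stream from it deterministically (recorded in the result), so identical
seed + config + inputs give bit-identical null samples and p-values.

## Synthetic data generator

The generator emulates the *structure* of a curated retrocopy dataset —
multi-chromosome genome with one X, monotone Marey maps, parent→retrocopy
multiplicities, sparse parent–partner networks — with a controllable
survival mechanism. Default scenario: **five 100 Mb chromosomes at a
uniform 1 cM/Mb** (1 Morgan each, so interchromosomal pairs dominate the
distance mixture as they do in real genomes), **60 parental genes**,
**Poisson(1.4) retrocopies per parent** (~84 copies, matching the scale of
the smaller of the two empirical datasets the analysis is aimed at), ~2
partners per parent, gene spans of 1 kb. Retrocopy counts and partner
counts are Poisson when given as floats, exact when given as ints.

Each retrocopy is placed uniformly and survives with probability

    logistic(β₀ + β_X·1[parent on X ∧ copy autosomal] + β_d·dist(parent, copy))

with β_d in Morgans⁻¹. This is the simplest mechanism that embodies
"selection on linkage" and the out-of-the-X bonus; it is a testbed for the
statistical machinery, not a fitted model of retrogene biology. Presets:

* `null` — β_X = β_d = 0, β₀ = 8 (survival ≈ 1), parents autosomes-only so
  the out-of-the-X filter is a no-op and the X2 calibration runs at full n;
* `out_of_x` — β₀ = −2, β_X = 5, Poisson(3) copies: survivors are dominated
  by X→autosome copies (expected standardized X1 excess ≈ 8σ);
* `linkage` — β₀ = 1, β_d = −8, 100 parents × Poisson(5): survival falls
  from ~0.73 at zero distance to ~0.05 for unlinked copies, pushing X2 into
  the null's lower tail (expected ≈ 5σ).

What the generator does **not** emulate: real recombination landscapes
(hotspots, sex-averaged map nonlinearity), chromosome size heterogeneity,
curation biases of retrocopy databases, network topology beyond a
parent-star, or gene clustering. Passing tests therefore demonstrate that
the machinery is calibrated and can recover planted effects of the assumed
form — not that any empirical dataset does or does not show such effects.

## Numerical and design choices

* Distances are exact floating-point linear interpolation; no smoothing
  (loess/spline Marey fits are deliberately out of scope, as are
  sex-specific maps).
* Ties in the X4 minimum need no breaking — only the minimum value enters.
* Degenerate inputs fail loudly: empty retrogene scope, no parent with a
  non-empty C, an assembly without an X where one is required, NaN observed
  statistics, and non-finite null samples are all hard errors rather than
  silent NaNs.
* Missing data policy is drop-and-log throughout the readers; nothing is
  imputed.
* Problem sizes in the test and acceptance runs (400 null datasets of ~84
  retrogenes × 1,000 iterations; 100 and 3×60 planted-effect replicates)
  were chosen so the whole battery completes in well under a minute while
  keeping the binomial acceptance bands tight enough to be meaningful.

## Known limitations

* The X2/X3 nulls draw a fresh parent per pair/group, while the observed
  statistics reuse empirical parents across retrogenes of one parent; under
  the null this mismatch only perturbs higher moments, and its effect on
  the measured type-I error is negligible at the default group-size
  distribution, but it is not exactly a permutation of the observed data.
* The two-tailed p is the doubled-smaller-tail estimator; for markedly
  skewed nulls (e.g. X1 with a tiny X chromosome) other two-tailed
  definitions exist and would differ.
* One genetic map per genome: no sex-specific maps, no uncertainty in the
  map itself is propagated.
* `random-partners` mode redraws partner positions independently and
  uniformly, which ignores any clustering of real regulatory partners.
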