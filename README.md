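# retrolink

Monte Carlo permutation tests for the question: **is retrogene survival
associated with changes in genetic linkage?**

Retrocopies arise when a reverse-transcribed mRNA reinserts somewhere in the
genome; most decay into pseudogenes, but some survive as functional
*retrogenes*. Because reinsertion rewires the linkage relationships of the
parental gene — to itself and to its regulatory-network partners — selection
on linkage is a candidate force in retrocopy survival. `retrolink` tests this
by comparing observed genetic-map distances of surviving retrogenes against
reference distributions built under the null that retrogenes are placed
i.i.d. uniformly over the genome, independent of parental location. It is a
library for statistical geneticists and genome-evolution researchers, with a
thin `retrolink` command line over the same functions.

## The statistics

With `dist(a, b)` the genetic distance in Morgans between the midpoints of
two loci — interpolated from per-chromosome Marey maps for intrachromosomal
pairs, and fixed at **0.5 Morgans** for interchromosomal (unlinked) pairs —
the package computes:

* **X1** = #{pairs with the parental gene on the X and the retrogene on a
  different chromosome} — the classic *out-of-the-X* excess, used as a
  data-quality check;
* **X2** = (1/n) Σ_b dist(a, b) over retrogenes *b* with parents *a* — the
  mean parent–retrogene distance, each retrogene weighted equally;
* **X3 (μ̂)** = mean over parental genes of the within-parent mean
  Σ_{x∈C} dist(a, x)/|C|, where C is the parent's retrocopy set — corrects
  for parents that spawned many copies;
* **X4 (μ̂)** = mean over retrogenes of min_{x∈C} dist(a, x), where C is
  {parental gene} ∪ {its network partners} — distance to the nearest member
  of the parent's regulatory neighbourhood.

X2–X4 are computed after removing all X-linked parental genes and their
retrocopies, so the linkage question is asked on strictly autosomal parents.
Each observed value is compared against 1,000 Monte Carlo realizations with a
two-tailed empirical p-value (add-one estimator, α = 0.05 by default).

## Worked example

```bash
python examples/02_simulate_and_test.py
```

generates a synthetic genome (five 100 Mb chromosomes at 1 cM/Mb, one X),
60 parental genes with Poisson retrocopy counts and a sparse partner
network, survival independent of placement, and runs all four tests:

```
scenario: 60 parents, 86 retrocopies, 86 retrogenes, 111 network edges
       X1: observed  18.0000  null mean  13.5790  p = 0.2438  [keep null]
       X2: observed   0.4368  null mean   0.4661  p = 0.0879  [keep null]
X3_mu_hat: observed   0.4434  null mean   0.4657  p = 0.2557  [keep null]
X4_mu_hat: observed   0.3617  null mean   0.3875  p = 0.1998  [keep null]
```

X1 is a pair count; X2–X4 are Morgans. All four observed values sit inside
their uniform-placement reference distributions, as they should under this
scenario. `examples/03_planted_effects.py` shows the converse: with a strong
X→autosome survival bonus the X1 test rejects (observed 18 of 34 pairs vs a
null mean of 5.4, p = 0.002), and with survival decaying in distance the X2
test rejects in the lower tail (0.281 M observed vs 0.466 M null mean,
p = 0.002).

The same pipeline is available from the shell:

```bash
retrolink simulate --preset linkage --seed 3 --out scenario/
retrolink test --which x2 --iterations 1000 --seed 3 \
    --assembly scenario/assembly.tsv --map scenario/marey.tsv \
    --parents scenario/parents.tsv --retro scenario/retrocopies.tsv \
    --out x2_result.json
```

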