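# Methods

This note documents the statistical model behind `elevagrad`, the
conventions and numerical choices it fixes, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Diversity metrics

**Taxonomic indices.**  For a plot with abundances *fᵢ* and proportions
*pᵢ = fᵢ/Σf*: Shannon–Weaver H′ = −Σ pᵢ ln pᵢ uses the natural
logarithm (the vegan convention; H′ is in nats, bounded by ln S);
Simpson's dominance is the inverse Simpson index D₂ = 1/Σpᵢ², the
effective number of equally common species in [1, S]; evenness
E = D₂/S ∈ (0, 1].  Species with zero abundance in a plot contribute to
the pool but not to pᵢ.  All three are invariant to multiplying every
abundance by a constant.  Report output is rounded to two decimals,
half-up, matching the print convention of field survey tables;
library functions always return unrounded values.

**Faith's PD** is the total branch length of the minimal subtree
spanning the species present.  Whether the path from the assemblage MRCA
up to the tree root counts is a genuine convention choice; `elevagrad`
includes it by default (`include_root=True`), the common convention for
rooted barcode phylogenies with an outgroup, under which a single-species
plot retains a positive PD.  The switch is exposed everywhere because the
exclusive (no-root) form is also in circulation.  Implementation: tips are
rows of a boolean tip × edge incidence matrix; PD is the length-sum of
edges ancestral to ≥ 1 present tip, and the root-ward correction is the
length-sum of edges ancestral to *all* present tips, which makes the
metric O(edges) per evaluation and fast enough to re-score thousands of
label permutations.

**Abundance-weighted MPD and MNTD.**  MPD is the weighted mean patristic
distance over ordered heterospecific pairs (weights fᵢfⱼ, self-pairs
excluded).  MNTD averages each species' distance to its nearest
heterospecific neighbour.  For MNTD the weighted *mean* (denominator
Σfᵢ) is the default, because it is the form that is invariant to
rescaling all abundances and reduces to the unweighted MNTD at equal
abundances.  A literal variant that divides the frequency-weighted sum by
the species count n (`denominator="as_printed_n"`) is retained behind a
flag for auditing analyses that used that formula; it is not a weighted
mean and changes scale with total abundance.  Both metrics are undefined
below two species and are reported as missing with a `singleton` flag.
Conspecific zero distances never enter the MNTD minima.

## Null model and standardized effect sizes

The null randomizes the *names* of species across all tips of the
analysis phylogeny — the full pool after any taxon exclusion, not just
the species of one plot — and leaves the community matrix untouched, so
richness, occupancy and the abundance distribution are all conditioned
on.  With 999 replicates (the default; tests and the acceptance script
use 199 as their chosen problem size),

* SES = (obs − mean(null)) / sd(null), with sd the sample (n − 1)
  standard deviation;
* obs.p = (#{null < obs} + ½ #{null = obs} + 1) / (reps + 1), an
  add-one rank with ties split at half weight.  The rule keeps obs.p
  strictly positive; an observation larger than every null value lands
  exactly at 1, so the classification domain is (0, 1].
* classification: clustered iff obs.p < 0.05, overdispersed iff
  obs.p > 0.95, otherwise random.  Classification follows the quantile,
  not the SES sign: the two can disagree in tie-heavy or skewed nulls,
  and the quantile is the quantity to which the significance thresholds
  attach.  SES is reported alongside.
* degenerate nulls (sd = 0, e.g. equal-branch star trees where every
  permutation is isometric) and missing observations map to
  `undefined`, never to a spurious significance call.

With 199 replicates the nominal two-tail flag rate under the null is
9/200 + 10/200 = 9.5 %, slightly below 10 % — the calibration test bands
account for this.

**Reproducibility.**  One master seed; each plot derives a child seed by
hashing its plot id (CRC-32) together with the master seed, so results do
not depend on the order in which plots are processed, and by default the
same permutation stream is reused across the three metrics of a plot so
cross-metric comparisons are paired (switchable via
`shared_permutations=False`).

## Gradient analyses

Pearson product–moment correlation with a two-sided t test (n − 2 df),
significance at p < 0.05, no multiple-testing correction (the plot ×
metric tallies are descriptive counts, not a corrected family of tests).
Missing metric values are dropped pairwise and the n used is reported;
fewer than 3 complete pairs or zero variance yields an undefined r.  The
plot-exclusion sensitivity analysis recomputes the correlation on the
reduced plot set and returns both results side by side.

Species elevational ranges: "range not exceeding the focal plots" is
read as upward non-exceedance — the species' maximum occurrence
elevation does not exceed the highest focal plot — which is the natural
reading when the focal plots are suspected of collecting an upper flora's
lower range limits.  A stricter two-sided containment
(`containment="two_sided"`) is available; exclusivity to the focal plots
always implies containment under either reading.

## Reconciliation and exclusions

Phylogenetic placement is typically incomplete (barcode recovery fails
for a fraction of species), so `reconcile` restricts the matrix and tree
to their shared pool and reports what was dropped and the fraction of
individuals those species represent — a logged drop rather than an
error, since partial placement is the normal state of such data.
`exclude_taxa` removes named taxa (e.g. the two tree ferns) from matrix
and tree consistently; plots emptied by an exclusion are retained and
flagged rather than silently vanishing from downstream tables.  Pruning
keeps the original root, so the root-path PD convention survives
exclusion; unifurcations are collapsed with branch lengths summed.
Missing branch lengths in input Newick are an error, never an implicit
zero — a zeroed edge would silently corrupt PD.

## Synthetic transects

The generator emulates the shape of a published Andean transect: 15
plots at 2440–3330 m, a pool of 70 species (88 in the fixed
margins-matching fixture), per-plot richness falling linearly from 17 at
the base at 7 species per km (≈ 11 at the top), and geometric
rank-abundance stem counts (mean 1/0.25 = 4 stems per species,
17–100 stems per plot in practice).  Trees are pure-birth (Yule) with
unit birth rate, grown to n tips and extended by one final waiting time,
hence ultrametric; pure birth is sufficient to give realistic topology
and avoids pruning extinct lineages.  Traits evolve by Brownian motion
(variance = rate × branch length), so trait similarity carries
phylogenetic signal.

Assembly mechanisms: *neutral* draws species uniformly without
replacement (the tip-shuffle null is exact for it, which is what the
type-I calibration exploits); *filtering* weights species by a Gaussian
kernel exp(−(tᵢ − θ(e))²/2σ²) around a trait optimum θ(e) mapped
linearly from elevation onto the trait range, sampled without
replacement by the Gumbel-top-k trick (σ = 0.5 by default — strong
enough to produce detectably negative SES at this pool size without
emptying the kernel tails); *repulsion* adds species sequentially with
probability proportional to the minimum patristic distance to those
already chosen.  `fern_injection` grafts a two-tip cherry next to the
root — stem 1.5× and cherry edges 0.5× the tree depth, so the pair is
farther from every resident than any resident pair is from each other,
but close to one another — and plants both taxa at high abundance
(7–10 stems) in the lower 60 % of the gradient, mimicking abundant tree
ferns among angiosperms.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring plots, dispersal limitation, multi-stemmed individuals,
non-ultrametric barcode trees, elevation-dependent abundance models, or
measurement error in elevations.  Passing tests therefore show that the
pipeline's statistics behave correctly under controlled assembly
processes — not that any particular field data set was generated by
those processes.

The `table1_shape` fixture is deterministic (fixed internal seed): its
per-plot stems and richness equal the published summary-table margins
exactly (595 stems, plot 6 the richest with 23 species); abundances are
filled by a halving rule (each successive species takes half the
remaining surplus) that reproduces single-species dominance of the kind
seen in real plots; its tree covers the 70 most abundant species, with
the top two grafted near the root as fern analogues, leaving 18 species
(20.5 % of the pool) without placement for exercising reconciliation.

## Problem sizes and runtime

Defaults are sized for a laptop core: the full test suite runs in about
15 s and the acceptance script in under 10 s, using 199-replicate nulls,
20 replicate transects per mechanism and 300 neutral plots for
calibration.  Production analyses should use the 999-replicate default;
a 15-plot × 70-species transect at 999 replicates × 3 metrics takes
under a second.

## Known limitations

* Patristic distances are computed densely; pools beyond a few thousand
  tips would need a sparser strategy.
* The null model family is tip-label randomization only; richness- or
  frequency-constrained matrix swaps (independent/trial swap) are out of
  scope.
* MPD/MNTD presence-absence variants exist only implicitly (set all
  abundances to 1); beta-diversity (UniFrac-like) metrics are not
  implemented.
* The published transect's raw plot × species matrix is not distributed,
  so analyses that need it (observed PD/MPD/MNTD magnitudes, SES–elevation
  correlations on real data) can only be reproduced in shape, via the
  synthetic generator, not in value.
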