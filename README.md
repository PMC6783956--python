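# elevagrad

Community phylogenetics along elevational gradients.

`elevagrad` is a pipeline for asking how tree communities are assembled
along a mountainside: do co-occurring species become more closely related
with elevation (phylogenetic clustering, the signature of habitat
filtering) or less (overdispersion, the signature of niche
differentiation)?  It is aimed at forest-plot studies of the kind run on
Andean transects — a series of inventory plots spanning hundreds of
metres of elevation, a species pool of some tens of taxa placed on a
DNA-barcode phylogeny, and per-plot stem counts — but works for any
rooted tree plus plot × species abundance matrix.

## What it computes

**Taxonomic alpha diversity** per plot: richness *S*, Shannon–Weaver
diversity (natural log)

> H′ = −Σᵢ pᵢ ln pᵢ,   pᵢ = fᵢ / Σⱼ fⱼ,

inverse-Simpson dominance D₂ = 1 / Σᵢ pᵢ² (the effective number of
equally common species) and Simpson's evenness E = D₂ / S.

**Phylogenetic alpha diversity** per plot:

* Faith's PD — the sum of branch lengths of the minimal subtree spanning
  the species present (root path included by default);
* abundance-weighted mean pairwise distance,
  MPD = Σᵢ Σⱼ≠ᵢ δᵢⱼ fᵢ fⱼ / Σᵢ Σⱼ≠ᵢ fᵢ fⱼ, with δᵢⱼ the patristic
  distance between species *i* and *j*;
* abundance-weighted mean nearest-taxon distance,
  MNTD = Σᵢ fᵢ · minⱼ≠ᵢ δᵢⱼ / Σᵢ fᵢ.

**Null models and standardized effect sizes.**  Species names are
randomized across *all* tips of the phylogeny (the community matrix is
held fixed), each metric is recomputed, and after 999 such
randomizations

> SES = (observed − mean(null)) / sd(null),

with a quantile position obs.p for the observed value in its null
distribution.  Plots are classified *clustered* (obs.p < 0.05),
*overdispersed* (obs.p > 0.95) or *random*.

**Gradient analyses.**  Pearson correlations of any metric with
elevation (two-sided t test, n − 2 df), re-run after excluding chosen
plots (off-trend sensitivity analysis) or taxa (e.g. dropping two
abundant, distantly related tree ferns and re-running the whole null
analysis), significance tallies across plot × metric tables, and
species elevational-range/overlap summaries.

**Synthetic transects.**  A generator producing Yule trees, Brownian
traits, and gradient-structured communities under three known assembly
mechanisms (`neutral`, `filtering`, `repulsion`), with optional
injection of two long-branch, highly abundant "tree-fern-like" taxa into
a band of plots — so every pipeline stage can be tested against inputs
whose expected behaviour is known.  A deterministic fixture mirrors the
published per-plot stem/richness margins of a 15-plot Andean transect
(2440–3330 m, 88 species, 595 stems).

## Worked example

```python
from elevagrad import AssemblyScenario, simulate_scenario, ses_table, summarize_significance

scenario = AssemblyScenario(assembly="filtering", filtering_strength=0.5, seed=42)
tree, matrix, traits = simulate_scenario(scenario)
print(matrix.richness().tolist())

tab = ses_table(matrix, tree, reps=999, seed=42)
print(tab[tab.metric == "mpd"].head(4).round(3).to_string(index=False))
summary = summarize_significance(tab)
print(f"clustered: {summary.clustered}, overdispersed: {summary.overdispersed}, "
      f"non-random: {summary.nonrandom} of {len(tab)} plot-metric cells")
```

prints

```
[17, 17, 16, 16, 15, 15, 14, 14, 13, 13, 13, 12, 12, 11, 11]
plot_id  elevation_m metric scenario  observed  null_mean  null_sd    ses  quantile_p classification
 plot01     2440.000    mpd all_taxa     6.181      6.322    0.391 -0.362       0.304         random
 plot02     2503.571    mpd all_taxa     5.633      6.319    0.477 -1.439       0.085         random
 plot03     2567.143    mpd all_taxa     5.737      6.296    0.479 -1.166       0.118         random
 plot04     2630.714    mpd all_taxa     5.514      6.307    0.476 -1.667       0.077         random
clustered: 9, overdispersed: 0, non-random: 9 of 45 plot-metric cells
```

Richness declines linearly up the gradient by construction.  Because the
`filtering` mechanism co-selects species with similar (phylogenetically
conserved) trait values, observed MPD sits below its null mean in nearly
every plot — negative SES — and 9 of the 45 plot × metric cells fall
under the 0.05 quantile threshold: phylogenetic clustering, with no
overdispersion anywhere.  A `repulsion` scenario flips the signs; a
`neutral` one classifies ~90 % of cells as random.

The same analysis runs from the shell on real files:

```sh
elevagrad simulate --scenario filtering --seed 42 --out-tree t.nwk --out-matrix m.csv
elevagrad taxdiv   --matrix m.csv --out taxdiv.tsv
elevagrad ses      --tree t.nwk --matrix m.csv --reps 999 --seed 42 --out ses.tsv
elevagrad reconcile --tree t.nwk --matrix m.csv
```

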