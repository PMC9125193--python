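# cycadiv

Coalescent–ABC inference of the geographic mode of speciation for the
cycad sister pair *Cycas revoluta* (Ryukyu Archipelago / southern
Kyushu; "CR") and *C. taitungensis* (Taiwan; "CT"), with the supporting
population-structure and morphometric analyses.  The package is aimed at
population geneticists who want a tested, fully synthetic-data version
of the analysis chain: every stage runs from simulated inputs, so no
sequence download is required.

## What it does

Four speciation scenarios share one two-population demography — recent
sizes (N<sub>CR2</sub>, N<sub>CT2</sub>), a bottleneck at t₁ back to
(N<sub>CR1</sub>, N<sub>CT1</sub>) = (N<sub>CR_REL</sub>·N<sub>CR2</sub>,
N<sub>CT_REL</sub>·N<sub>CT2</sub>), divergence at t₂ from an ancestor of
size N<sub>anc</sub> = N<sub>anc_REL</sub>·N<sub>CT1</sub>, and a
genealogically inert ghost split at t₃ — and differ only in when
interspecific migration is on:

- **CG** continuous gene flow (both epochs), **PC** primary contact
  (before t₁ only), **SC** secondary contact (after t₁ only), **CI**
  complete isolation (allopatric null).

A backward-time coalescent simulator (numba-compiled, infinite-sites
mutation on unlinked ~238-bp loci) generates SNP panels under each
scenario; 17 summary statistics (per-species S, π, He mean/sd; global
per-locus mean/sd of S, π, Weir–Cockerham F<sub>st</sub> and
F<sub>it</sub>; interspecific F<sub>st</sub>) feed rejection ABC with
Epanechnikov weights, model choice by retained-weight share and Bayes
factors, a nearest-distance goodness-of-fit test, and local-linear or
neural-network regression-adjusted posterior summaries (weighted
mean/median/95% interval).

Around this core: VCF/TSV IO with the ddRAD panel QC filters (MAF ≥
0.01, observed heterozygosity ≤ 0.8, site/individual missingness, one
SNP per locus), Nei (1972) distances, PCoA, Delaunay/kNN/MST connection
networks with Monmonier maximum-difference barrier search, pairwise
F<sub>st</sub> matrices, bootstrap NJ trees, and Mann–Whitney trait
comparisons with agglomerative trait clustering.  `docs/methods.md`
documents every model and convention.

## Worked example

```python
from cycadiv.synthdata import ScenarioConfig, generate_snp_dataset
from cycadiv.sumstats import summarize
from cycadiv.abcinf import (build_reference_table, default_priors,
                            prune_correlated, rejection, model_posterior,
                            goodness_of_fit, adjust_parameters)
from cycadiv.coalsim import SimConfig

# a pseudo-observed ddRAD panel generated under continuous gene flow
gm, truth = generate_snp_dataset(ScenarioConfig(seed=1, n_CR=20, n_CT=10,
                                                n_loci=200))
obs = summarize(gm)

table = build_reference_table(["CG", "PC", "CI", "SC"], default_priors(),
                              SimConfig(n_CR=20, n_CT=10, n_loci=200, seed=0),
                              n_per_model=500, seed=2)
keep = prune_correlated(table)
sel = model_posterior(table, rejection(obs, table, k=200, stat_names=keep))

cg = build_reference_table(["CG"], default_priors(),
                           SimConfig(n_CR=20, n_CT=10, n_loci=200, seed=0),
                           n_per_model=3000, seed=4)
keep_cg = prune_correlated(cg)
est = adjust_parameters(cg, rejection(obs, cg, k=500, stat_names=keep_cg))
```

Output (printed by the fuller version of this script):

```
panel: 200 SNPs x 30 individuals, missing 35.2%
observed He(CR)=0.452 He(CT)=0.429 interspecific Fst=0.048
model posterior: {'CG': 0.514, 'PC': 0.002, 'CI': 0.0, 'SC': 0.483}
N_CR2: median 6.02e+03 (95% 595-1.72e+04), true 5.84e+03
t2: median 3.27e+03 (95% 204-2.21e+04), true 4.59e+03
```

Read: the generating scenario (CG) gets the highest posterior
probability, the allopatric null (CI) is rejected outright, and the
adjusted 95% intervals cover the generating N<sub>CR2</sub> and t₂.
CG and SC are hard to separate at this scale — both allow recent gene
flow, which is what a 200-SNP panel mostly sees; larger reference
tables (the calibration suite uses 2,000–5,000 rows per model) sharpen
the contrast.

The same pipeline is scriptable end to end:

```bash
cycadiv pipeline run --config cfg.yaml --out run/
```

with a YAML config selecting stages (`snp`, `stats`, `abc`, `popstruct`,
`morpho`), a mandatory seed, and scenario/ABC settings; the run writes a
JSON manifest plus model-selection and parameter-estimate JSON shaped
like the study's summary tables.

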