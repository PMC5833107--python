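# taxafun

**Taxa-function robustness of microbial communities.**

A microbial community's functional capacity is a linear consequence of its
taxonomic composition: the abundance of gene family *j* in the metagenome is

```
F_j = Σ_i a_i · c_ij
```

where *a_i* is the relative abundance of taxon *i* and *c_ij* the copy
number of family *j* in taxon *i*'s genome. How stable is *F* when the
composition *a* fluctuates? `taxafun` answers this by simulating stochastic
perturbations of a community, measuring the taxonomic magnitude of each
perturbation (weighted UniFrac, *t*) against the functional shift it causes
(cosine dissimilarity of the predicted functional profiles, *f*), and
fitting the **taxa-function response curve**

```
f = t^b / e^a        ⇔        ln f = −a + b · ln t
```

by least squares on the log-log scale. The intercept term *a* is the
**attenuation** (higher ⇒ smaller shifts per unit perturbation ⇒ more
robust); the exponent *b* is the **buffering** (higher ⇒ stronger
suppression of shifts at small perturbations). The package is aimed at
microbial ecologists working with 16S OTU tables, reference genome content
(PICRUSt-style copy-number tables), and phylogenies.

It also provides:

* the perturbation model — per-taxon multipliers *m_i* ~ U(0, M] applied as
  *a_i·m_i^{±1}* over a grid of maximum magnitudes M (default 45 levels on
  [1.2, 10], 100 draws each = 4500 perturbations per community);
* sample processing (chloroplast filtering, QC thresholds, rarefaction,
  abundance-weighted OTU subsampling) and 16S copy-number correction with
  pathway-level summarisation of gene-family profiles;
* five **gene-distribution features** (average functional redundancy,
  average functional similarity, average genome size, genome size
  variability, unique function abundance) with PCA plumbing;
* environment-level statistics: Hodges-Lehmann pseudomedians with
  Wilcoxon-inversion CIs, Mood's-median-test logic for deciding in which
  environments a function is most robust, rank-sum contrasts with FDR
  control;
* **community mixing**: robustness estimation from pairs of real
  communities with measured functional profiles, via a binary search on the
  convex mixing fraction that hits target UniFrac distances;
* a synthetic-data generator (random trees, long-tailed abundances,
  genome-content matrices with a tunable core/accessory redundancy knob)
  so every stage is testable without external data.

## Worked example

```python
from taxafun import RobustnessModel
from taxafun.simulate import ScenarioConfig, generate_scenario

profile, tree, content, hierarchy = generate_scenario(
    ScenarioConfig(n_taxa=30, n_functions=150, redundancy=0.5, seed=1))
res = RobustnessModel(profile, content, tree, hierarchy=hierarchy,
                      community_id="demo", environment="synthetic").fit(seed=1)
print(res.summary())
```

prints

```
Taxa-Function Robustness Results
========================================
community:        demo
environment:      synthetic
taxa (non-zero):  30
perturbations:    4500 (used 1585, dropped 0)
attenuation (a):  7.2798
buffering (b):    1.6592
response curve:   f = t^1.659 / e^7.280
residual SS:      915.3344
----------------------------------------
avg_functional_redundancy   2.7377
avg_functional_similarity   0.9679
avg_genome_size             160.1667
genome_size_variability     0.0101
unique_function_abundance   0.0299
```

The community was perturbed 4500 times; after uniform re-sampling across
ln-*t* windows, 1585 records entered the fit. The attenuation of 7.28 and
buffering of 1.66 describe the fitted power law: at a taxonomic
perturbation of weighted UniFrac 0.1, the expected functional shift is
`res.predict(0.1)` ≈ 1.5 × 10⁻⁵ — this moderately redundant community is
highly robust. Communities built with a lower redundancy knob fit lower
attenuation (larger functional shifts for the same perturbations).

A command-line interface mirrors the library:

```sh
taxafun simulate --n-taxa 30 --redundancy 0.5 --seed 1 --out bundle/
taxafun pipeline --otu-table bundle/otu_table.tsv --tree bundle/tree.nwk \
    --genome-content bundle/genome_content.tsv --hierarchy bundle/hierarchy.tsv \
    --seed 1 --out results/
```

writing `curves.tsv` (attenuation/buffering per community), `gdfs.tsv`, and
environment `summaries.tsv`. Other subcommands: `perturb`, `dissim`, `fit`,
`summarize`, `gdf`, `mix`.

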