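# gemot

Three-layer module discovery for recombinant inbred panels: given genotypes
(variants × strains), gene expression (transcripts × strains), and phenotypes
(traits × strains), `gemot` finds **modules** consisting of a single genomic
interval, a set of validated **driver transcripts**, and the group of traits
those drivers causally affect. It is aimed at systems-genetics analyses of
panels like the BXD mouse strains, where many traits co-map to the same locus
and the question is *which transcripts mediate the locus's effect on which
traits*.

## The method

The pipeline has three stages:

**Stage I — bipartite modules.** For every variant *v* and trait *p*, the
*link potential* asks whether transcripts strongly associated with *v* are
also unusually correlated with *p*. Per transcript *g*, the
variant–transcript association score is −log₁₀ of a pooled two-sample
t-test p-value of expression between the two allele groups, and the
transcript–trait correlation score is |Pearson r|. The association range is
split into 6 equal-count groups (5 cutoffs); at each cutoff a one-sided
t-test compares correlation scores above vs below, and the best −log₁₀ p is
the edge weight of a variant × trait bipartite graph. Heavy biclusters —
each a consecutive run of variants (one genomic interval) plus a trait set —
are grown from seed pairs exceeding c_s and kept while every member's mean
weight exceeds c_i (defaults c_s = 180, c_i = 90 at genome scale).

**Stage II — candidate transcripts.** Each transcript's correlation and
association scores are ranked against all traits and all variants; its ranks
at the module's members are compared with all its ranks by a two-sample
Kolmogorov–Smirnov test. Transcripts with significant link scores become the
module's candidates.

**Stage III — driver validation.** For each (candidate, trait) pair and the
module's representative variant, five Gaussian structural models are
compared: M1 (causal, v→g→p), M2 (independent), M3 (reactive), and
M4/M5 (chains with a direct genetic effect, modeled together). Likelihood
ratios of M1 against M2 and against M3 are referred to empirical permutation
nulls obtained by reshuffling the transcript; the *broad-sense causality
p-value* is the larger of the two, so both M1 and M4 count as causal.
Per-transcript evidence over the module's traits is combined by Fisher's
method, χ²(2k) = −2Σⱼ ln p⁠ᵢⱼ, and transcripts/traits are iteratively
eliminated until a fixed point. Surviving transcripts are the drivers.

The package also ships the benchmark generators (M1–M5 triplets, Net-1/2/3
co-mapped sub-networks with noise level q_ε, and large composite networks)
and the evaluation metrics (balanced accuracy, π₀-adjusted balanced FDR,
broad-sense AUC, whole-pipeline permutation FDR).

## Worked example

```python
from gemot import simulate
from gemot.pipeline import run, synthetic_config

spec = simulate.NetworkSpec(
    sub_spec=simulate.SubNetworkSpec(k=5, noise_level=0.5), seed=20150317
)
ds, truth = simulate.simulate_network(spec)   # 100 variants, 200 transcripts,
                                              # 100 traits, 100 individuals,
                                              # 5 planted sub-networks
result = run(ds, synthetic_config(seed=20150317))
print(result.counts)
mod = result.gemot[0]
print(mod.representative_variant, mod.driver_transcripts, mod.trait_ids)
```

prints

```
{'bipartite_modules': 6, 'tripartite_modules': 6, 'gemot_modules': 6}
s000_v ['s000_gC2', 'bgg092', 'bgg031', 'bgg005', 'bgg070', 'bgg008', 'bgg009',
        'bgg026', 'bgg032', 'bgg052', 'bgg069', 'bgg074', 'bgg144', 's000_gC1',
        's000_gC3', 'bgg082', 'bgg072'] ['s000_pC1', 's000_pC2', 's000_pC3',
        's000_pC4', 's000_pC5']
```

The first module is anchored at a planted sub-network's variant (`s000_v`)
and its trait set is exactly the five causally affected traits — the
reactive and independent traits (`s000_pR1`, `s000_pI1`) were eliminated in
stage III. The drivers contain the three planted causal transcripts
(`s000_gC1..3`) plus background transcripts that the generator couples to
the sub-network (each background transcript is x + c·y for a sub-network
transcript y, so they carry the causal signal and are statistically valid
mediator proxies). `synthetic_config` is the operating point scaled to a
200-transcript background; the library defaults hold the genome-scale
constants (c_s = 180, c_i = 90, stage-III cutoff 0.005).

The same pipeline runs from the shell on TSV files:

```sh
gemot simulate network --seed 2 --out net/
gemot run net/genotypes.tsv net/expression.tsv net/traits.tsv --out out/
gemot benchmark causality --seed 1
```

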