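# crisprstat

Quantitative analysis of bacterial Class 1 CRISPR-Cas loci. The package
integrates a CRISPR array table (one row per annotated repeat-spacer array)
with a cas-operon classification table, then asks three questions about the
joined systems:

1. **What distribution does array size follow?**  Spacer counts are fitted
   by maximum likelihood to two discrete families — geometric (failures
   form, pmf `(1-p)^k p` on k = 0, 1, 2, …, MLE `p̂ = 1/(1+x̄)`) and Poisson
   (`λ̂ = x̄`) — and judged with a discrete Kolmogorov–Smirnov statistic
   `D = sup|F₀ − F_data|` whose p-value comes from a Lilliefors-type
   parametric bootstrap (refit on every resample), valid when the parameter
   is estimated from the data.
2. **Where do arrays sit on the chromosome?**  Start coordinates are
   standardized to a circle, `degrees = start/length × 360`, binned into
   360° polar histograms per strand, and tested for uniformity with a
   one-sample K-S test of degrees/360 against Uniform(0, 1).
3. **Is the cas-proximal array the largest?**  For replicons with a single
   cas operon, the fraction of genomes whose cas-adjacent array is the
   largest is tabulated against the number of arrays, and the association
   is summarized with Spearman's
   `r_s = 1 − 6ΣD_i²/(N(N²−1))` (rank-average Pearson under ties), in both
   an aggregated-proportion and a per-genome variant.

A seeded synthetic-table generator produces array/cas tables with the same
statistical structure (geometric sizes, configurable circular clustering,
multi-array replicons, a tunable proximal-size bias), so the entire
pipeline runs and is tested without any database download.  It is aimed at
microbial genomicists and biostatisticians who want the statistical
machinery of array-scale CRISPR surveys as reusable, tested code.

## Worked example

```python
import crisprstat as cs

# simulate a 400-genome survey with a strong proximal-size bias
cfg = cs.SimulationConfig(n_genomes=400, seed=77, proximal_bias=1.0)
arrays, operons = cs.simulate_dataset(cfg)

# integrate: filter to chromosomal, non-questionable Class 1 loci and
# join each operon to its closest array
arrays_f, operons_f = cs.filter_dataset(arrays, operons)
systems, unpaired = cs.associate_arrays(operons_f, arrays_f)

# fit the size distribution of the cas-proximal arrays
counts = [s.proximal_array.n_spacers for s in systems]
res = cs.ArraySizeModel(counts, label="Class 1").fit(n_boot=199, seed=1)
print(res.summary())
```

prints

```
Array size model: Class 1
  n = 454, mean = 33.401, quartiles = (6.00, 19.00, 40.75)
  geometric p_hat = 0.02907  loglik = -2053.63  D = 0.0859  p(boot) = 0.0050
  poisson   lambda_hat = 33.40088  loglik = -10158.46  D = 0.5265  p(boot) = 0.0050
  best fit by log-likelihood: geometric
```

The geometric family wins by ~8,100 log-likelihood units — the counts are
far too dispersed for Poisson — while the bootstrap p-value of 0.005 also
flags that a *biased* mixture (proximal arrays shrunk, trans arrays not) is
detectably non-geometric at n = 454.  The multiplicity stage quantifies
that bias:

```python
profiles = cs.profile_genomes(systems, arrays_f)
print(cs.proximal_size_association(profiles, "aggregated_proportion"))
# RhoResult(rho=-0.9746..., n=5, variant='aggregated_proportion', tie_corrected=True)
```

i.e. the proportion of single-operon genomes whose cas-proximal array is
the largest falls steeply as the number of arrays per genome grows.

`cs.run_report(arrays, operons, "out/", seed=1)` chains every stage and
writes the TSV/JSON tables and figures; the same pipeline is available
from a shell:

```sh
crisprstat simulate --seed 77 --out data/
crisprstat report --arrays data/arrays.tsv --cas data/cas.tsv --out out/
```

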