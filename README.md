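# ploidypop

Population genomics for species complexes that mix diploid and tetraploid
individuals — sagebrush-style heteroploid datasets where cytotypes, gene
pools and hybrids all occur in one sample. The package takes a study from
raw inputs (flow-cytometry fluorescence, allele read counts, presence
rasters) to the population-genetic endpoints: ploidy calls, ploidy-aware
dosage genotypes, a filtered SNP panel, a mixed-ploidy relatedness matrix
with PCoA, admixture proportions with best-K selection, threshold-based
introgression rates, an auto- vs allopolyploid inheritance-mode call, and
climate-niche overlap/loss accounting. A first-class synthetic-data module
generates every input with known truth, so the whole chain is testable
without field data.

## The models at the core

- **Dosage genotyping.** At a biallelic site, an individual of ploidy *v*
  with dosage *d* yields alternate reads *a* ~ Binomial(*n*, (d/v)(1−e) +
  (1−d/v)e), with *e* the site's sequencing-error rate. A flat prior over
  the *v*+1 dosages gives the posterior by normalization; calls are MAP
  dosages, and cells with depth ≤ 5 are missing.
- **Coancestry.** A Ritland-type method-of-moments estimator on dosage
  fractions, θ̂ = x_A y_A/p + x_a y_a/q − 1 averaged over loci, rescaled by
  √(v_x v_y) so self-comparisons expect 1 and non-relatives 0 at any
  ploidy.
- **Admixture.** d_il ~ Binomial(v_i, Σ_k q_ik f_kl), fitted by EM over
  the latent cluster of origin of each allele copy; Evanno's
  ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)|/SD(K) over replicate runs selects K;
  introgression is called where a non-home ancestry fraction exceeds
  q-thresholds {0.05, 0.1, 0.15}.
- **Inheritance mode.** Tetrasomic segregation predicts Binomial(4, p)
  genotype-class frequencies — all five classes visible at p = 0.5 —
  while fully disomic segregation with divergent subgenomes fixes the
  duplex heterozygote; a summed log-likelihood ratio between the two
  reference models over loci near p = 0.5 makes the call.
- **Niche accounting.** Presence = vote > 0.6; two subspecies models merge
  into co-occurring/only/absent classes; areas are cells × km²; percent
  loss = 100·(ref − scenario)/ref.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import numpy as np
from ploidypop import admix, genolik, filters, kinship, synthio

# two diploid + two tetraploid gene pools, ten 50:50 diploid hybrids
cfg = synthio.SimConfig(
    n_per_cluster=(50, 50, 50, 50), n_loci=300,
    admixture_spec=((10, (0.5, 0.5, 0.0, 0.0)),), seed=1,
)
truth, true_dosages, reads = synthio.simulate_dataset(cfg)

called = genolik.genotype_all(reads, min_depth=5)
ok = ~called.missing
print("dosage concordance:", (called.dosage[ok] == true_dosages.dosage[ok]).mean())

panel, log = filters.filter_sites(called)
panel = filters.thin_one_per_window(panel)
print("sites kept:", log.n_input, "->", log.n_retained, "->", panel.n_sites)

coa = kinship.pairwise_coancestry(panel)
print("mean self-relatedness:", np.diag(coa.values).mean().round(3))

res = admix.AdmixtureModel(panel, 4).fit(seed=2, restarts=3)
kept = (panel.sites["pos"].to_numpy() - 1) // 1000  # simulated locus index
perm = admix.align_clusters(truth.true_cluster_freqs[:, kept], res.freqs)
print("q MAE:", np.abs(res.q[:, perm] - truth.true_q).mean().round(4))
```

prints (seed 1):

```
dosage concordance: 0.9980476190476191
sites kept: 300 -> 290 -> 290
mean self-relatedness: 1.264
q MAE: 0.0307
```

The concordance is the fraction of genotype calls matching the simulated
truth at 50×/100× (diploid/tetraploid) depth; self-relatedness averages
the coancestry diagonal, which exceeds 1 here because drifted gene pools
violate the pooled-frequency Hardy–Weinberg baseline (the calibration
contract — self 1, parent–offspring 0.5, unrelated 0 — holds within a
single pool, see the tests); the q MAE is the mean absolute error of the
recovered ancestry fractions after resolving label switching.

A full simulated run with a report:

```sh
ploidypop run --seed 1 --outdir out/
```

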