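# Methods

`ploidypop` implements a population-genomic workflow for species complexes
that mix diploid and tetraploid individuals, exercised end to end on
synthetic data with known truth. This note documents the models, the
defaults and why they were chosen, what the generator does and does not
emulate, and the numerical conventions.

## Synthetic populations (`synthio`)

Gene pools diverge from a shared ancestral frequency by a Balding–Nichols
drift model: cluster k's frequency at a locus with ancestral frequency p is
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance F·p(1−p). The
drift parameter F defaults to 0.2 per cluster — strong enough that clusters
are clearly distinguishable at a few hundred loci, as the recognized
subspecies are, without approaching fixation. Ancestral frequencies are
drawn Uniform(0.05, 0.95) so simulated sites are not immediately removed by
the minor-allele-frequency filter; both choices are configurable.

Individuals draw alternate-allele dosages by ploidy. Diploids and
tetrasomic tetraploids draw Binomial(v, π) with π the q-weighted mixture of
cluster frequencies; admixed individuals draw each allele copy's cluster of
origin i.i.d. from their q vector, which is exactly the dosage model the
admixture estimator assumes. Disomic tetraploids draw the sum of two
independent Binomial(2, ·) subgenome draws with no inter-subgenome
exchange. The subgenome pair for mean frequency p at divergence s
interpolates between (p, p) at s=0 and the maximal mean-preserving split
((2p, 0) for p ≤ 0.5) at s=1, so s=1 at p=0.5 fixes every individual as
the duplex heterozygote — the textbook allopolyploid extreme.

Read counts are Poisson totals with Binomial alternate reads at success
probability (d/v)(1−e) + (1−d/v)e. The per-site error rate e is drawn from
a Gamma with mean `error_rate` (default 0.01, clipped to [1e-4, 0.49]) to
emulate position-specific error variation. The diploid mean depth defaults
to 50×, a realistic target for polyploid ddRAD designs; tetraploids receive
twice the diploid mean depth by default, emulating libraries pooled with
twice the PCR product for tetraploids so per-copy coverage is comparable
across ploidies. Depth is Poisson rather than negative-binomial for
simplicity; library-level overdispersion, linkage between SNPs on a read,
allele dropout and PCR duplicates are *not* modelled, so passing tests
demonstrate correctness of the estimators under their own model, not
robustness to those real-data artefacts.

Flow-cytometry fluorescence is Normal per ploidy band, truncated positive,
with at least two replicates per sample. Default bands are (6.73, 0.15)
for diploids and (12.2, 0.49) for tetraploids — a 2:1 ratio reflecting the
doubled genome.

All generators are deterministic given (config, seed); a single pipeline
seed fans out to per-stage seeds by SHA-256 hashing so toggling one stage
never perturbs another.

## Ploidy calling (`cytometry`)

Relative fluorescence (RF) is the sample/reference channel quotient. The
diploid acceptance band is center·(1 ± tol) and the tetraploid band twice
that; a mean RF outside both bands is called ambiguous and excluded, which
reproduces the "inconclusive" outcome of real screens. The default
relative tolerance 0.15 is conservative: the simulated band SDs are ≈2–4%
of the mean, so the bands sit far more than 10 SD apart and non-ambiguous
misclassification is effectively impossible. The band center is calibrated
as the median RF of known diploids (≥3), robust to an occasional
mislabeled tetraploid. Replicate CV > 0.05 flags a record without
ambiguating it. Pooled-sample deconvolution is out of scope; each record
is one individual.

## Dosage genotyping (`genolik`)

Likelihood of dosage d for a cell with a alternate reads of n total:
Binomial(a | n, (d/v)(1−e) + (1−d/v)e), with the site error e folded in
symmetrically. With a flat prior the posterior is the normalized
likelihood and the call is the MAP dosage; ties break toward the lower
dosage for determinism. Cells with n ≤ 5 are missing (strict DP > 5).
Site error is estimated from pileups as other-base reads over total,
floored at 1e-3 and capped at 0.49. An optional empirical-Bayes mode
replaces the flat prior with site-level genotype-class frequencies updated
from the posteriors (EM, tol 1e-8, cap 10,000 iterations); with a flat
prior the closed form needs no iteration. Multiallelic sites and mapping
quality are out of scope.

## Filtering (`filters`)

Cascade order: biallelic → QUAL > 100 → missing fraction ≤ 0.10 →
alternate-allele frequency > 0.04. The frequency is computed jointly on
ploidy-weighted allele copies among non-missing calls, because filtering
follows the cross-ploidy intersection step in the workflow. Thinning keeps
one SNP per 139-bp window (the ddRAD read length) per chromosome, greedy
left to right; the window member with least missingness wins, ties to the
lowest position. Real loci boundaries are unknown without locus
annotations, so windows anchor at the first unconsumed SNP — a documented
divergence from locus-based thinning. Missingness is assessed over all
individuals jointly (the per-ploidy alternative is noted as ambiguous and
not taken).

## Coancestry (`kinship`)

For individuals x, y at a locus with pooled frequency p and dosage
fractions x_A, y_A: θ̂ = x_A·y_A/p + (1−x_A)(1−y_A)/(1−p) − 1, averaged
over pairwise-complete polymorphic loci. The reported coefficient is
r̂ = θ̂·sqrt(v_x·v_y). This rescaling is the module's load-bearing choice:
the unscaled self-expectation is 1/(v) · (v/2)… concretely 1/2 for
diploids and 1/4 for tetraploids under Hardy–Weinberg, so multiplying by
sqrt(v_x·v_y) makes a non-inbred self-comparison expect 1 at any ploidy,
an outbred diploid parent–offspring pair 1/2, and non-relatives 0.
Estimates below 0 or above 1 are legitimate sampling error and are not
clipped. Frequencies are estimated from the full pooled sample
(ploidy-weighted), matching single-run usage; loci are equally weighted
since all sites are biallelic. PCoA eigendecomposes the symmetrized
relatedness matrix directly (no distance conversion), scaling eigenvectors
by sqrt(max(λ, 0)); variance explained is relative to the positive
eigenvalue mass. Group contrasts use the two-sided Mann–Whitney rank-sum.

## Admixture and best K (`admix`)

The likelihood is d_il ~ Binomial(v_i, Σ_k q_ik f_kl). A Bayesian MCMC
sampler over the same estimand is replaced by maximum-likelihood EM on the
latent cluster of origin of each allele copy: deterministic given a seed,
monotone in log-likelihood, desk-scale. The M-step reduces to matrix
products, so a fit at N≈200, L≈300, K≤6 takes ~1–2 s. Initialization draws
q from Dirichlet(1) and f from pooled frequencies plus noise; convergence
at relative log-likelihood change < 1e-8 or 2,000 iterations; frequencies
are clipped to [1e-6, 1−1e-6] for numerical stability.

Best-K uses the Evanno second-difference statistic
ΔK = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / SD(K) over replicate likelihoods, with
zero-SD K values excluded as undefined. Replicates need care with a
deterministic optimizer: whenever K under-fits, every EM run converges to
(nearly) the same optimum, so the spread of plain re-runs measures
convergence jitter, not anything statistical, and the ΔK denominator
becomes ill-conditioned. Each replicate therefore refits on a bootstrap
resample of loci — shared across K values so the second differences are
paired — making SD(K) an estimate of the sampling variance of L(K), the
role that run-to-run chain noise plays for a Bayesian sampler. Label
switching is resolved by greedy correlation matching of cluster frequency
vectors before any cross-run comparison.

Introgression: each individual's home cluster is its argmax q; it counts as
introgressed by donor cluster j at threshold t iff q_ij > t, strictly, at
t ∈ {0.05, 0.10, 0.15}; percentages are per home-cluster size. Home-cluster
assignment by argmax is a convention — sampling-site identity, the
alternative denominator, does not exist for synthetic data.

## Inheritance mode (`inherit`)

Spectra bin loci by allele frequency into half-open bins of width 0.05
centered on multiples of 0.05 (the central bin is [0.475, 0.525)),
accumulating dosage-class proportions from tetraploids whose largest
ancestry fraction is ≥ 0.9. The classifier scores each locus in bins
intersecting [0.4, 0.6] under two reference models at the locus's own
allele frequency: tetrasomic (Binomial(4, p)) versus the disomic extreme
(maximally divergent subgenomes; at p=0.5 this puts all mass on the duplex
class). Structurally-zero disomic classes are floored at 1e-6 so a stray
genotype keeps the log-likelihood ratio finite. The summed LLR calls
tetrasomic above +10 nats, disomic below −10, else indeterminate; 10 nats
means the data are e^10 ≈ 22,000 times more likely under the winning
model, a deliberately strong bar. The count of distinct observed genotype
classes near frequency 0.5 is reported alongside — five classes is the
autopolyploid hallmark, a lone duplex class the allopolyploid one.
Intermediate disomic models (partial subgenome divergence, homoeologous
exchange) exist in the generator but are not classifier hypotheses; as
exchange homogenizes subgenomes the LLR moves monotonically toward
tetrasomic, mirroring the known masking of allopolyploid origins.

## Niche-raster accounting (`nicheops`)

Votes strictly above 0.6 are presence. Merging two subspecies models gives
four classes per cell; areas are cell counts times a uniform nominal cell
area (1 km² by default) — geographic projection distortion is explicitly
out of scope. Percent loss versus a reference scenario is
100·(ref − scenario)/ref rounded half-up to 2 decimals; overlap shares are
rounded to the nearest whole percent. Class areas sum exactly to the total
on grids by construction.

## Problem sizes

The packaged tests and the acceptance script use scaled-down but
structurally faithful datasets chosen as the package's own defaults: four
gene pools (two diploid, two tetraploid) of 50 individuals each plus ten
50:50 hybrids at 300 loci for admixture/ΔK experiments (K ∈ 2..6,
replicate EM runs per K); 2,000 loci and 40 parent–offspring pairs for
coancestry calibration; 200 tetraploids at 100 loci fixed at allele
frequency 0.5 for inheritance-mode recovery — the regime where the two
segregation models are maximally distinct.

## Known limitations

- No linkage, recombination map, or coalescent ancestry in the generator;
  sites are exchangeable draws.
- The Evanno statistic remains a heuristic; the bootstrap-replicate SD
  makes its denominator well-defined for an ML fit but cannot rescue it
  when the likelihood profile has no elbow (the flat-profile case is
  reported as "no K preferred" rather than forced).
- The coancestry rescaling assumes non-inbred reference individuals;
  inbreeding inflates self-relatedness above 1.
- The disomic classifier hypothesis is the maximal-divergence extreme;
  weakly divergent allopolyploids are expected to classify tetrasomic, as
  they do in real data when subgenomes have homogenized.
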