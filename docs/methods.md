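# Methods

## Demographic models

Three regional haploid lineages (Central Europe, Eastern Europe, Near
East) are each panmictic and continuous through time; the six sampled
cultures are dated sampling events on their region's lineage, so e.g. GAC
and Corded Ware tips both draw from the Central European pool at their
respective ages. The inter-regional topology is not identified by the
sampled data and is a configurable design choice; the default merges
Central Europe and the Near East (backward in time) at `t_split_CE_NE`
and that joint lineage with Eastern Europe at the older `t_split_EE`,
into an ancestral population of size `N_ancestral`.

Migration is an instantaneous pulse: forward in time a fraction *m* of
the destination population is replaced by source migrants at time *t*;
in the backward simulation every lineage present in the destination deme
at *t* relocates to the source deme independently with probability *m*.
This matches the discrete "proportion of lineages" parameterisation being
estimated. Event windows are chronological constraints: event 1 predates
the GAC tips; event 2 lies between the Corded Ware and GAC tip ages;
event 3 between the Srubnaya and Corded Ware tip ages; all events predate
both splits, and `t_split_CE_NE < t_split_EE`. Draws violating any
constraint are rejection-resampled (truncated-prior semantics), with a
hard cap of 10⁵ attempts before an explicit error.

### Priors and defaults (stand-ins, all configurable)

| parameter | prior | rationale |
|---|---|---|
| N per region, N ancestral (haploid) | log-uniform [500, 50 000] | scale-free over plausible mtDNA effective sizes |
| μ per site per generation | log-uniform [10⁻⁸, 10⁻⁷] | brackets published whole-mitogenome rates |
| m₁, m₂, m₃ | uniform [0, 1] | uninformative on proportions |
| event times | uniform within their constraint windows | no within-window information |
| t_split_CE_NE, t_split_EE | uniform [240, 1200], [240, 2400] gen | older than every tip, younger than deep prehistory |
| generation time | 25 y | common ancient-DNA convention |

Tip ages (years BP): GAC 4900, Corded Ware 4500, Bell Beaker 4300,
Unetice 4000, Yamnaya 5000, Srubnaya 3800 — placeholders chosen inside
the cultures' date ranges; per-sample ages may be supplied as lists. The
sampling design is 9 GAC + 56 comparative mitogenomes; the split of the
56 (Unetice 14, Bell Beaker 12, Corded Ware 12, Yamnaya 12, Srubnaya 6)
is a documented configurable vector, since only the total is fixed by
the design.

## Coalescent simulation

The simulator is event-driven: between scheduled events (tip entries,
pulses, deme merges) each deme coalesces at rate k(k−1)/(2Nₑ); competing
exponential waiting times decide the next coalescence. After the final
merge all lineages share one deme, so coalescence to a single root is
guaranteed. One replicate is one genealogy — a single non-recombining
locus, as appropriate for mtDNA.

Mutations follow a Poisson process of rate μ·L per generation along
branches (L = 16 569 sites, the complete mitogenome, by default). Each
hit strikes a uniformly chosen site and substitutes the current base by a
draw from the jump chain of an HKY model with transition/transversion
rate ratio κ = 20 and mtDNA-like base frequencies (A .309, C .313,
G .131, T .247) — i.e. the per-site hit rate is uniform across sites and
base states, and only the substitution *type* is HKY-biased. This is the
usual coalescent-simulator simplification; with whole-mitogenome L and
realistic θ the multiple-hit correction is < 1%, which the pairwise-
difference acceptance check confirms against θ = 2NμL. Setting κ = 1
with equal frequencies recovers Jukes–Cantor-like behaviour exactly
(used in the msprime cross-validation, which matches our TMRCA and
segregating-site distributions on panmictic, serially-sampled and
pulse-structured benchmarks by two-sample KS tests).

Rate heterogeneity across sites is not modelled; with transition-biased
mtDNA hypervariable sites this understates homoplasy on deep trees.

## Summary statistics

Per population: S, number of haplotypes K, haplotype diversity
H = n/(n−1)(1−Σpᵢ²), π (per site), Π (mean pairwise Hamming
differences; Π = π·L exactly) and Tajima's D (undefined — NaN — when
S = 0, and structurally for n < 4 where its variance constants vanish).
Per pair: AMOVA Φ_ST on the Hamming distance matrix (two-level variance
partition; estimates may be slightly negative and are recorded
unclamped — the unbiased estimator gives exactly −1/(n−1) for two
populations with identical haplotype compositions, and its panmictic
null is centred at zero only at the level of the among-population
variance component, which `phi_st_components` exposes) and the mean
between-population pairwise difference. Pooled totals complete the fixed,
documented vector layout (`summary_layout`). A substitution-corrected
distance (e.g. Tamura–Nei) behind Φ_ST is a config hook left at plain
Hamming by default.

Undefined entries are imputed to 0 at the reference-table stage with
`*_def` indicator columns, so forests can exploit missingness while
distance-based rejection sees finite values.

## ABC random forest

The reference table holds (model, parameter draw, summary vector) rows,
each row seeded independently from (seed, model index, row index), which
makes builds reproducible and resumable in chunks. Rows are canonically
sorted before training so votes are invariant to table row order.

The classifier is a random forest (500 trees by default, √p features per
split, fully grown); votes are per-tree predictions at the observed
vector, ties broken by the documented model-name order with a warning.
The posterior probability of the selected model is 1 − Ê[misclassified |
s_obs], where the expectation is a regression forest trained on the
out-of-bag misclassification indicator of the table. That regression
forest uses regression defaults (p/3 features) and an adaptive minimum
leaf size of 2% of the table (floor 5): leaf means must estimate the
*local error rate*, and memorising 0/1 indicators in singleton leaves
makes the posterior estimate far too noisy (we measured a point-wise SD
of ≈ 0.22 with singleton leaves on an uninformative toy, vs ≈ 0.05 with
adaptive leaves, at the cost of some smoothing of sharp error gradients).

Classification error is reported from the out-of-bag predictions (every
table row acting as a POD), as a global rate and a confusion matrix.
LDA and PCA goodness-of-fit projections operate on z-scored statistics;
each LDA axis is sign-fixed so the first-listed model has a negative
mean, and the axes agree with a dense generalized-eigenproblem solution.

## Parameter estimation

Rejection keeps the n closest simulations in Euclidean distance on
statistics z-scored by the table SD (zero-variance columns dropped with
a warning). Weights are Epanechnikov in distance with bandwidth equal to
the largest accepted distance. The local-linear adjustment regresses the
logit-transformed proportion on the centred statistics (weighted least
squares; a small ridge handles the exact collinearities the panel
contains by construction, e.g. Π = π·L) and moves each accepted value
along the fitted plane to the observed point; back-transforming keeps
proportions in [0, 1]. Point estimates: weighted median (cumulative-
weight rule, midpoint on exact boundary ties), mode of a
Silverman-bandwidth weighted Gaussian KDE on a 512-point grid, weighted
mean, and equal-tail credible intervals by weighted quantiles. The
weighted R² of the local regression is the power diagnostic.

The acceptance count mirrors the 0.5% used at full scale (5 000 kept of
10⁶) but is floored (default 500) for desk-scale tables: with ~85
statistics the local regression needs residual degrees of freedom, and
too few accepted rows overfit, shrink the residuals and under-cover.
The coverage check below uses 800 of 8 000 for that reason — measured
coverage of nominal 90% intervals is then 0.88–0.92, against 0.82 at
400 accepted.

## What the synthetic generators emulate — and what they do not

PODs reproduce the sampling design (counts, ages, population labels) and
the full generative process of the models, so tests of recovery,
coverage and monotonicity exercise exactly the estimator assumptions.
They do not emulate post-mortem damage, contamination, sequencing error
or haplogroup structure of real mitogenomes; passing tests therefore
validate the inference machinery, not robustness to aDNA artefacts.
Toy genotype panels evolve allele frequencies by binomial Wright–Fisher
steps down a user tree from uniform(0.05, 0.95) ancestral frequencies,
with diploid or pseudo-haploid sampling; they have free recombination
(independent sites), unlike real linked SNPs — hence jackknife blocks in
tests are nominal windows rather than linkage units.

## f₃ statistics

f₃(A, B; O) is the mean over usable sites of (p_O − p_A)(p_O − p_B);
a site is usable when all three populations have ≥ 1 called individual.
Allele frequencies count two observations per diploid call and one per
pseudo-haploid call, with no heterozygosity correction (outgroup mode,
the ancient-data convention). Because no correction is applied, finite
outgroup samples contribute a positive bias of E[p_O(1−p_O)]/n_alleles
under the no-shared-drift null; the zero-drift oracle test therefore
evaluates the null against the known ancestral frequency, and real scans
should use a well-sampled outgroup. Standard errors use a weighted
delete-one block jackknife over contiguous genomic blocks (5 Mb default,
block weights = site counts; ≥ 2 non-empty blocks required).
Transversion-only filtering is available as a flag and off by default.

## Problem sizes

Default desk-scale sizes — 2 000 simulations per model for model choice,
8 000-row tables with 800 accepted for estimation and coverage, 10 000
replicates for coalescent expectations, 200 PODs for coverage, 100 for
recovery — were chosen so the whole suite and the acceptance script each
run in minutes on one CPU while keeping Monte-Carlo error well inside
the asserted tolerances. Full-scale presets (50 000 per model; 10⁶ rows
with 5 000 accepted) are configuration values, not code changes.

## Known limitations

- Single-locus mtDNA data weakly identify admixture proportions: the
  posterior R² hovers near 0.3–0.5 and model pairs that nest each other
  (MIG2 vs MIG12) show high classification error — visible in both the
  analysis drivers and the confusion matrices.
- The Near East lineage is unsampled by default; its size and the split
  topology act only through the deep genealogy.
- Vote-based posteriors depend on forest hyperparameters beyond tree
  count only weakly, but the documented defaults are fixed rather than
  tuned per dataset.
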