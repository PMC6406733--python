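# Methods

This note records the models, estimators and numerical choices behind
exprphylo, the defaults that matter, and what the synthetic-data
validation does and does not demonstrate.

## Expression phylogenies

Samples are taxa, genes are characters. All tree methods assume genes are
exchangeable, independent characters — co-regulation is ignored, which
inflates apparent certainty (bootstrap supports) on real data relative to
the i.i.d. simulations used here.

**Distances and NJ.** Distances are computed over all genes on log2-scale
values (linear input is log2(x+1)-transformed first; the scale is recorded
on the matrix). The default metric is Euclidean; Manhattan and
1 − Pearson are available, and the chosen metric is recorded in every
summary because figure-level comparisons depend on it. NJ uses the
Studier–Keppler Q criterion with a deterministic tie-break (smallest index
pair). Negative branch-length estimates, a known NJ artifact, are clamped
to zero with the deficit moved to the sibling edge so downstream consumers
see non-negative lengths; the clamp changes path lengths only on
non-additive inputs. Rooting inserts the root at the midpoint of the edge
separating the outgroup (the untreated time-0 replicates) from the rest.
When called through the model front end and the outgroup replicates are
not monophyletic (which happens only in noise-dominated regimes), rooting
falls back to a single outgroup leaf; the low-level `root_at` keeps the
strict monophyly contract.

**Discretization.** States are 0/1/2 for down/constant/up relative to the
outgroup mean, at cut-off τ: state = 2 if log-ratio ≥ τ, 0 if ≤ −τ, else
1. τ is selected by maximizing the parsimony-informative character count
over a grid — by default 21 points between the 50th and 99th percentile of
|log-ratio|, spanning "almost nothing constant" to "almost everything
constant". The objective is non-monotone (raising τ can *create* an
informative character by merging singleton states into a constant pair),
so the entire grid is evaluated; ties go to the smallest τ. The outgroup
itself enters the matrix as an all-constant taxon so discrete trees can be
rooted on it, and it is included in the informative count by default (a
flag records the choice).

**Parsimony.** Fitch's algorithm on state-set bitmasks, vectorized across
characters; scores are rooting-independent. Uninformative characters cost
a topology-independent constant (number of observed states − 1), so the
search scores only informative characters and adds the constant back —
identical argmax, faster scan. Exhaustive search enumerates all (2n−5)!!
unrooted topologies up to 9 taxa and reports all co-optimal trees (capped
at 100); beyond that, a greedy NNI hill climb starts from the NJ tree on
mean character differences and stops at a local optimum, keeping the first
tree found at each improving score.

**Likelihood.** The Mk model with k = 3 equally frequent states and one
exchange rate; branch lengths are expected changes per character, with
P_same(b) = 1/3 + (2/3)·exp(−1.5·b). Pruning runs on compressed site
patterns with per-node rescaling (guards underflow on long trees).
Branch lengths are optimized one edge at a time by bounded Brent on
[0, 10] (P_same(10) is within 4·10⁻⁷ of 1/3, so longer branches are
unidentifiable), tolerance 1e-6, sweeping until the log-likelihood gain
drops below 1e-8 or 50 sweeps. During *topology search* candidate trees
are scored with a cheaper setting (4 sweeps, tolerance 1e-4) and the
winning topology is then re-optimized at full precision; the final
reported likelihood is always the precise one. No rate heterogeneity and
no ascertainment correction for constant characters are applied.

**Bootstrap.** Characters (or genes, for NJ on expression) are resampled
with replacement; each edge's support is the percentage of replicate trees
containing the same bipartition, mapped onto the point-estimate tree (no
consensus tree is constructed). Supports are reproducible given (seed,
n_reps).

**Temporal-order score.** Kendall τ-b between each leaf's known time rank
and its divergence order — the depth (edge count from the root) of its
parent node. On a caterpillar whose deepest cherry holds same-rank
replicates the score is exactly ±1; with multi-replicate clades the
within-clade sub-structure creates harmless rank ties, so a perfect
27-leaf replicate tree scores ≈ 0.93 rather than 1.0. The score is used
comparatively (against shuffles and across noise levels), not as an
absolute calibration.

**Major clades and differential genes.** The two children of the root
(after pruning the outgroup) define the clade split. The default
differential test is Welch's unequal-variance t per gene with
Benjamini–Hochberg correction at q < 0.05; within-clade variance then
includes biological drift across the time points inside a clade, which is
the intended null. The synapomorphy mode (state uniform within each clade,
different between) is the stricter, phylogenetically natural alternative
when replicates are scarce.

**Enrichment.** Per set, the upper-tail hypergeometric p of the overlap
between the query and the set, both intersected with the universe (by
default, all genes on the array — the measured background, not the GMT's
vocabulary). The family-wise adjusted p follows the min-p permutation
construction: the fraction of n_perm random same-size queries whose
minimum raw p across the whole collection is ≤ the observed set's raw p.
n_perm defaults to 1000. The minimum adjusted p is uniform under the null
by construction; its rejection rate at 0.05 is checked empirically.

## Drug-screen scoring

Resistance is the viability fold change FC = mean(TGF-β)/mean(vehicle)
per drug, computed per plating density and then averaged (densities act as
replicates); FC > 1 calls the drug resistant, < 1 sensitive. No plate
normalization is applied by default; FC is invariant to any per-plate
scale factor that hits both conditions. Re-sensitization is assessed over
the drugs resistant in the control arm; the default rule calls a drug
re-sensitized when its knockdown-arm FC falls to ≤ 1 (symmetric with the
resistance definition), with a relative-drop rule (FC_kd ≤ FC_ctrl·(1−f))
available for sensitivity analysis. QC fits OLS of control-well (empty +
DMSO) signal on the row-major well index pooled across plates and reports
R²; R² > 0.1 raises a flag. Density reproducibility is the Pearson r
between per-drug mean signals at low vs high density, per treatment.

## Synthetic data: what it emulates

**Time course.** Per gene, a latent Gaussian random walk over the ordered
time points (step sd `drift_sd`), observed per replicate with i.i.d. noise
(`noise_sd`); an optional signal subset shifts by ±`signal_shift` log2
units at every rank ≥ `signal_onset`, with a fixed random sign per gene.
Rank 0 is the outgroup. The random walk makes expected squared distance
additive in time separation — the regime where NJ provably recovers the
chain — so the generator is a principled positive control for temporal
ordering. Defaults are 2000 genes, 9 ranks × 3 replicates, drift 1.0,
noise 0.05, matching a microarray treatment series in size; temporal-order
validation uses exactly these. For planted-signal recovery the generator
is run at drift 0.25 with shift 2.0 on 10% of genes from rank 4: a
differential program can only dominate the clade split when the treatment
response exceeds the accumulated background drift (at drift 1.0 the
early/late drift displacement, sd ≈ 1.7, would mask a 2-unit shift for a
large fraction of genes regardless of the test used — a property of the
generative model, not of any estimator).

What the generator does *not* emulate: probe effects, intensity-dependent
noise, gene–gene correlation, batch structure. Passing the recovery tests
shows the estimators are correct and well-calibrated under their own
assumptions, not that real microarray series will order this cleanly.

**Screen.** One well per drug per plate, a plate per treatment × density,
DMSO and empty controls interleaved evenly across the 384-well layout so
position and well kind are not confounded in the QC regression. Well
signal = baseline × density factor × drug survival × condition multiplier
× LogNormal(cv), plus an optional linear positional gradient. Non-resistant
drug (and DMSO) wells under TGF-β carry a growth-arrest multiplier
`tgfb_effect` (used at 0.8 in validations): with a perfectly neutral null
the fold-change distribution would straddle 1.0 and exact planted-set
recovery at the threshold would be impossible for any scorer, whereas with
arrest vs protection (0.8 vs 1.5) the calls separate cleanly below 5% CV.
Validation plants 71 resistant drugs of 119 and re-sensitizes 29 of them
in the knockdown arm, so the computed percentages (≈ 60% resistant, ≈ 41%
re-sensitized) are directly comparable to the screen design the package
targets.

## Problem sizes and determinism

All validation runs are sized to desk-scale: oracle comparisons use ≤ 10
taxa (NJ), ≤ 6 taxa × all 105 topologies (Fitch), ≤ 5 taxa (likelihood
enumeration and 3ⁿ pattern sums); calibration uses 500 null enrichment
trials at 250 permutations and a 10,000-rep oracle at matched precision;
simulation studies use 20 seeds at the full 2000 × 27 time-course size.
Every stochastic component takes an explicit seed through
`numpy.random.default_rng`; nothing touches global random state, and equal
seeds give byte-identical outputs.

## Known limitations

- NNI hill climbs can stop at local optima; on clean simulated signal they
  match the exhaustive optimum ≥ 90% of the time (tested), but ratchet or
  TBR searches are out of scope.
- The Mk likelihood ignores among-character rate variation; strongly
  heterogeneous responses will look artificially clock-like.
- Bootstrap support under many weakly informative characters concentrates
  on whatever the point estimate is; supports on real, correlated gene
  sets should be read comparatively.
- The screen module is single-dose by design: no IC50 or dose–response
  fitting, and drug→pathway grouping is a user-supplied join.
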