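# Methods

This note documents the models, conventions and numerical choices
behind `germid`, and what the synthetic-data tests do and do not
establish about real collections.

## Genotype coding

Variant callers for high polyploids emit GT fields at ploidy 4 or
higher; single-dose biallelic markers are informative only through
allele *presence*. `read_vcf` therefore collapses a GT of any ploidy to
0 (no alternate allele), 2 (no reference allele) or 1 (both present).
This is the only coding under which observed heterozygosity lies in
[0, 1] and biallelic gene diversity is capped at 0.5, which is how the
downstream statistics are defined. Depth filters (total depth ≥ 20,
each claimed allele supported by ≥ 2 reads) apply only when the VCF
carries DP and RO/AO (or AD) fields; CSV input is assumed pre-called.
Missing is explicit everywhere; nothing is imputed.

## QC filter order

The retention rules run markers → samples → monomorphic → MAF:
markers with ≥ 10% missing, then samples with ≥ 10% missing (recomputed
on surviving markers), then monomorphic markers, then markers with
MAF < 5% (computed on surviving samples). The source protocols state
the rules but not their order; this order is a documented convention
and the QC report makes every stage auditable. Both missing-rate
filters drop at *greater-or-equal* ("10% or more").

## Duplicate and homonym calls

"Allele difference" is Σ|g_a − g_b| over loci called in both samples
(a hom/hom mismatch counts 2); a per-locus mismatch count is available
as an alternative metric, and grouping, calibration and homonym calls
all use the same metric. Error calibration takes the modal code among
≥ 3 clonal replicates as the per-locus consensus; tied loci carry no
majority signal and are excluded from both the deviant and the called
count. The mismatch threshold is the *maximum* pairwise difference
observed within the control — the budget a genuine clone pair can
exhaust through error alone. Duplicate groups are transitive closures
(connected components at ≤ threshold); pairs with zero shared loci are
undefined and never create edges.

A consequence worth stating: with per-call error ε ≈ 9.3e-4 on 357
loci, a clone copy occasionally accumulates two errors (≈ 4.5%
probability per copy) and can then exceed a control-derived threshold
against *every* member of its group. Exact recovery of a planted
clonal partition is therefore a high-probability event, not a
certainty; the test suite runs this check over five fixed fixtures and
the per-fixture behavior is exactly this binomial.

## Probability of identity

Per-locus PIDsib follows the standard sibling-pair formula
(0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴); unit tests pin it to a brute-
force enumeration of Hardy–Weinberg parental pairs and Mendelian sib
draws to 1e-12. The cumulative curve orders loci by ascending per-locus
PIDsib ("most informative first"), the convention used by standard
genetic-identity software, so the value at rank k is the power of the
best k-locus sub-panel; per-population curves use population-specific
frequencies.

## Differentiation and diversity

θ is the Weir–Cockerham variance-components estimator with the
heterozygosity correction, combined across loci as a ratio of sums.
Permutation p-values use the add-one convention,
p = (#{θ* ≥ θ} + 1)/(n_perm + 1), so p ∈ (0, 1]. AMOVA partitions the
squared-Euclidean genotype distance (pairwise-complete, rescaled by
total/shared loci) into among- and within-population components with
n₀ weighting; negative among-components are floored at zero before
percentages. One distance kernel feeds AMOVA, PCoA and the NJ tree.
PCoA is Gower double-centering with negative eigenvalues reported but
excluded from the percent-variance denominator; neighbor joining
breaks Q-criterion ties toward the lexicographically lowest leaf pair
and clamps negative branch lengths to zero, transferring the deficit
to the sister branch so leaf-to-leaf path lengths are preserved.
scikit-bio's independent implementations serve as oracles in the test
suite; they are never on the computation path.

## Admixture model

The sampler implements the admixture model with *independent* cluster
allele frequencies (flat Beta(1,1) prior) and fixed α = 1.0; the
correlated-frequencies variant is deliberately out of scope — at the
differentiation levels simulated (F ≈ 0.07–0.32) the independent model
separates populations cleanly, and one sampler serves both the
unsupervised scans and the supervised assignment (reference allele
copies pinned to their species cluster). Posterior means of Q and P
are accumulated after burn-in; the data log-likelihood trace feeds the
Evanno table. Library defaults are burn-in 2,000 / 5,000 retained
sweeps, sized for desk-scale panels; the original protocol's
50,000/100,000 is a parameter choice away.

Mixing caveat: on panels with little information (the degenerate case
being a monomorphic panel), the z–Q coupling makes cluster-label
collapse sticky, and the posterior-mean Q approaches the symmetric 1/K
only after long chains on small panels. This is a property of the
Gibbs scheme, not of the model.

**Model selection.** ΔK(K) = mean over runs |L(K+1) − 2L(K) + L(K−1)|
divided by the across-run sd of L(K), interior K only, with runs paired
by index; zero sd reports ∞. ΔK cannot test K = 1 — it produces
positive values on homogeneous data where L(2) ≤ L(1). Hierarchical
re-runs therefore split a cluster only when (a) the ΔK peak clears a
floor (default 5), and (b) mean L(K*) exceeds mean L(K_min) by an
AIC-style margin of 0.5·(K*−K_min)·(n_loci + n_samples), the
overfitting headroom of the extra parameters. In every simulated
structured scenario genuine gains exceed this margin by 1–3 orders of
magnitude. Replicate runs matter: with only 2 runs per K the sd
denominator is unstable, so 4+ runs are used in tests (the original
protocol used 10). Clusters below 10 members are never re-split.

**Assignment and mislabels.** Queries are called as the species with
mean Q > 0.80 over replicate runs (strictly above, the core-member
cutoff reused), otherwise as an inter-specific hybrid annotated with
the two largest-ancestry species. `flag_mislabels` distinguishes four
outcomes: `ok` (concrete record confirmed), `mislabel` (concrete record
contradicted by a *concrete* inferred species), `admixed` (concrete
record, but no species reached the call threshold), and
`clarification` (record was 'unknown'/'hybrid'). The admixed category
is deliberate: at realistic divergence a fraction of genuinely pure
individuals sits below Q = 0.80 (the motivating study likewise
retained only ~70% of clones as core members), so a sub-threshold call
is evidence of admixture, not of a wrong record. The recovery property
that holds — and is tested — is that planted mislabels are never
confirmed `ok`, and correctly labelled pure clones are never
confidently called `mislabel`.

## Synthetic genebank generator

The generator encodes the study conditions as defaults: 357 loci;
ancestral MAF ~ Beta(2, 11) restricted to [0.05, 0.5] (mean ≈ 0.153,
alternate allele on a random strand); six populations with the census
19/62/104/28/99/100 and Balding–Nichols parameters
{0.15, 0.26, 0.08, 0.32, 0.20, 0.22}, giving expected pairwise θ of
(F_i + F_j)/2 spanning ≈ 0.07–0.32; ten clone groups of size 2–5 plus
a 12-replicate control, each copy perturbed per call with probability
ε = 9.3e-4 (replacement uniform over the other two codes — error
direction is not characterized, so none is modelled); F1 hybrids drawn
one gamete per parent species; uniform missing calls at 1.5e-3; planted
homonyms and species mislabels. Everything planted is recorded in
`SimTruth`.

What the generator does *not* emulate: linkage between loci, polyploid
dosage and aneuploidy, somaclonal mutation, and the heterozygosity
excess (H_obs > H_exp) real clonally propagated, intercrossed material
shows — species draws are Hardy–Weinberg. Passing recovery tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to those unmodelled features.

## Problem sizes in the test suite

Deterministic oracles run at full scale (e.g. the 12 × 357 replicate
arithmetic; 357-locus PID panels; 100-per-population θ recovery at
F = 0.073 and 0.323 over 10 seeds). MCMC-based checks run on scaled
panels chosen for chain length: 3 species × 20–25 samples at 100–357
loci with 2–4 runs of 150/300 sweeps for ΔK, hierarchical and
assignment recovery, five seeds each. These sizes are the package's
test protocol; all thresholds quoted above are independent of them.
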