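# Methods

This note documents the statistical models and procedures implemented in
`ssrpop`, their assumptions, the parameters that matter, and the design
choices made where the standard literature leaves room.

## Data model

A genotype panel is an individuals × loci table of unordered diploid allele
pairs; alleles are integer fragment sizes (bp) assumed pre-called — no
binning of ±1 bp sizing error is attempted. Missing calls are whole-cell: a
diploid cell cannot be half missing, so any operation that would invalidate
one copy (e.g. rare-allele removal) blanks the cell. All frequency-based
statistics use per-locus ("pairwise") deletion of missing calls, so per-locus
sample sizes n_l differ; this matches how mixed-completeness SSR panels are
normally summarized and is applied consistently in every module. File
dialects follow field conventions: `.` missing in the native TSV, `-9` in the
two-row STRUCTURE layout, `0` in the GenAlEx-like two-columns-per-locus
layout.

The packaged marker map places 48 SSRs on peach's 8 linkage groups with
genetic (cM) and physical (scaffold:bp) coordinates. Genetic distance is
defined only within a linkage group, physical distance only within a shared
scaffold — the code requires scaffold equality rather than assuming scaffold
N equals linkage group N.

## Diversity statistics

Per locus: Ao (distinct alleles), Ae = 1/Σp̂ᵢ², Ho (fraction heterozygous),
He = 1 − Σp̂ᵢ² (plug-in Nei gene diversity), F = 1 − Ho/He, PD = 1 − Σĝⱼ²
over observed unordered-genotype frequencies (homozygotes included), MAF
(largest p̂ᵢ) and Gn (distinct genotypes). He is uncorrected by default
because published Ae/He pairs for SSR panels are frequently inconsistent
with any single small-sample correction; an unbiased n/(n−1) variant is
available via `unbiased_he=True`. F is undefined (NaN) at a monomorphic
locus (0/0) and excluded from panel means. Panel summaries are arithmetic
means across loci plus the total allele count.

Rarefaction subsamples m individuals **without** replacement (B replicates,
default 100): sampling with replacement would not recover the observed Ao at
m = N, and the purpose of the curve is comparing groups at equal m. The
band is the only distribution-free two-sided interval consistent with a
Chebyshev claim: mean ± k·sd with k = √(1/α) (k ≈ 4.472 at α = 0.05). The
curve reports the per-locus **average** Ao; a summed variant would only
rescale it.

## Band-sharing distances and trees

Individuals are treated as multilocus fingerprints: each observed allele is
a band, pooled over loci into one presence/absence set per individual
(`per_locus_average=True` switches to averaging Dice similarity over
shared-typed loci — the pooled form is the default because that is how
restriction-fragment band-sharing was historically applied to multilocus
data). Distance is 1 − 2n_xy/(n_x + n_y). Missing cells contribute no
bands.

Neighbour joining follows Saitou–Nei with two determinism/validity choices:
Q-matrix ties break at the lowest (row, col) pair, and negative branch
lengths are clamped to zero with the deficit moved to the sibling edge so
path lengths (and Newick output) stay valid. On additive matrices the
topology and path lengths are recovered exactly (asserted to 1e-9, and
cross-checked against scikit-bio's NJ). Bootstrap support resamples loci
with replacement, rebuilds distance + NJ, and reports the percentage of
replicates containing each internal bipartition of the reference tree.
Rooting places the root at the midpoint of the outgroup's pendant edge;
degree-2 relics of a previous rooting are suppressed, making re-rooting
idempotent.

## Admixture model

The sampler is the classic Bayesian admixture model for unlinked,
multi-allelic co-dominant loci. Latent variables: for every allele copy a
cluster of origin z; per individual a membership vector q_i ~ Dir(α·1_K);
per cluster and locus allele frequencies P_{k,l}. Updates are
Dirichlet-conjugate Gibbs for z, Q and P. Two frequency priors:

- independent: P_{k,l} ~ Dir(1,…,1);
- correlated: P_{k,l} ~ Dir(p_{A,l}(1−F_k)/F_k), with ancestral frequencies
  p_A ~ Dir(1,…,1) updated by Metropolis–Hastings with a
  Dirichlet(200·p_A) proposal (Hastings-corrected), and drift parameters
  F_k ~ U(0,1) updated by a logit-space random walk (sd 0.15, Jacobian
  corrected).

α is inferred by a random-walk Metropolis step (sd 0.05) under a uniform
prior on (0, 10], starting at 1.0; it can be fixed. Missing genotypes
contribute no copies (marginalized by omission). The data log-probability
reported per run is mean(logL) − var(logL)/2 over thinned post-burn-in
samples; this estimator is known to sit above the exact marginal likelihood
(the normal approximation under-corrects), which is why the K = 1 sanity
check asserts proximity to the closed-form Dirichlet-multinomial marginal
only within 15%.

Default chain lengths are desk-scale — burn-in 2,000, 10,000 sweeps, thin
10 — chosen so that membership recovery (mean absolute error of aligned Q
vs simulation truth ≤ 0.1 at K = 3, drift 0.2, N = 150, 25 loci) holds
while a full run stays in the tens of seconds; production-scale lengths
(10⁵/10⁶) are plain parameters. Correctness is established by recovery,
not chain length.

**Choosing K.** ΔK = |L″(K)|/sd[L(K)] with L″ computed from the per-K means
of the replicate log-probabilities (the per-repeat variant differs only in
weighting and the literature is ambiguous; one variant is fixed for
determinism). ΔK needs ≥ 3 consecutive K and ≥ 2 repeats, and is flagged
undefined where the replicate sd is 0. The scan driver declares "no
substructure" (K = 1) when ΔK is unavailable or its maximum falls below a
threshold (default 2.0) — for homogeneous data both |L″| and sd are noise
of similar scale, so ΔK hovers near 1, while real structure produces ΔK
one to four orders of magnitude larger.

**Replicate alignment.** Label switching between runs is resolved by the
column permutation maximizing G = 1 − ‖Q − Q′π‖_F/√(2N); exhaustive search
for K ≤ 6, Hungarian assignment on squared column distances above.
Individuals are assigned to their argmax cluster when the aligned mean
membership reaches the threshold (default 0.8), otherwise UNSTRUCTURED.
The nested driver repeats the entire scan inside each assigned cluster,
excluding UNSTRUCTURED individuals and skipping groups below a minimum size
(default 10).

## AMOVA, pairwise Fst, PCoA

Allele copies are the units; distance between copies is identity /
non-identity (infinite-allele view — no stepwise size weighting, since the
analysis makes no mutation-model claim). Per locus, sums of squares for a
set of copies use the counts identity SS = (m² − Σ m_a²)/(2m), partitioned
among groups / among individuals within groups / within individuals;
variance components follow the standard moment equations with the unequal-
size coefficient n_c, and per-locus components are summed across loci
(pairwise-available missing-data handling). Fst = Va/(Va+Vb+Vc),
Fis = Vb/(Vb+Vc), Fit = (Va+Vb)/(Va+Vb+Vc). Negative components are
retained in the ratios (flagged; truncation is an option) to preserve the
unbiasedness of the moment estimators. Permutation nulls respect the
hierarchy — individuals among groups (Fst), copies among individuals within
groups (Fis), copies globally (Fit) — with add-one p-values
(#null ≥ obs + 1)/(n_perm + 1), which cannot return p = 0.

On biallelic data the implementation agrees to 1e-9 with a nested ANOVA on
allele indicator variables computed from explicit deviations. On simulated
drift data it agrees within ±0.03 with a Hudson-style estimator computed
directly from the realized subpopulation allele frequencies — that
estimator is the appropriate frequency-based oracle because, unlike Nei's
Gst, it estimates the same fixed-populations quantity as the
moment-equation Fst.

PCoA is classical metric scaling: Gower double-centering of −d²/2,
symmetric eigendecomposition, coordinates scaled by √λ, axis percentages
over the positive eigenvalues only. Euclidean inputs are reconstructed
exactly; negative eigenvalues (non-Euclidean input) are excluded and a
request for more axes than available truncates with a warning.

## Linkage disequilibrium

"Pairs of alleles" is implemented literally: each allele at a locus is
binarized against all others (dosage 0/1/2), and every ordered pair of
retained binarizations at two distinct loci is one comparison. For a locus
left biallelic after filtering the two binarizations are complements with
identical r²; both records are emitted, with a `unique` flag marking one
per complementary set so counts are not doubled.

Haplotype frequencies for two binarized loci are estimated by EM over the
double-heterozygote phase ambiguity under random union of gametes. Every EM
iterate preserves the observed allele-frequency margins, so the likelihood
has a single free parameter p_AB; with double heterozygotes present it can
be bimodal, so the EM runs from three starts (linkage equilibrium and both
Fréchet-bound extremes) and keeps the highest-likelihood fixed point.
Convergence: max frequency change < 1e-8 or 1,000 iterations;
non-converged records are kept with a flag. D = p_AB − p_A p_B and
r² = D²/(p_A(1−p_A)p_B(1−p_B)); a binarization monomorphic among the
jointly typed individuals yields an undefined (flagged) record.

Rare alleles (frequency < 5% in the input matrix, single pass) are removed
before scanning because they inflate r². Significance is a Monte-Carlo
permutation test (default 999 permutations) shuffling one locus's genotypes
among individuals; its type-I error is calibrated (≈ 5% at α = 0.05 over
1,000 independent-locus replicates). A Fisher-style exact test on haplotype
counts was deliberately not used: the haplotype counts are themselves EM
estimates, not observations.

Decay curves sort intra-chromosome comparisons by distance, split them into
four equal-count adjacent bins, and fit r̄² = a + b·ln(d̄) by least squares
through the four bin means only (an all-points fit is available as an
option). The crossing d* solves the fitted curve at r² = 0.1 and is
declared NO_DECAY when b ≥ 0 or the crossing falls outside (0, 10 × max
distance]. Separate fits are produced for cM and Kbp metrics. The 4-bin
fit is validated against a 20-bin empirical crossing on forward-simulated
panels (agreement within a factor of two).

## Synthetic data

`simulate_structured` draws ancestral frequencies p_A,l ~ Dir(1), cluster
frequencies P_k,l ~ Dir(p_A,l(1−F_k)/F_k), memberships one-hot or
~ Dir(α·1_K), and allele copies through the admixture mechanism. Selfing is
modelled as its equilibrium inbreeding coefficient F_is = s/(2−s): with
that probability the two copies at a locus are identical by descent. This
closed form (rather than explicit selfing generations) gives an exact
Ho/He = 1 − F_is target for tests; the realized ratio matches within 0.03
at N = 2,000. A selfing rate near 0.45 reproduces the Ho/He ≈ 0.78 deficit
typical of a self-compatible crop.

`simulate_ld_panel` assigns each of 2·n_founders founder chromosomes a
unique allele label at every locus and propagates N individuals for G
generations of random mating (selfing with probability s), with crossover
counts Poisson(length/100 cM) and uniform placement — the Haldane model, no
interference — so cM semantics are exact. Few founders ⇒ strong initial
LD; recombination erodes it with genetic distance while unlinked loci decay
toward the 1/(2N) background. Default test geometry uses the packaged
peach map (or linkage groups 1–2 of it where speed matters).

What the generators do **not** emulate: mutation (stepwise or otherwise)
during the simulated generations, genotyping error and allele-size binning
artefacts, null alleles, linked selection, and realistic pedigree
structure. Passing recovery tests therefore demonstrates correctness of
the estimators under their own model assumptions, not robustness to these
real-data complications.

## Pipeline and problem sizes

The `pipeline` subcommand chains diversity → tree → marker thinning
(greedy left-to-right, ≥ 15 cM default) → structure scan with nested
re-clustering → AMOVA / pairwise Fst / PCoA over the inferred groups → LD
per subpopulation, excluding subpopulations below 20 individuals from LD.
Every stage's effective parameters and seeds go into a JSON manifest, and a
rerun with the same config reproduces outputs byte-for-byte.

The test-suite and the acceptance script run everything at reduced problem
sizes chosen so each check still exercises the full code path with clear
statistical margins: recovery chains of a few thousand sweeps on panels of
100–300 individuals and 15–25 loci, 10-seed ensembles for stochastic
properties, LD scans restricted to two linkage groups, and 199–999
permutations. All randomness flows from explicit seeds; the acceptance
script derives every generator from its `--seed` argument.

## Known limitations

- The admixture sampler does not resolve label switching *within* a chain;
  for weakly separated data at large K, posterior-mean Q matrices can blur.
  Replicate alignment mitigates this across runs only.
- lnPD's mean − var/2 form overestimates the marginal likelihood; ΔK (a
  difference-based statistic) is robust to this, but lnPD values should not
  be compared across datasets.
- AMOVA assumes the infinite-allele distance; microsatellite stepwise
  distances (Rst-style) are out of scope.
- The EM r² treats each allele-vs-rest binarization independently;
  comparisons sharing a locus are correlated, and no multiple-testing
  correction is applied to the per-record permutation p-values.
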