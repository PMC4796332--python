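# Methods

This note records the models, algorithmic choices and defaults behind each
pipeline stage, what the synthetic generator does and does not emulate, and
the package's known limitations.

## Data model

Genotypes are **derived-allele dosages** {0, 1, 2} with a distinct missing
sentinel; polarity (ancestral/derived per SNP) is panel configuration, not
inferred.  The bundled 19-locus default panel carries nine real rs
identifiers from the studied intronic region; the other ten locus ids and
all base assignments except the core motif (derived A,G,G,A,A) and
rs150877473 (C→G) are synthetic placeholders, flagged as such in the config
file, to be replaced when real assay metadata is available.  The VCF reader
converts GT fields against the panel's derived allele — not the ALT allele —
so files where REF is the derived base are handled correctly.

Altitude classes partition the line: high > 3000 m, medium = [2000, 3000] m
(closed, so the printed boundary inequalities partition with no gap), low
< 2000 m.

## QC

Filter order: sex concordance → per-sample missingness (strict >20%) →
per-SNP missingness (strict >30%).  The composition is idempotent.
Concordance statistics exclude pairs with a missing call from the
denominator, which makes duplicate concordance independent of the
missingness rate; an empty denominator yields NaN, never 0.  Genotype sex is
an input column, not inferred — the panel is autosomal and sex inference
would require assay-external information.

## EM phasing

Haplotype frequencies maximize the random-mating multinomial likelihood
L(f) = Π_samples Σ_{(h,k) compatible} c_hk f_h f_k (c_hk = 2 for h ≠ k) via
EM over all haplotype pairs compatible with each genotype; missing sites sum
over both completions.  Samples with more than 20 ambiguous (heterozygous or
missing) sites are refused with advice to window the locus set.
Initialization puts weight on haplotypes observed as completions of
(near-)unambiguous samples plus a 1e-6 pseudocount on every other compatible
haplotype; seeded Dirichlet restarts are available and used in the
optimality tests.  Convergence: |Δ log L| < 1e-8 or 1000 iterations;
monotonicity is asserted at every iteration.  Best pairs maximize f_h·f_k
with lexicographic tie-breaking, so output is deterministic.

This deliberately replaces coalescent-informed phasing: at ~19 tightly
linked SNPs with two deep haplotype clusters, the EM estimator phases
cluster-structured sites essentially perfectly (linked-loci switch error
< 1% on synthetic surveys).  Sites in linkage equilibrium with the rest of
the panel — including the generator's altitude-independent loci — are
unphaseable from genotype data by *any* statistical method, and drive the
overall synthetic-survey switch error to ~15%; published haplotype counts
from sampler-based tools are therefore treated as approximate references,
never exact targets.

## Core-haplotype statistics

Population core frequencies are counted over hard best-pair assignments
(2 × retained samples chromosomes per population), matching count-based
reporting; a posterior-weighted variant is available.  The altitude
correlation is Spearman's ρ with midrank ties; the two-sided p-value is
exact by exhaustive permutation for n ≤ 8 populations and the
t-approximation above that (the asymptotic regime of a ~55-population
survey).  The shared-derived-allele filter returns loci that are derived,
carried by the archaic reference haplotype, present in every carrier and
absent from every non-carrier; its output shrinks monotonically as
non-carriers accumulate.

## Median-joining networks

Binary states only; edge weights are Hamming distances.  The construction
iterates: build the ε-relaxed minimum spanning network (ε = 0 default — the
union of all minimum spanning trees), propose the majority-consensus median
of every mutually linked triplet, and greedily add the median that most
strictly reduces the total minimum-spanning-tree cost (sorted iteration
makes ties lexicographic and the build deterministic).  Obsolete medians
whose removal leaves the cost unchanged are dropped; an optional
maximum-parsimony pass (off by default) additionally removes medians on no
shortest observed-to-observed path.  Termination is guaranteed because every
addition strictly reduces an integer cost.  On instances with ≤ 6 observed
haplotypes the final cost equals the brute-force minimum Steiner cost over
all candidate median subsets (verified in tests).

## Selection inference (island model)

Stationary density π(p) ∝ p^(Mπ̃−1)(1−p)^(M(1−π̃)−1)e^(σp) with genic kernel
e^(σp) — the minimal form consistent with σ = 2Nₑs; the normalizer is
B(a,b)·₁F₁(a; a+b; σ) (a = Mπ̃, b = M(1−π̃)), evaluated in log space with the
large-argument asymptotic ₁F₁(a;c;x) ≈ Γ(c)/Γ(a)·eˣ·x^(a−c) beyond x ≈ 600.
σ = 0 reduces exactly to Beta(Mπ̃, M(1−π̃)).

Inference is Metropolis-within-Gibbs, vectorized over demes × loci: logit
random walks for p_ij and π̃_j, a log random walk for M (log-uniform on
[0.1, 1000]), Gibbs for the locus shrinkage rates δ_j (σ_ij ~ Exp(δ_j),
δ_j ~ Exp(0.01)), and for σ_ij a reflected random walk mixed (20%) with a
long-tailed exponential independence proposal.  The mixture matters: with
hierarchical shrinkage the joint (σ, δ) posterior is bimodal when selection
is strong, and a pure random walk cannot cross between the σ≈0 and
strong-selection modes.  σ is initialized by moment matching (the σ at which
the stationary mode equals the observed frequency), which removes an
ignition race in which δ inflates before divergent demes can escape zero.
Pilot runs adapt proposal scales toward 25–45% acceptance.  Default schedule
follows the emulated tool (25 pilot runs × 1000, burn-in 25,000, thinning
25); tests and the acceptance script use reduced schedules (burn-in
1500–4000, 600–4000 draws) sized for a single core, with accuracy checked
against dense-grid numerical posteriors (marginal σ means within 5% on a
two-deme instance).

Two model-level caveats, documented rather than patched:

- selection is genic on the **derived** allele (σ ≥ 0); demes below the
  migrant-pool frequency are fitted through π̃_j and drift, not negative σ;
- a *single* selected deme among many neutral ones at moderate effect size
  (σ ≈ 100, n = 200 chromosomes) is statistically marginal under any
  shared-rate shrinkage hierarchy (the divergence evidence from one
  frequency is ~12–15 nats at any M); detection is reliable when several
  demes share the signal, which is the emulated study design (three
  high-altitude demes), and the recovery tests use that design.

Deme composition matters: the island model needs reference loci and
reference demes of similar frequency to pin M.  A gradient survey where
every deme differs at every locus is read as high drift (small M) and
yields shrunken σ — fits should use a contrast design (several homogeneous
lowland demes + the highland demes), as the examples do.

Association: per-locus OLS of altitude on coded genotype (additive = dosage;
dominant = any derived; recessive = two derived), two-sided t-test, missing
dosages dropped per locus; monomorphic loci give NaN rows, and an exactly
collinear fit reports the 1e-300 floor rather than zero.  A by-population
weighted variant (population mean coding regressed on altitude, weights =
calls) covers the other reading of frequency-based association.  No
multiple-testing correction is applied; a Bonferroni column is trivial to
add downstream.

## Forward simulation

Discrete generations: deterministic viability selection under
Hardy–Weinberg, then Binomial(2N) drift.  Scenario defaults: generation time
30 y (2800 y → 93 generations, 10,000 → 333, 30,000 → 1000); ancestral
Nₑ 10,000; lowland daughter 5,000; selected highland daughter 1,000, with
s = σ/(2·Nₑ(selected)).  The highland size is a stand-in chosen from the
deterministic recursion (fixation time ≈ (2/s)·ln(p'q/pq')): with σ ≈ 118 it
must be well under ~4300 for fixation inside 1000 generations, and ~1000
reproduces both qualitative anchors at once — fixation by ~300 generations
under an old split, and 0.05–0.1 starting frequencies reaching the 0.4–0.7
range within ~93 generations.  A small bottlenecked highlander deme is also
the demographic regime the relevant literature describes.  Selection acts
only post-split in the selected population; there is no migration after the
split and no recombination (single locus).  Each replicate runs on its own
spawned SeedSequence child, so any replicate reproduces in isolation.

## Synthetic data generator

Haplotype-level simulation from two clusters: a core cluster (two
haplotypes carrying the five-SNP motif on a derived upstream backbone plus
the downstream regulatory SNP) and four background haplotypes each ≥ 6
mutational steps away, echoing the observed six-SNP cluster separation.
Per-chromosome cluster membership is Bernoulli(core_freq_fn(altitude)); the
default map is logistic, near zero below 1000 m and ~0.75 above 4000 m.
Three mid-panel loci carry altitude-*independent* polymorphism (defaults
0.25–0.45) — the analogue of the panel region showing no selection in any
population, and the feature that lets the island model anchor its migration
rate on synthetic surveys.  Realism injected on top: 1% per-call genotyping
error (duplicate-pair concordance ≈ 98%), a 15% subpopulation of failed
samples with 40% missingness (so the >20% sample filter has real work, as
in the emulated survey where ~19% of samples were removed), duplicate
aliquot pairs and sex-discordant samples in the counts of the emulated
survey (283 and 79 at full scale).

Not emulated: coalescent history (no recombination, no mutation during
sampling, no within-cluster diversity gradient), genotype-intensity-level
artifacts, and real allele labels beyond the documented panel entries.
Passing tests therefore demonstrate correct *inference machinery* under the
assumed data structure, not robustness to demographic confounding.

## Problem sizes

Test-suite and acceptance-script runs use desk-scale sizes chosen as the
package's own defaults for a single core: surveys of 12–20 populations ×
30–40 samples, MCMC schedules of a few thousand sweeps (checked against
grid posteriors), 50–100 simulation replicates per grid cell.  The full
paper-scale schedule (25,000-step burn-in etc.) remains the library default
for real analyses.

## Known limitations

- The EM phaser has no recombination model; its haplotype *count* is not
  comparable to sampler-based tools' counts.
- The selection kernel is genic and one-sided (derived advantage only).
- Median-joining supports binary states only (no multistate, no indels).
- The network frequency>1 filter plus genotyping error can place rare error
  haplotypes between the two clusters, shrinking the reported separation
  below the designed six steps on noisy synthetic surveys.
- The forward simulator's effective sizes are documented stand-ins;
  quantitative statements tied to them (e.g. exact fixation timing) are
  scenario properties, not estimates.
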