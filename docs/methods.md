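# Methods

## The model

A microbial community is modelled as a set of S genetic lineages (OTUs at
dissimilarity radius d; d = 0.03 is the species-level convention). Each
lineage i holds N_i individuals with

    N_i = max(1, round(exp(Z_i))),   Z_i ~ Normal(μ, σ),

a discretized log-normal species-abundance distribution. Sequencing is
idealised: every individual yields one error-free read of its lineage's
sequence region. The planted generator realises this literally: one seed
sequence per OTU, mutually farther than a minimum separation s; each
additional member is the seed mutated out to dissimilarity m (default
0.0125) by single point-mutation events; the first member of each OTU is
the unmutated seed itself. The x2/x3 variants duplicate or triplicate
every read, modelling communities in which no lineage is represented by a
single individual.

The triangle inequality gives the recovery guarantee the tests rely on:
members of different OTUs are farther than s − 2m apart, so clustering at
threshold d recovers exactly the planted partition whenever
s > d + 2m. Fixtures use s = 0.06 with m = 0.0125 and d = 0.03 for
headroom; in practice rejection-sampled random seeds are far more
separated than the bound requires.

## Dissimilarity and clustering

Pairwise dissimilarity is (mismatches + indel columns) / alignment length
on a unit-cost global (Needleman–Wunsch) alignment, computed with edlib.
Among co-optimal alignments the reported alignment length can differ
between argument orders, so arguments are canonically ordered before
alignment, making the measure exactly symmetric and deterministic. This
convention (indels count; denominator is the alignment length) is the one
common clustering tools use; OTU counts depend on it, so it is fixed
explicitly.

Greedy clustering dereplicates identical sequences, processes unique
sequences by decreasing duplicate count (ties: decreasing length, then
id), and assigns each to the first centroid within d (first-fit; best-fit
is available behind a flag), else founds a new cluster. Two performance
guards never change results on data this package targets: a k-mer
prefilter (k = 8, ≥ 50% of the query's distinct k-mers shared; t edits
destroy at most t·k of ~L−k+1 k-mers, so centroids within d of an
amplicon-length query always survive) and a banded alignment capped at
⌈2·d·max_len⌉ + 8 edits (distances beyond the band exceed d anyway). The
brute-force oracle computes all C(n,2) full alignments and takes
single-linkage connected components — the most permissive grouping, chosen
because an all-vs-all grouping has no canonical linkage; greedy/oracle
discrepancies are possible on poorly separated data and are treated as a
property of the data, not hidden.

## Estimators

Bias-corrected Chao1: S_obs + F₁(F₁−1)/(2(F₂+1)), finite when F₂ = 0.
ACE with rare cutoff 10: S_abund + S_rare/C + (F₁/C)·γ², with coverage
C = 1 − F₁/N_rare and γ² the rare-class coefficient of variation term,
floored at 0. Degenerate branches follow the common EstimateS convention:
no rare clusters → S_obs; C = 0 (all rare clusters singletons) → fall back
to bias-corrected Chao1. These exact branches matter because all-singleton
synthetic communities hit them.

Rarefaction draws without-replacement subsamples of the fixed full
clustering (no re-clustering per depth, matching standard pipeline
practice) on the grid {step, 2·step, …, N}, always ending at N exactly,
with a fresh independent subsample per (iteration, depth) pair. The
hypergeometric closed form E[S(n)] = Σ_j [1 − C(N−N_j, n)/C(N, n)] serves
as the analytic oracle for the Monte-Carlo mean. Curve diagnostics are the
arithmetic mean of the last k points and the mean successive difference
over the last k steps; the slope is reported per rarefaction step (not per
read) — a unit choice that is stated rather than assumed, since end-of-
curve slopes are only comparable within one step size.

## Log-normal fitting — two estimands

`fit_lognormal(av, method="moments")` (default) is the continuous ML fit
on log sizes: μ̂ = mean, σ̂ = ML standard deviation, with asymptotic
standard errors σ̂/√S and σ̂/√(2S). It describes the *observed* size
distribution and is exactly shift-equivariant: doubling all sizes moves μ̂
by log 2 and leaves σ̂ unchanged — the right tool for comparing a dataset
with its duplicated variant.

`method="discretized"` fits the actual generative model
max(1, round(exp(Normal(μ, σ)))) by maximum likelihood (size 1 collects
all mass below 1.5; size k ≥ 2 the mass in [k−½, k+½)), with standard
errors from the observed information. The distinction matters: for
realistic (μ, σ) the floor at 1 puts roughly a third of the probability
mass on singletons, which biases the moment μ̂ upward by ~0.15 — so
recovering *generator* parameters requires the discretized fit, while the
moment fit remains the estimator whose equivariance mirrors the
duplication experiment. Nelder–Mead from the moment starting point; an
all-identical size vector short-circuits to a degenerate flag (σ̂ = 0).

## Synthetic-data scenarios

`make_scenario` wraps a planted community with nuisance reads whose fate
under the pipeline is forced, turning probabilistic arguments into exact
bookkeeping: unlabeled reads are taken as (seed read, one member) pairs
from distinct multi-member OTUs — at most m + tol ≈ 0.0155 < d apart, so
each pair survives the unclassified-singleton filter as a size-2 cluster;
planted unclassified singletons are rejection-sampled farther than
2d + m from every seed (hence, by the triangle inequality, farther than d
from every read), so each is dropped; contaminants and chimeras never
reach clustering. The truth report thus predicts every stage count
exactly, and the end-to-end test compares them with equality, not
tolerance.

## Parameter defaults and scale

- d = 0.03 (species-level OTU radius); rare cutoff 10 (classic ACE);
  rarefaction step 100 reads, 10 iterations.
- member distance m = 0.0125; distance targeting tolerance tol = 0.003
  (one event on a 250-nt read moves the distance by ~0.004, so a narrower
  band would be unreachable); mutation event mix 0.35/0.35/0.15/0.15
  (transition/transversion/insertion/deletion) — substitutions dominate,
  indels present.
- seed length 250 nt by default, a typical pyrosequencing amplicon;
  simulations in the test and acceptance suites use 25–200 OTUs
  (hundreds to ~1500 reads), a deliberate scale-down from
  tens-of-thousands-read field studies. The phenomena exercised —
  singleton-driven overestimation, x2 convergence, duplication
  equivariance, greedy/oracle agreement — are scale-free in these
  regimes, so the qualitative findings transfer; absolute estimator
  values of course do not.
- `mutate_to_distance` applies one event at a time, re-measuring the
  distance to the original; overshooting the band restarts from the
  original; budget 10·target·len events (min 50).

## What the simulator does not model

Reads are error-free and full-region: no position-dependent mutation
rates, base-pairing coevolution, phylum structure, sequencing-error or
chimera simulation (chimeras enter only as an id exclusion list, the
output shape of an external detector). Passing tests therefore certify
the analysis machinery on idealised communities — they do not certify
robustness to real sequencing noise, primer bias or database-dependent
taxonomy, which only experimental data can probe. The `naive_classifier`
is a shared-k-mer testing stand-in for an external search-and-assign
toolchain, not a reconstruction of one.

## Numerical and design notes

- `max_tolerated_errors` evaluates ⌊length·d⌋ with a 1e-9 guard against
  binary-representation artefacts (300 × 0.03 is not exactly 9 in
  floating point).
- Cluster ids are assigned in centroid-creation order from 0; all
  randomized operations take an explicit generator or seed, so every
  pipeline run is bit-reproducible.
- The taxonomy table is authoritative over FASTA header annotations, and
  reads absent from it are unclassified; group mapping (e.g.
  Eukaryota → contaminant) is configuration, not code, so studies with a
  different target group need no changes.
- Quality rules (length window, max undetermined bases) are per-dataset
  configuration; the default allows no N at all.
- Known limitations: greedy clustering is order-dependent by design (the
  abundance sort makes it deterministic but not order-free); ACE is
  undefined territory when N_rare = 1 (γ² is set to 0 there); the
  discretized log-normal fit assumes the floor-and-round model and is not
  appropriate for size vectors that are themselves scaled (e.g. x2 data).
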