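# Methods

## The model

`xtalknet` asks which gene pairs interact in a drug-resistant cell line
but not in its drug-sensitive (parental) progenitor, and which of those
pairs bridge a targeted pathway (EGFR/ErbB in the motivating
application) and another signaling pathway — candidate compensatory
cross-talks behind acquired resistance.

**Relationship networks.** For each condition c ∈ {R (resistant),
P (parental)}, genes i and j are connected when the absolute Pearson
correlation of their expression profiles exceeds a threshold ("above"
is strict). The threshold is either supplied per condition or derived
as the (1 − f) quantile of all defined pairwise |PCC| values so that
roughly a fraction f of pairs qualify. Pairs involving a zero-variance
gene are undefined and never become edges, but the gene stays in the
node set so the network model still assigns it a propensity.

**The undirected p1-model.** Each network is modelled as a
dyad-independent exponential random graph: for i < j,

    u_ij^c ~ Bernoulli( σ(θ_c + α_i^c + α_j^c) )

with σ the logistic function, θ_c a global density parameter and
α_i^c the propensity (expansiveness/attractiveness, collapsed to one
parameter per gene in the undirected form) of gene i. Writing the two
dyad states with a per-dyad scaling constant that forces their
probabilities to sum to one and eliminating that constant analytically
yields exactly this Bernoulli-logistic form; the scaling constant is
never a free parameter.

**Hierarchical priors.** θ_c ~ N(0, 1/τ_c) with τ_c ~ Gamma(0.001,
0.001) (a vague prior; shape/rate convention). Each gene's propensity
pair is drawn jointly, (α_i^R, α_i^P) ~ N(0, Σ), with
Σ⁻¹ ~ Wishart(scale I, df 2). The two conditions share no likelihood
terms; they are coupled *only* through Σ, whose off-diagonal element
captures how strongly a gene's connectivity persists across the
resistance transition. Because Wishart parameterizations vary: the
prior density is ∝ |Σ⁻¹|^((df−3)/2) exp(−tr(R₀Σ⁻¹)/2) with R₀ = I, and
the full conditional of Σ⁻¹ is Wishart with df 2 + g and scipy-scale
(R₀ + Σᵢ aᵢaᵢᵀ)⁻¹, where aᵢ = (α_i^R, α_i^P).

**Identifiability.** θ_c and the mean of α^c enter the linear predictor
only through their sum, so they are separated only softly by the priors
(no sum-to-zero constraint is imposed). Posterior intervals for θ are
therefore wide and can shift by roughly twice the empirical mean of the
realized propensities; the edge probabilities, which depend on the sum,
are unaffected. This shows up in the parameter-recovery experiment as
interval coverage near, not above, the nominal level.

## Sampling

The default sampler augments every dyad with a Polya-Gamma latent
variable ω_ij^c ~ PG(1, ψ_ij^c), ψ being the linear predictor. Given
ω, the full conditional of the entire 2g-vector of propensities is
Gaussian — the two condition blocks have precision diag(W·1) + W (W the
symmetric matrix of ω's) plus Σ⁻¹ applied per gene pair — and is drawn
exactly by one Cholesky factorization per sweep; θ_c is a scalar
Gaussian draw, and τ, Σ⁻¹ keep their conjugate Gamma/Wishart updates.
PG(1, z) variables are generated from the infinite convolution
representation PG(1, z) = (1/2π²) Σ_k E_k /((k−½)² + z²/4π²), E_k ~
Exp(1), truncated at 100 terms with the omitted tail replaced by its
analytic expectation (relative tail mass ~1/trunc, essentially
deterministic); the sampler reproduces the closed-form mean
tanh(z/2)/(2z) to three decimals in the unit tests.

An independent random-walk Metropolis-within-Gibbs sampler (scalar
updates per propensity and per θ, Robbins-Monro adaptation to 0.44
acceptance during burn-in) is provided as a cross-check; both samplers
must and do pass the same small-instance oracle tests.

Defaults follow the study design: 6000 iterations, 5000 burn-in, 1000
retained draws, no thinning. Posterior edge probabilities use either
the posterior-predictive "draws" rule (per retained draw, sample each
dyad's indicator and report the proportion of sampled networks
containing the edge) or the Rao-Blackwellized "mean" of σ(ψ) over draws
(identical expectation, lower variance; the default).

**Small-instance oracle.** `brute_force_posterior` sums likelihood ×
prior over a dense (θ, α₁..α_g) grid per condition and is tractable for
g ≤ 4. It requires a *fixed diagonal* Σ: the conditions are then a
priori independent and each grid has 1 + g dimensions; a free or
correlated Σ would force a single 2 + 2g-dimensional grid, intractable
even at g = 3. `gibbs_fit` accepts `fixed_sigma` / `fixed_tau_theta` so
both routes integrate the same proper posterior. Grid bounds ±6 (θ,
prior sd 2) and ±4 (α, prior sd 1) at step 0.25 leave discretization
error below 0.01; halving the step changes edge probabilities by less
than that.

## Cross-talk scoring

Each unordered pair is scored by odds = Pr(edge | R) / Pr(edge | P).
Pairs with odds ≥ 10 and Pr(edge | R) ≥ 0.5 (both inclusive; both
configurable — a validation-style run can lower the probability cut to
0.15) are resistant-specific. Candidate cross-talks are all (gene_i ∈
pathway of interest, gene_j ∈ other pathway Q) pairs over the network's
gene universe, excluding pairs whose genes co-occur in the pathway of
interest or co-occur in Q; one candidate per (pair, Q), so a pair can
appear under several pathways and the cross-talk count exceeds the
distinct-pair count. The reported table is the intersection of the two
sets, annotated with the posterior probabilities, the odds and
condition-averaged expression, sorted by descending odds.

Note that the p1-model is dyad-independent *given the parameters*: an
edge's posterior probability is driven by the global density and the
two genes' inferred propensities, not by memorizing the observed
adjacency bit. High-scoring pairs are therefore pairs of genes that are
hubs in the resistant network and peripheral in the parental one — a
deliberate smoothing that trades single-edge sensitivity for robustness
to the noisy thresholded networks.

## Expression screens

Condition profiles average replicates within each (condition, dose)
group. For display and screening, each gene's condition means are
z-scored (population sd; the choice is fixed so heatmaps are exactly
reproducible, and with 4-6 condition values either convention is
defensible) and rescaled by the maximum |z|, so every non-constant gene
spans [−1, 1] and constant genes map to 0. The up-regulation screen
keeps cross-talk records whose BOTH genes have strictly higher average
expression across resistant condition means than across parental ones.

The fold-change-reversal screen pairs samples across conditions by a
replicate index from the sample map. Per replicate, log2 fold-changes
of each parental treatment dose — and of each resistant dose — are
taken against the *parental basal* sample of that replicate. A gene is
selected when, in at least one replicate, all parental-treatment
fold-changes share a strict sign and all resistant-*treatment*
fold-changes have the opposite strict sign; the resistant basal
fold-change is computed but deliberately excluded from the predicate
(including it would make the test compare a baseline, not a response,
and no sign test results otherwise). A fold-change of exactly 0 counts
as neither direction; non-positive intensities make the ratio undefined
and skip that gene/replicate with a warning.

## Synthetic data: what it emulates and why

The generator produces what the method needs to be testable end to end:
a genes × samples matrix per condition (default g = 60; 3 doses × 2
replicates = 6 samples per condition), latent-factor gene blocks
(3 blocks of 3) co-expressed in both conditions, one latent group
co-expressed only in the resistant condition, independent background
genes, and a toy pathway collection.

Design choices that matter:

* **Planted pairs share one hub group.** Because the p1-model scores
  pairs through propensities, disjoint planted dyads (degree-1 genes)
  would be undetectable by construction. The resistant-only group has
  10 genes — 2 assigned to the pathway of interest, 5 to a partner
  pathway, 3 left unannotated (pathway annotations of real gene sets
  are incomplete, and the unannotated members keep the hub degrees high
  without creating extra candidate pairs). The 2 × 5 cross-pathway
  pairs are the 10 planted cross-talk pairs. A Chung-Lu-style estimate
  (p ≈ d_i d_j / 2m) with hub degree 9 and ~60 resistant edges puts the
  planted pairs' fitted probability near 0.6, comfortably over the 0.5
  cut, while their parental probability stays near 0.01 (odds ≫ 10).
* **Near-noiseless factors.** With only 6 samples, a pair's sample
  correlation conditional on a small-spread factor draw is dominated by
  the gene-specific noise, so the noise sd defaults to 0.03 against
  unit-variance factors (noise-to-signal variance ~10⁻³). Group pairs
  then stay above the 0.95 |PCC| threshold used for synthetic runs for
  essentially every factor draw, while the null |PCC| tail (density
  ∝ 1 − r² at n = 6) admits under 0.5% of background pairs.
* **Up-regulation signal.** Planted-group genes additionally gain a
  +20%-of-baseline mean shift in resistant samples so the up-regulation
  screen has true positives; `correlate`/`shift` flags disable either
  signal. Doses carry no systematic effect: a shared dose response
  would correlate *all* genes and confound the planted structure.

What the generator does **not** emulate: probe-level noise, platform
normalization artifacts, realistic correlation spectra of transcriptome
data, or overlapping pathway annotations of real databases. Passing the
recovery tests shows the inferential machinery is wired correctly and
can detect clean rewiring signal at small sample size — not that the
thresholds are optimal for any real dataset.

## Problem sizes and experiment design

* Oracle equivalence: all 2 single-dyad and all 8 three-node
  configurations, 1500 iterations (500 burn-in), tolerance 0.05;
  observed worst-case disagreement ≈ 0.02 for both samplers.
* Parameter recovery: g = 30, θ_R = −1, θ_P = −2, Σ with unit variances
  and correlation 0.5, 20 replicates at 2000 iterations / 1000 burn-in.
  Nominal-90% interval coverage is required at ≥ 80% (see the
  identifiability note above) and the sign of the posterior propensity
  correlation in ≥ 18/20.
* End-to-end recovery: 5 synthetic datasets at generator defaults,
  pipeline at 1500 iterations / 1000 burn-in, |PCC| threshold 0.95 per
  condition, paper-default filter (odds ≥ 10, Pr ≥ 0.5); pooled over
  seeds, ≥ 80% of planted pairs must be reported with ≤ 10% false
  positives. Observed during development: 130/130 recovered across a
  13-seed sweep with one false positive.

## Numerical notes and limitations

* All randomness flows through one integer seed per run
  (`numpy.random.Generator`); runs are bit-reproducible per (seed,
  sampler). Permuting the gene order permutes the posterior only up to
  Monte-Carlo error, because the dyad random-variate stream is laid out
  in gene order.
* The PG truncation (100 terms) biases each latent draw by less than
  0.1% relative; the oracle tests bound the end effect well below the
  0.05 tolerance.
* Edge probabilities of 0 in the parental condition give infinite odds,
  ranked above all finite scores; a 0/0 odds ratio is defined as 0 with
  a warning.
* The quantile rule for "top f of pairs" and an explicit threshold are
  both supported and mutually exclusive per run; with heavily tied
  correlation values the realized edge fraction can differ from f.
* The directed four-state dyad model, reciprocity effects, alternative
  association measures (partial correlation, mutual information),
  pathway-topology-aware cross-talk definitions and enrichment
  statistics are out of scope.
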