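# Methods

## Model

The hidden population is an undirected simple graph G on N vertices; vertex
i carries a binary trait x(i) ∈ {0,1} and degree deg(i).  Self-loops and
multi-edges are excluded — a self-referral is not an RDS referral — and all
ties are reciprocal.  The RDS sample is a recruitment forest 𝕋 of k
complete m-ary trees of height h (ℓ = (m^{h+1}−1)/(m−1) nodes per tree,
n = kℓ).  Node identities follow a Markov walk indexed by the tree: the k
seed members are i.i.d. draws from the stationary distribution
π_i = deg(i)/Σ_j deg(j), and each recruit is drawn uniformly over its
recruiter's neighbours, independently per coupon slot and **with
replacement** — the same population member can appear at several nodes.
Each node records (trait, degree) of its member; estimators and the
bootstrap consume only those records, as with real RDS data.

Two modelling points the formal setup leaves open are fixed here and
flagged: seeds are drawn *independently* of one another (the natural
reading of k independent seed-rooted trees; a caller-specified-seed mode
exists for realism studies but is excluded from consistency experiments),
and the m coupon draws of one recruiter are mutually independent.

## Estimators

* sample mean X̄ₙ = (1/n) Σ_s X_s, unbiased for μ = Σ_i x(i) π_i;
* IPW (Horvitz–Thompson) μ̂ = (Σ_j deg(j)/(nN)) Σ_s X_s/deg(W_s), unbiased
  for the population mean μ₀ = (1/N) Σ_i x(i); the total degree Σ_j deg(j)
  is a required input (known-normaliser regime) and is never estimated;
* Volz–Heckathorn μ̂_VH = (Σ_s X_s/deg_s)/(Σ_s 1/deg_s), the self-normalised
  (Hájek) version, with H = (1/n) Σ_s 1/deg_s reported as normaliser.

One notational wrinkle: the VH estimator is sometimes written with the
degree applied to the observed trait value rather than to the sampled
member.  Since the trait is binary, the only coherent reading — used
throughout — is deg(W_s), the sampled individual's network size.

The transform x^π(i) = x(i)/(π_i N) makes the sample mean of transformed
values identically equal to the IPW estimate; this identity is exact in
floating point up to 1e−12 and is tested as such.

## The tree bootstrap

Seeds are resampled uniformly with replacement (k independent uniform
draws), then each selected node's m children are resampled uniformly with
replacement, recursively.  Replicates always have the source design — n
never changes between bootstrap samples, a consequence of the complete
m-ary shape.

**Exact enumeration.**  Child slots are treated as *ordered*, so each seed
tree admits a = f(h) resampled trees with f(0) = 1, f(d) = (m·f(d−1))^m,
and every (seed, resampled tree) pair has probability 1/K, K = ak.  The
bootstrap mean is the average of k i.i.d. single draws from that uniform
law; its exact distribution is built as the k-fold convolution of the
single-draw sum law.  Enumeration is refused above 10^7 resampled trees
(balancing coverage of small cases against desk-scale runtime); larger
problems use Monte Carlo.  The enumeration natively covers the sample mean;
the IPW estimator is handled by relabelling each node's value to
Σdeg·X_s/(N·deg_s).  The VH ratio is not a per-node relabelling and has no
exact path here.

**Numerical conventions.**  Bootstrap variance uses the 1/B (not 1/(B−1))
normalisation so the B→∞ limit matches the exact enumeration without a
finite-B correction.  Percentile intervals use the linearly interpolated
empirical quantile function (numpy's "linear" rule), making CIs
bit-reproducible given the seed; normal intervals use
point ± z_{1−α/2}·√variance.  Both interval types are provided because the
theory asserts CI consistency without fixing a construction; percentile is
the default.  Support values in enumerated laws are aggregated after
rounding to 12 decimals (sums of binary traits are exact integers; the
rounding only matters for relabelled values).  All randomness flows from
`numpy.random.default_rng` seeds; replicate generation is chunked for
memory, with fixed default chunking so default runs are bit-reproducible.

## Stochastic block model and the critical threshold

The generator draws 2K equal blocks of `block_size` vertices; within-block
pairs are edges with probability p, between-block pairs with probability r,
each independently.  The default trait rule assigns trait 1 to the first K
blocks — a symmetric, block-aligned outcome with μ₀ = 1/2 — and an
arbitrary per-vertex trait vector can be supplied instead.  SBM draws can
be disconnected; generation does not silently take the giant component but
either returns the draw (walk-time checks reject it) or, on request,
redraws until connected with a retry cap.

The walk's trait process satisfies a central limit theorem when
1/(2K) < p̃ < 1/(2K) + 1/(2√2), p̃ = p/{p + r(K−1)}.  Both inequalities are
implemented strictly; the boundary counts as not below threshold.  Note the
formula degenerates to p̃ ≡ 1 at K = 1 (two blocks), making the condition
unsatisfiable there; the formula is computed exactly as stated and the
anomaly is simply documented — no alternative is guessed.

## Consistency experiment

The guarantee under study: conditional on the sample, the law of
√n(X̄ₙ* − X̄ₙ) approaches the sampling law of √n(X̄ₙ − μ) in the Kolmogorov
(sup-CDF) metric as the design grows with ℓ = o(√n), ℓ → ∞.  Almost-sure
convergence is not empirically testable; the surrogate is a fixed-seed,
multi-stage monotone trend.  Per stage the harness:

1. estimates the reference sampling law by Monte Carlo (`sampling_reps`
   fresh simulations of √n(estimate − target), target μ for the sample
   mean, μ₀ for IPW/VH);
2. for each of R fresh samples runs B bootstrap replicates and records the
   Kolmogorov distance of the centred, √n-scaled bootstrap law to the
   reference, whether the percentile CI covers the target, and the scaled
   bootstrap variance n·σ̂²;
3. aggregates the median distance (median, not mean, for robustness to the
   occasional pathological small-n sample), the coverage fraction, and the
   median and IQR of n·σ̂² alongside ρ̂², the variance of the reference law.

√n-scaling is applied to both laws so stages of different n are comparable.
The default schedule grows k = ℓ² (h_t = t), one admissible choice
guaranteeing ℓ/√n = ℓ^{−1/2} → 0; the schedule validator enforces ℓ
strictly increasing and ℓ/√n strictly decreasing for custom schedules.
Coverage is expected to *approach* nominal, from either direction; it is
never asserted to equal it at finite n.

**Default study conditions** (all configurable): SBM with K=2, blocks of
50 (N=200), p=0.3, r=0.2, hence p̃=0.6, comfortably inside the threshold
band (0.25, ≈0.6036); branching m=2 with stages h=1 (n=27, k=9) and h=2
(n=343, k=49); R=200 samples and B=2000 replicates per stage with a
2000-draw reference law; 95% percentile intervals.  These sizes give a
binomial 3-SE band of about ±0.046 on a 0.95 coverage estimate at R=200,
enough resolution for the trend checks, and the whole two-stage experiment
runs in seconds thanks to the vectorised wave-by-wave simulation and
level-by-level resampling on the deterministic breadth-first node layout.

## What the generator does and does not emulate

The simulator realises the idealised process the theory addresses:
complete m-ary trees (no ragged recruitment, no coupon depletion or
non-response), with-replacement recruiting, seeds at stationarity, degrees
reported without error.  Real RDS data violate most of these —
recruitment is ragged and without replacement within practical limits,
seeds are a convenience sample, and self-reported degrees are noisy.
Passing tests therefore validate the method *under its stated model*, not
its robustness to those violations.  Estimating SBM parameters from data,
successive-sampling or model-assisted estimators, studentised/BCa
intervals, and above-threshold limit behaviour are out of scope.

## Degenerate inputs and edge cases

Height-0 forests reduce the tree bootstrap to the classical i.i.d.
bootstrap of the k seed values (verified exactly against multinomial
enumeration).  An m=1 single chain admits exactly one resample — the
bootstrap is the identity there.  A constant trait makes every law
degenerate at a point: distances are 0 and CIs have zero width, a
documented edge case rather than an error.  Disconnected graphs, isolated
vertices, non-binary traits, non-positive degrees and malformed forest
files are all rejected with specific errors at construction or read time.
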