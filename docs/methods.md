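# Methods

## Model

A shotgun metagenomic sample is a random subset of the metagenome. For a
fixed k (default 20), the count of each distinct k-mer in the sample is
modelled as Poisson(λ) with λ drawn i.i.d. from an unknown mixing measure
μ(λ); overlapping k-mers are treated as independent, a standard and
well-tested approximation. With N the distinct k-mer count (DKC) of the full
metagenome, the expected frequency spectrum is
`E n_j = N ∫ e^{−λ} λ^j / j! dμ(λ)` and the expected number of *uncaptured*
distinct k-mers is `N ∫ e^{−λ} dμ(λ)`.

Writing ω(λ) = N λ e^{−λ} and m_j = (j+1)!·n_{j+1} makes the observed
spectrum a raw-moment sequence of the positive measure ω dμ, and the target
the integral of 1/λ against it — a Gaussian-quadrature problem. The
Golub–Welsch construction turns m_0 … m_{2P−1} into a P-point rule
{(λ_i, α_i)} and the estimate `Σ_i α_i / λ_i`. Because 1/λ is completely
monotone (all even derivatives positive), the Gauss rule *underestimates* the
integral when the moments are exact; the method therefore behaves as a
lower-bound-flavoured estimator in the regime where the uncaptured mass is
large relative to sampling noise. The total-DKC estimate adds the observed
DKC to the uncaptured estimate.

Total genome length is then `DKC_total × KRI`, where the k-mer redundancy
index KRI = TKC/DKC is computed on the *pooled* k-mer collection of the known
genome set: window counts summed over genomes, distinct k-mers deduplicated
across genomes. Pooling (rather than per-genome averaging) is used because
the quantity being converted is the DKC of the union of all genomes. The set
is held at species level — one genome per species identifier; strain
selection is the caller's responsibility.

## Numerical choices

* **Moments** are exact Python integers ((j+1)! n_{j+1} overflows doubles
  near j ≈ 20); floating point enters only inside the quadrature.
* **Golub–Welsch** builds the Hankel matrices H0 = [m_{i+j}] and
  H1 = [m_{i+j+1}] in mpmath at ≥ 50 decimal digits (30 + 8·P in practice),
  Cholesky-factorises H0 = L·Lᵀ, and forms the Jacobi matrix
  J = L⁻¹·H1·L⁻ᵀ, which is symmetric tridiagonal in exact arithmetic and
  well scaled; its eigendecomposition is done in double precision. Nodes are
  the eigenvalues; weights are m_0 times the squared first eigenvector
  components, which preserves Σα_i = m_0 by construction.
* **Point count**: raw-moment quadrature is severely ill-conditioned, so P
  starts at `max_points` (default 10) and decrements until H0 is positive
  definite and every node exceeds 10⁻¹² and every weight is positive. Nodes
  below 10⁻¹² are rejected because α/λ would explode.
* **Histogram truncation**: frequency classes above 2·max_points contribute
  no moments (high-j moments dominate numerically yet carry no information
  about λ ≈ 0) but still count toward observed DKC/TKC.
* **Saturated spectra**: when n_1 > 0 but every usable higher moment is zero
  (deeply covered data with a stray singleton), no positive measure matches
  the moment sequence and the decrement reaches zero. Rather than failing,
  the estimator falls back to a homogeneous single-rate rule — one node at
  the observed mean multiplicity λ̄ = TKC/DKC with weight n_1, giving
  uncaptured = n_1/λ̄, which vanishes for deeply covered samples — and flags
  the result with a warning. Genuinely uninformative inputs (no singletons
  at all) still raise.
* **Bootstrap**: DKC distinct k-mers are resampled with replacement across
  frequency classes (multinomial with probabilities n_j/DKC), the estimator
  is re-run per replicate, and a percentile interval is taken (default 100
  replicates, level 0.95, seeded). Replicates without singletons are redrawn
  up to 20 times, then dropped with a note. A percentile interval from
  finitely many replicates need not contain the point estimate; the reported
  interval is widened to include it when necessary. Resampling frequency
  classes (not reads) keeps the bootstrap independent of read storage and is
  the natural resampling unit for a spectrum-level statistic.
* **k-mer counting**: 2-bit packed uint64 codes for k ≤ 31 (default k = 20),
  with windows containing any non-ACGT symbol skipped whole; canonical mode
  (reverse-complement collapsing, the default, since reads come from both
  strands) keys each window by the smaller of the two orientations. Every
  stage of one run must share k and the canonical flag; the pipeline aborts
  on mismatch. For k > 31 a string-keyed fallback counter is used. Distinct
  and multiplicity tallies use an explicit sort-based unique.

## Synthetic data

The simulator is the package's validation instrument and defines the study
conditions:

* **Genomes**: i.i.d. uniform ACGT sequences; a `repeat_fraction` (default
  0.1) of each genome is built by copying segments (200–2000 bp) of the
  genome onto its end, producing tandem/dispersed repeats and KRI > 1 with a
  known truth. Default genome length in the validation experiments is 100 kb
  (50 kb for the error-model experiments), sized so a full grid runs on one
  CPU in minutes.
* **Abundances**: LC = one dominant species at 0.6, remainder shared with
  geometric decay (ratio 0.7); MC = two dominants at 0.45 and 0.30 (jointly
  0.75 > 0.7), remainder geometric; HC = symmetric Dirichlet(α = 5), redrawn
  (bounded, seeded) until no species reaches 3/G. These concrete laws fix
  the qualitative one-dominant / two-dominant / no-dominant definitions.
* **Reads**: single-end, fixed length (100 bp in the experiments), genome
  chosen per read with probability ∝ abundance × genome length (the standard
  shotgun model), start uniform, substitution errors i.i.d. per base to a
  different base; no indels, no quality model, no paired ends.
* **Ground truth**: true DKC is the genome-union distinct k-mer count; true
  total length is Σ(L_g − k + 1); initial coverage is the fraction of the
  union's distinct k-mers present in the sample.

What passing these simulations does *not* show: real communities have
non-uniform base composition, shared sequence between species, strain
mixtures, and error profiles with indels and quality structure; error
*correction* is assumed to happen upstream (the estimator deliberately does
not model error k-mers, and the simulations demonstrate how 1% substitution
errors inflate the estimate and how the inflation grows with depth).

## Experiment sizes

The validation experiments use 10-species communities at 100 kb/genome with
three depths (8k, 25k, 80k reads of 100 bp, spanning initial coverage ≈ 0.45
to ≈ 0.99) and three seeds; the KRI-subsampling experiment uses 50 genomes of
20 kb with repeat fraction 0.2 and ten 60% subsets; the error-inflation
experiment uses 10 × 50 kb communities at three depths and five seeds. The
lower-bound tendency is asserted in the shallow-coverage regime (≈ 0.12
initial coverage), where the uncaptured integral — not sampling noise —
dominates the estimate; at high coverage the estimator is essentially
unbiased and the sign of its tiny error is coin-flip.

## Limitations

* KRI estimation uncertainty is not propagated into the total-length CI
  (no principled procedure presents itself without a model of which genomes
  are known); the CI scales the DKC interval by the KRI point estimate only.
* The bootstrap resamples frequency classes, not reads, so it reflects
  spectrum-level sampling variability only.
* Species detection, error correction, taxonomy profiling and assembly are
  out of scope; the genome set for KRI is an input.
* In-memory counting targets desk-scale data (≤ ~10⁸ k-mer windows).
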