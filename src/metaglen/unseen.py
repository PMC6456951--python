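"""Unseen distinct k-mer estimation via a Poisson-mixture moment problem.

The number of times a given distinct k-mer of the metagenome is observed
in a shotgun sample is modelled as Poisson with an unknown per-k-mer
rate lambda, where the rates are i.i.d. draws from an unknown mixing
measure mu(lambda).  With N the (unknown) distinct k-mer count of the
whole metagenome, the expected spectrum is

    E n_j = N * Integral exp(-lambda) lambda^j / j!  d mu(lambda),

and the quantity of interest — the number of distinct k-mers that the
sample failed to capture — is

    U = N * Integral exp(-lambda) d mu(lambda).

Substituting omega(lambda) = N lambda exp(-lambda) and the transformed
moments  m_j = (j+1)! * n_{j+1}  turns the observed spectrum into a
raw-moment sequence of the positive measure omega d mu, and U into the
integral of 1/lambda against that measure.  A Gaussian quadrature rule
{(lambda_i, alpha_i)} built from m_0..m_{2P-1} by the Golub-Welsch
algorithm then gives

    U  ~=~  sum_i alpha_i / lambda_i .

Moments are computed in exact integer arithmetic (they grow factorially)
and the Hankel/Cholesky/Jacobi construction runs in arbitrary precision;
only the final symmetric-tridiagonal eigenproblem is solved in doubles.
Raw-moment quadrature is notoriously ill-conditioned, so the point count
is decremented from ``max_points`` until the Hankel matrix is positive
definite and every node and weight is strictly positive.

Uncertainty is quantified by a percentile bootstrap that resamples the
observed distinct k-mers across frequency classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from mpmath import mp

from .spectrum import KmerSpectrum

__all__ = [
    "MomentSequence",
    "QuadratureRule",
    "UnseenEstimate",
    "MomentProblemError",
    "moments_from_spectrum",
    "golub_welsch",
    "estimate_uncaptured",
    "estimate_total_dkc",
    "bootstrap_ci",
]

#: nodes below this are rejected (alpha/lambda would blow up)
NODE_TOLERANCE = 1e-12

#: spectra with fewer distinct k-mers than this are flagged as unreliable
SMALL_DKC_WARNING = 100


class MomentProblemError(ValueError):
    """The spectrum's moment sequence admits no valid quadrature rule."""


@dataclass
class MomentSequence:
    """Transformed moments m_j = (j+1)! * n_{j+1}, exact integers.

    m_0 = n_1 (the singleton count); trailing zero moments are dropped.
    """

    values: list[int]
    source_spectrum: KmerSpectrum | None = None

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class QuadratureRule:
    """Discrete stand-in {(lambda_i, alpha_i)} for the mixing measure.

    ``fallback`` marks the degenerate homogeneous-coverage rule used
    when the moment sequence carries no usable information beyond m_0
    (saturated spectra); see :func:`estimate_uncaptured`.
    """

    nodes: np.ndarray
    weights: np.ndarray
    n_points: int
    fallback: bool = False

    def moment(self, j: int) -> float:
        """sum_i alpha_i * lambda_i^j — should match m_j for j < 2P."""
        return float(np.sum(self.weights * self.nodes**j))


@dataclass
class UnseenEstimate:
    """Point estimate of total distinct k-mers with optional bootstrap CI."""

    uncaptured: float
    dkc_observed: int
    dkc_total: float
    n_points_used: int
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float | None = None
    n_bootstrap: int = 0
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)


def moments_from_spectrum(spectrum: KmerSpectrum, max_moments: int) -> MomentSequence:
    """Exact transformed moments m_j = (j+1)! * n_{j+1}, j = 0..max_moments-1.

    Frequency classes above ``max_moments`` contribute nothing here (they
    still count toward observed DKC/TKC); trailing zero moments are
    excluded so the length reflects the informative part of the spectrum.
    """
    if max_moments < 2:
        raise ValueError("max_moments must be >= 2")
    if spectrum.counts.get(1, 0) <= 0:
        raise MomentProblemError("no singletons; unseen count not estimable")
    limit = min(max_moments, spectrum.max_freq)
    values = [math.factorial(j + 1) * spectrum.counts.get(j + 1, 0) for j in range(limit)]
    while values and values[-1] == 0:
        values.pop()
    return MomentSequence(values=values, source_spectrum=spectrum)


def golub_welsch(moments: MomentSequence, n_points: int) -> QuadratureRule:
    """Gaussian quadrature rule from raw moments m_0..m_{2P-1}.

    The Hankel moment matrix H0 = [m_{i+j}] is Cholesky-factorised in
    arbitrary precision (it grows factorially); the Jacobi matrix
    J = L^-1 H1 L^-T with H1 = [m_{i+j+1}] is symmetric tridiagonal in
    exact arithmetic and well scaled, so its eigendecomposition is done
    in double precision.  Nodes are the eigenvalues; the weight of node
    i is m_0 times the squared first component of its eigenvector.

    Raises :class:`MomentProblemError` if H0 is not positive definite or
    any node/weight fails strict positivity — callers typically retry
    with ``n_points - 1``.
    """
    P = int(n_points)
    if P < 1:
        raise ValueError("n_points must be >= 1")
    m = moments.values
    if 2 * P > len(m):
        raise ValueError(f"{2 * P} moments needed for {P} points, have {len(m)}")
    if m[0] <= 0:
        raise MomentProblemError("zeroth moment (singleton count) must be positive")
    with mp.workdps(max(50, 30 + 8 * P)):
        H0 = mp.matrix(P, P)
        H1 = mp.matrix(P, P)
        for i in range(P):
            for j in range(P):
                H0[i, j] = mp.mpf(m[i + j])
                H1[i, j] = mp.mpf(m[i + j + 1])
        try:
            L = mp.cholesky(H0)
        except ValueError as exc:
            raise MomentProblemError(
                f"Hankel moment matrix not positive definite at {P} points"
            ) from exc
        Linv = L**-1
        J = Linv * H1 * Linv.T
        Jnp = np.array([[float(J[i, j]) for j in range(P)] for i in range(P)])
    Jnp = (Jnp + Jnp.T) / 2.0
    nodes, vecs = np.linalg.eigh(Jnp)
    weights = float(m[0]) * vecs[0, :] ** 2
    if np.any(nodes <= NODE_TOLERANCE):
        raise MomentProblemError(f"non-positive quadrature node at {P} points")
    if np.any(weights <= 0):
        raise MomentProblemError(f"non-positive quadrature weight at {P} points")
    order = np.argsort(nodes)
    return QuadratureRule(nodes=nodes[order], weights=weights[order], n_points=P)


def estimate_uncaptured(
    spectrum: KmerSpectrum, max_points: int = 10
) -> tuple[float, QuadratureRule]:
    """Estimate the count of distinct k-mers absent from the sample.

    Builds moments from the spectrum (frequency classes above
    ``2 * max_points`` are not used as moments) and returns
    sum_i alpha_i / lambda_i for the largest achievable valid rule with
    P <= max_points points.

    Saturated spectra — n_1 > 0 but every usable higher moment zero, as
    when nearly all k-mers are deeply covered — admit no positive
    measure through the moment sequence.  For these a homogeneous
    fallback is used: one node at the observed mean multiplicity
    lambda-bar = TKC/DKC with weight n_1, giving
    uncaptured = n_1 / lambda-bar (vanishing for deeply covered data).
    """
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    moments = moments_from_spectrum(spectrum, max_moments=2 * max_points)
    start = min(max_points, len(moments) // 2)
    for P in range(start, 0, -1):
        try:
            rule = golub_welsch(moments, P)
        except MomentProblemError:
            continue
        value = float(np.sum(rule.weights / rule.nodes))
        return value, rule
    # homogeneous fallback: mu = delta at the observed mean multiplicity
    lam = spectrum.tkc / spectrum.dkc
    n1 = spectrum.counts[1]
    rule = QuadratureRule(
        nodes=np.array([lam]), weights=np.array([float(n1)]), n_points=1, fallback=True
    )
    return n1 / lam, rule


def _resample_spectrum(spectrum: KmerSpectrum, rng: np.random.Generator) -> KmerSpectrum:
    """Multinomial resample of DKC distinct k-mers over frequency classes."""
    classes = np.array(sorted(spectrum.counts), dtype=np.int64)
    nj = np.array([spectrum.counts[int(j)] for j in classes], dtype=np.float64)
    dkc = int(nj.sum())
    draw = rng.multinomial(dkc, nj / nj.sum())
    counts = {int(j): int(c) for j, c in zip(classes, draw) if c > 0}
    return KmerSpectrum(k=spectrum.k, canonical=spectrum.canonical, counts=counts)


def bootstrap_ci(
    spectrum: KmerSpectrum,
    n_bootstrap: int = 100,
    level: float = 0.95,
    seed: int = 0,
    max_points: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the total distinct k-mer count."""
    lower, upper, _ = _bootstrap(spectrum, n_bootstrap, level, seed, max_points)
    return lower, upper


def _bootstrap(
    spectrum: KmerSpectrum,
    n_bootstrap: int,
    level: float,
    seed: int,
    max_points: int,
    max_retries: int = 20,
) -> tuple[float, float, list[str]]:
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    notes: list[str] = []
    stats: list[float] = []
    failed = 0
    for _ in range(n_bootstrap):
        replicate = None
        for _attempt in range(max_retries):
            candidate = _resample_spectrum(spectrum, rng)
            if candidate.counts.get(1, 0) > 0:
                replicate = candidate
                break
        if replicate is None:
            failed += 1
            continue
        try:
            unc, _rule = estimate_uncaptured(replicate, max_points=max_points)
        except MomentProblemError:
            failed += 1
            continue
        stats.append(replicate.dkc + unc)
    if failed:
        notes.append(f"{failed}/{n_bootstrap} bootstrap replicates failed and were dropped")
    if len(stats) < 2:
        raise MomentProblemError("too few successful bootstrap replicates for an interval")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lower), float(upper), notes


def estimate_total_dkc(
    spectrum: KmerSpectrum,
    max_points: int = 10,
    n_bootstrap: int = 0,
    ci_level: float = 0.95,
    seed: int = 0,
) -> UnseenEstimate:
    """Total distinct k-mers of the metagenome: observed DKC + uncaptured.

    With ``n_bootstrap >= 2`` a percentile bootstrap interval at
    ``ci_level`` is attached; the interval is widened, if necessary, to
    contain the point estimate.
    """
    warnings: list[str] = []
    dkc = spectrum.dkc
    if dkc < SMALL_DKC_WARNING:
        warnings.append(f"spectrum has only {dkc} distinct k-mers; estimate is unreliable")
    uncaptured, rule = estimate_uncaptured(spectrum, max_points=max_points)
    if rule.fallback:
        warnings.append(
            "moment sequence degenerate; homogeneous single-rate fallback used for the "
            "uncaptured count"
        )
    total = dkc + uncaptured
    est = UnseenEstimate(
        uncaptured=uncaptured,
        dkc_observed=dkc,
        dkc_total=total,
        n_points_used=rule.n_points,
        warnings=warnings,
    )
    if n_bootstrap >= 2:
        lower, upper, notes = _bootstrap(spectrum, n_bootstrap, ci_level, seed, max_points)
        est.ci_lower = min(lower, total)
        est.ci_upper = max(upper, total)
        est.ci_level = ci_level
        est.n_bootstrap = n_bootstrap
        est.seed = seed
        est.warnings.extend(notes)
    return est
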