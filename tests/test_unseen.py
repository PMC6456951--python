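"""Moment problem, Golub-Welsch quadrature, and unseen k-mer estimation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from metaglen import (
    KmerSpectrum,
    MomentProblemError,
    MomentSequence,
    bootstrap_ci,
    estimate_total_dkc,
    estimate_uncaptured,
    golub_welsch,
    moments_from_spectrum,
)


def poisson_spectrum(n_total: float, lam: float, k: int = 20, jmax: int = 50) -> KmerSpectrum:
    """Rounded expected spectrum of N k-mers with homogeneous Poisson rate lam."""
    counts = {}
    for j in range(1, jmax):
        nj = round(n_total * math.exp(-lam) * lam**j / math.factorial(j))
        if nj > 0:
            counts[j] = nj
    return KmerSpectrum(k=k, canonical=True, counts=counts)


def mixture_spectrum(components: list[tuple[float, float]], k: int = 20, jmax: int = 60):
    """Rounded expected spectrum of a finite Poisson-rate mixture."""
    counts = {}
    for j in range(1, jmax):
        nj = round(
            sum(n * math.exp(-lam) * lam**j / math.factorial(j) for n, lam in components)
        )
        if nj > 0:
            counts[j] = nj
    return KmerSpectrum(k=k, canonical=True, counts=counts)


def discrete_measure_moments(atoms: list[tuple[float, float]], n_moments: int) -> MomentSequence:
    """Exact raw moments m_j = sum_i mass_i * atom_i^j of a discrete measure."""
    values = [sum(mass * atom**j for mass, atom in atoms) for j in range(n_moments)]
    return MomentSequence(values=values)


class TestMoments:
    def test_direct_formula(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={1: 10, 2: 5})
        m = moments_from_spectrum(spec, max_moments=10)
        assert m.values == [10, 10]  # m_0 = n_1, m_1 = 2! * 5

    def test_three_class_example(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={1: 6, 2: 3, 3: 1})
        m = moments_from_spectrum(spec, max_moments=10)
        assert m.values == [6, 6, 6]

    def test_no_singletons_errors(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={5: 1000})
        with pytest.raises(MomentProblemError, match="no singletons"):
            moments_from_spectrum(spec, max_moments=10)

    def test_truncation_cap_respected(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={j: 100 for j in range(1, 30)})
        m = moments_from_spectrum(spec, max_moments=4)
        assert len(m) == 4

    def test_poisson_closed_form_oracle(self):
        # E m_j = (j+1)! * N e^-lam lam^(j+1)/(j+1)! = N e^-lam lam^(j+1)
        n_total, lam = 1e5, 2.0
        spec = poisson_spectrum(n_total, lam)
        m = moments_from_spectrum(spec, max_moments=8)
        expected = [n_total * math.exp(-lam) * lam ** (j + 1) for j in range(8)]
        got = [float(v) for v in m.values]
        assert got == pytest.approx(expected, rel=2e-3)  # slack for integer rounding of n_j

    def test_exact_integer_arithmetic_no_overflow(self):
        # (j+1)! n_{j+1} overflows doubles long before j = 30; ints must not
        spec = KmerSpectrum(k=20, canonical=True, counts={1: 1, 30: 10**7})
        m = moments_from_spectrum(spec, max_moments=30)
        assert m.values[29] == math.factorial(30) * 10**7
        assert isinstance(m.values[29], int)


class TestGolubWelsch:
    def test_one_point_measure_recovered(self):
        alpha, lam = 367.879441, 1.0
        m = discrete_measure_moments([(alpha, lam)], 2)
        rule = golub_welsch(m, 1)
        assert rule.nodes[0] == pytest.approx(lam, rel=1e-12)
        assert rule.weights[0] == pytest.approx(alpha, rel=1e-12)

    def test_first_moment_match(self):
        rule = golub_welsch(MomentSequence(values=[6, 6, 6]), 1)
        assert rule.nodes[0] == pytest.approx(1.0)
        assert rule.weights[0] == pytest.approx(6.0)

    def test_two_point_measure_eight_significant_digits(self):
        m = discrete_measure_moments([(100.0, 0.5), (50.0, 3.0)], 4)
        rule = golub_welsch(m, 2)
        assert rule.nodes == pytest.approx([0.5, 3.0], rel=1e-8)
        assert rule.weights == pytest.approx([100.0, 50.0], rel=1e-8)

    @pytest.mark.parametrize(
        "atoms",
        [
            [(500.0, 0.3), (200.0, 1.7), (50.0, 6.0)],
            [(1e4, 0.2), (5e3, 1.0), (2e3, 3.0), (1e3, 8.0), (500.0, 15.0)],
        ],
    )
    def test_multi_atom_recovery_and_exactness(self, atoms):
        """Rules from <=5-atom measures recover atoms/masses and match moments."""
        P = len(atoms)
        m = discrete_measure_moments(atoms, 2 * P)
        rule = golub_welsch(m, P)
        masses = [a[0] for a in atoms]
        nodes = [a[1] for a in atoms]
        assert rule.nodes == pytest.approx(nodes, rel=1e-8)
        assert rule.weights == pytest.approx(masses, rel=1e-8)
        for j in range(2 * P):  # quadrature exactness up to degree 2P-1
            assert rule.moment(j) == pytest.approx(float(m.values[j]), rel=1e-6)

    def test_not_positive_definite_raises(self):
        # moments of no positive measure: m_0 m_2 < m_1^2 violates Cauchy-Schwarz
        with pytest.raises(MomentProblemError, match="positive definite"):
            golub_welsch(MomentSequence(values=[1, 10, 1, 10]), 2)

    def test_requires_enough_moments(self):
        with pytest.raises(ValueError, match="moments"):
            golub_welsch(MomentSequence(values=[1, 2]), 2)


class TestEstimateUncaptured:
    def test_homogeneous_poisson_closed_form(self):
        n_total = 1e5
        spec = poisson_spectrum(n_total, 1.0)
        value, rule = estimate_uncaptured(spec, max_points=10)
        assert value == pytest.approx(n_total * math.exp(-1.0), rel=0.01)

    def test_two_point_mixture_closed_form(self):
        spec = mixture_spectrum([(1e4, 0.5), (1e4, 4.0)])
        value, rule = estimate_uncaptured(spec, max_points=10)
        expected = 1e4 * (math.exp(-0.5) + math.exp(-4.0))
        assert value == pytest.approx(expected, rel=0.01)
        assert rule.n_points >= 2

    def test_degenerate_single_class_errors(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={5: 1000})
        with pytest.raises(MomentProblemError, match="no singletons"):
            estimate_uncaptured(spec)

    def test_scaling_linearity(self):
        """Multiplying every n_j by c scales the estimate by exactly c."""
        base = mixture_spectrum([(1e4, 0.5), (1e4, 4.0)])
        scaled = KmerSpectrum(
            k=base.k, canonical=base.canonical, counts={j: 3 * n for j, n in base.counts.items()}
        )
        v1, r1 = estimate_uncaptured(base)
        v3, r3 = estimate_uncaptured(scaled)
        assert v3 == pytest.approx(3 * v1, rel=1e-9)
        assert r3.nodes == pytest.approx(r1.nodes, rel=1e-9)


class TestEstimateTotalDkc:
    def test_homogeneous_poisson_total(self):
        n_total = 1e5
        spec = poisson_spectrum(n_total, 1.0)
        est = estimate_total_dkc(spec)
        assert est.dkc_total == pytest.approx(n_total, rel=0.01)
        assert est.dkc_total >= est.dkc_observed
        assert est.uncaptured >= 0

    def test_near_saturation_uses_fallback(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={1: 1, 30: 100_000})
        est = estimate_total_dkc(spec)
        assert est.uncaptured < 1  # uncaptured << DKC observed
        assert est.dkc_total == pytest.approx(est.dkc_observed, rel=1e-4)
        assert any("fallback" in w for w in est.warnings)

    def test_tiny_spectrum_flagged(self):
        spec = KmerSpectrum(k=20, canonical=True, counts={1: 10, 2: 5})
        est = estimate_total_dkc(spec)
        assert any("unreliable" in w for w in est.warnings)


class TestLowerBoundTendency:
    def test_estimate_rarely_exceeds_truth_in_extrapolation_regime(self):
        """Gaussian quadrature of the completely monotone 1/lambda integrand
        underestimates, so at low coverage — where the uncaptured mass
        dominates sampling noise — the point estimate falls at or below the
        true DKC in the large majority of seeded runs."""
        from metaglen import count_kmers, make_community, simulate_reads

        below = 0
        n_runs = 30
        for s in range(n_runs):
            community = make_community(10, 50_000, "HC", repeat_fraction=0.1, seed=600 + s)
            truth = community.truth(20)["true_dkc"]
            sample = simulate_reads(community, 800, 100, 0.0, seed=700 + s)
            spec = count_kmers(sample.reads, k=20, canonical=True)
            est = estimate_total_dkc(spec, max_points=10)
            below += est.dkc_total <= truth
        assert below >= 0.8 * n_runs


class TestBootstrap:
    def test_seeded_determinism(self):
        spec = poisson_spectrum(1e4, 1.0)
        a = bootstrap_ci(spec, n_bootstrap=50, level=0.95, seed=7)
        b = bootstrap_ci(spec, n_bootstrap=50, level=0.95, seed=7)
        assert a == b
        c = bootstrap_ci(spec, n_bootstrap=50, level=0.95, seed=8)
        assert a != c

    def test_interval_brackets_point_and_truth(self):
        n_total = 1e5
        spec = poisson_spectrum(n_total, 1.0)
        est = estimate_total_dkc(spec, n_bootstrap=100, ci_level=0.95, seed=3)
        assert est.ci_level == 0.95
        assert est.ci_lower <= est.dkc_total <= est.ci_upper
        assert est.ci_lower <= n_total <= est.ci_upper

    def test_invalid_parameters(self):
        spec = poisson_spectrum(1e4, 1.0)
        with pytest.raises(ValueError):
            bootstrap_ci(spec, n_bootstrap=1)
        with pytest.raises(ValueError):
            bootstrap_ci(spec, n_bootstrap=10, level=1.5)
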