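import itertools
import math

import numpy as np
import pytest
from scipy.special import logit

from discoverym import (
    DiscoveryMatrix,
    HeterogeneityParams,
    column_pattern_lik,
    heterogeneous_loglik,
    homogeneous_loglik,
    log_permutation_count,
    naive_p,
    truncate_zero_columns,
)


def enumerate_observables(n: int, m: int):
    """All distinct observable matrices d reachable from n x m complete
    matrices, with brute-force counts of how many complete matrices
    truncate to each — the independent oracle for H(d, m)."""
    seen: dict[bytes, tuple[DiscoveryMatrix, int]] = {}
    for bits in itertools.product((0, 1), repeat=n * m):
        x = np.array(bits, dtype=np.int8).reshape(n, m)
        d = truncate_zero_columns(x)
        key = d.cells.tobytes() + bytes([d.j])
        if key in seen:
            seen[key] = (seen[key][0], seen[key][1] + 1)
        else:
            seen[key] = (d, 1)
    return list(seen.values())


class TestPermutationCount:
    def test_worked_example_six_matrices(self, two_by_two):
        assert math.exp(log_permutation_count(two_by_two, 3)) == pytest.approx(6)

    def test_m_equals_j_distinct_columns_gives_factorial(self, worked_matrix):
        assert math.exp(log_permutation_count(worked_matrix, 10)) == pytest.approx(
            math.factorial(10), rel=1e-9
        )

    def test_brute_force_enumeration_m4(self, two_by_two):
        count = sum(
            1
            for bits in itertools.product((0, 1), repeat=2 * 4)
            if truncate_zero_columns(
                np.array(bits, dtype=np.int8).reshape(2, 4)
            ).cells.tolist()
            == two_by_two.cells.tolist()
        )
        assert count == 12
        assert math.exp(log_permutation_count(two_by_two, 4)) == pytest.approx(12)

    def test_repeated_columns_divide_the_count(self):
        d = DiscoveryMatrix([[1, 1], [0, 0]])  # j1 = 2
        assert math.exp(log_permutation_count(d, 3)) == pytest.approx(3)  # 3!/1!/2!

    def test_m_below_j_rejected(self, two_by_two):
        with pytest.raises(ValueError):
            log_permutation_count(two_by_two, 1)


class TestHomogeneousLikelihood:
    def test_worked_value_m3(self, two_by_two):
        # 6 * p^2 (1-p)^4 at p = 0.5
        assert math.exp(homogeneous_loglik(two_by_two, 0.5, 3)) == pytest.approx(6 / 64)

    def test_worked_value_m2(self, two_by_two):
        assert math.exp(homogeneous_loglik(two_by_two, 0.5, 2)) == pytest.approx(0.125)

    def test_boundary_p_gives_minus_inf(self, two_by_two):
        assert homogeneous_loglik(two_by_two, 0.0, 3) == -math.inf
        assert homogeneous_loglik(two_by_two, 1.0, 3) == -math.inf

    @pytest.mark.parametrize("n,m,p", [(2, 3, 0.37), (3, 3, 0.2), (2, 4, 0.6)])
    def test_total_probability_over_observables(self, n, m, p):
        total = 0.0
        for d, _ in enumerate_observables(n, m):
            if d.degenerate:
                total += (1 - p) ** (n * m)
            else:
                total += math.exp(homogeneous_loglik(d, p, m))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_enumeration_count_equals_h(self):
        for n, m in [(2, 3), (3, 4), (2, 5)]:
            for d, count in enumerate_observables(n, m):
                if d.degenerate:
                    continue
                assert math.exp(log_permutation_count(d, m)) == pytest.approx(
                    count, rel=1e-9
                )

    def test_padded_matrix_mle_collapses_to_j(self, worked_matrix):
        # maximizing the padded-matrix likelihood (no permutation count)
        # over (m, p) gives the biased answer m = j, p = x../(n j):
        # the regression that motivates modelling d itself
        d = worked_matrix

        def padded_max_loglik(m):
            p = d.total_detections / (d.n * m)
            return d.total_detections * math.log(p) + (
                d.n * m - d.total_detections
            ) * math.log1p(-p)

        values = {m: padded_max_loglik(m) for m in range(d.j, d.j + 30)}
        assert max(values, key=values.get) == d.j
        assert naive_p(d).p == pytest.approx(d.total_detections / (d.n * d.j))


class TestHeterogeneousLikelihood:
    def test_sigma_zero_limit_matches_homogeneous(self, two_by_two):
        p = 0.3
        params = HeterogeneityParams(float(logit(p)), 1e-9)
        assert heterogeneous_loglik(two_by_two, params, 5) == pytest.approx(
            homogeneous_loglik(two_by_two, p, 5), abs=1e-6
        )

    def test_invariant_under_row_and_column_permutations(self):
        rng = np.random.default_rng(2)
        cells = (rng.random((5, 7)) < 0.4).astype(int)
        d = truncate_zero_columns(cells)
        params = HeterogeneityParams(-1.0, 0.8)
        ref = heterogeneous_loglik(d, params, 12)
        for _ in range(5):
            rp = rng.permutation(d.n)
            cp = rng.permutation(d.j)
            d2 = truncate_zero_columns(d.cells[rp][:, cp])
            assert heterogeneous_loglik(d2, params, 12) == pytest.approx(ref, rel=1e-12)

    @pytest.mark.parametrize(
        "mu,sigma", [(logit(0.1), 0.5), (logit(0.2), 1.0), (0.0, 2.0)]
    )
    def test_total_probability_over_observables(self, mu, sigma):
        n, m = 2, 3
        params = HeterogeneityParams(float(mu), sigma)
        q0 = column_pattern_lik(0, n, params)
        total = 0.0
        for d, _ in enumerate_observables(n, m):
            if d.degenerate:
                total += q0**m
            else:
                total += math.exp(heterogeneous_loglik(d, params, m))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_opposing_monotonicities_in_m(self, worked_matrix):
        # log H grows with m, the undiscovered-column penalty shrinks the
        # rest: the trade-off that identifies m
        params = HeterogeneityParams(float(logit(0.2)), 0.5)
        ms = range(worked_matrix.j, worked_matrix.j + 15)
        log_h = [log_permutation_count(worked_matrix, m) for m in ms]
        rest = [
            heterogeneous_loglik(worked_matrix, params, m)
            - log_permutation_count(worked_matrix, m)
            for m in ms
        ]
        assert all(b > a for a, b in zip(log_h, log_h[1:]))
        assert all(b < a for a, b in zip(rest, rest[1:]))

    def test_pattern_likelihood_sigma_zero(self):
        p = 0.25
        params = HeterogeneityParams(float(logit(p)), 1e-9)
        assert column_pattern_lik(2, 6, params) == pytest.approx(
            p**2 * (1 - p) ** 4, rel=1e-6
        )

    def test_monte_carlo_oracle_for_pattern_likelihood(self):
        from scipy.special import expit

        rng = np.random.default_rng(11)
        n, mu, sigma, N = 10, -1.5, 1.0, 200_000
        p = expit(mu + sigma * rng.standard_normal(N))
        params = HeterogeneityParams(mu, sigma)
        for k in (0, 2, 5):
            emp = (p**k * (1 - p) ** (n - k)).mean()
            se = (p**k * (1 - p) ** (n - k)).std() / math.sqrt(N)
            assert column_pattern_lik(k, n, params) == pytest.approx(
                emp, abs=3 * se + 1e-9
            )
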