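"""Unit and property tests of the four-block mixture core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invscan import mixture as mx
from conftest import (
    brute_force_mixture_loglik,
    dense_quartet,
    eval_mixture_loglik,
    sample_eq4_quartet,
)


class TestEncodeBlocks:
    def test_identity_mapping(self):
        q = mx.encode_blocks([["00", "0", "1", "11"], ["00", "1", "1", "00"], ["11", "0", "1", "11"]])
        assert list(q.codes[:, 0]) == [0, 0, 1]
        assert q.n_categories[0] == 2
        assert q.n_categories[2] == 1

    def test_single_observation(self):
        q = mx.encode_blocks([["010", "1", "00", "111"]])
        assert np.all(q.codes == 0)

    def test_ragged_lengths_error_names_column(self):
        with pytest.raises(ValueError, match="B2"):
            mx.encode_blocks([["00", "0", "1", "1"], ["00", "01", "1", "1"]])

    def test_non_binary_alleles_rejected(self):
        with pytest.raises(ValueError, match="B1"):
            mx.encode_blocks([["02", "0", "1", "1"]])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 15), min_size=1, max_size=12))
    def test_encode_decode_roundtrip(self, vals):
        strings = [[format(v, "04b"), "0", "0", "0"] for v in vals]
        q = mx.encode_blocks(strings)
        decoded = [q.decode(0, c) for c in q.codes[:, 0]]
        assert decoded == [s[0] for s in strings]
        # dense permutation of 0..K-1
        assert sorted(set(q.codes[:, 0])) == list(range(q.n_categories[0]))


class TestFitNull:
    def test_balanced_pairs(self):
        # two categories, twice each, in both pairings -> 8 * ln(0.5)
        q = dense_quartet([[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1]])
        nf = mx.fit_null(q)
        assert nf.loglik0 == pytest.approx(8 * np.log(0.5), abs=1e-12)
        assert nf.k0 == 2

    def test_identical_observations(self):
        q = dense_quartet([[1, 0, 1, 0]] * 5)
        assert mx.fit_null(q).loglik0 == pytest.approx(0.0, abs=1e-12)

    def test_small_quartet_matches_enumeration(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 2, size=(6, 4))
        q = dense_quartet(codes)
        nf = mx.fit_null(q)
        # direct enumeration of empirical joint frequencies
        ll = 0.0
        rows = [tuple(r) for r in q.codes]
        for b1, b2, b3, b4 in rows:
            p12 = sum(1 for r in rows if (r[0], r[1]) == (b1, b2)) / 6
            p34 = sum(1 for r in rows if (r[2], r[3]) == (b3, b4)) / 6
            ll += np.log(p12) + np.log(p34)
        assert nf.loglik0 == pytest.approx(ll, abs=1e-10)
        # tables are distributions
        assert nf.n12.sum() == pytest.approx(1.0, abs=1e-9)
        assert nf.n34.sum() == pytest.approx(1.0, abs=1e-9)


class TestFitMixture:
    def test_null_consistent_data_drives_pi_to_zero(self):
        # strong (B1,B2) and (B3,B4) coupling, no cross-pair structure:
        # the inverted factorization cannot represent it
        rng = np.random.default_rng(2)
        b1 = rng.integers(0, 2, 400)
        b3 = rng.integers(0, 2, 400)
        q = dense_quartet(np.stack([b1, b1, b3, b3], axis=1))
        nf = mx.fit_null(q)
        fit = mx.fit_mixture(q, nf)
        assert fit.pi < 0.05
        assert fit.loglik1 >= nf.loglik0 - 1e-9
        assert fit.loglik1 - nf.loglik0 < 1.0

    def test_em_trace_monotone(self):
        rng = np.random.default_rng(3)
        for seed in range(8):
            q, _ = sample_eq4_quartet(0.3, 60, np.random.default_rng(seed))
            fit = mx.fit_mixture(q)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_label_swap_symmetry(self):
        # relabeling the components (pi <-> 1-pi, forward role <-> inverted
        # role) leaves the mixture likelihood unchanged
        q, _ = sample_eq4_quartet(0.35, 200, np.random.default_rng(9))
        fit = mx.fit_mixture(q)
        ll = eval_mixture_loglik(q.codes, fit.pi, fit.f12, fit.f34, fit.r13, fit.r24)
        pf = fit.f12[q.codes[:, 0], q.codes[:, 1]] * fit.f34[q.codes[:, 2], q.codes[:, 3]]
        pv = fit.r13[q.codes[:, 0], q.codes[:, 2]] * fit.r24[q.codes[:, 1], q.codes[:, 3]]
        pi_swap = 1.0 - fit.pi
        ll_swap = float(np.log((1 - pi_swap) * pv + pi_swap * pf).sum())
        assert ll == pytest.approx(ll_swap, abs=1e-9)

    def test_degenerate_identical_rows(self):
        q = dense_quartet([[0, 1, 0, 1]] * 10)
        nf = mx.fit_null(q)
        fit = mx.fit_mixture(q, nf)
        assert fit.converged
        assert fit.loglik1 == pytest.approx(nf.loglik0, abs=1e-9)

    def test_invalid_arguments(self):
        q = dense_quartet([[0, 0, 0, 0], [1, 1, 1, 1]])
        with pytest.raises(ValueError):
            mx.fit_mixture(q, tol=0.0)
        with pytest.raises(ValueError):
            mx.fit_mixture(q, max_iter=0)

    def test_tiny_instances_match_brute_force(self):
        # the full 50-quartet battery runs in the acceptance suite
        rng = np.random.default_rng(21)
        for seed in range(6):
            r = np.random.default_rng(seed)
            m = int(r.integers(4, 9))
            q = dense_quartet(r.integers(0, 2, size=(m, 4)))
            fit = mx.fit_mixture(q, tol=1e-10, max_iter=5000, n_starts=8)
            oracle = brute_force_mixture_loglik(q, rng)
            assert fit.loglik1 == pytest.approx(oracle, abs=1e-4)

    def test_pi_recovery_spot_checks(self):
        for pi in (0.2, 0.5, 0.8):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(1000 * seed + int(pi * 10))
                q, _ = sample_eq4_quartet(pi, 2000, rng)
                fit = mx.fit_mixture(q)
                errs.append(abs(fit.pi - pi))
            assert np.median(errs) <= 0.05


class TestResponsibilities:
    def _hand_fit(self):
        # 2x2 tables set by hand over 2 categories per column
        f12 = np.array([[0.5, 0.1], [0.2, 0.2]])
        f34 = np.array([[0.4, 0.2], [0.3, 0.1]])
        r13 = np.array([[0.25, 0.25], [0.25, 0.25]])
        r24 = np.array([[0.7, 0.1], [0.1, 0.1]])
        return mx.MixtureFit(
            pi=0.3, f12=f12, f34=f34, r13=r13, r24=r24, loglik1=0.0,
            resp_fwd=None, n_iter=1, converged=True, support_r13=4, support_r24=4,
        )

    def test_hand_evaluation(self):
        fit = self._hand_fit()
        q = dense_quartet([[0, 0, 0, 0], [1, 0, 1, 1], [0, 1, 1, 0]])
        r0 = mx.responsibilities(fit, q)
        for i, (b1, b2, b3, b4) in enumerate(q.codes):
            pf = fit.f12[b1, b2] * fit.f34[b3, b4]
            pv = fit.r13[b1, b3] * fit.r24[b2, b4]
            assert r0[i] == pytest.approx(pf / (pf + pv), abs=1e-12)

    def test_symmetric_densities_give_half(self):
        fit = self._hand_fit()
        fit.r13 = fit.f12.copy()
        fit.r24 = np.ones((2, 2)) * 0.25
        fit.f34 = np.ones((2, 2)) * 0.25
        # choose observation where pf == pv by construction
        q = dense_quartet([[0, 0, 0, 0], [1, 1, 1, 1]])
        r0 = mx.responsibilities(fit, q)
        assert r0[0] == pytest.approx(0.5, abs=1e-12)

    def test_normalization_exact(self):
        q, _ = sample_eq4_quartet(0.4, 100, np.random.default_rng(4))
        fit = mx.fit_mixture(q)
        r1 = 1.0 - fit.resp_fwd
        assert np.all(fit.resp_fwd + r1 == 1.0)
        assert np.all((fit.resp_fwd >= 0) & (fit.resp_fwd <= 1))

    def test_unseen_inverted_support_pre_floor(self):
        # category combination absent from the inverted tables (floored):
        # responsibility goes to ~1 for the forward model
        fit = self._hand_fit()
        fit.r13 = np.array([[1.0, 0.0], [0.0, 0.0]])
        fit.r24 = np.array([[1.0, 0.0], [0.0, 0.0]])
        q = dense_quartet([[1, 1, 1, 1], [0, 0, 0, 0]])
        r0 = mx.responsibilities(fit, q)
        assert r0[0] > 1 - 1e-6

    def test_zero_densities_default_half_and_count(self):
        fit = self._hand_fit()
        fit.f12 = np.zeros((2, 2))
        fit.f34 = np.zeros((2, 2))
        fit.r13 = np.zeros((2, 2))
        fit.r24 = np.zeros((2, 2))
        before = mx.ZERO_DENSITY_EVENTS["count"]
        q = dense_quartet([[0, 0, 0, 0]])
        r0 = mx.responsibilities(fit, q)
        assert r0[0] == 0.5
        assert mx.ZERO_DENSITY_EVENTS["count"] == before + 1


class TestScoreModels:
    def test_collapsed_mixture_is_negative(self):
        q = dense_quartet([[0, 1, 0, 1]] * 10)
        nf = mx.fit_null(q)
        fit = mx.fit_mixture(q, nf)
        sc = mx.score_models(nf, fit, q.m)
        assert sc.bic == pytest.approx(-sc.delta_k * np.log(10), abs=1e-9)
        assert sc.bic < 0

    def test_arithmetic_identity(self):
        nf = mx.NullFit(n12=np.eye(2) / 2, n34=np.eye(2) / 2, loglik0=-30.0, k0=2)
        fit = mx.MixtureFit(
            pi=0.4, f12=None, f34=None, r13=None, r24=None, loglik1=-20.0,
            resp_fwd=None, n_iter=1, converged=True, support_r13=2, support_r24=2,
        )
        sc = mx.score_models(nf, fit, 50)
        assert sc.delta_k == 3
        assert sc.bic == pytest.approx(2 * 10 - 3 * np.log(50), abs=1e-12)

    def test_too_few_observations(self):
        nf = mx.NullFit(n12=np.eye(1), n34=np.eye(1), loglik0=0.0, k0=0)
        fit = mx.MixtureFit(
            pi=0.0, f12=None, f34=None, r13=None, r24=None, loglik1=0.0,
            resp_fwd=None, n_iter=1, converged=True, support_r13=1, support_r24=1,
        )
        with pytest.raises(ValueError):
            mx.score_models(nf, fit, 1)

    def test_genuine_mixture_scores_positive(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            q, _ = sample_eq4_quartet(0.4, 2000, rng)
            nf = mx.fit_null(q)
            fit = mx.fit_mixture(q, nf)
            if mx.score_models(nf, fit, q.m).bic > 0:
                hits += 1
        assert hits >= 9
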