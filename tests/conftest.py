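"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from invscan.mixture import BlockQuartet

# ---------------------------------------------------------------------------
# quartet generators


def dense_quartet(codes):
    """BlockQuartet from raw integer codes, densified per column."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty_like(codes)
    maps = []
    for j in range(4):
        cats, inv = np.unique(codes[:, j], return_inverse=True)
        out[:, j] = inv
        maps.append([format(int(c), "02b") for c in cats])
    return BlockQuartet(out, maps)


def sample_eq4_quartet(pi, m, rng, k_sub=2):
    """Sample observations from the mixture density with disjoint supports.

    Forward observations use categories 0..k_sub-1 in every column,
    inverted ones k_sub..2*k_sub-1; joint tables are Dirichlet draws.
    Returns (quartet, true inverted fraction of the sample).
    """
    f12 = rng.dirichlet(np.ones(k_sub * k_sub))
    f34 = rng.dirichlet(np.ones(k_sub * k_sub))
    r13 = rng.dirichlet(np.ones(k_sub * k_sub))
    r24 = rng.dirichlet(np.ones(k_sub * k_sub))
    z = rng.random(m) < pi
    codes = np.empty((m, 4), np.int64)
    nf = int((~z).sum())
    ni = m - nf
    a = rng.choice(k_sub * k_sub, size=nf, p=f12)
    b = rng.choice(k_sub * k_sub, size=nf, p=f34)
    codes[~z, 0], codes[~z, 1] = divmod(a, k_sub)
    codes[~z, 2], codes[~z, 3] = divmod(b, k_sub)
    a = rng.choice(k_sub * k_sub, size=ni, p=r13)
    b = rng.choice(k_sub * k_sub, size=ni, p=r24)
    b1, b3 = divmod(a, k_sub)
    b2, b4 = divmod(b, k_sub)
    codes[z, 0], codes[z, 2] = b1 + k_sub, b3 + k_sub
    codes[z, 1], codes[z, 3] = b2 + k_sub, b4 + k_sub
    k = 2 * k_sub
    maps = [[format(c, "02b") for c in range(k)]] * 4
    return BlockQuartet(codes, maps), z.mean()


# ---------------------------------------------------------------------------
# independent mixture-likelihood oracle (plain numpy, no shared code paths)

_EPS = 1e-12


def eval_mixture_loglik(codes, pi, f12, f34, r13, r24):
    """Direct evaluation of the mixture log-likelihood for given parameters."""
    pf = f12[codes[:, 0], codes[:, 1]] * f34[codes[:, 2], codes[:, 3]]
    pv = r13[codes[:, 0], codes[:, 2]] * r24[codes[:, 1], codes[:, 3]]
    return float(np.log(np.clip((1 - pi) * pf + pi * pv, _EPS**2, None)).sum())


def _norm(t):
    t = np.clip(t, _EPS, None)
    return t / t.sum()


def _oracle_em(codes, k, pi, f12, f34, r13, r24, free_pi, iters=600, tol=1e-11):
    prev = -np.inf
    ll = prev
    for _ in range(iters):
        pf = f12[codes[:, 0], codes[:, 1]] * f34[codes[:, 2], codes[:, 3]]
        pv = r13[codes[:, 0], codes[:, 2]] * r24[codes[:, 1], codes[:, 3]]
        mix = np.clip((1 - pi) * pf + pi * pv, _EPS**2, None)
        ll = float(np.log(mix).sum())
        if ll - prev < tol:
            break
        prev = ll
        w = pi * pv / mix
        if free_pi:
            pi = w.mean()
        if (1 - w).sum() > 1e-9:
            f12 = np.zeros((k, k))
            f34 = np.zeros((k, k))
            np.add.at(f12, (codes[:, 0], codes[:, 1]), 1 - w)
            np.add.at(f34, (codes[:, 2], codes[:, 3]), 1 - w)
            f12, f34 = _norm(f12), _norm(f34)
        if w.sum() > 1e-9:
            r13 = np.zeros((k, k))
            r24 = np.zeros((k, k))
            np.add.at(r13, (codes[:, 0], codes[:, 2]), w)
            np.add.at(r24, (codes[:, 1], codes[:, 3]), w)
            r13, r24 = _norm(r13), _norm(r24)
    return ll


def brute_force_mixture_loglik(q, rng, n_random=5, n_grid=51):
    """Grid on pi with multi-start EM on the tables, plus free-pi polishing.

    Independent maximizer of the mixture likelihood for tiny quartets; used
    as the reference for the packaged EM.
    """
    codes = q.codes
    k = max(q.n_categories)
    m = q.m
    emp12 = _norm(np.bincount(codes[:, 0] * k + codes[:, 1], minlength=k * k).reshape(k, k).astype(float) / m)
    emp34 = _norm(np.bincount(codes[:, 2] * k + codes[:, 3], minlength=k * k).reshape(k, k).astype(float) / m)
    emp13 = _norm(np.bincount(codes[:, 0] * k + codes[:, 2], minlength=k * k).reshape(k, k).astype(float) / m)
    emp24 = _norm(np.bincount(codes[:, 1] * k + codes[:, 3], minlength=k * k).reshape(k, k).astype(float) / m)

    def rand_t():
        return _norm(rng.dirichlet(np.ones(k * k)).reshape(k, k))

    best = -np.inf
    for pi0 in np.linspace(0.0, 1.0, n_grid):
        for s in range(n_random + 1):
            if s == 0:
                t = (emp12, emp34, emp13, emp24)
            else:
                t = (rand_t(), rand_t(), rand_t(), rand_t())
            best = max(best, _oracle_em(codes, k, pi0, *t, free_pi=False))
    for s in range(30):
        t = (emp12, emp34, emp13, emp24) if s == 0 else (rand_t(), rand_t(), rand_t(), rand_t())
        pi0 = 0.5 if s == 0 else float(rng.random())
        best = max(best, _oracle_em(codes, k, pi0, *t, free_pi=True, iters=1500))
    return best


# ---------------------------------------------------------------------------
# small simulated populations (shared across tests, module-independent sizes)


@pytest.fixture(scope="session")
def small_sim():
    """1 Mb population of 500 subjects with a 0.4 Mb inversion at 40%."""
    from invscan.simulate import SimConfig, simulate_population

    cfg = SimConfig(
        segment_length_bp=1_000_000,
        inv_start_bp=300_000,
        inv_end_bp=700_000,
        inv_freq=0.4,
        n_subjects=500,
        seed=7,
    )
    hap, geno, truth = simulate_population(cfg)
    return cfg, hap, geno, truth


@pytest.fixture(scope="session")
def small_null_sim():
    from invscan.simulate import SimConfig, simulate_null

    cfg = SimConfig(segment_length_bp=1_000_000, inv_start_bp=300_000, inv_end_bp=700_000, n_subjects=300, seed=11)
    hap, geno, truth = simulate_null(cfg)
    return cfg, hap, geno, truth
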