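"""Compiled EM kernels.

Two expectation-maximization loops dominate the scan runtime: the
four-block mixture fit (run twice per window) and the multilocus
haplotype-frequency fit used for local phasing (run once per candidate
breakpoint).  Both operate on weighted unique observations and are
compiled with numba.
"""

import numpy as np
from numba import njit

# Probability floor for unseen categories: keeps log-likelihoods finite
# without letting hard zeros lock the support during EM.
PROB_FLOOR = 1e-12


@njit(cache=True)
def _floor_norm(t):
    s = 0.0
    for k in range(t.size):
        if t[k] < PROB_FLOOR:
            t[k] = PROB_FLOOR
        s += t[k]
    for k in range(t.size):
        t[k] /= s


@njit(cache=True)
def mixture_em(i12, i34, i13, i24, w, f12, f34, r13, r24, pi0, tol, max_iter):
    """EM for the forward/inverted mixture over weighted unique quartet rows.

    ``i12`` .. ``i24`` are flattened joint-category indices per unique row,
    ``w`` the row multiplicities; the table arguments are the initial
    conditions (modified in place).  Returns the fitted tables, the mixture
    frequency, the log-likelihood trace and a convergence flag.  The E-step
    uses the standard pi-weighted posteriors.
    """
    n_rows = w.size
    k12 = f12.size
    k34 = f34.size
    k13 = r13.size
    k24 = r24.size
    m = 0.0
    for u in range(n_rows):
        m += w[u]

    pi = pi0
    wi = np.empty(n_rows)
    trace = np.empty(max_iter)
    prev = -1e300
    converged = False
    n_done = 0
    for it in range(max_iter):
        ll = 0.0
        for u in range(n_rows):
            pf = f12[i12[u]] * f34[i34[u]]
            pv = r13[i13[u]] * r24[i24[u]]
            mix = (1.0 - pi) * pf + pi * pv
            ll += w[u] * np.log(mix)
            wi[u] = pi * pv / mix
        trace[it] = ll
        n_done = it + 1
        if ll - prev < tol:
            converged = True
            break
        prev = ll

        sw = 0.0
        for u in range(n_rows):
            sw += w[u] * wi[u]
        pi = sw / m
        if sw > 1e-10:
            for k in range(k13):
                r13[k] = 0.0
            for k in range(k24):
                r24[k] = 0.0
            for u in range(n_rows):
                r13[i13[u]] += w[u] * wi[u]
                r24[i24[u]] += w[u] * wi[u]
            _floor_norm(r13)
            _floor_norm(r24)
        sf = m - sw
        if sf > 1e-10:
            for k in range(k12):
                f12[k] = 0.0
            for k in range(k34):
                f34[k] = 0.0
            for u in range(n_rows):
                f12[i12[u]] += w[u] * (1.0 - wi[u])
                f34[i34[u]] += w[u] * (1.0 - wi[u])
            _floor_norm(f12)
            _floor_norm(f34)

    return pi, f12, f34, r13, r24, trace[:n_done], converged


@njit(cache=True)
def enumerate_pairs(row, out_a, out_b):
    """Enumerate unordered haplotype pairs compatible with one genotype row.

    ``row`` holds per-SNP genotype codes (0/1/2, -1 missing).  Haplotypes are
    bit-packed with the first SNP in the highest bit.  Writes canonical
    (a <= b) pairs into ``out_a``/``out_b`` and returns the count.
    """
    n = row.size
    het_bit = np.empty(n, np.int64)
    mis_bit = np.empty(n, np.int64)
    nh = 0
    nm = 0
    base = 0
    for s in range(n):
        g = row[s]
        bit = n - 1 - s
        if g == 1:
            het_bit[nh] = bit
            nh += 1
        elif g == 2:
            base |= 1 << bit
        elif g < 0:
            mis_bit[nm] = bit
            nm += 1
    total = (1 << nh) * (1 << (2 * nm))
    cnt = 0
    for c in range(total):
        a = base
        b = base
        cc = c
        for t in range(nh):
            if cc & 1:
                a |= 1 << het_bit[t]
            else:
                b |= 1 << het_bit[t]
            cc >>= 1
        for t in range(nm):
            if cc & 1:
                a |= 1 << mis_bit[t]
            cc >>= 1
            if cc & 1:
                b |= 1 << mis_bit[t]
            cc >>= 1
        if a <= b:
            out_a[cnt] = a
            out_b[cnt] = b
            cnt += 1
    return cnt


@njit(cache=True)
def enumerate_rows(rows, out_a, out_b, out_row):
    """Enumerate compatible pairs for a matrix of unique genotype rows.

    Returns the total pair count, or -1 if any row has too many ambiguous
    sites for the output buffers.
    """
    cnt = 0
    cap = out_a.size
    for r in range(rows.shape[0]):
        row = rows[r]
        n_amb = 0
        for s in range(row.size):
            if row[s] == 1:
                n_amb += 1
            elif row[s] < 0:
                n_amb += 2
        if cnt + (1 << n_amb) > cap:
            return -1
        k = enumerate_pairs(row, out_a[cnt:], out_b[cnt:])
        for t in range(k):
            out_row[cnt + t] = r
        cnt += k
    return cnt


@njit(cache=True)
def phase_em(pair_row, a, b, row_w, n_rows, n_hap, tol, max_iter):
    """EM over multilocus haplotype frequencies.

    ``pair_row`` maps each candidate haplotype pair to its (unique) genotype
    row; ``a``/``b`` are dense haplotype ids; ``row_w`` row multiplicities.
    Returns the frequency vector, per-row best pair index, its posterior,
    the final log-likelihood and a convergence flag.
    """
    n_pairs = a.size
    p = np.full(n_hap, 1.0 / n_hap)
    lik = np.empty(n_pairs)
    rs = np.empty(n_rows)
    total_w = 0.0
    for r in range(n_rows):
        total_w += row_w[r]

    prev = -1e300
    converged = False
    ll = 0.0
    for _ in range(max_iter):
        for t in range(n_pairs):
            v = p[a[t]] * p[b[t]]
            if a[t] != b[t]:
                v *= 2.0
            lik[t] = v
        for r in range(n_rows):
            rs[r] = 0.0
        for t in range(n_pairs):
            rs[pair_row[t]] += lik[t]
        ll = 0.0
        for r in range(n_rows):
            ll += row_w[r] * np.log(rs[r])
        if ll - prev < tol:
            converged = True
            break
        prev = ll

        cnt = np.zeros(n_hap)
        for t in range(n_pairs):
            r = pair_row[t]
            wt = row_w[r] * lik[t] / rs[r]
            cnt[a[t]] += wt
            cnt[b[t]] += wt
        s = 0.0
        for h in range(n_hap):
            if cnt[h] < PROB_FLOOR:
                cnt[h] = PROB_FLOOR
            s += cnt[h]
        for h in range(n_hap):
            p[h] = cnt[h] / s

    best = np.full(n_rows, -1, np.int64)
    best_lik = np.zeros(n_rows)
    for t in range(n_pairs):
        r = pair_row[t]
        if lik[t] > best_lik[r]:
            best_lik[r] = lik[t]
            best[r] = t
    post = np.empty(n_rows)
    for r in range(n_rows):
        post[r] = best_lik[r] / rs[r]
    return p, best, post, ll, converged
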