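"""Compiled inner loops for the diploid haplotype-copying HMM.

The hidden state at site i is an ordered pair (x, y) of template haplotype
indices.  The per-haplotype transition kernel is

    t(w | x) = (1 - theta) * [w == x] + theta / H,

whose product over the two haplotypes reproduces the three-case ordered-pair
transition table (both jump, one jumps, both stay).  This factorization lets
every forward/backward step run in O(H^2) via row/column sums instead of the
naive O(H^4).

Emission values depend on the state only through the template allele pair
(a_x, a_y), so each site carries a 2x2 emission table ``V[i, a_x, a_y]``.
Forward variables are normalized per site; the log of the accumulated scale
factors is the total log-likelihood.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def forward_pass(alleles, V, theta, out=None):
    """Forward matrices for the ordered-pair copying HMM.

    alleles: (H, M) uint8 template alleles; V: (M, 2, 2) emission values by
    template allele pair; theta: (M-1,) per-interval jump rates.  Returns
    (F, loglik).  Each F[i] is the forward distribution up to an overall
    per-site scale (its entries are mutually proportional to P(S_i, R_1..i));
    downstream consumers renormalize per site, which keeps this pass to a
    single fused sweep per site.
    """
    H, M = alleles.shape
    aT = np.empty((M, H), dtype=np.uint8)  # site-major copy for streaming
    for w in range(H):
        for i in range(M):
            aT[i, w] = alleles[w, i]
    F = out if out is not None else np.empty((M, H, H), dtype=V.dtype)
    rs = np.zeros(H)
    cs = np.zeros(H)
    loglik = 0.0

    s = 0.0
    for w in range(H):
        aw = aT[0, w]
        rsw = 0.0
        for v in range(H):
            val = V[0, aw, aT[0, v]]
            F[0, w, v] = val
            rsw += val
            cs[v] += val
        rs[w] = rsw
        s += rsw
    if s <= 0.0:
        raise ValueError("total likelihood underflow in forward pass")
    loglik += np.log(s / (H * H))

    prev_rs = np.empty(H)
    prev_cs = np.empty(H)
    for i in range(1, M):
        th = theta[i - 1]
        a = 1.0 - th
        b = th / H
        # previous-site values are unnormalized with total s: fold 1/s into
        # the transition constants instead of a separate normalization sweep
        inv = 1.0 / s
        aa = a * a * inv
        ab = a * b * inv
        bb = b * b  # multiplies tot * inv = 1
        new_s = 0.0
        for w in range(H):
            prev_rs[w] = rs[w]
            prev_cs[w] = cs[w]
            rs[w] = 0.0
            cs[w] = 0.0
        for w in range(H):
            aw = aT[i, w]
            e0 = V[i, aw, 0]
            e1 = V[i, aw, 1]
            base = ab * prev_rs[w] + bb
            rsw = 0.0
            for v in range(H):
                g = aa * F[i - 1, w, v] + ab * prev_cs[v] + base
                val = (e1 if aT[i, v] == 1 else e0) * g
                F[i, w, v] = val
                rsw += val
                cs[v] += val
            rs[w] = rsw
            new_s += rsw
        if new_s <= 0.0:
            raise ValueError("total likelihood underflow in forward pass")
        loglik += np.log(new_s)
        s = new_s
    return F, loglik


@njit(cache=True)
def backward_posteriors(alleles, V, theta, F):
    """Per-site posterior P(S_i | R) via a scaled backward pass.

    Returns (M, H, H) posterior matrices, each summing to 1.
    """
    H, M = alleles.shape
    post = np.empty((M, H, H))
    B = np.ones((H, H))
    # last site
    s = 0.0
    for w in range(H):
        for v in range(H):
            p = F[M - 1, w, v]
            post[M - 1, w, v] = p
            s += p
    inv = 1.0 / s
    for w in range(H):
        for v in range(H):
            post[M - 1, w, v] *= inv

    D = np.empty((H, H))
    rs = np.empty(H)
    cs = np.empty(H)
    for i in range(M - 2, -1, -1):
        th = theta[i]
        a = 1.0 - th
        b = th / H
        for w in range(H):
            rs[w] = 0.0
            cs[w] = 0.0
        tot = 0.0
        for w in range(H):
            aw = alleles[w, i + 1]
            for v in range(H):
                d = V[i + 1, aw, alleles[v, i + 1]] * B[w, v]
                D[w, v] = d
                rs[w] += d
                cs[v] += d
                tot += d
        aa = a * a
        ab = a * b
        bb = b * b * tot
        bmax = 0.0
        for x in range(H):
            for y in range(H):
                val = aa * D[x, y] + ab * (rs[x] + cs[y]) + bb
                B[x, y] = val
                if val > bmax:
                    bmax = val
        inv = 1.0 / bmax
        s = 0.0
        for x in range(H):
            for y in range(H):
                B[x, y] *= inv
                p = F[i, x, y] * B[x, y]
                post[i, x, y] = p
                s += p
        inv = 1.0 / s
        for x in range(H):
            for y in range(H):
                post[i, x, y] *= inv
    return post


@njit(cache=True)
def sample_path(alleles, theta, F, FR, u):
    """Backward-sample one state path from P(S_1..M | R).

    u: (M,) iid uniforms; FR: (M, H) per-site row sums of F (shared across
    repeated draws).  Per-haplotype factorization makes each backward step
    O(H): sample x from its marginal (given the next state), then y | x.
    Returns (M, 2) template index pairs.
    """
    H, M = alleles.shape
    path = np.empty((M, 2), dtype=np.int64)

    # site M-1: sample (x, y) from F[M-1] (normalize on the fly)
    tot_last = 0.0
    for w in range(H):
        for v in range(H):
            tot_last += F[M - 1, w, v]
    target = u[M - 1] * tot_last
    acc = 0.0
    xs = H - 1
    ys = H - 1
    done = False
    for w in range(H):
        for v in range(H):
            acc += F[M - 1, w, v]
            if acc >= target and not done:
                xs = w
                ys = v
                done = True
    path[M - 1, 0] = xs
    path[M - 1, 1] = ys

    wx = np.empty(H)
    for i in range(M - 2, -1, -1):
        th = theta[i]
        a = 1.0 - th
        b = th / H
        w_next = path[i + 1, 0]
        v_next = path[i + 1, 1]
        # marginal over x: wx[x] = t(w_next|x) * sum_y F[i,x,y] t(v_next|y)
        #                        = t(w_next|x) * (a*F[i,x,v_next] + b*rowsum_x)
        tot = 0.0
        for x in range(H):
            inner = a * F[i, x, v_next] + b * FR[i, x]
            tx = b + (a if x == w_next else 0.0)
            wx[x] = tx * inner
            tot += wx[x]
        target = u[i] * tot
        # split the uniform: integer part selects x, fractional reuse for y
        acc = 0.0
        xs = H - 1
        for x in range(H):
            acc += wx[x]
            if acc >= target:
                xs = x
                break
        # conditional over y given x = xs, using the leftover uniform mass
        frac = (wx[xs] - (acc - target)) / wx[xs]
        toty = 0.0
        for y in range(H):
            ty = b + (a if y == v_next else 0.0)
            toty += F[i, xs, y] * ty
        target_y = frac * toty
        acc = 0.0
        ys = H - 1
        for y in range(H):
            ty = b + (a if y == v_next else 0.0)
            acc += F[i, xs, y] * ty
            if acc >= target_y:
                ys = y
                break
        path[i, 0] = xs
        path[i, 1] = ys
    return path


@njit(cache=True)
def transmission_forward_sample(Mc, sigma, u):
    """Forward-filter/backward-sample the 4-state transmission-slot chain.

    States encode (paternal slot, maternal slot) as 2*tf + tm; the chain
    starts in state 0 (both first slots transmitted) and each parent's slot
    switches between adjacent sites with probability sigma[i] (recombination
    within the family).  Mc: (M, 4) per-site emission values from the child's
    read likelihoods; u: (M,) uniforms.  Returns the sampled slot path (M,).
    """
    M = Mc.shape[0]
    F = np.empty((M, 4))
    f = np.zeros(4)
    f[0] = Mc[0, 0]
    s = f[0]
    for k in range(4):
        F[0, k] = f[k] / s
    for i in range(1, M):
        sg = sigma[i - 1]
        stay = 1.0 - sg
        s = 0.0
        for k in range(4):
            tf, tm = k // 2, k % 2
            acc = 0.0
            for kp in range(4):
                pf, pm = kp // 2, kp % 2
                w = (stay if tf == pf else sg) * (stay if tm == pm else sg)
                acc += F[i - 1, kp] * w
            val = acc * Mc[i, k]
            F[i, k] = val
            s += val
        if s <= 0.0:
            raise ValueError("transmission chain underflow")
        for k in range(4):
            F[i, k] /= s
    path = np.empty(M, dtype=np.int64)
    # sample last state
    target = u[M - 1]
    acc = 0.0
    ks = 3
    for k in range(4):
        acc += F[M - 1, k]
        if acc >= target:
            ks = k
            break
    path[M - 1] = ks
    for i in range(M - 2, -1, -1):
        sg = sigma[i]
        stay = 1.0 - sg
        nf, nm = path[i + 1] // 2, path[i + 1] % 2
        tot = 0.0
        wts = np.empty(4)
        for k in range(4):
            tf, tm = k // 2, k % 2
            w = (stay if nf == tf else sg) * (stay if nm == tm else sg)
            wts[k] = F[i, k] * w
            tot += wts[k]
        target = u[i] * tot
        acc = 0.0
        ks = 3
        for k in range(4):
            acc += wts[k]
            if acc >= target:
                ks = k
                break
        path[i] = ks
    return path


@njit(cache=True)
def orient_viterbi(h0, h1, p0, p1, switch_cost):
    """Best per-site slot assignment of a sampled pair against running votes.

    h0, h1: the round's two haplotypes (0/1); p0, p1: running per-slot vote
    fractions.  Orientation 0 keeps (h0 -> slot 0, h1 -> slot 1); orientation
    1 swaps.  Cost is the summed allele disagreement plus ``switch_cost`` per
    orientation change; ties prefer keeping the previous orientation, then
    orientation 0.  Returns the minimizing orientation per site.
    """
    M = h0.size
    bp = np.empty((M, 2), dtype=np.int64)
    c0 = abs(h0[0] - p0[0]) + abs(h1[0] - p1[0])
    c1 = abs(h1[0] - p0[0]) + abs(h0[0] - p1[0])
    for i in range(1, M):
        e0 = abs(h0[i] - p0[i]) + abs(h1[i] - p1[i])
        e1 = abs(h1[i] - p0[i]) + abs(h0[i] - p1[i])
        # state 0
        if c0 <= c1 + switch_cost:
            n0 = c0 + e0
            bp[i, 0] = 0
        else:
            n0 = c1 + switch_cost + e0
            bp[i, 0] = 1
        # state 1
        if c1 <= c0 + switch_cost:
            n1 = c1 + e1
            bp[i, 1] = 1
        else:
            n1 = c0 + switch_cost + e1
            bp[i, 1] = 0
        c0, c1 = n0, n1
    orient = np.empty(M, dtype=np.uint8)
    cur = 0 if c0 <= c1 else 1
    orient[M - 1] = cur
    for i in range(M - 1, 0, -1):
        cur = bp[i, cur]
        orient[i - 1] = cur
    return orient


@njit(cache=True)
def posterior_allele_pair_counts(alleles, post):
    """Collapse state posteriors to P(T(S) = t | R) for t in {0, 1, 2}.

    T(S) is the alt-allele count carried by the two templates at the site.
    """
    H, M = alleles.shape
    pT = np.zeros((M, 3))
    for i in range(M):
        for w in range(H):
            aw = alleles[w, i]
            for v in range(H):
                pT[i, aw + alleles[v, i]] += post[i, w, v]
    return pT
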