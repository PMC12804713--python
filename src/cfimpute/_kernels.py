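"""Numba inner loops for the haploid copying HMM and the read-label sampler.

The transition kernel between grids is the uniform-switch Li & Stephens
kernel: stay with probability 1 - sigma + sigma/K, switch to each other
state with sigma/K, which keeps every recursion O(K) per grid.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_ll(logem, sigma):
    """Scaled forward pass; returns log P(observations) for one label class.

    logem: (G, K) per-grid per-state log emission; sigma: (G-1,) switch probs.
    """
    G, K = logem.shape
    alpha = np.empty(K)
    m = logem[0, 0]
    for k in range(1, K):
        if logem[0, k] > m:
            m = logem[0, k]
    s = 0.0
    for k in range(K):
        alpha[k] = np.exp(logem[0, k] - m) / K
        s += alpha[k]
    ll = np.log(s) + m
    for k in range(K):
        alpha[k] /= s
    for g in range(1, G):
        sg = sigma[g - 1]
        m = logem[g, 0]
        for k in range(1, K):
            if logem[g, k] > m:
                m = logem[g, k]
        s = 0.0
        for k in range(K):
            alpha[k] = ((1.0 - sg) * alpha[k] + sg / K) * np.exp(logem[g, k] - m)
            s += alpha[k]
        ll += np.log(s) + m
        for k in range(K):
            alpha[k] /= s
    return ll


@njit(cache=True)
def forward_backward(logem, sigma):
    """Posterior state probabilities gamma (G, K), rows summing to 1."""
    G, K = logem.shape
    em = np.empty((G, K))
    for g in range(G):
        m = logem[g, 0]
        for k in range(1, K):
            if logem[g, k] > m:
                m = logem[g, k]
        for k in range(K):
            em[g, k] = np.exp(logem[g, k] - m)
    alpha = np.empty((G, K))
    s = 0.0
    for k in range(K):
        alpha[0, k] = em[0, k] / K
        s += alpha[0, k]
    for k in range(K):
        alpha[0, k] /= s
    for g in range(1, G):
        sg = sigma[g - 1]
        s = 0.0
        for k in range(K):
            alpha[g, k] = ((1.0 - sg) * alpha[g - 1, k] + sg / K) * em[g, k]
            s += alpha[g, k]
        for k in range(K):
            alpha[g, k] /= s
    beta = np.empty((G, K))
    for k in range(K):
        beta[G - 1, k] = 1.0
    for g in range(G - 2, -1, -1):
        sg = sigma[g]
        tot = 0.0
        w = np.empty(K)
        for k in range(K):
            w[k] = em[g + 1, k] * beta[g + 1, k]
            tot += w[k]
        s = 0.0
        for k in range(K):
            beta[g, k] = (1.0 - sg) * w[k] + sg / K * tot
            s += beta[g, k]
        for k in range(K):
            beta[g, k] /= s
    gamma = np.empty((G, K))
    for g in range(G):
        s = 0.0
        for k in range(K):
            gamma[g, k] = alpha[g, k] * beta[g, k]
            s += gamma[g, k]
        for k in range(K):
            gamma[g, k] /= s
    return gamma


@njit(cache=True)
def gibbs_sweep_kernel(labels, E, fptr, fgrid, flog, sigma, logprior, order, unif,
                       greedy=False):
    """One seeded-order sweep of per-fragment label resampling (in place).

    labels: (V,) current label of each fragment (0-based class index)
    E: (n_lab, G, K) per-class accumulated log emissions
    fptr/fgrid/flog: CSR fragment observation layout; entry e contributes
        flog[e, :] to grid fgrid[e] of whichever class owns the fragment
    order: visitation order; unif: one uniform draw per visit
    greedy: take the argmax label instead of sampling (ICM polish)
    """
    nlab, G, K = E.shape
    for ii in range(order.size):
        v = order[ii]
        old = labels[v]
        e0, e1 = fptr[v], fptr[v + 1]
        if e0 == e1:
            if greedy:
                continue  # no evidence: leave the label alone
            # no evidence: draw from the prior
            m = logprior[0]
            for c in range(1, nlab):
                if logprior[c] > m:
                    m = logprior[c]
            tot = 0.0
            p = np.empty(nlab)
            for c in range(nlab):
                p[c] = np.exp(logprior[c] - m)
                tot += p[c]
            u = unif[ii] * tot
            acc = 0.0
            new = nlab - 1
            for c in range(nlab):
                acc += p[c]
                if u < acc:
                    new = c
                    break
            labels[v] = new
            continue
        for e in range(e0, e1):
            g = fgrid[e]
            for k in range(K):
                E[old, g, k] -= flog[e, k]
        logp = np.empty(nlab)
        for c in range(nlab):
            if logprior[c] == -np.inf:
                logp[c] = -np.inf
                continue
            base = forward_ll(E[c], sigma)
            for e in range(e0, e1):
                g = fgrid[e]
                for k in range(K):
                    E[c, g, k] += flog[e, k]
            with_v = forward_ll(E[c], sigma)
            for e in range(e0, e1):
                g = fgrid[e]
                for k in range(K):
                    E[c, g, k] -= flog[e, k]
            logp[c] = logprior[c] + with_v - base
        if greedy:
            new = 0
            for c in range(1, nlab):
                if logp[c] > logp[new]:
                    new = c
        else:
            m = logp[0]
            for c in range(1, nlab):
                if logp[c] > m:
                    m = logp[c]
            tot = 0.0
            p = np.empty(nlab)
            for c in range(nlab):
                p[c] = np.exp(logp[c] - m)
                tot += p[c]
            u = unif[ii] * tot
            acc = 0.0
            new = nlab - 1
            for c in range(nlab):
                acc += p[c]
                if u < acc:
                    new = c
                    break
        for e in range(e0, e1):
            g = fgrid[e]
            for k in range(K):
                E[new, g, k] += flog[e, k]
        labels[v] = new
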