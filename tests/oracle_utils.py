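"""Independent brute-force oracles for the mixture tests.

Written against the statistical definitions with their own EM loop (batched
over exhaustive partition starts), not by calling the package's fitting
code.  For n <= 8 the start set covers every set partition, so the best
value found is the global optimum of the mixture likelihood.
"""

import math

import numpy as np


def set_partitions(n):
    """All set partitions of range(n) as label lists (restricted growth)."""
    labels = [0] * n

    def rec(i, maxlab):
        if i == n:
            yield list(labels)
            return
        for lab in range(maxlab + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab + 1))

    yield from rec(0, 0)


def hard_assignment_loglik(y, s, labels):
    """Classification log-likelihood of a labelled partition.

    Cluster means are the inverse-variance-weighted means of their members,
    weights proportional to cluster sizes.
    """
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    n = len(y)
    ll = 0.0
    for lab in set(labels):
        idx = [i for i in range(n) if labels[i] == lab]
        w = [1.0 / s[i] ** 2 for i in idx]
        mu = sum(wi * y[i] for wi, i in zip(w, idx)) / sum(w)
        pi = len(idx) / n
        for i in idx:
            ll += (
                math.log(pi)
                - 0.5 * ((y[i] - mu) / s[i]) ** 2
                - math.log(s[i])
                - 0.5 * math.log(2 * math.pi)
            )
    return ll


def best_partition_loglik(y, s, k):
    """Exhaustive maximum of the hard-assignment likelihood over all
    partitions into exactly k non-empty blocks."""
    best = -math.inf
    for labels in set_partitions(len(y)):
        if len(set(labels)) != k:
            continue
        best = max(best, hard_assignment_loglik(y, s, labels))
    return best


def _partition_params(y, s, k):
    """Stacked (P, k) mean/weight initialisers, one row per k-block partition."""
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    n = len(y)
    inv_var = 1.0 / (s * s)
    mus, pis = [], []
    for labels in set_partitions(n):
        blocks = sorted(set(labels))
        if len(blocks) != k:
            continue
        mu = np.empty(k)
        pi = np.empty(k)
        for j, lab in enumerate(blocks):
            idx = np.array(labels) == lab
            mu[j] = np.average(y[idx], weights=inv_var[idx])
            pi[j] = idx.sum() / n
        mus.append(mu)
        pis.append(pi)
    return np.array(mus), np.array(pis)


def best_mixture_loglik(y, s, k, iters=400, tol=1e-12):
    """Global maximum of the heteroscedastic mixture log-likelihood,
    found by running EM from every k-block set partition simultaneously."""
    y = np.asarray(y, float)
    s = np.asarray(s, float)
    var = s * s
    mu, pi = _partition_params(y, s, k)  # (P, k)
    ll_prev = np.full(mu.shape[0], -np.inf)
    ll = ll_prev
    for _ in range(iters):
        # dens: (P, n, k)
        diff = y[None, :, None] - mu[:, None, :]
        dens = (
            pi[:, None, :]
            * np.exp(-0.5 * diff * diff / var[None, :, None])
            / np.sqrt(2 * np.pi * var)[None, :, None]
        )
        tot = dens.sum(axis=2)  # (P, n)
        ll = np.log(tot).sum(axis=1)
        if np.all(np.abs(ll - ll_prev) <= tol * np.maximum(1.0, np.abs(ll))):
            break
        ll_prev = ll
        resp = dens / tot[:, :, None]
        w = resp / var[None, :, None]
        denom = w.sum(axis=1)  # (P, k)
        numer = (w * y[None, :, None]).sum(axis=1)
        good = denom > 0
        mu = np.where(good, np.divide(numer, denom, where=good, out=np.zeros_like(numer)), mu)
        pi = resp.mean(axis=1)
    return float(ll.max())
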