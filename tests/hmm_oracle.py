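"""Exhaustive path-enumeration oracle for the diploid copying HMM.

Computes genotype posteriors and the data log-marginal by summing over every
ordered-pair state path explicitly, with the transition matrix built as a
Kronecker product of dense single-haplotype matrices and emissions computed
by the direct four-term miscopy sum.  Tractable only for tiny K and M;
deliberately shares no code with the production recursion.
"""

from __future__ import annotations

import itertools

import numpy as np


def _single_hap_transition(d: float, rho: float, K: int) -> np.ndarray:
    s = 1.0 - np.exp(-rho * d)
    return np.full((K, K), s / K) + (1.0 - s) * np.eye(K)


def _miscopy(x: int, a: int, theta: float) -> float:
    return 1.0 - theta if x == a else theta


def enumerate_posteriors(gls, panel, rho: float, theta: float):
    """Return (posteriors (M, 3), log marginal likelihood) by enumeration."""
    gls = np.asarray(gls, dtype=float)
    K, M = panel.K, panel.M
    pos = panel.positions
    states = list(itertools.product(range(K), repeat=2))
    S = len(states)

    # Emission E[s, m] and joint genotype weight Wg[s, m, g] by brute sum.
    E = np.zeros((S, M))
    Wg = np.zeros((S, M, 3))
    for si, (i, j) in enumerate(states):
        for m in range(M):
            ai = int(panel.alleles[i, m])
            aj = int(panel.alleles[j, m])
            for x1 in (0, 1):
                for x2 in (0, 1):
                    w = _miscopy(x1, ai, theta) * _miscopy(x2, aj, theta)
                    Wg[si, m, x1 + x2] += w * gls[m, x1 + x2]
            E[si, m] = Wg[si, m].sum()

    # Pair transition per gap as a Kronecker product (chromosome restarts:
    # the oracle is only used on single-chromosome panels).
    T2 = [
        np.kron(t1 := _single_hap_transition(float(pos[m] - pos[m - 1]), rho, K), t1)
        for m in range(1, M)
    ]

    paths = np.asarray(list(itertools.product(range(S), repeat=M)), dtype=np.int64)
    probs = np.full(len(paths), 1.0 / S)
    for m in range(M):
        probs = probs * E[paths[:, m], m]
    for m in range(1, M):
        probs = probs * T2[m - 1][paths[:, m - 1], paths[:, m]]

    total = probs.sum()
    post = np.zeros((M, 3))
    for m in range(M):
        e_path = E[paths[:, m], m]
        w_path = Wg[paths[:, m], m, :]  # (P, 3)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(e_path[:, None] > 0, w_path / e_path[:, None], 0.0)
        post[m] = (probs[:, None] * frac).sum(axis=0)
    return post / total, float(np.log(total))


def random_instance(rng: np.random.Generator, max_K: int = 4, max_M: int = 4):
    """A random small panel + genotype-likelihood matrix + parameters."""
    from lowpasskit.panel_io import HaplotypePanel, Site

    K = int(rng.integers(2, max_K + 1))
    M = int(rng.integers(1, max_M + 1))
    positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=M, replace=False))
    while True:
        alleles = rng.integers(0, 2, size=(K, M)).astype(np.uint8)
        colsum = alleles.sum(axis=0)
        if ((colsum > 0) & (colsum < K)).all() or M == 0:
            break
    sites = [Site("1", int(p), "A", "G") for p in positions]
    panel = HaplotypePanel(sites=sites, alleles=alleles)
    gls = rng.random((M, 3)) + 1e-3
    rho = float(10 ** rng.uniform(-9, -6))
    theta = float(rng.uniform(0.0, 0.2))
    return panel, gls, rho, theta
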