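"""Independent oracles: brute-force references the implementation is checked
against.  Nothing here shares code with the package's estimation paths."""

import itertools
import math

import numpy as np


def two_locus_loglik(counts, p):
    """Log-likelihood of a 3x3 genotype count table under ordered haplotype
    frequencies p = (pAB, pAb, paB, pab)."""
    pAB, pAb, paB, pab = p
    cell = {
        (0, 0): pAB ** 2, (0, 1): 2 * pAB * pAb, (0, 2): pAb ** 2,
        (1, 0): 2 * pAB * paB, (1, 2): 2 * pAb * pab,
        (2, 0): paB ** 2, (2, 1): 2 * paB * pab, (2, 2): pab ** 2,
        (1, 1): 2 * (pAB * pab + pAb * paB),
    }
    ll = 0.0
    for (a, b), prob in cell.items():
        n = counts[a, b]
        if n:
            if prob <= 0:
                return -math.inf
            ll += n * math.log(prob)
    return ll


def grid_mle_pair(counts, levels=14, grid=13):
    """Brute-force maximization of the two-locus likelihood by iterative grid
    refinement over the 3-simplex (resolution well below 1e-6)."""
    center = np.array([0.5, 0.5, 0.5])
    half = 0.5
    best = None
    for _ in range(levels):
        axes = [np.linspace(c - half, c + half, grid) for c in center]
        g0, g1, g2 = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([g0.ravel(), g1.ravel(), g2.ravel()], axis=1)
        ok = (pts >= 0).all(axis=1) & (pts.sum(axis=1) <= 1.0)
        pts = pts[ok]
        lls = np.array([
            two_locus_loglik(counts, (p[0], p[1], p[2], 1 - p.sum()))
            for p in pts
        ])
        i = int(np.argmax(lls))
        center = pts[i]
        best = (lls[i], np.array([*center, 1 - center.sum()]))
        half *= 3.0 / (grid - 1)  # keep +-1.5 grid steps around the maximum
    return best[1]


def chain_hf(region_alleles01, pair_freqs):
    """Naive Markov-chain evaluation of the region haplotype frequency from a
    list of per-pair frequency 4-vectors (no logs, no K handling)."""
    x = list(region_alleles01)
    p4 = pair_freqs[0]
    hf = p4[2 * x[0]] + p4[2 * x[0] + 1]
    for t in range(1, len(x)):
        p4 = pair_freqs[t - 1]
        marg = p4[2 * x[t - 1]] + p4[2 * x[t - 1] + 1]
        hf *= p4[2 * x[t - 1] + x[t]] / marg
    return hf


def enum_share_prob(p, N, T):
    """P(at least N of T carriers) by enumeration of all 2^T carrier
    patterns weighted by p^k (1-p)^(T-k)."""
    total = 0.0
    for pattern in itertools.product([0, 1], repeat=T):
        k = sum(pattern)
        if k >= N:
            total += p ** k * (1 - p) ** (T - k)
    return total


def mosaic_region_freq_brute(pool_haps, weights, switch_rate, alleles01):
    """Exact frequency of an allele sequence under the copying process by
    enumeration over all pool-state paths (tiny pools only)."""
    H = len(weights)
    L = len(alleles01)
    total = 0.0
    for path in itertools.product(range(H), repeat=L):
        if any(pool_haps[path[j], j] != alleles01[j] for j in range(L)):
            continue
        prob = weights[path[0]]
        for j in range(1, L):
            stay = (1 - switch_rate) if path[j] == path[j - 1] else 0.0
            prob *= stay + switch_rate * weights[path[j]]
        total += prob
    return total
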