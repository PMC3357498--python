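"""Population frequency of an entire homozygous region.

The statistic works in three steps:

1. For every adjacent marker pair, the four two-locus haplotype frequencies
   are estimated from unphased control genotypes with an EM algorithm (only
   double heterozygotes carry phase ambiguity).
2. A haplotype that cannot be present in any control genotype is assigned the
   surrogate frequency ``K`` defined by a 95% chance of non-observation at the
   control sample size ``v``: ``(1 - K)^(2v) = 0.95``.
3. The frequency ``HF`` of the full homozygous allele sequence ``g_1..g_n`` is
   evaluated under a first-order Markov chain over the pairwise tables:
   ``HF = P(g_1) * prod_i P(g_{i-1}, g_i) / P(g_{i-1})``, computed in log
   space.  The chance of carrying the region homozygous is ``HBC_s = HF**2``.

Haplotype index convention: for a marker pair, haplotype ``k = 2*x + y``
where ``x``/``y`` are 0 for the first allele and 1 for the second allele at
the left/right marker, i.e. columns are ``[AB, Ab, aB, ab]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GT_MISSING, GenotypePanel, MarkerMap
from .roh import HomozygousRegion

LN10 = math.log(10.0)


class EMError(ValueError):
    pass


# ---------------------------------------------------------------------------
# EM estimation of pairwise haplotype frequencies
# ---------------------------------------------------------------------------

def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 genotype-combination counts over pairwise-complete individuals."""
    ok = (g1 != GT_MISSING) & (g2 != GT_MISSING)
    a, b = g1[ok], g2[ok]
    counts = np.zeros((3, 3), dtype=np.int64)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((a == i) & (b == j))
    return counts


def _em_from_counts(counts: np.ndarray, tol: float, max_iter: int
                    ) -> tuple[np.ndarray, bool]:
    """EM for one pair from a 3x3 genotype count table.

    Returns (four haplotype frequencies [AB, Ab, aB, ab], converged flag).
    Frequencies of haplotypes incompatible with every observed genotype are
    exact zeros.
    """
    v = counts.sum()
    if v == 0:
        raise EMError("no informative (pairwise-complete) control individuals")
    # fixed haplotype counts from unambiguous genotype cells
    base = np.zeros(4)
    for a in range(3):
        for b in range(3):
            nab = counts[a, b]
            if nab == 0 or (a == 1 and b == 1):
                continue
            xs = [0, 1] if a == 1 else [a // 2, a // 2]
            ys = [0, 1] if b == 1 else [b // 2, b // 2]
            for x, y in zip(xs, ys):
                base[2 * x + y] += nab
    n11 = counts[1, 1]
    # structural support: haplotype (x, y) is possible only if some observed
    # genotype combination is compatible with carrying it
    possible = np.zeros(4, dtype=bool)
    for a in range(3):
        for b in range(3):
            if counts[a, b] == 0:
                continue
            for x in ((0,) if a == 0 else (1,) if a == 2 else (0, 1)):
                for y in ((0,) if b == 0 else (1,) if b == 2 else (0, 1)):
                    possible[2 * x + y] = True

    # linkage-equilibrium initialization from allele counts
    tot = 2 * v
    pA = (2 * counts[0, :].sum() + counts[1, :].sum()) / tot
    pB = (2 * counts[:, 0].sum() + counts[:, 1].sum()) / tot
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    p = np.where(possible, np.maximum(p, 1e-12), 0.0)
    s = p.sum()
    if s == 0:
        raise EMError("degenerate pair: no possible haplotypes")
    p /= s

    converged = False
    for _ in range(max_iter):
        if n11:
            d1 = p[0] * p[3]
            d2 = p[1] * p[2]
            frac = d1 / (d1 + d2) if (d1 + d2) > 0 else 0.5
            amb = n11 * np.array([frac, 1 - frac, 1 - frac, frac])
        else:
            amb = 0.0
        newp = (base + amb) / tot
        newp[~possible] = 0.0
        if np.max(np.abs(newp - p)) < tol:
            p = newp
            converged = True
            break
        p = newp
    return p, converged


def em_pairwise_hf(controls: GenotypePanel, pair: tuple[int, int],
                   tol: float = 1e-8, max_iter: int = 1000
                   ) -> tuple[np.ndarray, int, bool]:
    """EM haplotype frequencies for one adjacent marker pair.

    Returns ``(freqs[4], v, converged)`` where ``v`` is the number of
    pairwise-complete control individuals.  Deterministic given inputs (no
    random restarts; the two-locus likelihood is well behaved).
    """
    i, j = pair
    if j != i + 1:
        raise ValueError("pair must be adjacent marker indices (i, i+1)")
    counts = _pair_counts(controls.genotypes[:, i], controls.genotypes[:, j])
    p, conv = _em_from_counts(counts, tol, max_iter)
    return p, int(counts.sum()), conv


# ---------------------------------------------------------------------------
# Rare-haplotype surrogate frequency K
# ---------------------------------------------------------------------------

def rare_haplotype_k(v: int, haploid_factor: int = 2, miss_prob: float = 0.95) -> float:
    """Frequency ``K`` such that an unobserved haplotype stays unobserved in
    the controls with probability 0.95: ``(1 - K)^(haploid_factor * v) = 0.95``.

    ``v`` is the control sample size in diploid individuals, hence the default
    of ``2v`` sampled haplotypes; set ``haploid_factor=1`` to read the
    criterion as ``v`` haplotypes instead.
    """
    if v <= 0:
        raise ValueError("control sample size v must be positive")
    return 1.0 - miss_prob ** (1.0 / (haploid_factor * v))


# ---------------------------------------------------------------------------
# Pairwise table over a whole panel
# ---------------------------------------------------------------------------

@dataclass
class PairwiseHFTable:
    """EM haplotype frequencies for every within-chromosome adjacent pair.

    ``freqs`` has shape (n_markers - 1, 4) with columns [AB, Ab, aB, ab];
    rows crossing a chromosome boundary are invalid (``valid`` False).
    ``allele1_freq`` is the per-marker frequency of the first allele among
    non-missing control genotypes.
    """

    markers: MarkerMap
    freqs: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    allele1_freq: np.ndarray
    k_haploid_factor: int = 2
    converged: np.ndarray | None = None

    def pair_k(self, j: int) -> float:
        return rare_haplotype_k(int(self.v[j]), self.k_haploid_factor)

    def to_tsv(self, path: str | Path) -> None:
        t = self.markers.table
        df = pd.DataFrame({
            "marker_i": t["marker_id"].to_numpy()[:-1],
            "marker_j": t["marker_id"].to_numpy()[1:],
            "P_AB": self.freqs[:, 0], "P_Ab": self.freqs[:, 1],
            "P_aB": self.freqs[:, 2], "P_ab": self.freqs[:, 3],
            "v": self.v, "valid": self.valid.astype(int),
        })
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, markers: MarkerMap,
                 k_haploid_factor: int = 2) -> "PairwiseHFTable":
        df = pd.read_csv(path, sep="\t")
        if len(df) != markers.n_markers - 1:
            raise ValueError("cached table does not match marker map")
        freqs = df[["P_AB", "P_Ab", "P_aB", "P_ab"]].to_numpy()
        a1 = np.empty(markers.n_markers)
        a1[:-1] = freqs[:, 0] + freqs[:, 1]
        a1[-1] = freqs[-1, 0] + freqs[-1, 2]
        return cls(markers, freqs, df["v"].to_numpy(),
                   df["valid"].to_numpy().astype(bool), a1, k_haploid_factor)


def pair_count_arrays(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Genotype-combination counts for all adjacent pairs.

    Returns ``(counts, cats)``: ``counts`` of shape (3, 3, m-1) and the
    per-individual pair category ``cats`` (n, m-1) with values ``3a + b`` or
    -1 when either genotype is missing, so individual contributions can be
    subtracted for leave-one-out estimation.
    """
    n, m = G.shape
    L, R = G[:, :-1], G[:, 1:]
    ok = (L != GT_MISSING) & (R != GT_MISSING)
    cats = np.where(ok, 3 * L + R, -1).astype(np.int8)
    counts = np.zeros((3, 3, m - 1), dtype=np.int64)
    for a in range(3):
        la = (L == a)
        for b in range(3):
            counts[a, b] = (la & (R == b) & ok).sum(axis=0)
    return counts, cats


def em_from_count_table(counts: np.ndarray, valid: np.ndarray,
                        tol: float = 1e-8, max_iter: int = 1000,
                        init: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM from a (3, 3, m-1) count table.

    ``init`` (shape (m-1, 4)) warm-starts the iteration — useful when
    re-estimating after removing a single individual.  Returns
    ``(freqs (m-1, 4), v (m-1,), converged (m-1,))``.
    """
    m1 = counts.shape[2]
    v = counts.sum(axis=(0, 1))
    if np.any(valid & (v == 0)):
        raise EMError("adjacent pair with zero informative controls")

    base = np.zeros((4, m1))
    possible = np.zeros((4, m1), dtype=bool)
    for a in range(3):
        for b in range(3):
            nab = counts[a, b]
            xs = (0, 1) if a == 1 else (a // 2,)
            ys = (0, 1) if b == 1 else (b // 2,)
            for x in xs:
                for y in ys:
                    possible[2 * x + y] |= nab > 0
            if a == 1 and b == 1:
                continue
            if a == 1:
                base[2 * 0 + ys[0]] += nab
                base[2 * 1 + ys[0]] += nab
            elif b == 1:
                base[2 * xs[0] + 0] += nab
                base[2 * xs[0] + 1] += nab
            else:
                base[2 * xs[0] + ys[0]] += 2 * nab
    n11 = counts[1, 1].astype(float)

    tot = np.maximum(2 * v, 1).astype(float)
    if init is not None:
        p = init.T.copy()
        p = np.where(possible, np.maximum(p, 1e-12), 0.0)
    else:
        pA = (2 * counts[0].sum(axis=0) + counts[1].sum(axis=0)) / tot
        pB = (2 * counts[:, 0].sum(axis=0) + counts[:, 1].sum(axis=0)) / tot
        p = np.stack([pA * pB, pA * (1 - pB), (1 - pA) * pB,
                      (1 - pA) * (1 - pB)])
        p = np.where(possible, np.maximum(p, 1e-12), 0.0)
    s = p.sum(axis=0)
    s[s == 0] = 1.0
    p = p / s

    conv = np.zeros(m1, dtype=bool)
    for _ in range(max_iter):
        d1 = p[0] * p[3]
        d2 = p[1] * p[2]
        den = d1 + d2
        frac = np.where(den > 0, d1 / np.where(den > 0, den, 1.0), 0.5)
        amb = n11 * np.stack([frac, 1 - frac, 1 - frac, frac])
        newp = (base + amb) / tot
        newp[~possible] = 0.0
        delta = np.abs(newp - p).max(axis=0)
        p = newp
        conv = delta < tol
        if conv[valid].all():
            break
    return p.T.copy(), v, conv


def estimate_pair_table(controls: GenotypePanel, tol: float = 1e-8,
                        max_iter: int = 1000, k_haploid_factor: int = 2,
                        exclude: int | None = None) -> PairwiseHFTable:
    """Vectorized EM over all within-chromosome adjacent marker pairs.

    ``exclude`` drops one individual (by row index) from estimation — the
    leave-one-out table used when scoring an individual who is part of the
    control panel.
    """
    G = controls.genotypes
    n, m = G.shape
    if m < 2:
        raise ValueError("need at least two markers")
    valid = controls.markers.pair_within_chrom()
    counts, cats = pair_count_arrays(G)
    if exclude is not None:
        counts = subtract_individual(counts, cats, exclude)
    freqs, v, conv = em_from_count_table(counts, valid, tol, max_iter)
    # per-marker allele-1 frequency from single-marker counts
    miss = G == GT_MISSING
    if exclude is not None:
        keep = np.arange(n) != exclude
        miss, Gm = miss[keep], G[keep]
    else:
        Gm = G
    nm = (~miss).sum(axis=0)
    dos = np.where(miss, 0, Gm).sum(axis=0)
    a1 = 1.0 - dos / np.maximum(2 * nm, 1)
    return PairwiseHFTable(controls.markers, freqs, v, valid, a1,
                           k_haploid_factor, conv)


def subtract_individual(counts: np.ndarray, cats: np.ndarray, i: int
                        ) -> np.ndarray:
    """Count table with individual ``i``'s pair contributions removed."""
    out = counts.copy()
    ci = cats[i]
    ok = ci >= 0
    cols = np.nonzero(ok)[0]
    c = ci[ok].astype(int)
    out[c // 3, c % 3, cols] -= 1
    return out


# ---------------------------------------------------------------------------
# Markov-chain region frequency
# ---------------------------------------------------------------------------

@dataclass
class RegionScore:
    """HF and derived statistics for one homozygous region.

    ``log_hf`` is the natural log of the region haplotype frequency; ``hf``
    and ``hbc_s`` may underflow to 0.0 for long regions, which is expected —
    comparisons should use the log scale.
    """

    region: HomozygousRegion
    log_hf: float
    hbc_m: float | None = None
    n_carriers: int = 1
    empirical_p: float | None = None

    @property
    def hf(self) -> float:
        return math.exp(self.log_hf)

    @property
    def hbc_s(self) -> float:
        return self.hf ** 2

    @property
    def log10_hf(self) -> float:
        return self.log_hf / LN10

    @property
    def neglog10_hbc_s(self) -> float:
        return -2.0 * self.log_hf / LN10


def _adjusted_pair(freqs4: np.ndarray, need: int, k: float) -> np.ndarray:
    """K-substitution: the needed haplotype got EM frequency 0 -> give it K
    and rescale the other three by (1 - K) so the four still sum to one."""
    p = freqs4 * (1.0 - k)
    p[need] = k
    return p


def region_hf(region: HomozygousRegion, table: PairwiseHFTable) -> RegionScore:
    """Markov-chain haplotype frequency of an entire homozygous region.

    Heterozygous exceptions and missing calls inside the span are treated as
    unobserved: the chain marginalizes over them by composing the adjacent
    transition matrices across the gap.  If a required transition has
    probability zero it is replaced by the rare-haplotype surrogate ``K``
    for the pair's control sample size.
    """
    i0, i1 = region.i_first, region.i_last
    if i1 - i0 < 1:
        raise ValueError("region must span at least 2 markers")
    codes = np.asarray(region.alleles)
    hom = (codes == 0) | (codes == 2)
    hom_idx = np.nonzero(hom)[0]
    if len(hom_idx) < 2:
        raise ValueError("region must contain at least 2 homozygous markers")
    x = (codes[hom_idx] == 2).astype(int)

    if not table.valid[i0:i1].all():
        raise ValueError("region spans a chromosome boundary in the pair table")

    log_hf = 0.0
    first = True
    for t in range(1, len(hom_idx)):
        ja, jb = int(hom_idx[t - 1]) + i0, int(hom_idx[t]) + i0
        xa, xb = int(x[t - 1]), int(x[t])
        if jb == ja + 1:
            p4 = table.freqs[ja].copy()
            need = 2 * xa + xb
            if p4[need] == 0.0:
                p4 = _adjusted_pair(p4, need, table.pair_k(ja))
            marg = p4[2 * xa] + p4[2 * xa + 1]
            if first:
                if marg == 0.0:
                    raise ValueError("region allele absent from control table")
                log_hf += math.log(marg)
                first = False
            log_hf += math.log(p4[need]) - math.log(marg)
        else:
            # compose transition matrices across skipped (het/missing) markers
            T = np.eye(2)
            vmin = int(table.v[ja:jb].min())
            for j in range(ja, jb):
                p4 = table.freqs[j]
                M = p4.reshape(2, 2)
                rows = M.sum(axis=1, keepdims=True)
                M = np.divide(M, rows, out=np.full((2, 2), 0.0), where=rows > 0)
                T = T @ M
            prob = T[xa, xb]
            if prob == 0.0:
                prob = rare_haplotype_k(max(vmin, 1), table.k_haploid_factor)
            if first:
                p4 = table.freqs[ja]
                marg = p4[2 * xa] + p4[2 * xa + 1]
                if marg == 0.0:
                    marg = rare_haplotype_k(max(vmin, 1), table.k_haploid_factor)
                log_hf += math.log(marg)
                first = False
            log_hf += math.log(prob)
    return RegionScore(region=region, log_hf=log_hf)


def score_regions(regions: Sequence[HomozygousRegion], table: PairwiseHFTable
                  ) -> list[RegionScore]:
    return [region_hf(r, table) for r in regions]


def best_region_score(regions: Sequence[HomozygousRegion], table: PairwiseHFTable
                      ) -> RegionScore | None:
    """The region with the smallest HF^2 (most extreme), or None."""
    scores = score_regions(regions, table)
    if not scores:
        return None
    return min(scores, key=lambda s: s.log_hf)
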