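"""Synthetic LD-structured control populations with known truth.

Two generator modes are provided:

* ``markov`` — haplotypes are drawn from a first-order Markov chain over the
  markers with prescribed per-marker allele frequencies and adjacent-pair
  linkage disequilibrium.  This matches the model class of the region
  frequency statistic, so the true pairwise haplotype frequencies and the
  true frequency of any allele sequence are available in closed form.
* ``pool`` — whole haplotypes are resampled per chromosome from a finite
  weighted pool, which creates genuinely rare long haplotypes (useful for
  exercising the rare-haplotype K substitution).
* ``mosaic`` — haplotypes copy from a finite pool with a small per-marker
  switch rate (Li–Stephens-style).  This produces haplotype-block sharing —
  short haplotypes are common, long ones rare — which is the structure that
  makes the age of a founder segment matter for detection.  The exact
  frequency of any allele sequence is still available via a forward
  recursion over the pool states.

None of the modes attempts demographic realism (bottlenecks, admixture);
they provide controlled LD structure and exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel, MarkerMap, ROLE_CONTROL


@dataclass
class PopulationModel:
    """Parameters of the synthetic haplotype process.

    ``ld_r`` is the target correlation between adjacent markers on the
    haplotype level; it is clipped per pair to 99% of the feasible range
    implied by the two allele frequencies, so strong LD between markers of
    mismatched frequency is attenuated exactly as it must be in real data.
    """

    n_chrom: int = 5
    markers_per_chrom: int = 1000
    spacing_bp: int = 10_000
    ld_r: float = 0.9
    freq_beta: tuple[float, float] = (0.5, 0.5)
    freq_clip: tuple[float, float] = (0.05, 0.95)
    mode: str = "markov"  # or "pool" or "mosaic"
    pool_size: int = 100
    pool_alpha: float = 0.5
    switch_rate: float = 0.005  # mosaic mode: per-marker copy-switch probability
    seed: int = 0
    # derived, filled by finalize()
    q: np.ndarray | None = field(default=None, repr=False)     # allele2 freq
    trans: np.ndarray | None = field(default=None, repr=False)  # (m-1, 2): P(1|0), P(1|1)
    pool_haps: np.ndarray | None = field(default=None, repr=False)
    pool_w: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    def marker_map(self) -> MarkerMap:
        m = self.markers_per_chrom
        chroms = np.repeat([str(c + 1) for c in range(self.n_chrom)], m)
        pos = np.tile(np.arange(1, m + 1) * self.spacing_bp, self.n_chrom)
        ids = [f"snp{c + 1}_{j + 1}" for c in range(self.n_chrom) for j in range(m)]
        return MarkerMap(pd.DataFrame({
            "chrom": chroms, "marker_id": ids, "pos_bp": pos,
            "cm": pos / 1e6,  # uniform 1 cM/Mb
            "allele1": "A", "allele2": "B",
        }))

    def finalize(self) -> "PopulationModel":
        """Draw the frequency spectrum and transition tables (deterministic
        under ``seed``)."""
        if self.q is not None:
            return self
        rng = np.random.default_rng(self.seed)
        m = self.n_markers
        a, b = self.freq_beta
        q = np.clip(rng.beta(a, b, size=m), *self.freq_clip)
        qp, qc = q[:-1], q[1:]
        dmax = np.minimum(qp * (1 - qc), (1 - qp) * qc)
        d = self.ld_r * np.sqrt(qp * (1 - qp) * qc * (1 - qc))
        d = np.minimum(d, 0.99 * dmax)
        # P(cur=1 | prev=1) and P(cur=1 | prev=0); restart at chromosome breaks
        p11 = (qp * qc + d) / qp
        p01 = ((1 - qp) * qc - d) / (1 - qp)
        within = self.marker_map().pair_within_chrom()
        p11 = np.where(within, p11, qc)
        p01 = np.where(within, p01, qc)
        self.q = q
        self.trans = np.stack([p01, p11], axis=1)
        if self.mode in ("pool", "mosaic"):
            self.pool_haps = _markov_sample(self, self.pool_size, rng)
            alpha = self.pool_alpha if self.mode == "pool" else 1.0
            self.pool_w = rng.dirichlet(np.full(self.pool_size, alpha))
        return self

    # ------------------------------------------------------------------
    # closed-form truth
    # ------------------------------------------------------------------

    def true_pair_freqs(self) -> np.ndarray:
        """(m-1, 4) haplotype frequencies [AB, Ab, aB, ab] of the process."""
        self.finalize()
        if self.mode == "pool":
            h = self.pool_haps
            w = self.pool_w
            out = np.zeros((self.n_markers - 1, 4))
            for x in (0, 1):
                for y in (0, 1):
                    match = (h[:, :-1] == x) & (h[:, 1:] == y)
                    out[:, 2 * x + y] = w @ match
            return out
        if self.mode == "mosaic":
            h = self.pool_haps
            w = self.pool_w
            lam = self.switch_rate
            out = np.zeros((self.n_markers - 1, 4))
            marg = {y: w @ (h == y) for y in (0, 1)}  # per-marker allele freq
            for x in (0, 1):
                for y in (0, 1):
                    stay = w @ ((h[:, :-1] == x) & (h[:, 1:] == y))
                    out[:, 2 * x + y] = ((1 - lam) * stay
                                         + lam * (w @ (h[:, :-1] == x)) * marg[y][1:])
            return out
        qp, qc = self.q[:-1], self.q[1:]
        p11h = qp * self.trans[:, 1]           # P(prev=1, cur=1)
        p01h = (1 - qp) * self.trans[:, 0]     # P(prev=0, cur=1)
        return np.stack([
            (1 - qp) - p01h,  # AB (0,0)
            p01h,             # Ab (0,1)
            qp - p11h,        # aB (1,0)
            p11h,             # ab (1,1)
        ], axis=1)

    def true_region_hf(self, i_first: int, alleles01: np.ndarray) -> float:
        """Exact process frequency of the allele sequence (0/1 codes) starting
        at global marker index ``i_first``."""
        self.finalize()
        i1 = i_first + len(alleles01)
        if self.mode == "pool":
            seg = self.pool_haps[:, i_first:i1]
            return float(self.pool_w @ (seg == alleles01).all(axis=1))
        if self.mode == "mosaic":
            # forward recursion over copy states (no mutation term)
            x = np.asarray(alleles01)
            h = self.pool_haps[:, i_first:i1]
            lam = self.switch_rate
            f = self.pool_w * (h[:, 0] == x[0])
            for j in range(1, len(x)):
                f = ((1 - lam) * f + lam * self.pool_w * f.sum()) * (h[:, j] == x[j])
            return float(f.sum())
        x = np.asarray(alleles01)
        p = self.q[i_first] if x[0] == 1 else 1 - self.q[i_first]
        tr = self.trans[i_first:i1 - 1]
        step = np.where(x[1:] == 1, tr[np.arange(len(x) - 1), x[:-1]],
                        1 - tr[np.arange(len(x) - 1), x[:-1]])
        return float(p * np.prod(step))


def _markov_sample(model: PopulationModel, n_haps: int, rng: np.random.Generator
                   ) -> np.ndarray:
    m = model.n_markers
    h = np.zeros((n_haps, m), dtype=np.int8)
    mm = model.marker_map()
    within = mm.pair_within_chrom()
    h[:, 0] = rng.random(n_haps) < model.q[0]
    for j in range(1, m):
        if within[j - 1]:
            pr = model.trans[j - 1][h[:, j - 1]]
        else:
            pr = model.q[j]
        h[:, j] = rng.random(n_haps) < pr
    return h


def sample_haplotypes(model: PopulationModel, n_haps: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw phased haplotypes (n_haps, m) with values 0/1 (allele1/allele2)."""
    model.finalize()
    if model.mode == "pool":
        m = model.markers_per_chrom
        out = np.empty((n_haps, model.n_markers), dtype=np.int8)
        for c in range(model.n_chrom):
            idx = rng.choice(model.pool_size, size=n_haps, p=model.pool_w)
            out[:, c * m:(c + 1) * m] = model.pool_haps[idx, c * m:(c + 1) * m]
        return out
    if model.mode == "mosaic":
        m = model.n_markers
        mc = model.markers_per_chrom
        state = np.empty((n_haps, m), dtype=np.int32)
        for j in range(m):
            if j % mc == 0:  # restart at chromosome starts
                state[:, j] = rng.choice(model.pool_size, size=n_haps, p=model.pool_w)
            else:
                sw = rng.random(n_haps) < model.switch_rate
                state[:, j] = state[:, j - 1]
                if sw.any():
                    state[sw, j] = rng.choice(model.pool_size, size=int(sw.sum()),
                                              p=model.pool_w)
        return model.pool_haps[state, np.arange(m)].astype(np.int8)
    return _markov_sample(model, n_haps, rng)


def true_table(model: PopulationModel, v: int = 10 ** 6):
    """The population's exact pairwise table (as if estimated from an
    unlimited control sample): useful for separating estimation error from
    the chain approximation in tests."""
    from .hapfreq import PairwiseHFTable

    model.finalize()
    mm = model.marker_map()
    freqs = model.true_pair_freqs()
    m = model.n_markers
    if model.mode == "markov":
        a1 = 1.0 - model.q
    else:
        a1 = 1.0 - (model.pool_w @ model.pool_haps)
    return PairwiseHFTable(mm, freqs, np.full(m - 1, v),
                           mm.pair_within_chrom(), a1)


def generate_panel(model: PopulationModel, n_individuals: int,
                   rng: np.random.Generator | int,
                   role: str = ROLE_CONTROL, iid_prefix: str = "ind"
                   ) -> tuple[GenotypePanel, np.ndarray]:
    """Draw a diploid panel plus its phased truth.

    Returns ``(panel, haps)`` where ``haps`` has shape (2*n, m); individual
    ``i`` is the pairing of haplotypes ``2i`` and ``2i+1``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    model.finalize()
    haps = sample_haplotypes(model, 2 * n_individuals, rng)
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    ind = pd.DataFrame({
        "iid": [f"{iid_prefix}{i + 1}" for i in range(n_individuals)],
        "fid": [f"{iid_prefix}{i + 1}" for i in range(n_individuals)],
        "role": role,
    })
    return GenotypePanel(model.marker_map(), ind, geno), haps
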