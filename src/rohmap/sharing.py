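"""Statistics for homozygous regions shared by several patients.

A shared region is a maximal marker interval over which at least
``min_carriers`` individuals both (a) have an overlapping run of
homozygosity and (b) are homozygous for the identical allele sequence
(missing calls and heterozygous exceptions act as wildcards).  The chance of
``N`` out of ``T`` patients sharing such a region is summarized by
``HBC_m``, the upper tail of a Binomial(T, p) at N with p the per-individual
chance ``HF**2`` of carrying the region homozygous.  For affected sib pairs
the family-level statistic is the smaller ``HF**2`` of the two siblings and
the final P-value carries a factor ``(1/4)**N`` for the chance that N sib
pairs each share both alleles identical by descent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .hapfreq import PairwiseHFTable, RegionScore, region_hf
from .roh import HomozygousRegion

_OUTSIDE = -2  # marker not covered by the individual's ROH
_WILD = -1     # covered but het exception / missing: compatible with either allele


@dataclass
class SharedRegion:
    """A consensus interval carried homozygous by ``n_carriers`` individuals."""

    chrom: str
    i_first: int
    i_last: int
    start_bp: int
    end_bp: int
    carriers: tuple[str, ...]
    alleles: np.ndarray  # consensus codes over span: 0/2, or -1 where all wild

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def n_snps(self) -> int:
        return self.i_last - self.i_first + 1

    def as_region(self) -> HomozygousRegion:
        """The consensus interval as a pseudo-region for HF evaluation."""
        return HomozygousRegion(
            iid="+".join(self.carriers), chrom=self.chrom,
            i_first=self.i_first, i_last=self.i_last,
            start_bp=self.start_bp, end_bp=self.end_bp,
            alleles=self.alleles.copy(),
            n_het=0, n_missing=int((self.alleles == _WILD).sum()),
        )


def hbc_m(p: float, N: int, T: int) -> float:
    """Probability that at least ``N`` of ``T`` patients carry the region
    homozygous by chance: the Binomial(T, p) upper tail at N, with
    ``p = HF**2``.  Reduces to ``HBC_s`` at N = T = 1.
    """
    if N == 0:
        return 1.0
    if not (1 <= N <= T):
        raise ValueError("need 1 <= N <= T (or N == 0)")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    return float(stats.binom.sf(N - 1, T, p))


def log10_hbc_m(log_hf: float, N: int, T: int) -> float:
    """log10 of ``hbc_m`` computed stably for very small ``p = HF**2``.

    For tiny p the binomial upper tail is dominated by the exactly-N term,
    ``C(T, N) p^N``; this path avoids the underflow of ``p`` itself.
    """
    if N == 0:
        return 0.0
    log10_p = 2.0 * log_hf / math.log(10.0)
    if log10_p > -12:
        return math.log10(max(hbc_m(10 ** log10_p, N, T), 1e-320))
    return math.log10(math.comb(T, N)) + N * log10_p


def find_shared_regions(regions: Sequence[HomozygousRegion],
                        min_carriers: int = 2,
                        min_snps: int = 2) -> list[SharedRegion]:
    """Maximal intervals shared (with identical homozygous alleles) by at
    least ``min_carriers`` of the individuals contributing ``regions``.

    A sweep over markers maintains groups of individuals that have been
    mutually compatible since some start marker; a group is emitted when it
    shrinks or splits, and subgroups inherit the parent's start because they
    were compatible all along.  Nested results (larger carrier set over a
    shorter interval alongside a subset over a longer one) are all reported.
    """
    out: list[SharedRegion] = []
    by_chrom: dict[str, list[HomozygousRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    for chrom, regs in by_chrom.items():
        lo = min(r.i_first for r in regs)
        hi = max(r.i_last for r in regs)
        width = hi - lo + 1
        iids = sorted({r.iid for r in regs})
        iid_pos = {iid: k for k, iid in enumerate(iids)}
        V = np.full((len(iids), width), _OUTSIDE, dtype=np.int8)
        bp = {}
        for r in regs:
            k = iid_pos[r.iid]
            codes = np.where((r.alleles == 0) | (r.alleles == 2), r.alleles, _WILD)
            V[k, r.i_first - lo:r.i_last - lo + 1] = codes
            bp[(r.iid, r.i_first)] = r
        pos_first = {r.i_first for r in regs}
        pos_bp_start = {}
        pos_bp_end = {}
        for r in regs:
            pos_bp_start[r.i_first] = r.start_bp
            pos_bp_end[r.i_last] = r.end_bp
        # bp positions per marker index, reconstructed from any region covering it
        bp_of = _bp_lookup(regs)

        active: dict[frozenset, int] = {}

        def emit(members: frozenset, start: int, end: int) -> None:
            if len(members) < min_carriers or end - start + 1 < min_snps:
                return
            cons = _consensus(V, [iid_pos[i] for i in members], start - lo, end - lo)
            if cons is None:
                return
            out.append(SharedRegion(
                chrom=chrom, i_first=start, i_last=end,
                start_bp=bp_of(start), end_bp=bp_of(end),
                carriers=tuple(sorted(members)), alleles=cons,
            ))

        for m in range(lo, hi + 1):
            col = V[:, m - lo]
            cov0 = frozenset(iids[k] for k in np.nonzero((col == 0) | (col == _WILD))[0])
            cov2 = frozenset(iids[k] for k in np.nonzero((col == 2) | (col == _WILD))[0])
            blocks = [b for b in {cov0, cov2} if b]
            new_active: dict[frozenset, int] = {}
            for members, start in active.items():
                conts = {members & b for b in blocks}
                conts = {c for c in conts if c}
                if members not in conts:
                    emit(members, start, m - 1)
                for c in conts:
                    prev = new_active.get(c)
                    new_active[c] = start if prev is None else min(prev, start)
            for b in blocks:
                if b not in new_active:
                    new_active[b] = m
            active = new_active
        for members, start in active.items():
            emit(members, start, hi)
    out.sort(key=lambda s: (s.chrom, s.i_first, -s.n_carriers))
    return _drop_dominated(out)


def _bp_lookup(regs: Sequence[HomozygousRegion]):
    """Map a global marker index to its bp position using region spans."""
    idx: dict[int, int] = {}
    for r in regs:
        n = r.i_last - r.i_first + 1
        if n > 1:
            step = (r.end_bp - r.start_bp) / (n - 1)
        else:
            step = 0.0
        for k in range(n):
            idx.setdefault(r.i_first + k, int(round(r.start_bp + step * k)))

    def bp_of(i: int) -> int:
        return idx.get(i, -1)

    return bp_of


def _consensus(V: np.ndarray, rows: list[int], a: int, b: int) -> np.ndarray | None:
    sub = V[rows, a:b + 1]
    if (sub == _OUTSIDE).any():
        return None
    cons = np.full(b - a + 1, _WILD, dtype=np.int8)
    for val in (0, 2):
        has = (sub == val).any(axis=0)
        cons[has] = val
    return cons


def _drop_dominated(regions: list[SharedRegion]) -> list[SharedRegion]:
    """Remove regions whose interval and carrier set are both contained in
    another region's (ties kept once)."""
    keep: list[SharedRegion] = []
    for r in regions:
        dominated = False
        for s in regions:
            if s is r:
                continue
            if (s.i_first <= r.i_first and s.i_last >= r.i_last
                    and set(s.carriers) >= set(r.carriers)
                    and (s.i_first < r.i_first or s.i_last > r.i_last
                         or set(s.carriers) > set(r.carriers))):
                dominated = True
                break
        if not dominated:
            keep.append(r)
    # exact duplicates
    seen = set()
    uniq = []
    for r in keep:
        key = (r.chrom, r.i_first, r.i_last, r.carriers)
        if key not in seen:
            seen.add(key)
            uniq.append(r)
    return uniq


def score_shared_region(shared: SharedRegion, table: PairwiseHFTable, T: int
                        ) -> RegionScore:
    """HF over the consensus interval and HBC_m for N carriers out of T."""
    score = region_hf(shared.as_region(), table)
    score.n_carriers = shared.n_carriers
    p = min(max(score.hbc_s, 1e-300), 1.0 - 1e-12)
    score.hbc_m = hbc_m(p, shared.n_carriers, T)
    return score


def neglog10_hbc_m_score(shared: SharedRegion, table: PairwiseHFTable, T: int
                         ) -> float:
    """-log10 HBC_m for a shared region (underflow-safe)."""
    score = region_hf(shared.as_region(), table)
    return -log10_hbc_m(score.log_hf, shared.n_carriers, T)


def sibpair_adjust(family_hf2: Mapping[str, tuple[float, float]],
                   n_sharing: int) -> tuple[dict[str, float], float]:
    """Per-family statistics and the IBD factor for affected sib pairs.

    Each family contributes the smaller ``HF**2`` of its two genotyped
    affected siblings; the final P-value is multiplied by ``(1/4)**N`` where
    ``N`` is the number of families sharing the founder allele (a sib pair
    shares both alleles IBD with chance one quarter).
    """
    stats_out: dict[str, float] = {}
    for fid, vals in family_hf2.items():
        if len(vals) != 2:
            raise ValueError(
                f"family {fid}: exactly 2 genotyped affected siblings required"
            )
        stats_out[fid] = float(min(vals))
    return stats_out, 0.25 ** n_sharing
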