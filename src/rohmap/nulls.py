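"""Monte-Carlo null distributions and genome-wide empirical P-values.

Nominal ``HBC`` values are not comparable across the genome (marker density
and rare-allele coverage vary), so significance is assessed against the best
regions that unaffected control genomes produce:

* single-patient mode — one statistic per control individual: the smallest
  ``HF**2`` among that control's runs of homozygosity (controls with no
  qualifying run contribute the sentinel 1.0);
* multi-patient mode — per simulation round, ``T`` controls are drawn
  without replacement and the shared region (by ``N`` or fewer of them) with
  the best ``HBC_m`` is recorded; the recorded interval is then masked in
  later rounds (configurable, because the published exclusion rule is
  ambiguous);
* sib-pair mode — controls are paired into pseudo sib pairs and the
  family-level statistic mirrors the case analysis; the ``(1/4)**N`` IBD
  factor is applied to the case P-value afterwards, not to the null.

All statistics are stored and compared as ``-log10 HBC`` so long regions do
not collapse into underflow ties at zero.  Empirical P-values use an add-one
pseudocount, ``P = (1 + #{null >= stat}) / (M + 1)``, which keeps them
strictly positive and conservative for finite nulls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hapfreq import (PairwiseHFTable, em_from_count_table, pair_count_arrays,
                      score_regions, subtract_individual)
from .roh import HomozygousRegion, call_roh_panel
from .sharing import find_shared_regions, log10_hbc_m, region_hf
from .io import GenotypePanel


def _rng(seed: int | None) -> np.random.Generator:
    # Philox is counter-based: reproducible bit-for-bit and cheap to seed
    return np.random.Generator(np.random.Philox(0 if seed is None else seed))


@dataclass
class NullDistribution:
    """Sorted best-region statistics (-log10 HBC) from control simulations."""

    mode: str
    stats: np.ndarray
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stats = np.sort(np.asarray(self.stats, dtype=float))

    @property
    def M(self) -> int:
        return len(self.stats)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            par = ";".join(f"{k}={v}" for k, v in sorted(self.params.items()))
            fh.write(f"# mode={self.mode} M={self.M} seed={self.seed} {par}\n")
            fh.write("neglog10_hbc\n")
            for s in self.stats:
                fh.write(f"{s:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NullDistribution":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ")
            fields = dict(kv.split("=", 1) for kv in header.split() if "=" in kv)
            fh.readline()
            stats = np.array([float(x) for x in fh.read().split()])
        seed = fields.get("seed")
        return cls(mode=fields.get("mode", "?"), stats=stats,
                   seed=None if seed in (None, "None") else int(seed))


def empirical_p(stat: float, null: NullDistribution) -> float:
    """Genome-wide empirical P for a -log10 HBC statistic (larger = more
    extreme): the add-one-corrected right-tail fraction of the null."""
    if null.M == 0:
        raise ValueError("empty null distribution")
    worse = int(np.count_nonzero(null.stats >= stat))
    return (1 + worse) / (null.M + 1)


# ---------------------------------------------------------------------------
# Single-patient null
# ---------------------------------------------------------------------------

def best_stats_per_individual(panel: GenotypePanel, table: PairwiseHFTable,
                              min_snps: int = 25, max_het: int = 0,
                              max_missing: int = 2) -> np.ndarray:
    """For every individual, -log10 of the smallest HF**2 over its ROH set
    (0.0 when the individual has no qualifying region)."""
    rois = call_roh_panel(panel, min_snps=min_snps, max_het=max_het,
                          max_missing=max_missing)
    out = np.zeros(panel.n_individuals)
    for i, iid in enumerate(panel.iids):
        scores = score_regions(rois[iid], table)
        if scores:
            out[i] = max(s.neglog10_hbc_s for s in scores)
    return out


def single_patient_null(controls: GenotypePanel, table: PairwiseHFTable,
                        min_snps: int = 25, max_het: int = 0,
                        max_missing: int = 2,
                        leave_one_out: bool = True) -> NullDistribution:
    """One statistic per control: its genome-wide best (smallest) HF**2.

    With ``leave_one_out`` (default) each control is scored against a
    pairwise table re-estimated without that control, mirroring how an
    external case is scored.  Scoring a control against a table containing
    its own two haplotypes inflates the frequency of exactly the haplotypes
    it carries, which weakens the null and makes case P-values
    anti-conservative.
    """
    if controls.n_individuals == 0:
        raise ValueError("empty control panel")
    if controls.n_individuals < 20:
        warnings.warn("fewer than 20 controls: the empirical null will be coarse")
    if leave_one_out and controls.n_individuals > 2:
        rois = call_roh_panel(controls, min_snps=min_snps, max_het=max_het,
                              max_missing=max_missing)
        counts, cats = pair_count_arrays(controls.genotypes)
        valid = controls.markers.pair_within_chrom()
        stats = np.zeros(controls.n_individuals)
        for i, iid in enumerate(controls.iids):
            if not rois[iid]:
                continue
            loo = subtract_individual(counts, cats, i)
            freqs, v, conv = em_from_count_table(loo, valid, init=table.freqs)
            tbl = PairwiseHFTable(controls.markers, freqs, v, valid,
                                  table.allele1_freq, table.k_haploid_factor,
                                  conv)
            scores = score_regions(rois[iid], tbl)
            stats[i] = max(s.neglog10_hbc_s for s in scores)
    else:
        stats = best_stats_per_individual(controls, table, min_snps, max_het,
                                          max_missing)
    return NullDistribution(
        mode="single", stats=stats, params={
            "min_snps": min_snps, "max_het": max_het,
            "max_missing": max_missing, "leave_one_out": leave_one_out,
        },
    )


# ---------------------------------------------------------------------------
# Multi-patient null
# ---------------------------------------------------------------------------

def _overlaps(chrom: str, a: int, b: int,
              masked: list[tuple[str, int, int]]) -> bool:
    return any(c == chrom and not (b < s or a > e) for (c, s, e) in masked)


def multi_patient_null(controls: GenotypePanel, table: PairwiseHFTable,
                       N: int, T: int, rounds: int, seed: int | None = None,
                       min_snps: int = 25, max_het: int = 0, max_missing: int = 2,
                       exclusion: bool = True,
                       control_regions: dict[str, list[HomozygousRegion]] | None = None,
                       ) -> NullDistribution:
    """Null for the N-of-T sharing statistic.

    Each round samples ``T`` controls without replacement, finds the shared
    region with carrier count between ``min(2, N)`` and ``N`` minimizing
    ``HBC_m`` and records its ``-log10 HBC_m``; with ``exclusion`` the
    recorded interval is masked for subsequent rounds.  Rounds in which every
    candidate region is masked (or none exists) contribute the sentinel
    statistic 0.0.  Single-carrier regions are only eligible when ``N == 1``
    (they belong to the single-patient statistic; their -log HBC_m scale is
    not comparable with genuine multi-carrier consensus regions).
    """
    if T > controls.n_individuals:
        raise ValueError("T exceeds the number of available controls")
    rng = _rng(seed)
    if control_regions is None:
        control_regions = call_roh_panel(controls, min_snps=min_snps,
                                         max_het=max_het, max_missing=max_missing)
    iids = controls.iids
    masked: list[tuple[str, int, int]] = []
    stats = np.zeros(rounds)
    cache: dict[tuple[str, int, int, int], float] = {}
    lo_carriers = min(2, N)
    for r in range(rounds):
        chosen = rng.choice(len(iids), size=T, replace=False)
        regs = [reg for i in chosen for reg in control_regions[iids[i]]]
        best = 0.0
        best_iv: tuple[str, int, int] | None = None
        for sr in find_shared_regions(regs, min_carriers=lo_carriers,
                                      min_snps=min_snps):
            if sr.n_carriers > N:
                continue
            if exclusion and _overlaps(sr.chrom, sr.i_first, sr.i_last, masked):
                continue
            key = (sr.chrom, sr.i_first, sr.i_last, sr.n_carriers)
            stat = cache.get(key)
            if stat is None:
                score = region_hf(sr.as_region(), table)
                stat = -log10_hbc_m(score.log_hf, sr.n_carriers, T)
                cache[key] = stat
            if stat > best:
                best, best_iv = stat, (sr.chrom, sr.i_first, sr.i_last)
        stats[r] = best
        if exclusion and best_iv is not None:
            masked.append(best_iv)
    return NullDistribution(
        mode=f"multi(N={N},T={T})", stats=stats, seed=seed,
        params={"rounds": rounds, "exclusion": exclusion, "min_snps": min_snps},
    )


# ---------------------------------------------------------------------------
# Sib-pair null
# ---------------------------------------------------------------------------

def sibpair_null(controls: GenotypePanel, table: PairwiseHFTable,
                 n_families: int, rounds: int, seed: int | None = None,
                 min_snps: int = 25, max_het: int = 0, max_missing: int = 2,
                 control_regions: dict[str, list[HomozygousRegion]] | None = None,
                 ) -> NullDistribution:
    """Null for the sib-pair mode: controls are paired into ``n_families``
    pseudo sib pairs per round; the best family-consensus region statistic
    (-log10 HBC_m over families) is recorded.  The ``(1/4)**N`` factor is not
    part of the null; it multiplies the case P-value afterwards."""
    if 2 * n_families > controls.n_individuals:
        raise ValueError("need at least 2 families' worth of controls")
    rng = _rng(seed)
    if control_regions is None:
        control_regions = call_roh_panel(controls, min_snps=min_snps,
                                         max_het=max_het, max_missing=max_missing)
    iids = controls.iids
    stats = np.zeros(rounds)
    for r in range(rounds):
        chosen = rng.choice(len(iids), size=2 * n_families, replace=False)
        fam_regs: list[HomozygousRegion] = []
        for f in range(n_families):
            a, b = iids[chosen[2 * f]], iids[chosen[2 * f + 1]]
            both = list(control_regions[a]) + list(control_regions[b])
            for sr in find_shared_regions(both, min_carriers=2, min_snps=min_snps):
                pseudo = sr.as_region()
                pseudo.iid = f"fam{f}"
                fam_regs.append(pseudo)
        best = 0.0
        for sr in find_shared_regions(fam_regs, min_carriers=1, min_snps=min_snps):
            score = region_hf(sr.as_region(), table)
            stat = -log10_hbc_m(score.log_hf, sr.n_carriers, n_families)
            best = max(best, stat)
        stats[r] = best
    return NullDistribution(
        mode=f"sibpair(F={n_families})", stats=stats, seed=seed,
        params={"rounds": rounds, "min_snps": min_snps},
    )
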