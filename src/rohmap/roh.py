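"""Detection of runs of homozygosity (ROH).

A run is a maximal stretch of homozygous genotypes in one individual, with a
small configurable budget of heterozygous exceptions and missing calls.  The
run caller here is intentionally plain (no HMM): the downstream haplotype
frequency statistic, not the run caller, is what discriminates homozygosity
by descent from homozygosity by chance.  Region boundaries are the first and
last homozygous markers of the run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GT_HET, GT_HOM1, GT_HOM2, GT_MISSING, GenotypePanel


@dataclass
class HomozygousRegion:
    """A maximal homozygous run in one individual.

    ``alleles`` holds the genotype codes over the marker span ``[i_first,
    i_last]`` (global marker indices, inclusive): 0/2 for the homozygous
    allele, 1 for a heterozygous exception, -1 for missing.
    """

    iid: str
    chrom: str
    i_first: int
    i_last: int
    start_bp: int
    end_bp: int
    alleles: np.ndarray
    n_het: int
    n_missing: int

    @property
    def n_snps(self) -> int:
        return self.i_last - self.i_first + 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _runs_one_chrom(codes: np.ndarray, max_het: int, max_missing: int,
                    min_snps: int) -> list[tuple[int, int, int, int]]:
    """Greedy maximal windows (start, end, n_het, n_missing) on one chromosome.

    Windows are grown left/right to a fixed point under the het/missing
    budget, always start and end on homozygous markers, and never overlap.
    """
    n = len(codes)
    is_hom = (codes == GT_HOM1) | (codes == GT_HOM2)
    is_het = codes == GT_HET
    is_mis = codes == GT_MISSING
    ch = np.concatenate(([0], np.cumsum(is_het)))
    cm = np.concatenate(([0], np.cumsum(is_mis)))

    def nhet(s, e):
        return int(ch[e + 1] - ch[s])

    def nmis(s, e):
        return int(cm[e + 1] - cm[s])

    out = []
    hom_idx = np.nonzero(is_hom)[0]
    ptr = 0  # index into hom_idx
    lo_bound = 0  # leftmost marker the next window may use (non-overlap)
    while ptr < len(hom_idx):
        s = e = int(hom_idx[ptr])
        grown = True
        while grown:
            grown = False
            # furthest feasible homozygous end to the right
            j = e + 1
            best = e
            while j < n and nhet(s, j) <= max_het and nmis(s, j) <= max_missing:
                if is_hom[j]:
                    best = j
                j += 1
            if best != e:
                e, grown = best, True
            # furthest feasible homozygous start to the left
            j = s - 1
            best = s
            while j >= lo_bound and nhet(j, e) <= max_het and nmis(j, e) <= max_missing:
                if is_hom[j]:
                    best = j
                j -= 1
            if best != s:
                s, grown = best, True
        if e - s + 1 >= min_snps:
            out.append((s, e, nhet(s, e), nmis(s, e)))
        lo_bound = e + 1
        while ptr < len(hom_idx) and hom_idx[ptr] <= e:
            ptr += 1
    return out


def call_roh(panel: GenotypePanel, individual: str, min_snps: int = 25,
             max_het: int = 0, max_missing: int = 2) -> list[HomozygousRegion]:
    """Identify maximal homozygous regions for one individual.

    Returns regions sorted by (chromosome, start), non-overlapping within a
    chromosome.  ``min_snps`` must be at least 2 because the downstream
    Markov-chain frequency needs at least one adjacent marker pair.
    """
    if min_snps < 2:
        raise ValueError("min_snps must be >= 2 (region frequency needs a marker pair)")
    row = panel.row(individual)
    return _call_roh_row(row, str(individual), panel, min_snps, max_het, max_missing)


def _call_roh_row(row: np.ndarray, iid: str, panel: GenotypePanel, min_snps: int,
                  max_het: int, max_missing: int) -> list[HomozygousRegion]:
    regions: list[HomozygousRegion] = []
    pos = panel.markers.pos_bp
    for chrom, sl in panel.markers.chrom_slices().items():
        codes = row[sl]
        for (s, e, nh, nm) in _runs_one_chrom(codes, max_het, max_missing, min_snps):
            gs, ge = sl.start + s, sl.start + e
            regions.append(
                HomozygousRegion(
                    iid=iid, chrom=chrom, i_first=gs, i_last=ge,
                    start_bp=int(pos[gs]), end_bp=int(pos[ge]),
                    alleles=row[gs:ge + 1].copy(), n_het=nh, n_missing=nm,
                )
            )
    return regions


def call_roh_panel(panel: GenotypePanel, min_snps: int = 25, max_het: int = 0,
                   max_missing: int = 2) -> dict[str, list[HomozygousRegion]]:
    """ROH for every individual in the panel, keyed by individual id."""
    if min_snps < 2:
        raise ValueError("min_snps must be >= 2 (region frequency needs a marker pair)")
    out: dict[str, list[HomozygousRegion]] = {}
    for i, iid in enumerate(panel.iids):
        out[iid] = _call_roh_row(panel.genotypes[i], iid, panel, min_snps,
                                 max_het, max_missing)
    return out


def regions_to_bed(regions: list[HomozygousRegion]) -> str:
    """BED text for a region list (0-based half-open at this boundary only)."""
    lines = [
        f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.iid}\t{r.n_snps}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
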