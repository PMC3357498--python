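"""Founder-allele inheritance simulation.

A mutation is placed on one chromosome of an ancestor; each generation a
meiosis shortens the mutation-carrying haplotype by recombination, and an
affected individual inherits two copies of the ancestral allele through two
independent inheritance paths, producing a homozygous tract equal to the
intersection of the two surviving segments.

Crossovers follow a Poisson process on genetic distance (Haldane model, no
interference).  Transmission of the focal allele is conditioned on at every
generation — otherwise the allele is lost and no affected individual exists —
so the surviving segment around the focal locus shrinks by the distance to
the nearest flanking crossover on each side, an Exponential(1) draw in
Morgans per meiosis per arm.

The same crossover machinery drives the cousin IBD-sharing simulation:
labelled segments from an ancestral couple are followed down independent
lineages across the 22 autosomes and relatives share a region IBD when
segments descending from the same ancestral haplotype copy overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypePanel
from .synth import PopulationModel, sample_haplotypes

logger = logging.getLogger(__name__)

#: Sex-averaged autosome genetic lengths in cM (deCODE-like; total ~3541 cM).
#: The crossover model only needs chromosome lengths, not a full map.
AUTOSOME_CM: dict[int, float] = {
    1: 286.3, 2: 268.6, 3: 223.2, 4: 214.5, 5: 204.1, 6: 192.0, 7: 187.2,
    8: 168.0, 9: 166.4, 10: 181.1, 11: 158.2, 12: 174.7, 13: 125.9,
    14: 120.8, 15: 141.9, 16: 134.0, 17: 128.5, 18: 117.5, 19: 107.9,
    20: 108.3, 21: 62.8, 22: 74.1,
}


@dataclass
class IBDSegmentTrack:
    """Per-chromosome intervals (in cM) carrying founder material.

    ``segments`` maps chromosome id to a list of ``(start_cm, end_cm)`` or
    ``(start_cm, end_cm, label)`` tuples; intervals are non-overlapping and
    sorted, and may be absent when the allele was lost.
    """

    segments: dict = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not any(self.segments.values())


# ---------------------------------------------------------------------------
# Conditioned transmission of a focal founder segment
# ---------------------------------------------------------------------------

def transmit_haplotype(chrom: str, focal_cm: float, generations: int,
                       chrom_length_cm: float, rng: np.random.Generator
                       ) -> IBDSegmentTrack:
    """Surviving founder interval around a focal locus after ``generations``
    meioses, conditioned on transmission of the focal allele each time.

    With Poisson crossovers, the distances from the focal locus to the nearest
    crossover on each side are independent Exponential(1 per Morgan) draws,
    truncated at the chromosome ends; ``generations = 0`` returns the full
    founder chromosome.
    """
    if not (0.0 <= focal_cm <= chrom_length_cm):
        raise ValueError("focal locus outside the chromosome")
    lo, hi = 0.0, chrom_length_cm
    for _ in range(generations):
        left = rng.exponential(1.0) * 100.0   # Morgans -> cM
        right = rng.exponential(1.0) * 100.0
        lo = max(lo, focal_cm - left)
        hi = min(hi, focal_cm + right)
    return IBDSegmentTrack(segments={chrom: [(lo, hi)]})


def intersect_tracks(a: IBDSegmentTrack, b: IBDSegmentTrack) -> IBDSegmentTrack:
    out: dict = {}
    for chrom, segs in a.segments.items():
        other = b.segments.get(chrom, [])
        keep = []
        for s1 in segs:
            for s2 in other:
                lo, hi = max(s1[0], s2[0]), min(s1[1], s2[1])
                if hi > lo:
                    keep.append((lo, hi))
        if keep:
            out[chrom] = keep
    return IBDSegmentTrack(segments=out)


def make_affected(markers, background_pair: np.ndarray, founder_hap: np.ndarray,
                  track_a: IBDSegmentTrack, track_b: IBDSegmentTrack,
                  ) -> tuple[np.ndarray, tuple[int, int] | None]:
    """Case genotypes: homozygous for the founder haplotype over the
    intersection of the two transmitted tracks, background elsewhere.

    Returns ``(genotype_row, (i_first, i_last))``; the planted span is None
    when the intersection is empty or covers no markers (callers typically
    resample in that case, matching conditioning on an inherited homozygous
    region).
    """
    geno = (background_pair[0] + background_pair[1]).astype(np.int8)
    inter = intersect_tracks(track_a, track_b)
    span = None
    cm = markers.cm
    chrom_arr = markers.chrom
    for chrom, segs in inter.segments.items():
        sel = chrom_arr == str(chrom)
        for (lo, hi) in segs:
            inside = sel & (cm >= lo) & (cm <= hi)
            idx = np.nonzero(inside)[0]
            if len(idx) == 0:
                continue
            geno[idx] = (2 * founder_hap[idx]).astype(np.int8)
            span = (int(idx[0]), int(idx[-1]))
    return geno, span


def plant_case(model: PopulationModel, generations: int,
               rng: np.random.Generator,
               focal: tuple[str, float] | None = None,
               max_resample: int = 100,
               ) -> tuple[np.ndarray, tuple[int, int]]:
    """Simulate one affected individual on a synthetic population background.

    The founder haplotype is a fresh draw from the population process; two
    independent ``generations``-deep inheritance paths produce the homozygous
    tract.  Resamples (logged) when the planted tract covers fewer than two
    markers.
    """
    markers = model.marker_map()
    chrom_cm = {}
    for chrom, sl in markers.chrom_slices().items():
        chrom_cm[chrom] = float(markers.cm[sl.stop - 1])
    for attempt in range(max_resample):
        if focal is None:
            chrom = list(chrom_cm)[rng.integers(len(chrom_cm))]
            focal_cm = float(rng.uniform(0, chrom_cm[chrom]))
        else:
            chrom, focal_cm = focal
        ta = transmit_haplotype(chrom, focal_cm, generations, chrom_cm[chrom], rng)
        tb = transmit_haplotype(chrom, focal_cm, generations, chrom_cm[chrom], rng)
        bg = sample_haplotypes(model, 2, rng)
        founder = sample_haplotypes(model, 1, rng)[0]
        geno, span = make_affected(markers, bg, founder, ta, tb)
        if span is not None and span[1] - span[0] + 1 >= 2:
            return geno, span
        logger.info("empty founder intersection at generation depth %d; resampling",
                    generations)
    raise RuntimeError("could not plant a founder tract (intersections empty)")


def plant_shared_cases(model: PopulationModel, n_carriers: int, generations: int,
                       rng: np.random.Generator,
                       focal: tuple[str, float] | None = None,
                       max_resample: int = 100,
                       ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Simulate ``n_carriers`` affected individuals inheriting two copies of
    the same founder allele via independent paths.  Returns their genotype
    rows and per-carrier planted spans (all overlapping the focal locus)."""
    markers = model.marker_map()
    chrom_cm = {c: float(markers.cm[sl.stop - 1])
                for c, sl in markers.chrom_slices().items()}
    if focal is None:
        chrom = list(chrom_cm)[rng.integers(len(chrom_cm))]
        focal = (chrom, float(rng.uniform(0, chrom_cm[chrom])))
    chrom, focal_cm = focal
    founder = sample_haplotypes(model, 1, rng)[0]
    genos, spans = [], []
    for _ in range(n_carriers):
        for attempt in range(max_resample):
            ta = transmit_haplotype(chrom, focal_cm, generations, chrom_cm[chrom], rng)
            tb = transmit_haplotype(chrom, focal_cm, generations, chrom_cm[chrom], rng)
            bg = sample_haplotypes(model, 2, rng)
            geno, span = make_affected(markers, bg, founder, ta, tb)
            if span is not None and span[1] - span[0] + 1 >= 2:
                genos.append(geno)
                spans.append(span)
                break
        else:
            raise RuntimeError("could not plant a shared founder tract")
    return np.array(genos, dtype=np.int8), spans


# ---------------------------------------------------------------------------
# Cousin IBD sharing over 22 autosomes
# ---------------------------------------------------------------------------

def _mosaic(L: float, lab_a: int, lab_b: int, rng) -> list:
    """Gamete of a parent whose two homologs are wholly labelled a / b."""
    n = rng.poisson(L)
    if n == 0:
        return [(0.0, L, lab_a if rng.random() < 0.5 else lab_b)]
    pts = np.empty(n + 2)
    pts[0], pts[-1] = 0.0, L
    pts[1:-1] = np.sort(rng.random(n) * L)
    ph = int(rng.random() < 0.5)
    return [(pts[i], pts[i + 1], lab_a if (i + ph) % 2 == 0 else lab_b)
            for i in range(n + 1)]


def _meiosis(track_a: list, track_b: list, L: float, rng) -> list:
    """Gamete from two labelled segment tracks (either may be empty,
    representing non-founder material)."""
    n = rng.poisson(L)
    if n:
        xs = np.sort(rng.random(n) * L)
        pts = np.concatenate(([0.0], xs, [L]))
    else:
        pts = np.array([0.0, L])
    ph = int(rng.random() < 0.5)
    out = []
    for i in range(len(pts) - 1):
        src = track_a if (i + ph) % 2 == 0 else track_b
        a, b = pts[i], pts[i + 1]
        for (s, e, lab) in src:
            if e <= a or s >= b:
                continue
            out.append((max(s, a), min(e, b), lab))
    return out


def _lineage(degree: int, rng, lengths_m: dict, chroms) -> dict:
    """Labelled ancestral-couple track of one k-th cousin's lineage haplotype.

    The couple's four haplotype copies are labelled 0-3.  A child of the
    couple carries two fully ancestral haplotypes; its gamete starts the
    lineage, followed by ``degree - 1`` meioses against non-founder spouses.
    """
    out = {}
    for c in chroms:
        L = lengths_m[c]
        pat = _mosaic(L, 0, 1, rng)
        mat = _mosaic(L, 2, 3, rng)
        t = _meiosis(pat, mat, L, rng)
        for _ in range(degree - 1):
            if not t:
                break
            t = _meiosis(t, [], L, rng)
        if t:
            out[c] = t
    return out


def _label_overlap(t1: dict, t2: dict) -> dict:
    out = {}
    for c, segs1 in t1.items():
        segs2 = t2.get(c)
        if not segs2:
            continue
        keep = []
        for (s1, e1, l1) in segs1:
            for (s2, e2, l2) in segs2:
                if l1 == l2 and min(e1, e2) > max(s1, s2):
                    keep.append((max(s1, s2), min(e1, e2), l1))
        if keep:
            out[c] = keep
    return out


def cousin_sharing_probability(degree: int, n_relatives: int = 2,
                               replicates: int = 20_000,
                               seed: int | None = None,
                               chrom_lengths_cm: dict | None = None) -> float:
    """Monte-Carlo probability that ``n_relatives`` k-th cousins all share at
    least one autosomal segment IBD from their common ancestral couple.

    ``degree = 0`` denotes siblings (two children of the couple), who share
    essentially surely.  Crossovers are Poisson on genetic distance across
    the 22 autosomes (``AUTOSOME_CM`` by default).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if degree < 0 or n_relatives < 2:
        raise ValueError("degree >= 0 and n_relatives >= 2 required")
    lengths = chrom_lengths_cm or AUTOSOME_CM
    lengths_m = {c: l / 100.0 for c, l in lengths.items()}
    rng = np.random.Generator(np.random.Philox(0 if seed is None else seed))
    all_chroms = list(lengths_m)
    hits = 0
    for _ in range(replicates):
        if degree == 0:
            # siblings: both haplotypes of each child are fully ancestral
            tracks = []
            for _r in range(n_relatives):
                t = {}
                for c in all_chroms:
                    L = lengths_m[c]
                    t[c] = _mosaic(L, 0, 1, rng) + _mosaic(L, 2, 3, rng)
                tracks.append(t)
            acc = tracks[0]
            for t in tracks[1:]:
                acc = _label_overlap(acc, t)
                if not acc:
                    break
            hits += bool(acc)
            continue
        acc = _lineage(degree, rng, lengths_m, all_chroms)
        ok = bool(acc)
        for _r in range(n_relatives - 1):
            if not ok:
                break
            t2 = _lineage(degree, rng, lengths_m, list(acc))
            acc = _label_overlap(acc, t2)
            ok = bool(acc)
        hits += ok
    return hits / replicates


def expected_shared_segments(degree: int, n_ancestors: int = 2,
                             chrom_lengths_cm: dict | None = None) -> float:
    """Closed-form expected number of segments two k-th cousins share IBD
    from their ancestral couple: ``a (L d + c) / 2^(d-1)`` with ``d = 2(k+1)``
    meioses, ``L`` the map length in Morgans, ``c`` the chromosome count and
    ``a`` the number of ancestors.  Used as an independent cross-check of the
    Monte-Carlo machinery."""
    lengths = chrom_lengths_cm or AUTOSOME_CM
    L = sum(lengths.values()) / 100.0
    c = len(lengths)
    d = 2 * (degree + 1)
    return n_ancestors * (L * d + c) / 2 ** (d - 1)
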