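"""Genotype panel I/O: PLINK text (.ped/.map) and VCF readers, writers and
harmonization.

The shared data model is deliberately small: a :class:`MarkerMap` (one row per
biallelic SNP, sorted by chromosome then position) and a :class:`GenotypePanel`
(an individual table plus an ``int8`` genotype matrix).  Genotypes are coded as
the number of copies of the marker's second allele: ``0`` hom first allele,
``1`` het, ``2`` hom second allele, ``-1`` missing.  Missing genotypes are kept
explicit and never imputed here.

Coordinates are 1-based inclusive base pairs, as in PLINK/VCF; regions are
reported as closed intervals ``[start_bp, end_bp]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GT_HOM1 = 0
GT_HET = 1
GT_HOM2 = 2
GT_MISSING = -1

ROLE_CASE = "case"
ROLE_CONTROL = "control"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _chrom_key(c: str):
    s = str(c)
    return (0, int(s)) if s.isdigit() else (1, s)


@dataclass
class MarkerMap:
    """Per-marker records: chromosome, bp position, genetic position, alleles.

    ``table`` columns: ``chrom`` (str), ``marker_id`` (str), ``pos_bp``
    (int, 1-based), ``cm`` (float), ``allele1``, ``allele2``.  The first
    allele is the reference for genotype code 0; when read from a file it is
    the first allele observed for that marker.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chrom", "marker_id", "pos_bp", "cm", "allele1", "allele2"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"MarkerMap missing columns: {missing}")
        t = self.table
        for chrom, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")
        same = t["allele1"].astype(str) == t["allele2"].astype(str)
        if same.any():
            bad = t.loc[same, "marker_id"].iloc[0]
            raise ValueError(f"marker {bad} is not biallelic (identical allele labels)")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.table["cm"].to_numpy()

    def pair_within_chrom(self) -> np.ndarray:
        """Boolean mask of length n_markers-1: adjacent pair on one chromosome."""
        c = self.chrom
        return c[:-1] == c[1:]

    def chrom_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        c = self.chrom
        start = 0
        for i in range(1, len(c) + 1):
            if i == len(c) or c[i] != c[start]:
                out[str(c[start])] = slice(start, i)
                start = i
        return out


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for a set of individuals over a MarkerMap.

    ``individuals`` columns: ``iid``, ``fid``, ``role`` (``case``/``control``).
    ``genotypes`` has shape (n_individuals, n_markers), dtype int8.
    """

    markers: MarkerMap
    individuals: pd.DataFrame
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), self.markers.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {self.markers.n_markers} markers"
            )
        if "fid" not in self.individuals.columns:
            self.individuals = self.individuals.assign(fid=self.individuals["iid"])
        if "role" not in self.individuals.columns:
            self.individuals = self.individuals.assign(role=ROLE_CONTROL)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def iids(self) -> list[str]:
        return [str(x) for x in self.individuals["iid"]]

    def row(self, iid: str) -> np.ndarray:
        idx = self.iids.index(str(iid))
        return self.genotypes[idx]

    def subset(self, mask_or_indices) -> "GenotypePanel":
        idx = np.asarray(mask_or_indices)
        return GenotypePanel(
            self.markers,
            self.individuals.iloc[idx].reset_index(drop=True),
            self.genotypes[idx],
        )

    def by_role(self, role: str) -> "GenotypePanel":
        mask = (self.individuals["role"] == role).to_numpy()
        return self.subset(np.nonzero(mask)[0])

    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing genotypes."""
        return (self.genotypes == GT_MISSING).mean(axis=0)

    def all_missing_markers(self) -> np.ndarray:
        return np.nonzero((self.genotypes == GT_MISSING).all(axis=0))[0]


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def read_plink(prefix_or_ped: str | Path, map_path: str | Path | None = None) -> GenotypePanel:
    """Read a PLINK text fileset (``.ped`` + ``.map``).

    ``prefix_or_ped`` may be a prefix (``study`` -> ``study.ped``/``study.map``)
    or an explicit ``.ped`` path together with ``map_path``.  Alleles are
    normalized per marker so that allele1 is the first allele observed in the
    file.  The phenotype column maps 2 -> case, anything else -> control.
    """
    p = Path(prefix_or_ped)
    if p.suffix == ".ped":
        base = str(p)[:-4]
        ped_path = p
        mp = Path(map_path) if map_path else Path(base + ".map")
    else:  # treat as a fileset prefix (may itself contain dots)
        ped_path, mp = Path(str(p) + ".ped"), Path(str(p) + ".map")

    chroms, ids, cms, bps = [], [], [], []
    with open(mp) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{mp}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                bp = int(parts[3])
                cm = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{mp}:{ln}: {exc}") from None
            chroms.append(parts[0])
            ids.append(parts[1])
            cms.append(cm)
            bps.append(bp)
    m = len(ids)

    iids, fids, roles = [], [], []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            roles.append(ROLE_CASE if parts[5] == "2" else ROLE_CONTROL)
            allele_rows.append(np.array(parts[6:], dtype=object))

    n = len(iids)
    geno = np.full((n, m), GT_MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        seen: list[str] = []
        col1 = [allele_rows[i][2 * j] for i in range(n)]
        col2 = [allele_rows[i][2 * j + 1] for i in range(n)]
        for a in col1 + col2:
            if a != "0" and a not in seen:
                seen.append(a)
        if len(seen) > 2:
            logger.warning("skipping non-biallelic marker %s (alleles %s)",
                           ids[j], ",".join(seen))
            keep[j] = False
            a1[j], a2[j] = "N", "0"
            continue
        if not seen:
            seen = ["N"]  # marker entirely missing: alleles unknown
        if len(seen) == 1:
            seen.append("0")  # PLINK convention: unobserved second allele
        a1[j], a2[j] = seen[0], seen[1]
        for i in range(n):
            x, y = col1[i], col2[i]
            if x == "0" or y == "0":
                continue
            geno[i, j] = (x == a2[j]) + (y == a2[j])

    mm = pd.DataFrame(
        {"chrom": chroms, "marker_id": ids, "pos_bp": bps, "cm": cms,
         "allele1": a1, "allele2": a2}
    )
    if not keep.all():
        mm = mm[keep].reset_index(drop=True)
        geno = geno[:, keep]
    panel = GenotypePanel(
        MarkerMap(_sorted_markers(mm)[0]),
        pd.DataFrame({"iid": iids, "fid": fids, "role": roles}),
        geno[:, _sorted_markers(mm)[1]],
    )
    return panel


def _sorted_markers(mm: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    order = sorted(
        range(len(mm)),
        key=lambda i: (_chrom_key(mm["chrom"].iloc[i]), int(mm["pos_bp"].iloc[i])),
    )
    idx = np.array(order)
    return mm.iloc[idx].reset_index(drop=True), idx


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK text ``.ped``/``.map``."""
    t = panel.markers.table
    with open(f"{prefix}.map", "w") as fh:
        for _, r in t.iterrows():
            fh.write(f"{r.chrom}\t{r.marker_id}\t{r.cm:g}\t{r.pos_bp}\n")
    a1 = t["allele1"].to_numpy()
    a2 = t["allele2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, ind in panel.individuals.iterrows():
            phen = "2" if ind["role"] == ROLE_CASE else "1"
            fields = [str(ind["fid"]), str(ind["iid"]), "0", "0", "0", phen]
            g = panel.genotypes[i]
            for j in range(panel.markers.n_markers):
                if g[j] == GT_MISSING:
                    fields += ["0", "0"]
                elif g[j] == GT_HOM1:
                    fields += [str(a1[j]), str(a1[j])]
                elif g[j] == GT_HET:
                    fields += [str(a1[j]), str(a2[j])]
                else:
                    fields += [str(a2[j]), str(a2[j])]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF dialect (GT field only)
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, role: str = ROLE_CONTROL) -> GenotypePanel:
    """Read genotypes (GT only) from a VCF.  Non-biallelic sites are skipped
    with a logged warning.  allele1 = REF, allele2 = first ALT."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, ids, bps, a1, a2, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or var.ALT[0] in (".", ""):
            logger.warning("skipping non-biallelic site %s:%s", var.CHROM, var.POS)
            continue
        gt = np.asarray(var.genotype.array())[:, :2]
        code = np.where((gt < 0).any(axis=1), GT_MISSING, (gt > 0).sum(axis=1))
        chroms.append(var.CHROM)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        bps.append(var.POS)
        a1.append(var.REF)
        a2.append(var.ALT[0])
        rows.append(code.astype(np.int8))
    vcf.close()
    mm = pd.DataFrame(
        {"chrom": chroms, "marker_id": ids, "pos_bp": bps,
         "cm": [bp / 1e6 for bp in bps], "allele1": a1, "allele2": a2}
    )
    mm_sorted, idx = _sorted_markers(mm)
    geno = np.array(rows, dtype=np.int8).T[:, idx] if rows else np.zeros((len(samples), 0), np.int8)
    return GenotypePanel(
        MarkerMap(mm_sorted),
        pd.DataFrame({"iid": samples, "fid": samples, "role": role}),
        geno,
    )


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal VCF (GT only) for round-tripping and interchange."""
    t = panel.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(t["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.iids) + "\n")
        gmap = {GT_HOM1: "0/0", GT_HET: "0/1", GT_HOM2: "1/1", GT_MISSING: "./."}
        for j, (_, r) in enumerate(t.iterrows()):
            gts = "\t".join(gmap[int(g)] for g in panel.genotypes[:, j])
            fh.write(f"{r.chrom}\t{r.pos_bp}\t{r.marker_id}\t{r.allele1}\t{r.allele2}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Harmonization and result tables
# ---------------------------------------------------------------------------

def harmonize(cases: GenotypePanel, controls: GenotypePanel) -> tuple[GenotypePanel, GenotypePanel]:
    """Align two panels on shared marker ids with consistent alleles.

    Markers absent from either panel are dropped.  If the two panels list the
    same two alleles in swapped order, the case genotype codes are flipped.
    Any other allele mismatch (e.g. an apparent strand flip) is logged and the
    marker excluded; strand flips are never auto-resolved.
    """
    tc = cases.markers.table
    tk = controls.markers.table
    pos_c = {mid: i for i, mid in enumerate(tc["marker_id"])}
    keep_c, keep_k, flip = [], [], []
    for i, mid in enumerate(tk["marker_id"]):
        j = pos_c.get(mid)
        if j is None:
            continue
        ca1, ca2 = str(tc["allele1"].iloc[j]), str(tc["allele2"].iloc[j])
        ka1, ka2 = str(tk["allele1"].iloc[i]), str(tk["allele2"].iloc[i])
        # "0" marks a second allele never observed in that file (PLINK style)
        noflip = ca1 == ka1 and (ca2 == ka2 or ca2 == "0" or ka2 == "0")
        flipped = (ca1 == ka2 and (ca2 == ka1 or ca2 == "0")) or \
                  (ka2 == "0" and ca2 == ka1)
        if noflip:
            keep_c.append(j), keep_k.append(i), flip.append(False)
        elif flipped:
            keep_c.append(j), keep_k.append(i), flip.append(True)
        else:
            logger.warning(
                "marker %s allele mismatch (%s/%s vs %s/%s): excluded",
                mid, ca1, ca2, ka1, ka2,
            )
    keep_ca, keep_ka = np.array(keep_c, int), np.array(keep_k, int)
    flips = np.array(flip, bool)
    geno_c = cases.genotypes[:, keep_ca].copy()
    if flips.any():
        cols = geno_c[:, flips]
        swapped = np.where(cols == GT_MISSING, GT_MISSING, 2 - cols)
        geno_c[:, flips] = swapped
    mm = MarkerMap(tk.iloc[keep_ka].reset_index(drop=True))
    return (
        GenotypePanel(mm, cases.individuals.copy(), geno_c),
        GenotypePanel(mm, controls.individuals.copy(), controls.genotypes[:, keep_ka]),
    )


REGION_TSV_COLUMNS = [
    "chrom", "start_bp", "end_bp", "n_snps", "individuals",
    "HF", "HBC_s", "HBC_m", "empirical_P",
]


def write_regions_tsv(rows: Iterable[dict], path: str | Path) -> None:
    """Write scored regions as a TSV with the standard column set."""
    df = pd.DataFrame(list(rows))
    for col in REGION_TSV_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df[REGION_TSV_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")
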