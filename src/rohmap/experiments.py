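"""Validation experiments: planted founder alleles on synthetic populations.

These routines wire the simulator, the region statistic and the Monte-Carlo
nulls into the study designs used to characterize the method: recovery of a
planted founder region in a single patient as a function of founder age,
recovery of a region shared by N of T patients, and calibration of the
empirical P-values under the global null.

The study population is a mosaic-mode synthetic panel (haplotypes copying
from a finite pool), which reproduces the haplotype-block sharing of real
populations: short haplotypes are common, long ones rare, so older (shorter)
founder segments are genuinely harder to distinguish from chance
homozygosity.  Problem sizes default to a desk-scale genome of 2 chromosomes
x 2500 markers (10 kb spacing, 1 cM/Mb) and 100 controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .founder import plant_case, plant_shared_cases
from .hapfreq import PairwiseHFTable, estimate_pair_table, score_regions
from .io import GenotypePanel
from .nulls import (NullDistribution, best_stats_per_individual, empirical_p,
                    single_patient_null)
from .roh import _call_roh_row, call_roh_panel
from .sharing import find_shared_regions, log10_hbc_m, region_hf
from .synth import PopulationModel, generate_panel


def study_model(seed: int = 11) -> PopulationModel:
    """The default study-condition population for recovery experiments."""
    return PopulationModel(n_chrom=2, markers_per_chrom=2500, mode="mosaic",
                           seed=seed)


@dataclass
class Study:
    """A frozen control panel with its pairwise table and single-patient null."""

    model: PopulationModel
    controls: GenotypePanel
    table: PairwiseHFTable
    null: NullDistribution

    @classmethod
    def build(cls, model: PopulationModel, n_controls: int = 100,
              seed: int = 0, min_snps: int = 25) -> "Study":
        rng = np.random.Generator(np.random.Philox(seed))
        controls, _ = generate_panel(model, n_controls, rng, iid_prefix="ctrl")
        table = estimate_pair_table(controls)
        null = single_patient_null(controls, table, min_snps=min_snps)
        return cls(model, controls, table, null)


def planted_recovery_rate(study: Study, generations: int, replicates: int,
                          seed: int, min_snps: int = 25) -> float:
    """Fraction of replicate patients in which the planted founder region
    attains the smallest genome-wide empirical P (ties broken by HF**2)."""
    rng = np.random.Generator(np.random.Philox(seed))
    hits = 0
    for _ in range(replicates):
        geno, span = plant_case(study.model, generations, rng)
        regs = _call_roh_row(geno, "case", study.controls, min_snps, 0, 2)
        scores = score_regions(regs, study.table)
        if not scores:
            continue
        ranked = sorted(
            scores,
            key=lambda s: (empirical_p(s.neglog10_hbc_s, study.null),
                           -s.neglog10_hbc_s),
        )
        top = ranked[0].region
        if top.i_first <= span[1] and top.i_last >= span[0]:
            hits += 1
    return hits / replicates


def sharing_recovery_rate(study: Study, generations: int, n_carriers: int,
                          n_patients: int, replicates: int, seed: int,
                          min_snps: int = 25) -> float:
    """Fraction of replicates in which the top-ranked shared region (by
    HBC_m among regions with 2..n_carriers carriers) is the planted founder
    region, carried exclusively by planted carriers."""
    rng = np.random.Generator(np.random.Philox(seed))
    hits = 0
    for _ in range(replicates):
        carr, spans = plant_shared_cases(study.model, n_carriers, generations,
                                         rng)
        bg, _ = generate_panel(study.model, n_patients - n_carriers, rng)
        genos = np.vstack([carr, bg.genotypes])
        regs = []
        for i in range(n_patients):
            regs += _call_roh_row(genos[i], f"p{i}", study.controls,
                                  min_snps, 0, 2)
        shared = [s for s in find_shared_regions(regs, min_carriers=2,
                                                 min_snps=min_snps)
                  if s.n_carriers <= n_carriers]
        if not shared:
            continue
        best, best_stat = None, -np.inf
        for sr in shared:
            stat = -log10_hbc_m(region_hf(sr.as_region(), study.table).log_hf,
                                sr.n_carriers, n_patients)
            if stat > best_stat:
                best, best_stat = sr, stat
        core_lo = max(s[0] for s in spans)
        core_hi = min(s[1] for s in spans)
        planted_ids = {f"p{i}" for i in range(n_carriers)}
        if (best.i_first <= core_hi and best.i_last >= core_lo
                and set(best.carriers) <= planted_ids):
            hits += 1
    return hits / replicates


def calibration_pvalues(study: Study, n_cases: int, seed: int,
                        min_snps: int = 25) -> np.ndarray:
    """Empirical P of the best region of ``n_cases`` unaffected individuals
    drawn from the same population as the controls (the global null)."""
    rng = np.random.Generator(np.random.Philox(seed))
    cases, _ = generate_panel(study.model, n_cases, rng, iid_prefix="case")
    stats = best_stats_per_individual(cases, study.table, min_snps=min_snps)
    return np.array([empirical_p(s, study.null) for s in stats])


def calibration_pvalues_replicated(n_panels: int, n_cases_per: int, seed: int,
                                   n_controls: int = 100,
                                   min_snps: int = 25) -> np.ndarray:
    """Global-null P-values pooled over independent study panels.

    Cases scored against a single finite null share its realization, so
    their P-values are dependent; drawing fresh controls (and their null)
    for each batch of cases makes the pooled sample close to independent,
    which is what a distributional uniformity check assumes.
    """
    out = []
    for b in range(n_panels):
        study = Study.build(study_model(seed=11 + 7 * b),
                            n_controls=n_controls, seed=seed + 1000 * b,
                            min_snps=min_snps)
        out.append(calibration_pvalues(study, n_cases_per, seed + 13 + b,
                                       min_snps=min_snps))
    return np.concatenate(out)
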