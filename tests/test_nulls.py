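import numpy as np
import pytest

from rohmap.hapfreq import estimate_pair_table
from rohmap.nulls import (NullDistribution, best_stats_per_individual,
                          empirical_p, multi_patient_null, sibpair_null,
                          single_patient_null)
from rohmap.roh import call_roh_panel
from rohmap.sharing import find_shared_regions, log10_hbc_m, region_hf
from rohmap.synth import generate_panel

from conftest import make_panel


def test_single_null_one_statistic_per_control(control_data):
    panel, _, table = control_data
    null = single_patient_null(panel, table)
    assert null.M == panel.n_individuals
    assert np.all(np.diff(null.stats) >= 0)  # stored sorted ascending


def test_control_without_roh_contributes_sentinel(control_data):
    _, _, table = control_data
    m = table.markers.n_markers
    geno = np.ones((2, m), dtype=np.int8)  # all het: no runs at all
    geno[1, 20:80] = 0
    panel = make_panel(geno, chrom=table.markers.chrom,
                       pos=table.markers.pos_bp)
    with pytest.warns(UserWarning, match="fewer than 20"):
        null = single_patient_null(panel, table)
    # sentinel HF^2 = 1.0 -> -log10 = 0 for the ROH-free control
    assert null.stats[0] == 0.0
    assert null.stats[1] > 0.0


def test_planted_rare_tract_is_most_extreme_control(control_data, mosaic_model):
    panel, haps, table = control_data
    geno = panel.genotypes.copy()
    # give control 0 a long homozygous tract from a sampled haplotype
    geno[0, 30:270] = 2 * haps[33, 30:270]
    planted = make_panel(geno, chrom=panel.markers.chrom,
                         pos=panel.markers.pos_bp,
                         iids=[f"c{i}" for i in range(len(geno))])
    stats = best_stats_per_individual(planted, table)
    assert np.argmax(stats) == 0


def test_empirical_p_pseudocount_bounds():
    null = NullDistribution(mode="single", stats=np.arange(999, dtype=float))
    assert empirical_p(10_000.0, null) == pytest.approx(1 / 1000)
    assert empirical_p(float(np.median(null.stats)), null) == pytest.approx(
        0.5, abs=0.01)
    # add-one correction always at least the naive fraction
    for s in (0.0, 5.0, 500.0, 2000.0):
        naive = np.mean(null.stats >= s)
        assert empirical_p(s, null) >= naive


def test_empirical_p_monotone_in_extremeness(control_data):
    panel, _, table = control_data
    null = single_patient_null(panel, table)
    ps = [empirical_p(s, null) for s in (0.0, 1.0, 5.0, 20.0, 100.0)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_multi_null_deterministic_under_seed(control_data):
    panel, _, table = control_data
    kw = dict(N=2, T=20, rounds=25, min_snps=10)
    a = multi_patient_null(panel, table, seed=7, **kw)
    b = multi_patient_null(panel, table, seed=7, **kw)
    c = multi_patient_null(panel, table, seed=8, **kw)
    np.testing.assert_array_equal(a.stats, b.stats)
    assert a.M == 25
    assert not np.array_equal(a.stats, c.stats)


def test_multi_null_n1_reduces_to_best_single_statistic(control_data):
    panel, _, table = control_data
    T = panel.n_individuals  # every round samples the whole panel
    null = multi_patient_null(panel, table, N=1, T=T, rounds=1, seed=3,
                              exclusion=False, min_snps=25)
    regions = call_roh_panel(panel, min_snps=25)
    regs = [r for rs in regions.values() for r in rs]
    best = max(
        -log10_hbc_m(region_hf(sr.as_region(), table).log_hf, 1, T)
        for sr in find_shared_regions(regs, min_carriers=1, min_snps=25)
    )
    assert null.stats[-1] == pytest.approx(best, rel=1e-9)


def test_multi_null_exclusion_masks_previous_best(control_data):
    panel, _, table = control_data
    T = panel.n_individuals
    excl = multi_patient_null(panel, table, N=2, T=T, rounds=4, seed=1,
                              exclusion=True, min_snps=10)
    # with the whole panel sampled every round, masking forces later rounds
    # onto different (weaker) regions, while no-exclusion repeats the best
    noex = multi_patient_null(panel, table, N=2, T=T, rounds=4, seed=1,
                              exclusion=False, min_snps=10)
    assert np.all(noex.stats == noex.stats[0])  # same best every round
    assert excl.stats[-1] <= noex.stats[-1]
    assert len(np.unique(excl.stats)) >= len(np.unique(noex.stats))


def test_multi_null_rejects_oversized_T(control_data):
    panel, _, table = control_data
    with pytest.raises(ValueError, match="T exceeds"):
        multi_patient_null(panel, table, N=2, T=panel.n_individuals + 1,
                           rounds=2)


def test_null_tsv_round_trip(tmp_path, control_data):
    panel, _, table = control_data
    null = single_patient_null(panel, table)
    null.to_tsv(tmp_path / "null.tsv")
    back = NullDistribution.from_tsv(tmp_path / "null.tsv")
    np.testing.assert_allclose(back.stats, null.stats, rtol=1e-9)
    assert back.mode == "single"


def test_sibpair_null_runs_and_is_seed_stable(control_data):
    panel, _, table = control_data
    a = sibpair_null(panel, table, n_families=5, rounds=6, seed=2, min_snps=10)
    b = sibpair_null(panel, table, n_families=5, rounds=6, seed=2, min_snps=10)
    np.testing.assert_array_equal(a.stats, b.stats)
    assert a.M == 6
    assert np.all(a.stats >= 0)


def test_null_calibration_mini(mosaic_model):
    """Cases drawn from the control population should get conservative
    empirical P-values (small smoke version of the full calibration check)."""
    rng = np.random.Generator(np.random.Philox(77))
    controls, _ = generate_panel(mosaic_model, 60, rng)
    cases, _ = generate_panel(mosaic_model, 40, rng, iid_prefix="case")
    table = estimate_pair_table(controls)
    null = single_patient_null(controls, table)
    stats = best_stats_per_individual(cases, table)
    ps = np.array([empirical_p(s, null) for s in stats])
    # anti-conservative behaviour would concentrate P near 0
    assert np.mean(ps <= 0.1) <= 0.25
    assert ps.min() >= 1 / (null.M + 1)
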