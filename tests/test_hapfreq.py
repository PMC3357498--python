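import math

import numpy as np
import pytest

from rohmap.hapfreq import (EMError, PairwiseHFTable, em_pairwise_hf,
                            estimate_pair_table, rare_haplotype_k, region_hf)
from rohmap.roh import HomozygousRegion, call_roh
from rohmap.synth import PopulationModel, generate_panel, true_table

from conftest import make_panel
from oracles import chain_hf, grid_mle_pair, two_locus_loglik


def region_from(panel, i_first, codes):
    pos = panel.markers.pos_bp
    return HomozygousRegion(
        iid="x", chrom=str(panel.markers.chrom[i_first]), i_first=i_first,
        i_last=i_first + len(codes) - 1, start_bp=int(pos[i_first]),
        end_bp=int(pos[i_first + len(codes) - 1]),
        alleles=np.asarray(codes, dtype=np.int8),
        n_het=int(np.sum(np.asarray(codes) == 1)),
        n_missing=int(np.sum(np.asarray(codes) == -1)),
    )


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def test_em_unambiguous_panel_all_hom_AB():
    geno = np.zeros((8, 2), dtype=np.int8)  # everyone AB/AB
    panel = make_panel(geno)
    p, v, conv = em_pairwise_hf(panel, (0, 1))
    assert v == 8 and conv
    np.testing.assert_allclose(p, [1.0, 0.0, 0.0, 0.0], atol=1e-12)


def test_em_equals_direct_counting_without_double_hets(rng):
    # build genotypes from known phased haplotypes, discarding double hets
    haps = rng.integers(0, 2, size=(400, 2))
    g = haps[0::2] + haps[1::2]
    keep = ~((g[:, 0] == 1) & (g[:, 1] == 1))
    panel = make_panel(g[keep].astype(np.int8))
    kept_haps = haps.reshape(-1, 2, 2)[keep].reshape(-1, 2)
    counts = np.zeros(4)
    for (x, y) in kept_haps:
        counts[2 * x + y] += 1
    p, v, _ = em_pairwise_hf(panel, (0, 1))
    np.testing.assert_allclose(p, counts / counts.sum(), atol=1e-9)
    assert v == keep.sum()


@pytest.mark.parametrize("seed", range(10))
def test_em_matches_grid_search_oracle(seed):
    rng = np.random.default_rng(seed)
    hap_freq = rng.dirichlet([1.5, 1.5, 1.5, 1.5])
    haps = rng.choice(4, size=(2 * 25), p=hap_freq)
    g = np.stack([haps // 2, haps % 2], axis=1)
    geno = (g[0::2] + g[1::2]).astype(np.int8)
    if not ((geno[:, 0] == 1) & (geno[:, 1] == 1)).any():
        pytest.skip("no phase ambiguity drawn for this seed")
    panel = make_panel(geno)
    p_em, v, conv = em_pairwise_hf(panel, (0, 1), tol=1e-12, max_iter=5000)
    assert conv
    from rohmap.hapfreq import _pair_counts
    counts = _pair_counts(panel.genotypes[:, 0], panel.genotypes[:, 1])
    p_grid = grid_mle_pair(counts)
    assert two_locus_loglik(counts, p_em) >= two_locus_loglik(counts, p_grid) - 1e-9
    np.testing.assert_allclose(p_em, p_grid, atol=1e-6)


def test_em_zero_informative_controls_is_error():
    geno = np.full((3, 2), -1, dtype=np.int8)
    panel = make_panel(geno)
    with pytest.raises(EMError):
        em_pairwise_hf(panel, (0, 1))


def test_vectorized_table_agrees_with_single_pair_em(control_data):
    panel, _, table = control_data
    for j in (0, 7, 150, 298):
        if not table.valid[j]:
            continue
        p, v, _ = em_pairwise_hf(panel, (j, j + 1))
        np.testing.assert_allclose(table.freqs[j], p, atol=1e-7)
        assert table.v[j] == v
    # invariants: unit sums and marginal consistency
    s = table.freqs[table.valid].sum(axis=1)
    np.testing.assert_allclose(s, 1.0, atol=1e-9)
    left_marg = table.freqs[:, 0] + table.freqs[:, 1]
    np.testing.assert_allclose(left_marg[table.valid],
                               table.allele1_freq[:-1][table.valid], atol=1e-6)


def test_table_tsv_round_trip(tmp_path, control_data):
    _, _, table = control_data
    table.to_tsv(tmp_path / "pairs.tsv")
    back = PairwiseHFTable.from_tsv(tmp_path / "pairs.tsv", table.markers)
    np.testing.assert_allclose(back.freqs, table.freqs, atol=1e-12)
    np.testing.assert_array_equal(back.v, table.v)


# ---------------------------------------------------------------------------
# rare-haplotype K
# ---------------------------------------------------------------------------

def test_k_closed_form_values():
    assert rare_haplotype_k(1) == pytest.approx(1 - 0.95 ** 0.5, abs=1e-12)
    assert rare_haplotype_k(1) == pytest.approx(0.02532, abs=5e-6)
    # control count used for the real-case panels in the source study
    assert rare_haplotype_k(112) == pytest.approx(1 - 0.95 ** (1 / 224), rel=1e-12)
    assert rare_haplotype_k(112) == pytest.approx(2.290e-4, abs=5e-7)
    # configurable haploid reading: v haplotypes instead of 2v
    assert rare_haplotype_k(50, haploid_factor=1) == pytest.approx(
        1 - 0.95 ** (1 / 50), rel=1e-12)


def test_k_monotone_decreasing_with_limit():
    vs = [1, 2, 5, 10, 100, 1000, 10000]
    ks = [rare_haplotype_k(v) for v in vs]
    assert all(a > b for a, b in zip(ks, ks[1:]))
    assert ks[-1] * 2 * vs[-1] == pytest.approx(-math.log(0.95), rel=1e-3)


def test_k_rejects_nonpositive_sample_size():
    with pytest.raises(ValueError):
        rare_haplotype_k(0)


# ---------------------------------------------------------------------------
# region HF chain
# ---------------------------------------------------------------------------

def test_two_marker_region_reduces_to_pairwise_frequency(control_data):
    panel, _, table = control_data
    r = region_from(panel, 4, [0, 0])
    score = region_hf(r, table)
    assert score.hf == pytest.approx(table.freqs[4, 0], rel=1e-12)
    r2 = region_from(panel, 4, [2, 2])
    assert region_hf(r2, table).hf == pytest.approx(table.freqs[4, 3], rel=1e-12)


def test_linkage_equilibrium_gives_allele_frequency_product():
    model = PopulationModel(n_chrom=1, markers_per_chrom=12, ld_r=0.0, seed=5)
    table = true_table(model)
    panel, _ = generate_panel(model, 5, 1)
    alleles = [0, 2, 0, 0, 2, 0, 2, 0]
    r = region_from(panel, 2, alleles)
    score = region_hf(r, table)
    marg = [model.q[2 + t] if a == 2 else 1 - model.q[2 + t]
            for t, a in enumerate(alleles)]
    assert score.hf == pytest.approx(float(np.prod(marg)), rel=1e-9)


def test_region_hf_matches_naive_chain_and_truth(control_data):
    panel, _, table = control_data
    # exact agreement with a brute-force chain evaluation on the EM table
    r = region_from(panel, 10, [0, 2, 2, 0, 0, 2, 0, 0, 2, 0])
    x = [a // 2 for a in r.alleles]
    expected = chain_hf(x, [table.freqs[10 + t] for t in range(9)])
    assert region_hf(r, table).hf == pytest.approx(expected, rel=1e-12)


def test_region_hf_close_to_generator_truth():
    model = PopulationModel(n_chrom=1, markers_per_chrom=60, seed=9)
    panel, haps = generate_panel(model, 2000, 33)
    table = estimate_pair_table(panel)
    hap = haps[0]
    i0 = 20
    codes = (2 * hap[i0:i0 + 10]).astype(np.int8)
    r = region_from(panel, i0, codes)
    est = region_hf(r, table).hf
    truth = model.true_region_hf(i0, hap[i0:i0 + 10])
    assert est == pytest.approx(truth, rel=0.05)


def test_chain_splits_additively_at_interior_markers(control_data):
    panel, _, table = control_data
    codes = [0, 2, 0, 0, 2, 2, 0, 2, 0, 0, 2, 0]
    r = region_from(panel, 30, codes)
    full = region_hf(r, table).log_hf
    for k in (2, 5, 8):
        left = region_hf(region_from(panel, 30, codes[:k + 1]), table).log_hf
        right = region_hf(region_from(panel, 30 + k, codes[k:]), table).log_hf
        x = codes[k] // 2
        marg = table.freqs[30 + k, 2 * x] + table.freqs[30 + k, 2 * x + 1]
        assert full == pytest.approx(left + right - math.log(marg), abs=1e-10)


def test_extension_never_increases_hf(control_data):
    panel, _, table = control_data
    rng = np.random.default_rng(0)
    codes = list(2 * rng.integers(0, 2, size=20))
    prev = 0.0
    for ln in range(2, 21):
        lh = region_hf(region_from(panel, 50, codes[:ln]), table).log_hf
        if ln > 2:
            assert lh <= prev + 1e-12
        prev = lh


def test_hbc_s_is_hf_squared_exactly(control_data):
    panel, _, table = control_data
    s = region_hf(region_from(panel, 70, [0, 0, 2, 0, 2]), table)
    assert s.hbc_s == s.hf ** 2  # bitwise identical arithmetic


def test_k_substitution_for_unseen_haplotype():
    # controls carry only A-B haplotypes at the pair: a-b transition unseen
    geno = np.zeros((10, 3), dtype=np.int8)
    panel = make_panel(geno)
    table = estimate_pair_table(panel)
    k = rare_haplotype_k(10)
    r = region_from(panel, 0, [2, 2])  # hom for the unseen allele pair
    score = region_hf(r, table)
    # 2-marker chain: HF equals the substituted pairwise frequency K
    assert score.hf == pytest.approx(k, rel=1e-9)


def test_region_spanning_missing_marker_composes_transitions(control_data):
    panel, _, table = control_data
    codes = [0, 0, -1, 0, 0]
    r = region_from(panel, 90, codes)
    score = region_hf(r, table)
    # manual composition across the missing marker
    f = table.freqs
    m0 = f[90, 0] + f[90, 1]
    step1 = f[90, 0] / m0
    T1 = f[91].reshape(2, 2)
    T1 = T1 / T1.sum(axis=1, keepdims=True)
    T2 = f[92].reshape(2, 2)
    T2 = T2 / T2.sum(axis=1, keepdims=True)
    comp = (T1 @ T2)[0, 0]
    m3 = f[93, 0] + f[93, 1]
    step3 = f[93, 0] / m3
    assert score.hf == pytest.approx(m0 * step1 * comp * step3, rel=1e-10)


def test_roh_to_score_pipeline_on_synthetic_individual(control_data):
    panel, haps, table = control_data
    geno = panel.genotypes[3].copy()
    geno[100:180] = 2 * haps[6, 100:180]  # plant an 80-marker homozygous run
    case = make_panel(geno[None, :], chrom=panel.markers.chrom,
                      pos=panel.markers.pos_bp)
    regs = call_roh(case, "i1", min_snps=25)
    assert any(r.i_first <= 100 and r.i_last >= 179 for r in regs)
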