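import numpy as np
import pytest

from rohmap.roh import call_roh_panel
from rohmap.sharing import (find_shared_regions, hbc_m, log10_hbc_m,
                            score_shared_region, sibpair_adjust)

from conftest import make_panel
from oracles import enum_share_prob


# ---------------------------------------------------------------------------
# HBC_m
# ---------------------------------------------------------------------------

def test_hbc_m_single_patient_reduction():
    assert hbc_m(0.013, 1, 1) == pytest.approx(0.013, rel=1e-12)


def test_hbc_m_zero_carriers_is_certain():
    assert hbc_m(0.3, 0, 5) == 1.0


def test_hbc_m_two_of_three_enumeration_value():
    # brute-force enumeration over the 8 carrier patterns gives 0.028
    assert hbc_m(0.1, 2, 3) == pytest.approx(0.028, abs=1e-12)


@pytest.mark.parametrize("T", [1, 2, 3, 5, 8])
@pytest.mark.parametrize("p", [0.01, 0.1, 0.5])
def test_hbc_m_matches_enumeration_small(T, p):
    for N in range(1, T + 1):
        assert hbc_m(p, N, T) == pytest.approx(enum_share_prob(p, N, T),
                                               abs=1e-12)


def test_hbc_m_monotonicities():
    assert hbc_m(0.2, 2, 6) > hbc_m(0.1, 2, 6)   # increasing in p
    assert hbc_m(0.1, 2, 8) > hbc_m(0.1, 2, 6)   # increasing in T
    assert hbc_m(0.1, 3, 6) < hbc_m(0.1, 2, 6)   # decreasing in N
    with pytest.raises(ValueError):
        hbc_m(0.0, 1, 2)
    with pytest.raises(ValueError):
        hbc_m(0.5, 4, 3)


def test_log10_hbc_m_continuous_across_underflow_guard():
    # tiny-p branch must agree with the direct binomial tail where both work
    for log_hf in (-10.0, -13.0, -13.8):
        direct = np.log10(hbc_m(np.exp(2 * log_hf), 3, 40))
        assert log10_hbc_m(log_hf, 3, 40) == pytest.approx(direct, abs=1e-6)


# ---------------------------------------------------------------------------
# shared-region detection
# ---------------------------------------------------------------------------

def _regions(geno, **kw):
    panel = make_panel(np.asarray(geno, dtype=np.int8), **kw)
    per = call_roh_panel(panel, min_snps=2, max_het=0, max_missing=0)
    return [r for regs in per.values() for r in regs], panel


def test_identical_homozygous_pair_share_whole_chromosome():
    geno = [[0, 0, 2, 0, 2, 2], [0, 0, 2, 0, 2, 2]]
    regs, _ = _regions(geno)
    shared = find_shared_regions(regs, min_carriers=2)
    assert len(shared) == 1
    sr = shared[0]
    assert sr.n_carriers == 2 and (sr.i_first, sr.i_last) == (0, 5)
    np.testing.assert_array_equal(sr.alleles, [0, 0, 2, 0, 2, 2])


def test_interior_allele_discordance_splits_interval():
    geno = [[0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 2, 0, 0, 0]]  # differ at interior marker 3
    regs, _ = _regions(geno)
    shared = find_shared_regions(regs, min_carriers=2, min_snps=2)
    spans = sorted((s.i_first, s.i_last) for s in shared)
    assert spans == [(0, 2), (4, 6)]
    assert all(s.n_carriers == 2 for s in shared)


def test_wildcard_missing_marker_does_not_split():
    geno = [[0, 0, -1, 0, 0], [0, 0, 0, 0, 0]]
    # individual 1's ROH spans the missing call (max_missing allows it)
    panel = make_panel(np.asarray(geno, dtype=np.int8))
    per = call_roh_panel(panel, min_snps=2, max_het=0, max_missing=1)
    regs = [r for rs in per.values() for r in rs]
    shared = find_shared_regions(regs, min_carriers=2)
    assert any((s.i_first, s.i_last) == (0, 4) and s.n_carriers == 2
               for s in shared)


def test_planted_carriers_among_many_recovered():
    rng = np.random.default_rng(8)
    n, m = 50, 260
    geno = np.ones((n, m), dtype=np.int8)  # heterozygous background
    geno[:, ::3] = rng.choice([0, 2], size=(n, (m + 2) // 3))
    carriers = [4, 11, 23, 37]
    tract = rng.choice([0, 2], size=60).astype(np.int8)
    for c in carriers:
        geno[c, 100:160] = tract
        geno[c, 99] = geno[c, 160] = 1
    regs, _ = _regions(geno)
    shared = [s for s in find_shared_regions(regs, min_carriers=4, min_snps=25)]
    assert len(shared) == 1
    sr = shared[0]
    assert sr.carriers == tuple(sorted(f"i{c + 1}" for c in carriers))
    assert (sr.i_first, sr.i_last) == (100, 159)


def test_min_carriers_one_returns_individual_roh_set():
    # disjoint homozygous runs, one per individual
    geno = np.ones((3, 30), dtype=np.int8)
    geno[0, 0:8] = 0
    geno[1, 10:19] = 2
    geno[2, 22:30] = 0
    regs, _ = _regions(geno)
    shared = find_shared_regions(regs, min_carriers=1, min_snps=2)
    got = sorted((s.i_first, s.i_last, s.carriers) for s in shared)
    assert got == [(0, 7, ("i1",)), (10, 18, ("i2",)), (22, 29, ("i3",))]


def test_shared_region_scoring_uses_consensus_interval(control_data):
    panel, haps, table = control_data
    hap = haps[10]
    geno = np.ones((2, panel.markers.n_markers), dtype=np.int8)
    geno[:, 40:100] = (2 * hap[40:100])[None, :]
    regs, _ = _regions(geno, chrom=panel.markers.chrom,
                       pos=panel.markers.pos_bp)
    shared = find_shared_regions(regs, min_carriers=2, min_snps=25)
    assert len(shared) == 1
    score = score_shared_region(shared[0], table, T=10)
    assert score.n_carriers == 2
    assert 0 < score.hbc_m < 1


# ---------------------------------------------------------------------------
# sib pairs
# ---------------------------------------------------------------------------

def test_sibpair_statistic_and_ibd_factor():
    stats, factor = sibpair_adjust({"fam1": (1e-6, 1e-4)}, n_sharing=1)
    assert stats["fam1"] == 1e-6
    assert factor == 0.25


def test_sibpair_factor_counts_sharing_families():
    _, f0 = sibpair_adjust({}, n_sharing=0)
    assert f0 == 1.0
    _, f3 = sibpair_adjust({"a": (0.1, 0.2), "b": (0.3, 0.4), "c": (0.5, 0.6)},
                           n_sharing=3)
    assert f3 == pytest.approx(1 / 64)


def test_sibpair_requires_exactly_two_sibs():
    with pytest.raises(ValueError, match="exactly 2"):
        sibpair_adjust({"fam1": (1e-6, 1e-4, 1e-3)}, n_sharing=1)
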