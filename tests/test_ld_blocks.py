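"""Two-locus and multi-locus haplotype EM, D' confidence intervals,
confidence-interval blocks and per-group comparison."""
import numpy as np
import pytest

from admixcohort import (SimulationConfig, block_haplotypes, compare_groups,
                         dprime_ci, gabriel_blocks, simulate_cohort,
                         two_locus_em)
from admixcohort.io_formats import GenotypeMatrix, variant_table
from admixcohort.ld_blocks import pair_counts, _table_loglik


def _dosages_from_haps(hf, n, rng):
    haps = rng.choice(4, size=(n, 2), p=hf)
    a2d = {0: (1, 1), 1: (1, 0), 2: (0, 1), 3: (0, 0)}
    d1 = np.array([a2d[a][0] + a2d[b][0] for a, b in haps], dtype=np.int8)
    d2 = np.array([a2d[a][1] + a2d[b][1] for a, b in haps], dtype=np.int8)
    return d1, d2


def test_two_locus_em_no_double_het_is_direct_count():
    t = np.zeros((3, 3))
    t[2, 2], t[0, 0], t[2, 0] = 10, 5, 5
    h = two_locus_em(t)
    # direct haplotype counting: 20 AB + 10 Ab + 10 ab over 40
    assert np.allclose(h, [0.5, 0.25, 0.0, 0.25])


def test_two_locus_em_recovery():
    rng = np.random.default_rng(61)
    hf = np.array([0.4, 0.1, 0.1, 0.4])
    d1, d2 = _dosages_from_haps(hf, 1000, rng)
    h = two_locus_em(pair_counts(d1, d2))
    assert np.abs(h - hf).max() < 0.02


def test_two_locus_em_equilibrium_fixed_point():
    # cell counts proportional to products of HWE margins: D stays 0
    pa, pb = 0.6, 0.3
    ga = np.array([(1 - pa) ** 2, 2 * pa * (1 - pa), pa ** 2])
    gb = np.array([(1 - pb) ** 2, 2 * pb * (1 - pb), pb ** 2])
    t = 1000 * np.outer(ga, gb)
    h = two_locus_em(t)
    d = h[0] - (h[0] + h[1]) * (h[0] + h[2])
    assert abs(d) < 1e-6


def test_two_locus_em_loglik_monotone_and_relabel_invariant():
    rng = np.random.default_rng(62)
    hf = np.array([0.5, 0.2, 0.2, 0.1])
    d1, d2 = _dosages_from_haps(hf, 400, rng)
    t = pair_counts(d1, d2)
    h, trace = two_locus_em(t, return_trace=True)
    assert (np.diff(trace) >= -1e-9).all()
    # relabeling locus-1 alleles permutes the 4-vector accordingly
    h_flip = two_locus_em(pair_counts(2 - d1, d2))
    assert np.allclose(h_flip, h[[2, 3, 0, 1]], atol=1e-9)


def test_dprime_complete_ld_boundary():
    rng = np.random.default_rng(63)
    d1, d2 = _dosages_from_haps(np.array([0.6, 0.0, 0.0, 0.4]), 200, rng)
    ld = dprime_ci(d1, d2)
    assert ld.dprime == pytest.approx(1.0)
    assert ld.ci_low > 0.9
    assert ld.ci_low <= ld.dprime <= ld.ci_high


def test_dprime_ci_width_shrinks_with_n():
    rng = np.random.default_rng(64)
    hf = np.array([0.25, 0.25, 0.25, 0.25])        # equilibrium
    d1, d2 = _dosages_from_haps(hf, 50, rng)
    small = dprime_ci(d1, d2)
    assert small.ci_low < 0.3                      # CI spans most of [0,1]
    d1, d2 = _dosages_from_haps(hf, 5000, rng)
    big = dprime_ci(d1, d2)
    assert big.ci_high < 0.2                       # concentrates near 0


def test_dprime_counted_allele_swap_invariance():
    rng = np.random.default_rng(65)
    hf = np.array([0.45, 0.15, 0.1, 0.3])
    d1, d2 = _dosages_from_haps(hf, 600, rng)
    base = dprime_ci(d1, d2)
    for x, y in ((2 - d1, d2), (d1, 2 - d2), (2 - d1, 2 - d2)):
        other = dprime_ci(x.astype(np.int8), y.astype(np.int8))
        assert other.dprime == pytest.approx(base.dprime, abs=1e-9)
        assert other.ci_low == pytest.approx(base.ci_low, abs=1e-3)


def test_dprime_monomorphic_raises():
    d1 = np.ones(50, dtype=np.int8) * 2
    d2 = np.array([0, 1, 2] * 16 + [1, 1], dtype=np.int8)
    with pytest.raises(ValueError, match="monomorphic"):
        dprime_ci(d1, d2)


def _pool_cohort(seed, m=60, block=10, n=400, pool=8):
    cfg = SimulationConfig(n_samples=n, m_variants=m, n_chromosomes=1,
                           k_true=1, fst=(0.1,), alpha=(1.0,),
                           ld_block_size=block, n_haplotypes_per_pool=pool,
                           seed=seed)
    return simulate_cohort(cfg)


def test_gabriel_blocks_none_under_linkage_equilibrium():
    cfg = SimulationConfig(n_samples=400, m_variants=40, n_chromosomes=1,
                           k_true=1, fst=(0.1,), alpha=(1.0,), seed=66)
    g, v, s, _ = simulate_cohort(cfg)
    blocks = gabriel_blocks(g, v, np.arange(40), with_haplotypes=False)
    assert blocks == []


def test_gabriel_blocks_perfect_pair_flanked_by_noise():
    rng = np.random.default_rng(67)
    noise = rng.integers(0, 3, size=(300, 4)).astype(np.int8)
    pair = rng.binomial(2, 0.5, size=300).astype(np.int8)
    d = np.column_stack([noise[:, :2], pair, pair, noise[:, 2:]])
    g = GenotypeMatrix(d, [f"s{i}" for i in range(300)])
    v = variant_table([f"rs{i}" for i in range(6)], ["1"] * 6,
                      np.arange(1, 7) * 1000, ["A"] * 6, ["G"] * 6)
    blocks = gabriel_blocks(g, v, np.arange(6), with_haplotypes=False)
    assert len(blocks) == 1
    assert (blocks[0].first, blocks[0].last) == (2, 3)
    assert blocks[0].n_snps == 2


def test_gabriel_blocks_within_vs_between_dprime(small_cohort=None):
    g, v, s, _ = _pool_cohort(68)
    within, between = [], []
    for a in range(0, 20):
        for b in range(a + 1, 20):
            try:
                ld = dprime_ci(g.dosages[:, a], g.dosages[:, b])
            except ValueError:
                continue
            (within if (a // 10) == (b // 10) else between).append(ld.dprime)
    assert np.mean(within) > np.mean(between) + 0.3


def test_gabriel_blocks_do_not_overlap_and_are_deterministic():
    g, v, s, _ = _pool_cohort(69)
    blocks = gabriel_blocks(g, v, np.arange(60), with_haplotypes=False)
    blocks2 = gabriel_blocks(g, v, np.arange(60), with_haplotypes=False)
    assert [(b.first, b.last) for b in blocks] == \
        [(b.first, b.last) for b in blocks2]
    spans = sorted((b.first, b.last) for b in blocks)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 < a2


def test_block_haplotypes_matches_two_locus_on_pairs():
    g, v, s, _ = _pool_cohort(70)
    tab = block_haplotypes(g, np.array([0, 1]))
    h4 = two_locus_em(pair_counts(g.dosages[:, 0], g.dosages[:, 1]))
    lookup = {"11": h4[0], "10": h4[1], "01": h4[2], "00": h4[3]}
    for _, row in tab.iterrows():
        assert row["frequency"] == pytest.approx(lookup[row["haplotype"]],
                                                 abs=1e-6)


def test_block_haplotypes_recovers_pool_frequencies():
    """EM haplotype frequencies converge to the pool frequencies on
    pool-simulated data (consistency at n = 2000)."""
    cfg = SimulationConfig(n_samples=2000, m_variants=6, n_chromosomes=1,
                           k_true=1, fst=(0.1,), alpha=(1.0,),
                           ld_block_size=6, n_haplotypes_per_pool=4,
                           seed=71)
    g, v, s, t = simulate_cohort(cfg)
    counts = np.round(t.freqs_true[0] * 4).astype(int)
    pool_haps = {}
    for rank in range(4):
        key = "".join("1" if rank < c else "0" for c in counts)
        pool_haps[key] = pool_haps.get(key, 0) + 0.25
    tab, trace = block_haplotypes(g, np.arange(6), return_trace=True)
    assert (np.diff(trace) >= -1e-9).all()
    # 0.02 covers the binomial noise of the pool-rank draws (~0.014 at
    # 2 sigma for n = 2,000 diploids) on top of EM error
    for hap, freq in pool_haps.items():
        est = tab.loc[tab["haplotype"] == hap, "frequency"]
        assert len(est) == 1 and abs(float(est.iloc[0]) - freq) < 0.02


def test_block_haplotypes_monomorphic_block():
    d = np.zeros((40, 3), dtype=np.int8)
    g = GenotypeMatrix(d, [f"s{i}" for i in range(40)])
    tab = block_haplotypes(g, np.arange(3))
    assert len(tab) == 1
    assert tab["frequency"].iloc[0] == pytest.approx(1.0)
    assert tab["haplotype"].iloc[0] == "000"


def test_block_haplotypes_size_cap():
    g = GenotypeMatrix(np.zeros((5, 13), dtype=np.int8), list("abcde"))
    with pytest.raises(ValueError, match="12"):
        block_haplotypes(g, np.arange(13))


def test_compare_groups_identical_groups_identical_blocks():
    g, v, s, _ = _pool_cohort(72)
    s2 = s.copy()
    s2["group"] = ["g1"] * 200 + ["g2"] * 200
    d = g.dosages.copy()
    d[200:] = d[:200]                      # duplicate the first half
    g2 = GenotypeMatrix(d, g.sample_ids)
    blocks, summary = compare_groups(g2, v, s2, np.arange(60))
    assert summary["n_blocks"].nunique() == 1
    assert [(b.first, b.last) for b in blocks["g1"]] == \
        [(b.first, b.last) for b in blocks["g2"]]


def test_compare_groups_pool_scale_changes_block_count():
    """Groups drawn from pools with different block sizes differ in
    block count in the expected direction (majority of 5 seeds)."""
    hits = 0
    for seed in range(5):
        ga, v, _, _ = _pool_cohort(80 + seed, block=5, n=200)
        gb, _, _, _ = _pool_cohort(90 + seed, block=15, n=200)
        d = np.vstack([ga.dosages, gb.dosages])
        g = GenotypeMatrix(d, [f"a{i}" for i in range(200)]
                           + [f"b{i}" for i in range(200)])
        from admixcohort.io_formats import sample_table
        s = sample_table(g.sample_ids, group=["small"] * 200 + ["large"] * 200)
        _, summary = compare_groups(g, v, s, np.arange(60))
        row = summary.set_index("group")
        if row.loc["small", "n_blocks"] > row.loc["large", "n_blocks"]:
            hits += 1
    assert hits >= 3


def test_compare_groups_focal_variant_in_block():
    g, v, s, _ = _pool_cohort(73)
    focal = v["rsid"].iloc[5]              # interior of the first block
    _, summary = compare_groups(g, v, s, np.arange(60), focal_rsid=focal)
    assert bool(summary["focal_in_block"].iloc[0])
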