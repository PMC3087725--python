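"""QC cascade, Hardy-Weinberg exact test, relatedness, batch and sex
checks."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from admixcohort import (MISSING, QCThresholds, SimulationConfig,
                         hwe_exact_test, ibd_estimate,
                         inbreeding_coefficient, ledger_from_counts,
                         sex_check, simulate_cohort)
from admixcohort.io_formats import GenotypeMatrix, sample_table
from admixcohort.qc import (EmptySurvivorSet, apply_cascade,
                            batch_concordance, batch_effect_scan, call_rates,
                            differential_missingness, hwe_pvalues)


def test_call_rates_basic():
    d = np.array([[0, 1, 2, MISSING], [MISSING] * 4, [1, 1, 1, 1]],
                 dtype=np.int8)
    g = GenotypeMatrix(d, ["a", "b", "c"])
    per_sample, per_snp = call_rates(g)
    assert np.allclose(per_sample, [0.25, 1.0, 0.0])
    assert np.allclose(per_snp, [1 / 3] * 3 + [2 / 3])


def test_hwe_examples():
    # modal configuration: p-value 1 region
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)
    # complete heterozygote deficit: vanishing p
    assert hwe_exact_test(50, 0, 50) < 1e-10
    # monomorphic: 1 by convention
    assert hwe_exact_test(10, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
def test_hwe_symmetry_and_range(naa, nab, nbb):
    if naa + nab + nbb == 0:
        return
    p = hwe_exact_test(naa, nab, nbb)
    assert 0.0 < p <= 1.0
    assert p == pytest.approx(hwe_exact_test(nbb, nab, naa), rel=1e-12)


def test_ledger_replay_chains_and_conserves():
    led = ledger_from_counts("SNP", 1000, [("a", 100), ("b", 50), ("c", 0)])
    led.validate()
    assert led.final("SNP") == 850
    with pytest.raises(ValueError, match="chain"):
        bad = ledger_from_counts("SNP", 1000, [("a", 100)])
        bad.add("b", "SNP", 950, 10)


def test_cascade_identity_when_nothing_fails():
    cfg = SimulationConfig(n_samples=50, m_variants=300, k_true=1,
                           fst=(0.05,), alpha=(1.0,), seed=21)
    g, v, s, _ = simulate_cohort(cfg)
    thr = QCThresholds(sample_missing_max=1.0, snp_missing_max=1.0,
                       maf_min=0.0, hwe_p_min=0.0, inbreeding_sd_limit=1e6)
    g2, v2, s2, led = apply_cascade(g, v, s, thr)
    assert all(st_.n_excluded == 0 for st_ in led.steps)
    assert np.array_equal(g2.dosages, g.dosages)


def test_cascade_catches_forced_missing_snps(small_cohort):
    cfg, (g, v, s, _) = small_cohort
    d = g.dosages.copy()
    target = np.arange(10)
    d[:, target] = MISSING
    g2 = GenotypeMatrix(d, g.sample_ids)
    _, _, _, led = apply_cascade(g2, v, s, QCThresholds(),
                                 diff_missing_flag="diabetes")
    step = next(st_ for st_ in led.steps if st_.name == "snp_call_rate")
    assert step.n_excluded >= 10
    led.validate()


def test_cascade_invariant_under_sample_permutation(small_cohort):
    cfg, (g, v, s, _) = small_cohort
    rng = np.random.default_rng(0)
    perm = rng.permutation(g.n_samples)
    gp = GenotypeMatrix(g.dosages[perm].copy(),
                        [g.sample_ids[i] for i in perm])
    sp = s.iloc[perm].reset_index(drop=True)
    _, _, _, led1 = apply_cascade(g, v, s, diff_missing_flag="diabetes")
    _, _, _, led2 = apply_cascade(gp, v, sp, diff_missing_flag="diabetes")
    assert [(x.name, x.n_excluded) for x in led1.steps] == \
        [(x.name, x.n_excluded) for x in led2.steps]


def test_cascade_empty_survivors_is_explicit():
    g = GenotypeMatrix(np.full((5, 30), MISSING, dtype=np.int8),
                       [f"s{i}" for i in range(5)])
    from admixcohort.io_formats import variant_table
    v = variant_table([f"rs{i}" for i in range(30)], ["1"] * 30,
                      np.arange(1, 31), ["A"] * 30, ["G"] * 30)
    s = sample_table(g.sample_ids)
    with pytest.raises(EmptySurvivorSet):
        apply_cascade(g, v, s)


def test_hwe_type_one_rate_on_clean_cohort():
    """On a clean one-population cohort the HWE step flags about the
    nominal 0.1% of SNPs (exact test is conservative)."""
    cfg = SimulationConfig(n_samples=500, m_variants=10000, k_true=1,
                           fst=(0.05,), alpha=(1.0,), seed=22)
    g, _, _, _ = simulate_cohort(cfg)
    p = hwe_pvalues(g)
    frac = float((p < 0.001).mean())
    assert 0.0 < frac < 0.003


def test_differential_missingness_examples():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(100, 30)).astype(np.int8)
    flag = np.arange(100) < 50
    # identical missingness in both classes -> p = 1
    d[0, 0] = MISSING
    d[50, 0] = MISSING
    g = GenotypeMatrix(d, [f"s{i}" for i in range(100)])
    p = differential_missingness(g, flag)
    assert p[0] == pytest.approx(1.0)
    assert np.allclose(p[1:], 1.0)          # no missingness -> p = 1
    # (10 missing / 40 called) vs (0 / 50): hypergeometric tail
    d2 = rng.integers(0, 3, size=(100, 1)).astype(np.int8)
    d2[:10, 0] = MISSING
    g2 = GenotypeMatrix(d2, g.sample_ids)
    from scipy import stats
    expect = stats.fisher_exact([[10, 0], [40, 50]])[1]
    assert differential_missingness(g2, flag)[0] == pytest.approx(expect)


def test_batch_concordance_duplicates(small_cohort):
    _, (g, v, s, t) = small_cohort
    conc = batch_concordance(g, s)
    assert len(conc) == len(t.excluded_truth["duplicates"])
    assert (conc["concordance"] == 1.0).all()


def test_batch_concordance_counts_injected_flips():
    rng = np.random.default_rng(2)
    d = rng.integers(0, 3, size=(2, 1000)).astype(np.int8)
    d[1] = d[0]
    flip = rng.choice(1000, size=10, replace=False)
    d[1, flip] = (d[1, flip] + 1) % 3
    g = GenotypeMatrix(d, ["x", "xrep"])
    s = sample_table(["x", "xrep"], is_replicate=[False, True])
    conc = batch_concordance(g, s)
    assert conc["concordance"].iloc[0] == pytest.approx(0.99)


def test_batch_effect_scan_flags_corrupted_snps():
    cfg = SimulationConfig(n_samples=500, m_variants=2000, k_true=1,
                           fst=(0.05,), alpha=(1.0,),
                           batch_distortion=(2, 50, 0.3), seed=23)
    g, v, s, t = simulate_cohort(cfg)
    p = batch_effect_scan(g, s)
    bad = t.excluded_truth["batch_bad_snps"]
    bonf = 0.05 / g.n_variants
    assert (p[bad] < bonf).mean() >= 0.9
    clean = np.setdiff1d(np.arange(g.n_variants), bad)
    assert (p[clean] < bonf).mean() < 0.01


def test_batch_effect_two_identical_batches_null():
    d = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (8, 1))
    g = GenotypeMatrix(d, [f"s{i}" for i in range(8)])
    s = sample_table(g.sample_ids,
                     batch=["b1"] * 4 + ["b2"] * 4)
    assert np.allclose(batch_effect_scan(g, s), 1.0)


def test_inbreeding_examples():
    cfg = SimulationConfig(n_samples=500, m_variants=10000, k_true=1,
                           fst=(0.05,), alpha=(1.0,), seed=24)
    g, _, _, _ = simulate_cohort(cfg)
    f = inbreeding_coefficient(g)
    assert abs(np.nanmean(f)) < 0.01        # HWE cohort: F centers on 0
    # fully homozygous sample
    d = g.dosages.copy()
    d[0] = np.where(d[0] == 1, 0, d[0])
    f2 = inbreeding_coefficient(GenotypeMatrix(d, g.sample_ids))
    assert f2[0] == pytest.approx(1.0, abs=0.05)


def test_wahlund_pooling_inflates_inbreeding():
    cfg = SimulationConfig(n_samples=400, m_variants=4000, k_true=2,
                           fst=(0.25, 0.25), alpha=(0.05, 0.05), seed=25)
    g, _, _, _ = simulate_cohort(cfg)
    f = inbreeding_coefficient(g)
    assert np.nanmean(f) > 0.05


def test_ibd_duplicates_parent_child_unrelated():
    cfg = SimulationConfig(n_samples=30, m_variants=20000, k_true=1,
                           fst=(0.05,), alpha=(1.0,), n_duplicates=1,
                           n_parent_child_pairs=1, seed=26)
    g, _, _, t = simulate_cohort(cfg)
    ib = ibd_estimate(g)
    key = ib.set_index(["id_a", "id_b"])["pihat"]
    dup = t.excluded_truth["duplicates"][0]
    pc = t.excluded_truth["parent_child"][0]
    assert key[dup] >= 0.95
    assert abs(key[pc] - 0.5) < 0.05
    z1 = ib.set_index(["id_a", "id_b"])["z1"][pc]
    assert z1 > 0.5
    others = ib[~(ib["id_b"].str.endswith("rep")
                  | ib["id_b"].str.endswith("child"))]
    assert (others["pihat"] < 0.1).all()


def test_ibd_flags_sparse_pairs_unreliable():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(3, 250)).astype(np.int8)
    d[2, 60:] = MISSING
    g = GenotypeMatrix(d, ["a", "b", "c"])
    ib = ibd_estimate(g, min_snps=100)
    flag = ib.set_index(["id_a", "id_b"])["unreliable"]
    assert not flag[("a", "b")]
    assert flag[("a", "c")]


def test_sex_check_recovers_true_sex(small_cohort):
    _, (g, v, s, t) = small_cohort
    x_cols = np.flatnonzero((v["chrom"] == "X").to_numpy())
    chk = sex_check(g.subset(variants=x_cols), s)
    flagged = set(chk.loc[chk["mismatch"], "sample_id"])
    assert flagged == set(t.excluded_truth["sex_mismatches"])
    true_sex = dict(zip(g.sample_ids, t.excluded_truth["true_sex"]))
    inferred = dict(zip(chk["sample_id"], chk["inferred"]))
    agree = np.mean([inferred[sid] == true_sex[sid] for sid in g.sample_ids
                     if inferred[sid] != "undetermined"])
    assert agree > 0.97


def test_sex_check_needs_x_variants():
    g = GenotypeMatrix(np.zeros((3, 5), dtype=np.int8), ["a", "b", "c"])
    s = sample_table(["a", "b", "c"])
    with pytest.raises(ValueError, match="20 X variants"):
        sex_check(g, s)
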