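"""The cohort generator: frequency model, admixture, nuisance
injection, phenotype model, determinism."""
import numpy as np
import pytest

from admixcohort import (MISSING, SimulationConfig, simulate_cohort,
                         simulate_frequencies, simulate_phenotype)
from admixcohort.io_formats import allele_frequencies
from admixcohort.structure_inference import admixture_em


def test_identical_seed_gives_bit_identical_output(small_cohort):
    cfg, (g, v, s, t) = small_cohort
    g2, v2, s2, t2 = simulate_cohort(cfg)
    assert np.array_equal(g.dosages, g2.dosages)
    assert s.equals(s2)
    assert v.equals(v2)
    assert np.array_equal(t.q_true, t2.q_true)


def test_balding_nichols_mean_and_fst():
    """Population frequencies center on the ancestral frequency, and
    Hudson FST over many SNPs matches the drift parameter (expected
    value frozen from a 10^6-SNP simulation oracle: F=0.2 gives
    Hudson-FST ~ 0.2 within Monte-Carlo error)."""
    cfg = SimulationConfig(m_variants=20000, k_true=2, fst=(0.2, 0.2),
                           alpha=(1.0, 1.0), seed=3)
    anc, freqs = simulate_frequencies(cfg)
    assert np.abs(freqs.mean() - anc.mean()) < 0.01
    p1, p2 = freqs
    num = (p1 - p2) ** 2 - (p1 * (1 - p1) + p2 * (1 - p2)) / 1e9
    den = p1 * (1 - p1) + p2 * (1 - p2) + num
    hudson = num.sum() / den.sum()
    # frozen oracle value 0.2006 at 10^6 SNPs (clipping shaves a little)
    assert abs(hudson - 0.2006) < 0.02


def test_fst_limit_concentrates_on_ancestral():
    cfg = SimulationConfig(m_variants=5000, k_true=1, fst=(1e-4,),
                           alpha=(1.0,), seed=4)
    anc, freqs = simulate_frequencies(cfg)
    assert np.abs(freqs[0] - anc).std() < 0.01


def test_dirichlet_mean_conservation():
    cfg = SimulationConfig(n_samples=1500, m_variants=10, k_true=3,
                           fst=(0.1, 0.1, 0.1), alpha=(2.0, 1.0, 1.0),
                           seed=5)
    _, _, _, t = simulate_cohort(cfg)
    expect = np.array([2.0, 1.0, 1.0]) / 4.0
    assert np.abs(t.q_true[:1500].mean(axis=0) - expect).max() < 0.03


def test_degenerate_alpha_reduces_to_single_population():
    """alpha = (100, 0.01) collapses every admixture row onto one
    population; the K = 2 likelihood is then flat along Q f = p-hat, so
    the identifiable check is that the K = 2 fit attains (essentially)
    the closed-form single-population likelihood."""
    cfg = SimulationConfig(n_samples=120, m_variants=800, k_true=2,
                           fst=(0.2, 0.2), alpha=(100.0, 0.01), seed=6)
    g, v, s, t = simulate_cohort(cfg)
    assert (t.q_true.max(axis=1) > 0.99).all()
    model = admixture_em(g, k=2, n_restarts=1, seed=0, tol=1e-3,
                         max_iter=60)
    k1 = admixture_em(g, k=1)
    # the K=2 fit exceeds K=1 only by noise overfitting, whose expected
    # size is (extra parameters)/2 log-lik units; allow twice that
    n, m = g.n_samples, g.n_variants
    gap = (model.loglik - k1.loglik) / (n * m)
    assert -1e-4 < gap < (m + n) / (n * m)


def test_duplicate_rows_identical_and_flagged(small_cohort):
    _, (g, v, s, t) = small_cohort
    for orig, rep in t.excluded_truth["duplicates"]:
        i, j = g.sample_ids.index(orig), g.sample_ids.index(rep)
        assert np.array_equal(g.dosages[i], g.dosages[j])
        assert bool(s.loc[s["sample_id"] == rep, "is_replicate"].iloc[0])


def test_parent_child_shares_an_allele_everywhere(small_cohort):
    _, (g, v, s, t) = small_cohort
    auto = (v["chrom"] != "X").to_numpy()
    for parent, child in t.excluded_truth["parent_child"]:
        dp = g.dosages[g.sample_ids.index(parent), auto]
        dc = g.dosages[g.sample_ids.index(child), auto]
        both = (dp != MISSING) & (dc != MISSING)
        # IBS >= 1 at every co-called autosomal SNP (never opposite homs)
        assert (np.abs(dp[both] - dc[both]) < 2).all()


def test_local_mode_zero_switch_rate_gives_whole_chrom_segments():
    cfg = SimulationConfig(n_samples=30, m_variants=300, n_chromosomes=1,
                           k_true=2, fst=(0.2, 0.2), alpha=(1.0, 1.0),
                           ancestry_mode="local", switch_rate_per_mb=0.0,
                           seed=8)
    _, _, _, t = simulate_cohort(cfg)
    # each haplotype fully assigned to one population
    assert (t.local_ancestry == t.local_ancestry[:, :1]).all()


def test_x_chromosome_males_hemizygous():
    # no batch corruption here: that nuisance can overwrite X calls
    cfg = SimulationConfig(n_samples=60, m_variants=100, k_true=1,
                           fst=(0.1,), alpha=(1.0,), x_variants=50,
                           n_parent_child_pairs=2, seed=7)
    g, v, s, t = simulate_cohort(cfg)
    x_cols = np.flatnonzero((v["chrom"] == "X").to_numpy())
    true_sex = np.array(t.excluded_truth["true_sex"])
    males = np.flatnonzero(true_sex == "male")
    dx = g.dosages[np.ix_(males, x_cols)]
    assert not np.isin(dx, [1]).any()       # no heterozygous male calls


def test_phenotype_null_model_constant():
    cfg = SimulationConfig(n_samples=50, m_variants=20, k_true=1, fst=(0.1,),
                           alpha=(1.0,), sigma_env=0.0, seed=9)
    g, v, s, t = simulate_cohort(cfg)
    assert np.allclose(s["bmi"], np.exp(cfg.mu_log_bmi))


def test_phenotype_age_effect_sign():
    cfg = SimulationConfig(n_samples=2000, m_variants=20, k_true=1,
                           fst=(0.1,), alpha=(1.0,), beta_age=-0.5,
                           sigma_env=0.2, seed=10)
    g, v, s, t = simulate_cohort(cfg)
    r = np.corrcoef(np.log(s["bmi"]), s["age"])[0, 1]
    assert r < -0.2


def test_missingness_rates_injected(small_cohort):
    cfg, (g, v, s, t) = small_cohort
    frac = (g.dosages == MISSING).mean()
    assert 0.5 * cfg.missing_rate < frac < 4 * cfg.missing_rate
    # diagnosis-linked extra missingness concentrates on the chosen SNPs
    dm = t.excluded_truth["diff_missing_snps"]
    flag = s["diagnoses"].str.contains("diabetes").to_numpy()
    miss_flag = (g.dosages[flag][:, dm] == MISSING).mean()
    miss_rest = (g.dosages[~flag][:, dm] == MISSING).mean()
    assert miss_flag > miss_rest + 0.05


def test_config_validation_errors():
    with pytest.raises(ValueError, match="fst"):
        SimulationConfig(k_true=2, fst=(0.2,), alpha=(1, 1)).validate()
    with pytest.raises(ValueError, match="alpha"):
        SimulationConfig(k_true=2, fst=(0.2, 0.2), alpha=(1,)).validate()
    with pytest.raises(ValueError, match="causal"):
        SimulationConfig(k_true=1, fst=(0.2,), alpha=(1.0,), m_variants=10,
                         causal_snps=((50, 0.2),)).validate()


def test_allele_frequency_tracks_admixture(clean_two_pop):
    cfg, (g, v, s, t) = clean_two_pop
    expect = (t.q_true @ t.freqs_true).mean(axis=0)
    assert np.abs(allele_frequencies(g) - expect).mean() < 0.05
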