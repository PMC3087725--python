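"""Global/local structure: IBS, MDS, PCA, canonical correlation, EM
admixture."""
import numpy as np
import pandas as pd
import pytest

from admixcohort import (MISSING, SimulationConfig, admixture_em,
                         align_components, cca_rho2, classical_mds,
                         continuum_sort, delta_statistic, ibs_matrix,
                         ld_prune, local_global_scan, loglik_by_k, pca,
                         select_aims, simulate_cohort)
from admixcohort.io_formats import GenotypeMatrix, allele_frequencies
from admixcohort.marker_sets import MarkerSet


def test_ibs_examples():
    d = np.array([[0, 0, 0], [2, 2, 2], [1, 1, 1], [0, 0, 0]],
                 dtype=np.int8)
    g = GenotypeMatrix(d, ["a", "b", "c", "d"])
    ibs = ibs_matrix(g)
    assert ibs[0, 3] == 1.0      # identical samples
    assert ibs[0, 1] == 0.0      # opposite homozygotes everywhere
    assert ibs[0, 2] == 0.5      # one shared allele everywhere
    assert np.allclose(ibs, ibs.T)


def test_ibs_missing_pair_is_nan():
    d = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
    g = GenotypeMatrix(d, ["a", "b"])
    assert np.isnan(ibs_matrix(g)[0, 1])


def test_mds_equilateral_for_equidistant_samples():
    ibs = np.full((3, 3), 0.6)
    np.fill_diagonal(ibs, 1.0)
    res = classical_mds(ibs, n_dims=2)
    dist = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=2)
    off = dist[np.triu_indices(3, 1)]
    assert np.allclose(off, off[0], atol=1e-9)


def test_mds_reproduces_euclidean_distances_exactly():
    """Full-rank Euclidean input: embedded distances equal D (checked
    against a direct eigendecomposition oracle on a 6-point instance)."""
    rng = np.random.default_rng(41)
    pts = rng.normal(size=(6, 5)) * 0.1
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    res = classical_mds(1.0 - d, n_dims=5)
    emb = np.linalg.norm(res.coords[:, None] - res.coords[None, :], axis=2)
    assert np.allclose(emb, d, atol=1e-8)
    assert (np.diff(res.eigenvalues) <= 1e-12).all()


def test_mds_separates_populations():
    # two near-discrete populations at FST 0.1
    cfg = SimulationConfig(n_samples=200, m_variants=3000, k_true=2,
                           fst=(0.1, 0.1), alpha=(0.02, 0.02), seed=40)
    g, v, s, t = simulate_cohort(cfg)
    lab = (t.q_true[:, 0] > 0.5).astype(float)
    res = classical_mds(ibs_matrix(g), n_dims=2)
    r = np.corrcoef(res.coords[:, 0], lab)[0, 1]
    assert abs(r) > 0.9


def test_pca_duplicated_cohort_scores_identical(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    d = np.vstack([g.dosages, g.dosages])
    gg = GenotypeMatrix(d, g.sample_ids + [f"{i}b" for i in g.sample_ids])
    res = pca(gg, n_components=3)
    assert np.allclose(res.scores[:g.n_samples], res.scores[g.n_samples:],
                       atol=1e-8)


def test_pca_recovers_admixture_axis():
    cfg = SimulationConfig(n_samples=300, m_variants=5000, k_true=2,
                           fst=(0.2, 0.2), alpha=(1.0, 1.0), seed=42)
    g, v, s, t = simulate_cohort(cfg)
    res = pca(g, n_components=2)
    r = np.corrcoef(res.scores[:, 0], t.q_true[:, 0])[0, 1]
    assert abs(r) > 0.95


def test_pca_sample_permutation_equivariance(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    rng = np.random.default_rng(43)
    perm = rng.permutation(g.n_samples)
    gp = GenotypeMatrix(g.dosages[perm].copy(),
                        [g.sample_ids[i] for i in perm])
    a = pca(g, n_components=3).scores
    b = pca(gp, n_components=3).scores
    assert np.allclose(a[perm], b, atol=1e-8)


def test_pca_mds_concordance(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    sc = pca(g, n_components=2).scores[:, 0]
    mc = classical_mds(ibs_matrix(g), n_dims=2).coords[:, 0]
    assert abs(np.corrcoef(sc, mc)[0, 1]) > 0.9


def test_cca_invariances(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    x = pca(g, n_components=5).scores
    assert cca_rho2(x, x) == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(44)
    r = rng.normal(size=(5, 5)) + 5 * np.eye(5)
    assert cca_rho2(x @ r, x) == pytest.approx(1.0, abs=1e-9)


def test_cca_null_matches_permutation_band():
    rng = np.random.default_rng(45)
    x = rng.normal(size=(500, 10))
    y = rng.normal(size=(500, 10))
    observed = cca_rho2(x, y)
    null = np.array([cca_rho2(x, y[rng.permutation(500)])
                     for _ in range(200)])
    lo, hi = np.quantile(null, [0.025, 0.975])
    assert lo <= observed <= hi


def test_scan_local_mode_has_more_window_spread():
    common = dict(n_samples=150, m_variants=3000, n_chromosomes=3,
                  chrom_length_bp=100_000_000, k_true=2, fst=(0.2, 0.2),
                  alpha=(1.0, 1.0), switch_rate_per_mb=0.1, seed=46)
    iqr = {}
    for mode in ("global", "local"):
        g, v, s, _ = simulate_cohort(
            SimulationConfig(ancestry_mode=mode, **common))
        res = pca(g, n_components=10)
        scan = local_global_scan(g, v, res.scores)
        q = scan["rho2"]
        iqr[mode] = q.quantile(0.75) - q.quantile(0.25)
        assert ((scan["end_bp"] - scan["start_bp"]) == 20_000_000).all()
    assert iqr["local"] > iqr["global"]


def test_scan_pure_noise_window_sits_in_null_band():
    cfg = SimulationConfig(n_samples=300, m_variants=1500, n_chromosomes=1,
                           chrom_length_bp=60_000_000, k_true=2,
                           fst=(0.25, 0.25), alpha=(0.5, 0.5), seed=47)
    g, v, s, _ = simulate_cohort(cfg)
    rng = np.random.default_rng(48)
    pos = v["pos"].to_numpy()
    noise_cols = np.flatnonzero(pos < 20_000_000)
    d = g.dosages.copy()
    # frequencies equal across populations: pure noise in window 1
    d[:, noise_cols] = rng.binomial(
        2, rng.uniform(0.2, 0.8, size=len(noise_cols))[None, :],
        size=(g.n_samples, len(noise_cols))).astype(np.int8)
    g = GenotypeMatrix(d, g.sample_ids)
    # global PCs from the structured SNPs only (the scan's global
    # marker set); the noise window carries no shared signal with them
    struct_cols = np.flatnonzero(pos >= 20_000_000)
    res = pca(g, MarkerSet("glob", struct_cols, {}), n_components=10)
    scan = local_global_scan(g, v, res.scores)
    noise_rho2 = float(scan.loc[scan["start_bp"] == 0, "rho2"].iloc[0])
    other = scan.loc[scan["start_bp"] > 0, "rho2"]
    # permutation oracle for the null of the noise window
    local = pca(g, MarkerSet("w", noise_cols, {}), n_components=10)
    null = np.array([cca_rho2(local.scores,
                              res.scores[rng.permutation(g.n_samples), :10])
                     for _ in range(200)])
    lo, hi = np.quantile(null, [0.025, 0.975])
    assert lo * 0.9 <= noise_rho2 <= hi * 1.1   # band itself is estimated
    assert noise_rho2 < other.min()


def test_admixture_k1_closed_form(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    model = admixture_em(g, k=1)
    assert np.allclose(model.q, 1.0)
    expect = np.clip(allele_frequencies(g), 1e-6, 1 - 1e-6)
    assert np.allclose(model.freqs[0], expect)
    assert len(model.loglik_trace) == 1


def test_admixture_duplicate_samples_get_identical_rows(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    d = np.vstack([g.dosages[:50], g.dosages[:1]])
    gg = GenotypeMatrix(d, [f"s{i}" for i in range(50)] + ["dup0"])
    model = admixture_em(gg, k=2, n_restarts=1, seed=0, tol=1e-3,
                         max_iter=50)
    assert np.allclose(model.q[0], model.q[50], atol=1e-10)


def test_admixture_em_loglik_monotone(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    model = admixture_em(g, k=3, n_restarts=2, seed=1, tol=1e-3,
                         max_iter=80)
    assert np.diff(model.loglik_trace).min() >= -1e-9
    assert abs(model.q.sum(axis=1) - 1.0).max() < 1e-8


def test_admixture_k_exceeding_samples_errors():
    g = GenotypeMatrix(np.zeros((3, 10), dtype=np.int8) + 1, ["a", "b", "c"])
    with pytest.raises(ValueError, match="exceeds"):
        admixture_em(g, k=4)


def test_aims_beat_equal_sized_random_set_for_recovery():
    """At matched SNP count, the delta-selected panel recovers admixture
    better than an unselected panel (paired two-seed experiment)."""
    gains = []
    for seed in (51, 52):
        cfg = SimulationConfig(n_samples=200, m_variants=2500, k_true=2,
                               fst=(0.1, 0.1), alpha=(1.0, 1.0), seed=seed)
        g, v, s, t = simulate_cohort(cfg)
        delta = delta_statistic(t.freqs_true[0], t.freqs_true[1])
        aims = select_aims(g, v, delta, delta_min=0.3)
        k = len(aims)
        rng = np.random.default_rng(seed)
        rand = MarkerSet("rand", np.sort(rng.choice(g.n_variants, size=k,
                                                    replace=False)), {})
        err = {}
        for name, ms in (("aims", aims), ("rand", rand)):
            m = admixture_em(g, ms, k=2, n_restarts=1, seed=0, tol=1e-3,
                             max_iter=60)
            qa = align_components(m.q, t.q_true)
            err[name] = np.sqrt(((qa - t.q_true) ** 2).mean())
        gains.append(err["rand"] - err["aims"])
    assert np.mean(gains) > 0


def test_continuum_sort_properties(clean_two_pop):
    _, (g, v, s, _) = clean_two_pop
    model = admixture_em(g, k=2, n_restarts=1, seed=2, tol=1e-2,
                         max_iter=40)
    order = continuum_sort(model, 0, g.sample_ids)
    col = model.q[order, 0]
    assert (np.diff(col) <= 1e-12).all()            # monotone non-increasing
    rev = continuum_sort(model, 1, g.sample_ids)
    # sorting on the complementary component reverses the order (no ties
    # expected in a continuous fit)
    assert np.array_equal(rev, order[::-1])
    with pytest.raises(ValueError, match="component"):
        continuum_sort(model, 5)


def test_loglik_by_k_nesting_and_elbow():
    cfg = SimulationConfig(n_samples=150, m_variants=1200, k_true=3,
                           fst=(0.25, 0.25, 0.25), alpha=(0.3, 0.3, 0.3),
                           seed=53)
    g, v, s, _ = simulate_cohort(cfg)
    table = loglik_by_k(g, k_range=range(1, 6), n_restarts=1, seed=0,
                        tol=1e-3, max_iter=80)
    ll = table["loglik"].to_numpy()
    assert (np.diff(ll) >= -1e-6).all()             # nested models
    gain = np.diff(ll)
    k_vals = table["k"].to_numpy()
    g23 = gain[np.flatnonzero(k_vals == 2)[0]]      # K=2 -> 3
    g34 = gain[np.flatnonzero(k_vals == 3)[0]]      # K=3 -> 4
    assert g23 >= 10 * max(g34, 1e-9)               # elbow at K_true
    # K=1 row equals the closed-form binomial fit
    k1 = admixture_em(g, k=1)
    assert table.loc[table["k"] == 1, "loglik"].iloc[0] == \
        pytest.approx(k1.loglik, abs=1e-6)
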