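"""Global and local population structure.

Global structure comes from genome-wide identity-by-state (IBS) with
classical multidimensional scaling, and from allele-frequency-
standardized genotype PCA.  Local structure is probed by tiling each
autosome into fixed windows, computing window-local PCs with the same
standardization, and recording the largest squared canonical
correlation rho2 between the local and global PC subspaces — a flat,
high rho2 profile indicates genome-wide (global) ancestry; spread in
rho2 across windows indicates locally varying ancestry.

Admixture proportions are estimated by maximum-likelihood EM under the
standard admixture observation model: genotype g_ij ~ Binomial(2,
sum_k q_ik f_kj) with loci assumed in linkage equilibrium (hence the
model should be fitted on a pruned marker set).  This is a
maximum-likelihood stand-in for Bayesian MCMC clustering tools that
share the same observation model; it is validated here by parameter
recovery on simulated cohorts.
"""
from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING, allele_frequencies
from .marker_sets import MarkerSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# IBS + classical MDS
# ---------------------------------------------------------------------------

def ibs_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise IBS similarity: mean over co-called SNPs of
    1 - |d_i - d_j| / 2.  Entries with no co-called SNPs are NaN."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    d = g.dosages
    a = [(d == k).astype(float) for k in (0, 1, 2)]
    valid = (d != MISSING).astype(float)
    # sum over co-called SNPs of |d_i - d_j|
    diff1 = a[0] @ a[1].T + a[1] @ a[0].T + a[1] @ a[2].T + a[2] @ a[1].T
    diff2 = a[0] @ a[2].T + a[2] @ a[0].T
    total = diff1 + 2.0 * diff2
    n = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = 1.0 - total / (2.0 * n)
    ibs[n == 0] = np.nan
    np.fill_diagonal(ibs, 1.0)
    return ibs


@dataclasses.dataclass
class MDSResult:
    ibs: np.ndarray
    coords: np.ndarray        # (N, n_dims), columns ordered by eigenvalue
    eigenvalues: np.ndarray


def classical_mds(ibs: np.ndarray, n_dims: int = 4) -> MDSResult:
    """Classical (Torgerson) MDS of D = 1 - IBS.

    Double-centers -1/2 J (D*D) J, takes the top eigenpairs and scales
    eigenvectors by the square root of their eigenvalues.
    """
    ibs = np.asarray(ibs, dtype=float)
    if ibs.shape[0] != ibs.shape[1] or np.isnan(ibs).any():
        raise ValueError("IBS matrix must be square and complete")
    if not np.allclose(ibs, ibs.T, atol=1e-10):
        raise ValueError("IBS matrix must be symmetric")
    n = ibs.shape[0]
    d = 1.0 - ibs
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] < -1e-8:
        raise ValueError("degenerate IBS input: leading eigenvalue negative")
    k = min(n_dims, n)
    lead = vals[:k]
    if (lead < -1e-8).any():
        raise ValueError("requested dimensions include negative eigenvalues")
    coords = vecs[:, :k] * np.sqrt(np.clip(lead, 0.0, None))
    coords = _fix_signs(coords)
    return MDSResult(ibs=ibs, coords=coords, eigenvalues=lead)


def _fix_signs(mat: np.ndarray) -> np.ndarray:
    """Sign convention: each column's largest-magnitude entry positive."""
    out = mat.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray         # (N, K) ordered by eigenvalue
    eigenvalues: np.ndarray
    loadings: np.ndarray       # (M_used, K)
    variant_indices: np.ndarray
    means: np.ndarray
    scales: np.ndarray


def _standardize(g: GenotypeMatrix, variants: np.ndarray):
    """Allele-frequency standardization with per-variant mean imputation
    of missing calls; monomorphic variants dropped."""
    d = g.called_float()[:, variants]
    p = np.nanmean(d, axis=0) / 2.0
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.all():
        log.info("pca: dropping %d monomorphic variants", int((~poly).sum()))
    d = d[:, poly]
    p = p[poly]
    mean = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    d = np.where(np.isnan(d), mean[None, :], d)
    x = (d - mean[None, :]) / scale[None, :]
    return x, variants[poly], mean, scale


def pca(g: GenotypeMatrix, markers: MarkerSet | None = None,
        n_components: int = 10) -> PCAResult:
    """Genotype PCA with 2p-centering and sqrt(2p(1-p)) scaling."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    variants = (markers.indices if markers is not None
                else np.arange(g.n_variants))
    x, used, mean, scale = _standardize(g, np.asarray(variants))
    n = x.shape[0]
    k = min(n_components, n - 1, x.shape[1])
    gram = x @ x.T
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:k]
    sv = np.sqrt(np.clip(vals[order], 0.0, None))    # singular values
    u = vecs[:, order]
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = x.T @ (u / np.where(sv > 0, sv, 1.0))
    loadings = _fix_signs(loadings)
    # re-derive scores under the loading sign convention
    scores = x @ loadings
    eigenvalues = sv ** 2 / (n - 1)
    return PCAResult(scores=scores, eigenvalues=eigenvalues,
                     loadings=loadings, variant_indices=used,
                     means=mean, scales=scale)


# ---------------------------------------------------------------------------
# Canonical correlation of PC subspaces
# ---------------------------------------------------------------------------

def cca_rho2(local_pcs: np.ndarray, global_pcs: np.ndarray,
             rank_tol: float = 1e-8) -> float:
    """Largest squared canonical correlation between two column spaces.

    Columns are centered, each matrix is orthonormalized by SVD (rank-
    deficient input is reduced to its effective rank), and rho1 is the
    largest singular value of the product of the bases.
    """
    def _basis(m):
        m = np.asarray(m, dtype=float)
        m = m - m.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        rank = int((s > rank_tol * max(s[0], 1.0)).sum())
        if rank < m.shape[1]:
            log.info("cca_rho2: rank reduced from %d to %d", m.shape[1], rank)
        if rank == 0:
            raise ValueError("matrix has no variation after centering")
        return u[:, :rank]

    ua, ub = _basis(local_pcs), _basis(global_pcs)
    if ua.shape[0] != ub.shape[0]:
        raise ValueError("sample dimension mismatch")
    rho = np.linalg.svd(ua.T @ ub, compute_uv=False)[0]
    return float(np.clip(rho, 0.0, 1.0) ** 2)


def local_global_scan(g: GenotypeMatrix, v: pd.DataFrame,
                      global_pcs: np.ndarray, window_mb: float = 20.0,
                      n_pcs: int = 10, n_snps_min: int = 50) -> pd.DataFrame:
    """Tile autosomes into half-open ``window_mb`` windows anchored at 0
    and record per-window rho2 between the local and global top PCs.
    Windows with fewer than ``n_snps_min`` SNPs are skipped."""
    window_bp = int(window_mb * 1e6)
    k = min(n_pcs, global_pcs.shape[1])
    gpcs = global_pcs[:, :k]
    rows = []
    chroms = v["chrom"].to_numpy()
    pos = v["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        if chrom == "X":
            continue
        on = chroms == chrom
        cmax = pos[on].max()
        for start in range(0, int(cmax) + 1, window_bp):
            sel = np.flatnonzero(on & (pos >= start) & (pos < start + window_bp))
            if len(sel) < n_snps_min:
                continue
            local = pca(g, MarkerSet("win", sel, {}), n_components=k)
            rho2 = cca_rho2(local.scores[:, :k], gpcs)
            rows.append({"chrom": chrom, "start_bp": start,
                         "end_bp": start + window_bp, "n_snps": len(sel),
                         "rho2": rho2})
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "rho2"])


# ---------------------------------------------------------------------------
# EM admixture
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AncestryModel:
    k: int
    freqs: np.ndarray          # (K, M) population allele frequencies
    q: np.ndarray              # (N, K) admixture proportions
    loglik_trace: np.ndarray   # best restart, per accepted iteration
    restart_logliks: np.ndarray
    n_restarts: int
    seed: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def n_parameters(self) -> int:
        n, k = self.q.shape
        m = self.freqs.shape[1]
        return k * m + n * (k - 1)


_F_EPS = 1e-6


def _binomial_loglik(d, called, q, f):
    pi = np.clip(q @ f, 1e-12, 1.0 - 1e-12)
    with np.errstate(invalid="ignore"):
        ll = np.where(called, d * np.log(pi) + (2.0 - d) * np.log1p(-pi), 0.0)
    return float(ll.sum())


def admixture_em(g: GenotypeMatrix, markers: MarkerSet | None = None,
                 k: int = 2, n_restarts: int = 3, seed: int = 0,
                 tol: float = 1e-4, max_iter: int = 1000,
                 inits=None) -> AncestryModel:
    """Maximum-likelihood EM for the admixture model.

    Missing genotypes contribute no likelihood terms.  Frequencies are
    box-clipped to [1e-6, 1 - 1e-6] and Q rows renormalized each
    update.  The best of ``n_restarts`` random restarts (plus any
    explicit ``inits``, given as (Q0, F0) pairs) is returned; the
    log-likelihood trace of the winning run is monotone non-decreasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.n_samples:
        raise ValueError("k exceeds the number of samples")
    variants = (markers.indices if markers is not None
                else np.arange(g.n_variants))
    draw = g.dosages[:, variants]
    called = draw != MISSING
    d = np.where(called, draw, 0).astype(float)
    n, m = d.shape
    n_called = 2.0 * called.sum(axis=1).astype(float)
    if (n_called == 0).any():
        raise ValueError("sample with no called genotypes")

    if k == 1:
        f = np.clip(allele_frequencies(g.subset(variants=variants)),
                    _F_EPS, 1 - _F_EPS)[None, :]
        q = np.ones((n, 1))
        ll = _binomial_loglik(d, called, q, f)
        return AncestryModel(1, f, q, np.array([ll]), np.array([ll]), 1, seed)

    rng = np.random.default_rng(seed)
    base = np.clip(allele_frequencies(g.subset(variants=variants)),
                   0.05, 0.95)
    starts = []
    try:
        starts.append(_structured_start(g, variants, d, called, k, rng))
    except Exception as exc:             # degenerate inputs: fall back
        log.info("structured start unavailable (%s); using random only", exc)
    while len(starts) < n_restarts:
        q0 = rng.dirichlet(np.ones(k), size=n)
        f0 = np.clip(base[None, :] + rng.uniform(-0.1, 0.1, size=(k, m)),
                     _F_EPS, 1 - _F_EPS)
        starts.append((q0, f0))
    for q0, f0 in (inits or []):
        if q0.shape != (n, k) or f0.shape != (k, m):
            raise ValueError("explicit init has wrong shape")
        starts.append((q0.copy(), np.clip(f0, _F_EPS, 1 - _F_EPS)))
    d_cnt = np.where(called, d, 0.0)
    d_other = np.where(called, 2.0 - d, 0.0)
    best = None
    restart_lls = []
    for q, f in starts:
        trace = []
        for _it in range(max_iter):
            q, f, ll = _em_step(d_cnt, d_other, q, f, n_called)
            trace.append(ll)          # log-lik at the pre-update parameters
            if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                break
        _, _, ll = _em_step(d_cnt, d_other, q, f, n_called, update=False)
        trace.append(ll)              # at the returned parameters
        restart_lls.append(trace[-1])
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], q, f, np.array(trace))
    _, q, f, trace = best
    return AncestryModel(k, f, q, trace, np.array(restart_lls),
                         n_restarts, seed)


def _structured_start(g, variants, d, called, k, rng):
    """Anchored initialization: k-means on the leading PC scores gives
    tentative clusters; Q starts softly on its cluster and F at the
    cluster allele frequencies.  Purely an initialization device — EM
    refines everything — but it breaks the symmetric saddle that slows
    random starts."""
    from scipy.cluster.vq import kmeans2

    res = pca(g, MarkerSet("init", np.asarray(variants), {}),
              n_components=max(1, k - 1))
    scores = res.scores
    seed2 = int(rng.integers(2 ** 31 - 1))
    _, labels = kmeans2(scores, k, minit="++", seed=seed2)
    if len(np.unique(labels)) < k:
        raise ValueError("k-means produced empty clusters")
    n = scores.shape[0]
    q0 = np.full((n, k), 0.3 / k)
    q0[np.arange(n), labels] += 0.7
    q0 /= q0.sum(axis=1, keepdims=True)
    d_sum = np.vstack([np.where(called[labels == kk], d[labels == kk], 0)
                       .sum(axis=0) for kk in range(k)])
    n_sum = np.vstack([2.0 * called[labels == kk].sum(axis=0)
                       for kk in range(k)])
    with np.errstate(invalid="ignore", divide="ignore"):
        f0 = np.where(n_sum > 0, d_sum / n_sum, 0.5)
    return q0, np.clip(f0, 0.05, 0.95)


def _em_step(d_cnt, d_other, q, f, n_called, update=True):
    """One EM update; returns (q, f, loglik-at-entry).  The returned
    log-likelihood is evaluated at the *incoming* parameters so the
    recorded trace is exactly the EM ascent sequence."""
    n, k = q.shape
    pi = np.clip(q @ f, 1e-12, 1.0 - 1e-12)
    log_pi = np.log(pi)
    log_1mpi = np.log1p(-pi)
    ll = float((d_cnt * log_pi).sum() + (d_other * log_1mpi).sum())
    if not update:
        return q, f, ll
    t_cnt = d_cnt / pi
    t_other = d_other / (1.0 - pi)
    new_q = np.empty_like(q)
    num_f = np.empty_like(f)
    den_f = np.empty_like(f)
    for kk in range(k):
        a = t_cnt * (q[:, kk:kk + 1] * f[kk][None, :])
        b = t_other * (q[:, kk:kk + 1] * (1.0 - f[kk])[None, :])
        ab = a + b
        new_q[:, kk] = ab.sum(axis=1) / n_called
        num_f[kk] = a.sum(axis=0)
        den_f[kk] = ab.sum(axis=0)
    new_q = new_q / new_q.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        new_f = np.where(den_f > 0, num_f / den_f, f)
    return new_q, np.clip(new_f, _F_EPS, 1.0 - _F_EPS), ll


def align_components(q_hat: np.ndarray, q_true: np.ndarray) -> np.ndarray:
    """Resolve label switching for evaluation: permute the columns of
    ``q_hat`` to maximize the summed (signed) correlation with
    ``q_true``.  Signed correlation is essential: simplex columns are
    linearly dependent (for K = 2 exact complements), so absolute
    correlation cannot distinguish a component from its complement.
    Exhaustive over permutations (K is small)."""
    k = q_hat.shape[1]
    if q_true.shape[1] != k:
        raise ValueError("component count mismatch")
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            a, b = q_hat[:, i], q_true[:, j]
            if a.std() == 0 or b.std() == 0:
                corr[i, j] = 0.0
            else:
                corr[i, j] = np.corrcoef(a, b)[0, 1]
    best_perm = max(itertools.permutations(range(k)),
                    key=lambda p: sum(corr[p[j], j] for j in range(k)))
    return q_hat[:, list(best_perm)]


def continuum_sort(model: AncestryModel, component: int,
                   sample_ids=None) -> np.ndarray:
    """Sample order by descending ancestry proportion of one component,
    with a stable sample-id tie-break."""
    if not 0 <= component < model.k:
        raise ValueError(f"component {component} out of range for K={model.k}")
    col = model.q[:, component]
    ids = (np.asarray(sample_ids) if sample_ids is not None
           else np.arange(len(col)))
    return np.lexsort((ids, -col))


def loglik_by_k(g: GenotypeMatrix, markers: MarkerSet | None = None,
                k_range=range(2, 8), n_restarts: int = 3, seed: int = 0,
                tol: float = 1e-4, max_iter: int = 1000) -> pd.DataFrame:
    """Best log-likelihood and parameter count per K; no automatic model
    selection."""
    rows = []
    prev: AncestryModel | None = None
    for k in sorted(k_range):
        inits = []
        if prev is not None and prev.k == k - 1:
            # split one component of the previous fit: reproduces its
            # likelihood exactly, so the profile is non-decreasing in K
            f0 = np.vstack([prev.freqs, prev.freqs[-1:]])
            q0 = np.hstack([prev.q[:, :-1], prev.q[:, -1:] / 2.0,
                            prev.q[:, -1:] / 2.0])
            inits.append((q0, f0))
        model = admixture_em(g, markers, k=k, n_restarts=n_restarts,
                             seed=seed + k, tol=tol, max_iter=max_iter,
                             inits=inits)
        prev = model
        rows.append({"k": k, "loglik": model.loglik,
                     "n_parameters": model.n_parameters(),
                     "n_iterations": len(model.loglik_trace) - 1})
    return pd.DataFrame(rows)
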