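"""Sample- and SNP-level quality control with exact exclusion accounting.

The cascade mirrors the standard clinical-genotyping workflow: sample
filters first (declared-vs-genetic sex, sample call rate), then SNP
filters (call rate, MAF, batch deviation, diagnosis-linked differential
missingness, Hardy-Weinberg), and finally removal of inbreeding-
coefficient outliers.  Every step is recorded in a :class:`QCLedger`
whose integer accounting is conservation-checked: n_after =
n_before - n_excluded at each step and consecutive steps chain.

The Hardy-Weinberg test is the exact conditional test (probability of
the heterozygote count given allele counts summed over configurations
no more probable than the observed one).  Relatedness uses the
method-of-moments IBD estimator (IBS-state counts inverted through
their allele-frequency expectations), summarized as PI-hat = z1/2 + z2.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, MISSING, allele_frequencies


@dataclasses.dataclass
class QCThresholds:
    sample_missing_max: float = 0.05
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    diff_missing_p_min: float = 1e-4
    batch_p_min: float = 0.05       # applied after Bonferroni correction
    inbreeding_sd_limit: float = 4.0
    pihat_max: float = 0.95


@dataclasses.dataclass
class LedgerStep:
    name: str
    axis: str                # "sample" or "SNP"
    n_before: int
    n_excluded: int
    n_after: int


@dataclasses.dataclass
class QCLedger:
    """Ordered record of filter steps with conservation-checked counts."""

    steps: list = dataclasses.field(default_factory=list)

    def add(self, name: str, axis: str, n_before: int, n_excluded: int) -> None:
        if axis not in ("sample", "SNP"):
            raise ValueError(f"axis must be 'sample' or 'SNP', got {axis!r}")
        step = LedgerStep(name, axis, int(n_before), int(n_excluded),
                          int(n_before) - int(n_excluded))
        self.steps.append(step)
        self.validate()

    def validate(self) -> None:
        last_after = {}
        for t, st in enumerate(self.steps):
            if st.n_after != st.n_before - st.n_excluded:
                raise ValueError(f"ledger step {st.name!r} does not conserve counts")
            if st.n_excluded < 0 or st.n_after < 0:
                raise ValueError(f"ledger step {st.name!r} has negative counts")
            if st.axis in last_after and st.n_before != last_after[st.axis]:
                raise ValueError(
                    f"ledger step {st.name!r} does not chain on axis {st.axis}: "
                    f"n_before={st.n_before}, previous n_after={last_after[st.axis]}")
            last_after[st.axis] = st.n_after

    def final(self, axis: str) -> int:
        for st in reversed(self.steps):
            if st.axis == axis:
                return st.n_after
        raise ValueError(f"no steps on axis {axis!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.steps])


def ledger_from_counts(axis: str, n_start: int, steps) -> QCLedger:
    """Replay a cascade from published (step name, exclusion count)
    pairs; useful for auditing a reported QC chain."""
    ledger = QCLedger()
    n = int(n_start)
    for name, n_excl in steps:
        ledger.add(name, axis, n, int(n_excl))
        n -= int(n_excl)
    return ledger


# ---------------------------------------------------------------------------
# Elementary per-matrix statistics
# ---------------------------------------------------------------------------

def call_rates(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(per-sample, per-SNP) missing fractions with the full matrix as
    denominator."""
    if g.n_samples == 0 or g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    miss = g.missing_mask()
    return miss.mean(axis=1), miss.mean(axis=0)


def hwe_het_distribution(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count given ``n`` diploid
    genotypes and ``n_a`` copies of allele A.

    Support is every h with the parity of ``n_a`` for which the implied
    homozygote counts are non-negative.  Probabilities are computed by
    the stable ratio recurrence P(h+2)/P(h) = 4 nAA(h) nBB(h) /
    ((h+1)(h+2)) and normalized.  Returns ``(hs, probs)``.
    """
    n_b = 2 * n - n_a
    if n_a < 0 or n_b < 0:
        raise ValueError("invalid allele count")
    # h ranges over parity-matching values with nAA, nBB >= 0
    h_lo = n_a % 2
    h_hi = min(n_a, n_b)
    if (h_hi - h_lo) % 2:
        h_hi -= 1
    hs = np.arange(h_lo, h_hi + 1, 2)
    if len(hs) == 0:
        raise ValueError("empty heterozygote support")
    naa = (n_a - hs) / 2.0
    nbb = (n_b - hs) / 2.0
    ratios = 4.0 * naa[:-1] * nbb[:-1] / ((hs[:-1] + 1.0) * (hs[:-1] + 2.0))
    probs = np.concatenate([[1.0], np.cumprod(ratios)])
    probs /= probs.max()          # re-anchor before normalizing, for range
    probs /= probs.sum()
    return hs, probs


def hwe_exact_pvalues(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact-test p-value for every possible heterozygote count at
    fixed allele counts: p(h0) = sum of P(h) over all h with
    P(h) <= P(h0) (relative tie tolerance at floating precision).
    Returns ``(hs, pvals)``."""
    hs, probs = hwe_het_distribution(n, n_a)
    order = np.argsort(probs, kind="stable")
    csum = np.cumsum(probs[order])
    sorted_probs = probs[order]
    # each h sums the mass of all configurations no more probable
    cutoff = np.searchsorted(sorted_probs,
                             probs * (1.0 + 1e-12), side="right") - 1
    pvals = np.minimum(csum[cutoff], 1.0)
    return hs, pvals


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums P(h) over all heterozygote counts whose conditional
    probability does not exceed the observed one.  Monomorphic input
    returns 1.
    """
    if min(n_aa, n_ab, n_bb) < 0 or (n_aa + n_ab + n_bb) == 0:
        raise ValueError("genotype counts must be non-negative, not all zero")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hs, pvals = hwe_exact_pvalues(n, n_a)
    return float(pvals[np.searchsorted(hs, n_ab)])


def hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    """Per-SNP exact HWE p-values on pooled samples (NaN if no calls)."""
    d = g.dosages
    out = np.empty(g.n_variants)
    for j in range(g.n_variants):
        col = d[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                                int((col == 0).sum()))
    return out


def differential_missingness(g: GenotypeMatrix, flag: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p per SNP for (missing/called x flag)."""
    flag = np.asarray(flag, dtype=bool)
    if flag.all() or not flag.any():
        raise ValueError("both flag classes must be non-empty")
    miss = g.missing_mask()
    m1 = miss[flag].sum(axis=0)
    m0 = miss[~flag].sum(axis=0)
    n1, n0 = int(flag.sum()), int((~flag).sum())
    out = np.empty(g.n_variants)
    cache: dict[tuple, float] = {}
    for j in range(g.n_variants):
        a, b = int(m1[j]), int(m0[j])
        c, d = n1 - a, n0 - b
        if c + d == 0:
            out[j] = np.nan
            continue
        key = (a, b)
        if key not in cache:
            cache[key] = stats.fisher_exact([[a, b], [c, d]])[1]
        out[j] = cache[key]
    return out


def batch_concordance(g: GenotypeMatrix, s: pd.DataFrame,
                      pairs=None) -> pd.DataFrame:
    """Genotype concordance for replicate pairs.

    ``pairs`` is a list of (id_a, id_b); if omitted, every sample
    flagged ``is_replicate`` whose id is "<base>rep" is paired with
    ``<base>``.  Concordance is the fraction of co-called SNPs with
    equal dosage (NaN when none are co-called).
    """
    idx = {sid: i for i, sid in enumerate(g.sample_ids)}
    if pairs is None:
        pairs = []
        for sid, is_rep in zip(s["sample_id"], s["is_replicate"]):
            if is_rep and sid.endswith("rep") and sid[:-3] in idx:
                pairs.append((sid[:-3], sid))
    rows = []
    for a, b in pairs:
        da, db = g.dosages[idx[a]], g.dosages[idx[b]]
        both = (da != MISSING) & (db != MISSING)
        conc = float((da[both] == db[both]).mean()) if both.any() else np.nan
        rows.append({"id_a": a, "id_b": b, "n_cocalled": int(both.sum()),
                     "concordance": conc})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "n_cocalled",
                                       "concordance"])


def batch_effect_scan(g: GenotypeMatrix, s: pd.DataFrame) -> np.ndarray:
    """Per-SNP chi-square test of allele counts across genotyping
    batches (df = n_batches - 1)."""
    batches = pd.Categorical(s["batch"])
    b = len(batches.categories)
    if b < 2:
        raise ValueError("batch_effect_scan needs at least two batches")
    codes = np.asarray(batches.codes)
    member = np.eye(b)[codes]                       # (N, B)
    d = g.dosages
    called = (d != MISSING).astype(float)
    dc = np.where(d == MISSING, 0, d).astype(float)
    counted = member.T @ dc                         # allele-A counts (B, M)
    total = 2.0 * (member.T @ called)               # allele totals per batch
    other = total - counted
    col_a = counted.sum(axis=0)
    col_o = other.sum(axis=0)
    grand = total.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_a = total * (col_a / grand)[None, :]
        exp_o = total * (col_o / grand)[None, :]
        chi2 = (np.where(exp_a > 0, (counted - exp_a) ** 2 / exp_a, 0.0)
                + np.where(exp_o > 0, (other - exp_o) ** 2 / exp_o, 0.0)).sum(axis=0)
    p = stats.chi2.sf(chi2, df=b - 1)
    p[(col_a == 0) | (col_o == 0)] = 1.0            # monomorphic: no signal
    return p


def inbreeding_coefficient(g: GenotypeMatrix,
                           freqs: np.ndarray | None = None) -> np.ndarray:
    """Per-sample F = (O_hom - E_hom) / (n_called - E_hom), expectation
    from (sample) allele frequencies."""
    if freqs is None:
        freqs = allele_frequencies(g)
    d = g.dosages
    called = d != MISSING
    informative = ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    use = called & informative[None, :]
    o_hom = (use & ((d == 0) | (d == 2))).sum(axis=1).astype(float)
    exp_term = 1.0 - 2.0 * freqs * (1.0 - freqs)
    e_hom = use @ np.where(informative, exp_term, 0.0)
    n_called = use.sum(axis=1).astype(float)
    denom = n_called - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / denom
    f[n_called == 0] = np.nan
    return f


def ibd_estimate(g: GenotypeMatrix, freqs: np.ndarray | None = None,
                 min_snps: int = 100) -> pd.DataFrame:
    """Method-of-moments IBD for every sample pair.

    Observed IBS-state counts are inverted through their expectations
    given IBD state (computed from allele frequencies, no finite-sample
    correction), then (z0, z1, z2) is projected onto the simplex and
    PI-hat = z1/2 + z2 reported.  Pairs with fewer than ``min_snps``
    co-called SNPs are flagged unreliable.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    d = g.dosages
    ok = ~np.isnan(freqs) & (freqs > 0) & (freqs < 1)
    d = d[:, ok]
    p = freqs[ok]
    q = 1.0 - p
    a0 = ((d == 0)).astype(float)
    a1 = ((d == 1)).astype(float)
    a2 = ((d == 2)).astype(float)
    valid = (d != MISSING).astype(float)
    ibs0 = a0 @ a2.T + a2 @ a0.T
    ibs1 = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    # per-SNP expected IBS-state probabilities given IBD state
    e0_z0 = 2.0 * p ** 2 * q ** 2
    e1_z0 = 4.0 * p ** 3 * q + 4.0 * p * q ** 3
    e1_z1 = 2.0 * p * q        # 2 p^2 q + 2 p q^2
    s0 = valid @ (e0_z0[:, None] * valid.T)
    s1 = valid @ (e1_z0[:, None] * valid.T)
    s2 = valid @ (e1_z1[:, None] * valid.T)
    m_pair = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = ibs0 / s0
        z1 = (ibs1 - z0 * s1) / s2
    z2 = 1.0 - z0 - z1
    n = g.n_samples
    iu, ju = np.triu_indices(n, k=1)
    rows = []
    for i, j in zip(iu, ju):
        z = _project_simplex(np.array([z0[i, j], z1[i, j], z2[i, j]]))
        pihat = z[1] / 2.0 + z[2]
        rows.append({
            "id_a": g.sample_ids[i], "id_b": g.sample_ids[j],
            "ibs0": int(ibs0[i, j]), "ibs1": int(ibs1[i, j]),
            "ibs2": int(ibs2[i, j]), "n_cocalled": int(m_pair[i, j]),
            "z0": z[0], "z1": z[1], "z2": z[2], "pihat": float(pihat),
            "unreliable": bool(m_pair[i, j] < min_snps),
        })
    return pd.DataFrame(rows)


def _project_simplex(z: np.ndarray) -> np.ndarray:
    """Euclidean projection of a length-3 vector onto the probability
    simplex."""
    z = np.where(np.isfinite(z), z, 0.0)
    u = np.sort(z)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, 4) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(z - theta, 0.0)


def sex_check(g_x: GenotypeMatrix, s: pd.DataFrame,
              male_f_min: float = 0.8,
              female_f_max: float = 0.2) -> pd.DataFrame:
    """Infer sex from X heterozygosity.

    F is the inbreeding coefficient restricted to X variants (males,
    hemizygous and coded homozygous, sit near 1; females at HWE near
    0).  Requires >= 20 X variants.
    """
    if g_x.n_variants < 20:
        raise ValueError("sex_check needs at least 20 X variants")
    f = inbreeding_coefficient(g_x)
    inferred = np.where(f > male_f_min, "male",
                        np.where(f < female_f_max, "female", "undetermined"))
    declared = s["sex"].to_numpy()
    mismatch = (inferred != "undetermined") & (declared != "unknown") \
        & (inferred != declared)
    return pd.DataFrame({
        "sample_id": g_x.sample_ids, "f_x": f, "declared": declared,
        "inferred": inferred, "mismatch": mismatch,
    })


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------

class EmptySurvivorSet(RuntimeError):
    pass


def apply_cascade(g: GenotypeMatrix, v: pd.DataFrame, s: pd.DataFrame,
                  thresholds: QCThresholds | None = None,
                  diff_missing_flag: str | None = None):
    """Run the full QC cascade; every step is evaluated on the data
    surviving the previous steps.

    Order: sex mismatch, sample call rate | SNP call rate, MAF, batch
    deviation, differential missingness, HWE | inbreeding outliers.
    Steps without the data they need (no X variants, one batch, no
    diagnosis flag) record zero exclusions.  X variants are used for
    the sex check and then set aside from SNP-level filters.  Returns
    ``(g, v, s, ledger)``.
    """
    thr = thresholds or QCThresholds()
    ledger = QCLedger()
    sample_keep = np.ones(g.n_samples, dtype=bool)
    is_x = (v["chrom"] == "X").to_numpy()
    auto_idx = np.flatnonzero(~is_x)
    snp_keep = np.ones(len(auto_idx), dtype=bool)

    def _current():
        rows = np.flatnonzero(sample_keep)
        cols = auto_idx[snp_keep]
        return g.subset(rows, cols), rows, cols

    # -- sample axis ---------------------------------------------------
    n_s = int(sample_keep.sum())
    if is_x.any() and int(is_x.sum()) >= 20:
        gx = g.subset(np.flatnonzero(sample_keep), np.flatnonzero(is_x))
        chk = sex_check(gx, s.iloc[np.flatnonzero(sample_keep)])
        bad = chk["mismatch"].to_numpy()
        sample_keep[np.flatnonzero(sample_keep)[bad]] = False
        ledger.add("sex_mismatch", "sample", n_s, int(bad.sum()))
    else:
        ledger.add("sex_mismatch", "sample", n_s, 0)
    _check_nonempty(sample_keep, "sex_mismatch")

    n_s = int(sample_keep.sum())
    cur, rows, _ = _current()
    samp_miss, _ = call_rates(cur)
    bad = samp_miss > thr.sample_missing_max
    sample_keep[rows[bad]] = False
    ledger.add("sample_call_rate", "sample", n_s, int(bad.sum()))
    _check_nonempty(sample_keep, "sample_call_rate")

    # -- SNP axis ------------------------------------------------------
    def _snp_step(name, bad_local):
        nonlocal snp_keep
        n_before = int(snp_keep.sum())
        live = np.flatnonzero(snp_keep)
        snp_keep[live[bad_local]] = False
        ledger.add(name, "SNP", n_before, int(bad_local.sum()))
        if not snp_keep.any():
            raise EmptySurvivorSet(f"no SNPs survive step {name!r}")

    cur, rows, _ = _current()
    _, snp_miss = call_rates(cur)
    _snp_step("snp_call_rate", snp_miss > thr.snp_missing_max)

    cur, _, _ = _current()
    freq = allele_frequencies(cur)
    maf = np.minimum(freq, 1.0 - freq)
    _snp_step("maf", np.nan_to_num(maf, nan=0.0) < thr.maf_min)

    cur, rows, _ = _current()
    s_cur = s.iloc[rows]
    if s_cur["batch"].nunique() >= 2:
        p_batch = batch_effect_scan(cur, s_cur)
        bonf = thr.batch_p_min / cur.n_variants
        _snp_step("batch_effect", p_batch < bonf)
    else:
        _snp_step("batch_effect", np.zeros(cur.n_variants, dtype=bool))

    cur, rows, _ = _current()
    s_cur = s.iloc[rows]
    if diff_missing_flag is not None:
        flag = np.array([diff_missing_flag in dx.split(";") if dx else False
                         for dx in s_cur["diagnoses"]])
        if flag.any() and not flag.all():
            p_dm = differential_missingness(cur, flag)
            _snp_step("differential_missingness",
                      np.nan_to_num(p_dm, nan=1.0) < thr.diff_missing_p_min)
        else:
            _snp_step("differential_missingness",
                      np.zeros(cur.n_variants, dtype=bool))
    else:
        _snp_step("differential_missingness",
                  np.zeros(cur.n_variants, dtype=bool))

    cur, _, _ = _current()
    p_hwe = hwe_pvalues(cur)
    _snp_step("hwe", np.nan_to_num(p_hwe, nan=1.0) < thr.hwe_p_min)

    # -- final sample step --------------------------------------------
    n_s = int(sample_keep.sum())
    cur, rows, _ = _current()
    f = inbreeding_coefficient(cur)
    mu, sd = np.nanmean(f), np.nanstd(f)
    bad = (np.abs(f - mu) > thr.inbreeding_sd_limit * sd) if sd > 0 \
        else np.zeros(len(f), dtype=bool)
    bad = np.nan_to_num(bad, nan=False).astype(bool)
    sample_keep[rows[bad]] = False
    ledger.add("inbreeding_outlier", "sample", n_s, int(bad.sum()))
    _check_nonempty(sample_keep, "inbreeding_outlier")

    rows = np.flatnonzero(sample_keep)
    cols = auto_idx[snp_keep]
    g_out = g.subset(rows, cols)
    v_out = v.iloc[cols].reset_index(drop=True)
    s_out = s.iloc[rows].reset_index(drop=True)
    return g_out, v_out, s_out, ledger


def _check_nonempty(keep: np.ndarray, step: str) -> None:
    if not keep.any():
        raise EmptySurvivorSet(f"no samples survive step {step!r}")
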