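"""Ground-truthed simulation of admixed genotype cohorts.

The generator emulates the structure of an admixed clinical sample: K
ancestral populations drift away from shared ancestral allele
frequencies under a Balding-Nichols model, individuals carry Dirichlet
admixture proportions, and ancestry either applies genome-wide
("global" mode) or varies along chromosomes in exponential-length
segments ("local" mode).  Optional haplotype pools create blocks of
strong linkage disequilibrium.  On top of the clean genotypes a fixed
sequence of nuisance processes is applied, in this order:

    LD pools -> MCAR missingness -> diagnosis-linked missingness ->
    batch corruption -> duplicates / parent-child pairs ->
    sex-label mismatches -> phenotype

so that :class:`GroundTruth` describes exactly what was injected.
A log-normal BMI phenotype with age, sex and per-SNP genetic effects
closes the loop for association testing.  Identical configuration
(including ``seed``) yields bit-identical output.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io_formats import (GenotypeMatrix, MISSING, sample_table,
                         variant_table)

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    ``n_samples`` maps group label to size (an int means one group
    "pop").  ``alpha`` is the Dirichlet concentration vector of
    individual admixture, either one vector for all groups or a
    per-group mapping.  ``fst`` gives the Balding-Nichols drift of each
    ancestral population.  Rates are probabilities per call;
    ``switch_rate_per_mb`` is the local-ancestry segment break rate.
    ``causal_snps`` lists (variant index, effect size) pairs with
    effects in residual-SD units of log BMI.
    """

    n_samples: dict | int = 100
    m_variants: int = 1000
    n_chromosomes: int = 2
    chrom_length_bp: int = 100_000_000
    k_true: int = 2
    fst: tuple = (0.2, 0.2)
    alpha: tuple | dict = (1.0, 1.0)
    ancestry_mode: str = "global"
    switch_rate_per_mb: float = 0.1
    ld_block_size: int = 0
    n_haplotypes_per_pool: int = 8
    missing_rate: float = 0.0
    diff_missing: tuple | None = None        # (flag, extra_rate, snp_fraction)
    batch_distortion: tuple = (1, 0, 0.0)    # (n_batches, n_bad_snps, rate)
    n_duplicates: int = 0
    n_parent_child_pairs: int = 0
    sex_mismatch_rate: float = 0.0
    x_variants: int = 0
    diagnosis_prevalence: dict = dataclasses.field(
        default_factory=lambda: {"diabetes": 0.3})
    mu_log_bmi: float = math.log(27.0)
    beta_age: float = 0.0
    beta_sex: float = 0.0
    causal_snps: tuple = ()
    sigma_env: float = 0.15
    age_mean: float = 52.8                   # clinical-cohort age profile
    age_sd: float = 14.2
    seed: int = 0

    def groups(self) -> dict:
        if isinstance(self.n_samples, int):
            return {"pop": self.n_samples}
        return dict(self.n_samples)

    def group_alpha(self, group: str) -> np.ndarray:
        a = self.alpha[group] if isinstance(self.alpha, dict) else self.alpha
        a = np.asarray(a, dtype=float)
        if a.shape != (self.k_true,):
            raise ValueError(
                f"alpha for group {group!r} has length {a.size}, "
                f"expected k_true={self.k_true}")
        return a

    def validate(self) -> None:
        fst = np.asarray(self.fst, dtype=float)
        if fst.shape != (self.k_true,):
            raise ValueError("fst must have one value per ancestral population")
        if not ((fst > 0) & (fst < 1)).all():
            raise ValueError("fst values must lie in (0, 1)")
        for grp in self.groups():
            self.group_alpha(grp)
        for rate in (self.missing_rate, self.sex_mismatch_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.ancestry_mode not in ("global", "local"):
            raise ValueError("ancestry_mode must be 'global' or 'local'")
        for j, _ in self.causal_snps:
            if not 0 <= j < self.m_variants:
                raise ValueError(f"causal SNP index {j} out of range")


@dataclasses.dataclass
class GroundTruth:
    """What the generator actually did: admixture rows ``q_true`` (one
    simplex row per sample, duplicates/children included), population
    frequencies ``freqs_true`` (K x M), per-haplotype local-ancestry
    labels (local mode only), the injected-nuisance record
    ``excluded_truth`` and an echo of the phenotype parameters."""

    q_true: np.ndarray
    freqs_true: np.ndarray
    local_ancestry: np.ndarray | None
    excluded_truth: dict
    phenotype_params: dict


def simulate_frequencies(cfg: SimulationConfig, rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols population frequencies.

    Ancestral frequency p_j ~ U[0.05, 0.95]; population k draws
    Beta(p_j (1-F_k)/F_k, (1-p_j)(1-F_k)/F_k), so E = p_j and
    Var = F_k p_j (1-p_j).  Clipped to [0.01, 0.99].  Returns
    ``(ancestral, freqs)`` with freqs of shape (K, M).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = cfg.m_variants
    ancestral = rng.uniform(0.05, 0.95, size=m)
    freqs = np.empty((cfg.k_true, m))
    for k, f in enumerate(np.asarray(cfg.fst, dtype=float)):
        lam = (1.0 - f) / f
        freqs[k] = rng.beta(ancestral * lam, (1.0 - ancestral) * lam)
    return ancestral, np.clip(freqs, 0.01, 0.99)


def _variant_frame(cfg: SimulationConfig, rng) -> pd.DataFrame:
    m = cfg.m_variants
    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    chroms, pos = [], []
    for c, idx in enumerate(per_chrom, start=1):
        chroms.extend([str(c)] * len(idx))
        p = np.sort(rng.choice(cfg.chrom_length_bp - 1, size=len(idx),
                               replace=False)) + 1
        pos.extend(p.tolist())
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=m)
    a = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    b = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    return variant_table([f"rs{j + 1}" for j in range(m)], chroms, pos, a, b)


def _segment_labels(length_mb: float, positions_mb: np.ndarray, q: np.ndarray,
                    rate: float, rng) -> np.ndarray:
    """Ancestry labels along one chromosome for one haplotype: segments
    with Exp(rate) lengths, labels i.i.d. from q (the chain's stationary
    distribution)."""
    k = len(q)
    if rate <= 0:
        return np.full(len(positions_mb), rng.choice(k, p=q), dtype=np.int8)
    breaks = [0.0]
    while breaks[-1] < length_mb:
        breaks.append(breaks[-1] + rng.exponential(1.0 / rate))
    labels = rng.choice(k, size=len(breaks) - 1, p=q)
    seg = np.searchsorted(np.array(breaks[1:]), positions_mb, side="right")
    seg = np.clip(seg, 0, len(labels) - 1)
    return labels[seg].astype(np.int8)


def _pool_carrier_counts(freqs: np.ndarray, n_pool: int) -> np.ndarray:
    """Carrier counts per pool haplotype rank: SNP j of population k is
    carried by the first round(H * f_kj) pool members.  Nested carrier
    sets make within-block D' maximal while matching pool frequencies
    to the population frequencies up to rounding."""
    return np.round(freqs * n_pool).astype(np.int64)


def simulate_cohort(cfg: SimulationConfig):
    """Simulate a full cohort.  Returns ``(g, v, s, truth)``.

    Clean genotypes follow the admixture model: in global mode the
    genotype at SNP j for sample i is Binomial(2, sum_k q_ik f_kj)
    (haplotype-level when pools or relatives require it); in local mode
    each haplotype's ancestry is a segment process along every
    chromosome with stationary distribution q_i.  Nuisance processes
    are then applied in the fixed documented order.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ancestral, freqs = simulate_frequencies(cfg, rng)
    v = _variant_frame(cfg, rng)
    m = cfg.m_variants
    groups = cfg.groups()
    n_total = sum(groups.values())

    q_rows, group_labels = [], []
    for grp, n in groups.items():
        q_rows.append(rng.dirichlet(cfg.group_alpha(grp), size=n))
        group_labels.extend([grp] * n)
    q = np.vstack(q_rows)

    use_haplotypes = (cfg.ancestry_mode == "local" or cfg.ld_block_size > 0
                      or cfg.n_parent_child_pairs > 0)
    pos_mb = v["pos"].to_numpy() / 1e6
    chrom_of = v["chrom"].to_numpy()
    chrom_ids = [str(c + 1) for c in range(cfg.n_chromosomes)]

    local_anc = None
    hap = None
    if use_haplotypes:
        # per-haplotype ancestry labels (2N x M)
        local_anc = np.empty((2 * n_total, m), dtype=np.int8)
        for i in range(n_total):
            for h in range(2):
                row = 2 * i + h
                if cfg.ancestry_mode == "global":
                    # ancestry varies freely locus to locus (no linkage)
                    local_anc[row] = rng.choice(
                        cfg.k_true, size=m, p=q[i]).astype(np.int8)
                else:
                    for c in chrom_ids:
                        sel = chrom_of == c
                        local_anc[row, sel] = _segment_labels(
                            cfg.chrom_length_bp / 1e6, pos_mb[sel], q[i],
                            cfg.switch_rate_per_mb, rng)
        if cfg.ld_block_size > 0:
            hap = _alleles_from_pools(cfg, freqs, local_anc, chrom_of,
                                      chrom_ids, rng)
        else:
            p_site = freqs[local_anc, np.arange(m)[None, :]]
            hap = rng.random((2 * n_total, m)) < p_site
        dos = (hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8))
    else:
        pi = q @ freqs
        dos = rng.binomial(2, pi).astype(np.int8)

    # sample metadata (before nuisances so they can reference it)
    ids = [f"S{i:04d}" for i in range(n_total)]
    sexes = np.where(rng.random(n_total) < 0.5, "male", "female")
    ages = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_total), 18, 95)
    diagnoses = _draw_diagnoses(cfg, rng, n_total)
    n_batches = max(1, int(cfg.batch_distortion[0]))
    batches = [f"batch{i % n_batches}" for i in range(n_total)]

    excluded_truth: dict = {}

    # X-like chromosome appended after autosomes (males hemizygous)
    fx = None
    if cfg.x_variants > 0:
        dos, v, fx = _append_x(cfg, dos, v, q, sexes, rng)
        m_all = m + cfg.x_variants
        excluded_truth["x_variants"] = {"freqs_x": fx}
    else:
        m_all = m

    # --- nuisances, fixed order -------------------------------------------
    if cfg.missing_rate > 0:
        mask = rng.random(dos.shape) < cfg.missing_rate
        dos[mask] = MISSING

    if cfg.diff_missing is not None:
        flag, extra_rate, frac = cfg.diff_missing
        flagged = np.array([flag in dx.split(";") if dx else False
                            for dx in diagnoses])
        n_dm = int(round(frac * m_all))
        dm_snps = rng.choice(m_all, size=n_dm, replace=False)
        sub = rng.random((flagged.sum(), n_dm)) < extra_rate
        block = dos[np.ix_(flagged, dm_snps)]
        block[sub] = MISSING
        dos[np.ix_(flagged, dm_snps)] = block
        excluded_truth["diff_missing_snps"] = np.sort(dm_snps)

    n_bad = int(cfg.batch_distortion[1])
    if n_bad > 0 and n_batches > 1:
        rate = float(cfg.batch_distortion[2])
        bad_snps = rng.choice(m_all, size=n_bad, replace=False)
        in_batch = np.array([b == "batch0" for b in batches])
        sub = dos[np.ix_(in_batch, bad_snps)]
        corrupt = (rng.random(sub.shape) < rate) & (sub != MISSING)
        # stylized cluster-calling failure: affected calls collapse to
        # the homozygote of the rarer allele, shifting the batch's
        # allele frequency at every affected SNP
        with np.errstate(invalid="ignore"):
            col_freq = np.nanmean(
                np.where(dos[:, bad_snps] == MISSING, np.nan,
                         dos[:, bad_snps]), axis=0) / 2.0
        collapse_to = np.where(col_freq < 0.5, 2, 0).astype(np.int8)
        sub[corrupt] = np.broadcast_to(collapse_to, sub.shape)[corrupt]
        dos[np.ix_(in_batch, bad_snps)] = sub
        excluded_truth["batch_bad_snps"] = np.sort(bad_snps)
        excluded_truth["batch_corrupted"] = "batch0"

    dup_pairs, child_pairs = [], []
    extra_rows, extra_meta = [], []
    for d in range(cfg.n_duplicates):
        src = d % n_total
        rep_id = f"{ids[src]}rep"
        extra_rows.append(dos[src].copy())
        extra_meta.append((rep_id, group_labels[src], sexes[src], ages[src],
                           diagnoses[src], True))
        dup_pairs.append((ids[src], rep_id))
        q = np.vstack([q, q[src][None, :]])
    for pc in range(cfg.n_parent_child_pairs):
        src = (cfg.n_duplicates + pc) % n_total
        child_id = f"{ids[src]}child"
        child_sex = "male" if rng.random() < 0.5 else "female"
        child = _mendelian_child(dos[src], q[src], freqs, fx, m_all, m,
                                 child_sex, rng)
        extra_rows.append(child)
        extra_meta.append((child_id, group_labels[src], child_sex,
                           float(np.clip(ages[src] - 25, 18, None)),
                           "", False))
        child_pairs.append((ids[src], child_id))
        q = np.vstack([q, q[src][None, :]])
    if extra_rows:
        dos = np.vstack([dos] + [r[None, :] for r in extra_rows])
        for rep_id, grp, sx, age, dx, is_rep in extra_meta:
            ids.append(rep_id)
            group_labels.append(grp)
            sexes = np.append(sexes, sx)
            ages = np.append(ages, age)
            diagnoses.append(dx)
            batches.append(f"batch{(len(batches)) % n_batches}")
    excluded_truth["duplicates"] = dup_pairs
    excluded_truth["parent_child"] = child_pairs

    true_sex = sexes.copy()
    if cfg.sex_mismatch_rate > 0:
        n_flip = int(round(cfg.sex_mismatch_rate * len(ids)))
        flip_idx = rng.choice(len(ids), size=n_flip, replace=False)
        sexes = sexes.copy()
        for i in flip_idx:
            sexes[i] = "male" if sexes[i] == "female" else "female"
        excluded_truth["sex_mismatches"] = [ids[i] for i in np.sort(flip_idx)]
    else:
        excluded_truth["sex_mismatches"] = []

    g = GenotypeMatrix(dos, ids)
    s = sample_table(ids, group=group_labels, sex=list(sexes),
                     age=ages, diagnoses=diagnoses, batch=batches,
                     is_replicate=[bool(i) for i in
                                   [sid.endswith("rep") for sid in ids]])
    s, pheno_params = simulate_phenotype(g, s, cfg, rng=rng)

    truth = GroundTruth(
        q_true=q,
        freqs_true=freqs,
        local_ancestry=(local_anc if cfg.ancestry_mode == "local" else None),
        excluded_truth={**excluded_truth, "true_sex": list(true_sex)},
        phenotype_params=pheno_params,
    )
    return g, v, s, truth


def _draw_diagnoses(cfg, rng, n) -> list[str]:
    flags = {name: rng.random(n) < prev
             for name, prev in cfg.diagnosis_prevalence.items()}
    out = []
    for i in range(n):
        out.append(";".join(name for name, hit in flags.items() if hit[i]))
    return out


def _alleles_from_pools(cfg, freqs, local_anc, chrom_of, chrom_ids, rng):
    """Draw haplotype alleles from per-(population, block) pools.

    Pools have nested carrier sets (see :func:`_pool_carrier_counts`):
    a pool member of rank u carries SNP j iff u < round(H * f_kj), so a
    single uniform rank per haplotype per block induces maximal
    within-block LD while per-SNP frequencies track the population
    frequencies.  Ancestry at the first SNP of a block selects the
    population pool for the whole block.
    """
    n_hap, m = local_anc.shape
    hap = np.zeros((n_hap, m), dtype=bool)
    counts = _pool_carrier_counts(freqs, cfg.n_haplotypes_per_pool)
    for c in chrom_ids:
        snp_idx = np.flatnonzero(chrom_of == c)
        for start in range(0, len(snp_idx), cfg.ld_block_size):
            block = snp_idx[start:start + cfg.ld_block_size]
            anc = local_anc[:, block[0]]
            ranks = rng.integers(cfg.n_haplotypes_per_pool, size=n_hap)
            hap[:, block] = ranks[:, None] < counts[anc][:, block]
    return hap


def _append_x(cfg, dos, v, q, sexes, rng):
    """Simulate an X-like chromosome: females diploid, males hemizygous
    with the single allele recorded as a homozygous call (dosage 0/2)."""
    n = dos.shape[0]
    mx = cfg.x_variants
    anc = rng.uniform(0.05, 0.95, size=mx)
    fst = np.asarray(cfg.fst, dtype=float)
    fx = np.empty((cfg.k_true, mx))
    for k, f in enumerate(fst):
        lam = (1 - f) / f
        fx[k] = rng.beta(anc * lam, (1 - anc) * lam)
    fx = np.clip(fx, 0.01, 0.99)
    px = q @ fx
    female = sexes == "female"
    xdos = np.empty((n, mx), dtype=np.int8)
    xdos[female] = rng.binomial(2, px[female]).astype(np.int8)
    male_allele = rng.random((int((~female).sum()), mx)) < px[~female]
    xdos[~female] = (2 * male_allele).astype(np.int8)
    pos = np.sort(rng.choice(50_000_000, size=mx, replace=False)) + 1
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=mx)
    vx = variant_table(
        [f"rsX{j + 1}" for j in range(mx)], ["X"] * mx, pos,
        [_ALLELE_PAIRS[i][0] for i in pair_idx],
        [_ALLELE_PAIRS[i][1] for i in pair_idx])
    v_all = pd.concat([v, vx], ignore_index=True)
    return np.hstack([dos, xdos]), v_all, fx


def _mendelian_child(parent_dos, parent_q, freqs, fx, m_all, m_auto,
                     child_sex, rng):
    """One transmitted allele per SNP drawn from the parent's genotype,
    the other from the population given the parent's admixture.  On the
    X-like tail a male child is hemizygous for the transmitted allele;
    a female child gets a second allele from the population."""
    child = np.full(m_all, MISSING, dtype=np.int8)
    called = parent_dos != MISSING
    transmitted = rng.random(m_all) < (np.clip(parent_dos, 0, 2) / 2.0)
    pi = parent_q @ freqs
    other = rng.random(m_auto) < pi
    ca = transmitted[:m_auto].astype(np.int8) + other.astype(np.int8)
    child[:m_auto] = np.where(called[:m_auto], ca, MISSING)
    if m_all > m_auto:
        t = transmitted[m_auto:].astype(np.int8)
        if child_sex == "male":
            tail = 2 * t
        else:
            px = parent_q @ fx
            tail = t + (rng.random(m_all - m_auto) < px).astype(np.int8)
        child[m_auto:] = np.where(called[m_auto:], tail, MISSING)
    return child


def simulate_phenotype(g: GenotypeMatrix, s: pd.DataFrame,
                       cfg: SimulationConfig, rng=None):
    """Log-normal BMI with age, sex and additive SNP effects.

    log BMI = mu + sigma_env * (beta_age z(age) + beta_sex male +
    sum_j beta_j z(dosage_j) + eps), eps ~ N(0, 1), so the beta are in
    residual-SD units.  With sigma_env = 0 the noise and all scaled
    effects vanish and BMI is constant exp(mu).  Returns the updated
    sample table and an echo of the parameters used.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_samples
    age = s["age"].to_numpy(dtype=float)
    age_z = np.zeros(n) if np.nanstd(age) == 0 else (
        (age - np.nanmean(age)) / np.nanstd(age))
    male = (s["sex"] == "male").to_numpy(dtype=float)
    lin = cfg.beta_age * age_z + cfg.beta_sex * male
    for j, beta in cfg.causal_snps:
        d = g.called_float()[:, j]
        d = np.where(np.isnan(d), np.nanmean(d), d)
        sd = d.std()
        if sd > 0:
            lin = lin + beta * (d - d.mean()) / sd
    log_bmi = cfg.mu_log_bmi + cfg.sigma_env * (lin + rng.standard_normal(n))
    out = s.copy()
    out["bmi"] = np.exp(log_bmi)
    params = {
        "mu_log_bmi": cfg.mu_log_bmi, "beta_age": cfg.beta_age,
        "beta_sex": cfg.beta_sex, "causal_snps": tuple(cfg.causal_snps),
        "sigma_env": cfg.sigma_env,
    }
    return out, params
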