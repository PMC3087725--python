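"""Pairwise D' from unphased genotypes and confidence-interval
haplotype blocks.

Two-locus haplotype frequencies are estimated by EM over the double-
heterozygote phase ambiguity.  D' is |D| over its margin-determined
bound; its confidence interval comes from a normalized likelihood grid
over D' in [0, 1] (margins fixed at their estimates, grid step 0.001),
taking the central mass percentiles.  Blocks follow the confidence-
interval method: a pair is in "strong LD" when its CI is (>= 0.70,
>= 0.98) and shows "strong recombination" when the CI top is < 0.90; a
candidate block is an outermost strong-LD pair with at least 95% of
informative interior pairs in strong LD, and candidates are accepted
greedily longest-span first.  Haplotype frequencies within a block are
estimated by exact multi-locus EM (capped at 12 SNPs).
"""
from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING, allele_frequencies


@dataclasses.dataclass
class PairwiseLD:
    i: int
    j: int
    hap_freqs: np.ndarray      # (p_AB, p_Ab, p_aB, p_ab)
    d: float
    dprime: float
    r2: float
    ci_low: float
    ci_high: float
    n_informative: int


@dataclasses.dataclass
class GabrielParams:
    ci_low_strong: float = 0.70
    ci_high_strong: float = 0.98
    ci_high_recomb: float = 0.90
    frac_strong_min: float = 0.95
    maf_min: float = 0.05
    confidence: float = 0.95
    grid_step: float = 0.001


@dataclasses.dataclass
class HaplotypeBlock:
    chrom: str
    first: int                  # inclusive variant indices
    last: int
    n_snps: int
    haplotypes: pd.DataFrame | None
    frac_strong: float


def pair_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """3x3 genotype count table over samples called at both loci;
    entry [i, j] counts dosage pair (i, j)."""
    both = (x != MISSING) & (y != MISSING)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (x[both], y[both]), 1)
    return table


def _table_loglik(t: np.ndarray, h: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 dosage-pair table under
    haplotype frequencies h = (AB, Ab, aB, ab), random mating."""
    probs = {
        (2, 2): h[0] ** 2, (2, 1): 2 * h[0] * h[1], (2, 0): h[1] ** 2,
        (1, 2): 2 * h[0] * h[2], (0, 2): h[2] ** 2,
        (1, 1): 2 * h[0] * h[3] + 2 * h[1] * h[2],
        (1, 0): 2 * h[1] * h[3], (0, 1): 2 * h[2] * h[3], (0, 0): h[3] ** 2,
    }
    ll = 0.0
    for (i, j), pr in probs.items():
        if t[i, j] > 0:
            ll += t[i, j] * np.log(max(pr, 1e-300))
    return float(ll)


def two_locus_em(table: np.ndarray, tol: float = 1e-9,
                 max_iter: int = 1000, return_trace: bool = False):
    """EM haplotype frequencies (AB, Ab, aB, ab) from a 3x3 dosage-pair
    count table; A/B denote the counted alleles.  Starts at linkage
    equilibrium; log-likelihood is non-decreasing (returned when
    ``return_trace``)."""
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n <= 0:
        raise ValueError("empty genotype table")
    # haplotype contributions resolved except for the double heterozygote
    base_ab = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    base_a_b = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    base_b_a = 2 * t[0, 2] + t[1, 2] + t[0, 1]
    base__ = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    c = t[1, 1]
    p_a = (2 * t[2].sum() + t[1].sum()) / (2 * n)
    p_b = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    h = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    trace = [_table_loglik(t, h)]
    for _ in range(max_iter):
        coupling = h[0] * h[3]
        repulsion = h[1] * h[2]
        x = c * coupling / (coupling + repulsion) if c > 0 and \
            (coupling + repulsion) > 0 else 0.0
        counts = np.array([base_ab + x, base_a_b + (c - x),
                           base_b_a + (c - x), base__ + x])
        new_h = counts / (2 * n)
        converged = np.abs(new_h - h).max() < tol
        h = new_h
        trace.append(_table_loglik(t, h))
        if converged:
            break
    if return_trace:
        return h, np.array(trace)
    return h


def _pair_loglik_grid(t: np.ndarray, p_a: float, p_b: float,
                      dmax: float, grid: np.ndarray) -> np.ndarray:
    """Log-likelihood of the 3x3 table along a D' grid with margins
    fixed (alleles oriented so D >= 0)."""
    d_vals = grid * dmax
    h_ab = np.clip(p_a * p_b + d_vals, 1e-12, 1.0)
    h_a_b = np.clip(p_a * (1 - p_b) - d_vals, 1e-12, 1.0)
    h_b_a = np.clip((1 - p_a) * p_b - d_vals, 1e-12, 1.0)
    h__ = np.clip((1 - p_a) * (1 - p_b) + d_vals, 1e-12, 1.0)
    # genotype-pair probabilities under random union of haplotypes
    probs = {
        (2, 2): h_ab ** 2, (2, 1): 2 * h_ab * h_a_b, (2, 0): h_a_b ** 2,
        (1, 2): 2 * h_ab * h_b_a, (0, 2): h_b_a ** 2,
        (1, 1): 2 * h_ab * h__ + 2 * h_a_b * h_b_a,
        (1, 0): 2 * h_a_b * h__, (0, 1): 2 * h_b_a * h__, (0, 0): h__ ** 2,
    }
    ll = np.zeros_like(grid)
    for (i, j), pr in probs.items():
        if t[i, j] > 0:
            ll = ll + t[i, j] * np.log(np.clip(pr, 1e-300, None))
    return ll


def dprime_ci(x: np.ndarray, y: np.ndarray, i: int = 0, j: int = 1,
              params: GabrielParams | None = None) -> PairwiseLD:
    """Pairwise LD summary with a likelihood-grid D' confidence
    interval.  Raises on a monomorphic locus (uninformative pair)."""
    prm = params or GabrielParams()
    t = pair_counts(np.asarray(x), np.asarray(y))
    n = int(t.sum())
    h = two_locus_em(t)
    p_a = h[0] + h[1]
    p_b = h[0] + h[2]
    if min(p_a, 1 - p_a, p_b, 1 - p_b) <= 0:
        raise ValueError("monomorphic locus: D' undefined")
    d = h[0] - p_a * p_b
    if d < 0:
        # relabel locus-2 alleles so the association is positive
        t = t[:, ::-1]
        p_b = 1 - p_b
        h = h[[1, 0, 3, 2]]
        d = -d
    dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    dprime = 0.0 if dmax <= 0 else min(d / dmax, 1.0)
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    grid = np.arange(0.0, 1.0 + prm.grid_step / 2, prm.grid_step)
    ll = _pair_loglik_grid(t, p_a, p_b, dmax, grid)
    mass = np.exp(ll - ll.max())
    mass /= mass.sum()
    cdf = np.cumsum(mass)
    tail = (1.0 - prm.confidence) / 2.0
    low_idx = int(np.searchsorted(cdf, tail, side="right"))
    high_idx = int(np.searchsorted(cdf, 1.0 - tail, side="left"))
    ci_low = float(grid[min(low_idx, len(grid) - 1)])
    ci_high = float(grid[min(high_idx, len(grid) - 1)])
    return PairwiseLD(i=i, j=j, hap_freqs=h, d=float(d),
                      dprime=float(dprime), r2=float(r2),
                      ci_low=min(ci_low, float(dprime)),
                      ci_high=max(ci_high, float(dprime)),
                      n_informative=n)


def pairwise_ld_table(g: GenotypeMatrix, indices: np.ndarray,
                      params: GabrielParams | None = None) -> pd.DataFrame:
    """Long-form pairwise LD for every informative pair (both MAF above
    the gate) in a variant span."""
    prm = params or GabrielParams()
    indices = np.asarray(indices)
    freq = allele_frequencies(g.subset(variants=indices))
    maf = np.minimum(freq, 1 - freq)
    informative = np.nan_to_num(maf, nan=0.0) >= prm.maf_min
    rows = []
    d = g.dosages
    for a, b in itertools.combinations(range(len(indices)), 2):
        if not (informative[a] and informative[b]):
            continue
        try:
            ld = dprime_ci(d[:, indices[a]], d[:, indices[b]], a, b, prm)
        except ValueError:
            continue
        rows.append({"i": a, "j": b, "vi": int(indices[a]),
                     "vj": int(indices[b]), "d": ld.d, "dprime": ld.dprime,
                     "r2": ld.r2, "ci_low": ld.ci_low, "ci_high": ld.ci_high,
                     "n": ld.n_informative})
    return pd.DataFrame(rows, columns=["i", "j", "vi", "vj", "d", "dprime",
                                       "r2", "ci_low", "ci_high", "n"])


def gabriel_blocks(g: GenotypeMatrix, v: pd.DataFrame, region: np.ndarray,
                   params: GabrielParams | None = None,
                   with_haplotypes: bool = True) -> list[HaplotypeBlock]:
    """Confidence-interval haplotype blocks over a sorted variant span.

    Pairs are classified from their D' CI; candidate blocks (outermost
    strong-LD pair, >= 95% of informative interior pairs strong) are
    accepted longest-span-first (bp; ties leftmost), discarding
    overlaps.
    """
    prm = params or GabrielParams()
    region = np.asarray(region)
    if len(region) < 2:
        return []
    chroms = v["chrom"].to_numpy()[region]
    if len(set(chroms)) > 1:
        raise ValueError("region spans multiple chromosomes")
    pos = v["pos"].to_numpy()[region]
    if not (np.diff(pos) > 0).all():
        raise ValueError("region not sorted by position")
    ld = pairwise_ld_table(g, region, prm)
    if ld.empty:
        return []
    # conclusive pairs only: strong LD or strong recombination; pairs
    # with wide (inconclusive) CIs carry no evidence either way
    strong = {}
    conclusive = {}
    for _, row in ld.iterrows():
        key = (int(row["i"]), int(row["j"]))
        is_strong = (row["ci_low"] >= prm.ci_low_strong
                     and row["ci_high"] >= prm.ci_high_strong)
        is_recomb = row["ci_high"] < prm.ci_high_recomb
        strong[key] = is_strong
        conclusive[key] = is_strong or is_recomb
    m = len(region)
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong.get((i, j), False):
                continue
            inside = [strong[k] for k in conclusive
                      if conclusive[k] and i <= k[0] and k[1] <= j]
            if not inside:
                continue
            frac = float(np.mean(inside))
            if frac >= prm.frac_strong_min:
                candidates.append((pos[j] - pos[i], i, j, frac))
    # longest span first, ties leftmost
    candidates.sort(key=lambda c: (-c[0], c[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j, frac in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        haps = None
        if with_haplotypes and (j - i + 1) <= 12:
            haps = block_haplotypes(g, region[i:j + 1])
        blocks.append(HaplotypeBlock(
            chrom=str(chroms[0]), first=int(region[i]), last=int(region[j]),
            n_snps=j - i + 1, haplotypes=haps, frac_strong=frac))
    blocks.sort(key=lambda b: b.first)
    return blocks


def block_haplotypes(g: GenotypeMatrix, block_indices: np.ndarray,
                     min_freq: float = 0.01, tol: float = 1e-8,
                     max_iter: int = 500, return_trace: bool = False):
    """Exact multi-locus EM haplotype frequencies for a block of at
    most 12 SNPs.

    Samples with any missing call in the block are dropped.  Haplotypes
    are reported as strings of counted-allele counts ('1' = counted
    allele present) with frequency >= ``min_freq``, sorted by
    frequency.
    """
    block_indices = np.asarray(block_indices)
    L = len(block_indices)
    if L > 12:
        raise ValueError(f"block of {L} SNPs exceeds the exact-EM cap of 12; "
                         "partition the block")
    d = g.dosages[:, block_indices]
    complete = (d != MISSING).all(axis=1)
    d = d[complete]
    if d.shape[0] == 0:
        raise ValueError("no samples fully called in block")
    # enumerate compatible haplotype pairs per distinct genotype row
    patterns, inverse, weights = np.unique(d, axis=0, return_inverse=True,
                                           return_counts=True)
    pair_sets = [_compatible_pairs(row) for row in patterns]
    n_h = 2 ** L
    f = np.full(n_h, 1.0 / n_h)
    n = d.shape[0]
    trace = []
    for _ in range(max_iter):
        new = np.zeros(n_h)
        ll = 0.0
        for pat_i, pairs in enumerate(pair_sets):
            w = weights[pat_i]
            probs = np.array([f[a] * f[b] * (2.0 if a != b else 1.0)
                              for a, b in pairs])
            tot = probs.sum()
            ll += w * np.log(max(tot, 1e-300))
            if tot <= 0:
                probs = np.ones(len(pairs))
                tot = probs.sum()
            probs = probs / tot
            for (a, b), pr in zip(pairs, probs):
                new[a] += w * pr
                new[b] += w * pr
        new /= 2.0 * n
        trace.append(ll)        # log-lik at the pre-update frequencies
        converged = np.abs(new - f).max() < tol
        f = new
        if converged:
            break
    keep = np.flatnonzero(f >= min_freq)
    labels = ["".join("1" if (h >> (L - 1 - k)) & 1 else "0"
                      for k in range(L)) for h in keep]
    out = pd.DataFrame({"haplotype": labels, "frequency": f[keep]})
    out = out.sort_values("frequency", ascending=False, ignore_index=True)
    if return_trace:
        return out, np.array(trace)
    return out


def _compatible_pairs(row: np.ndarray) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs consistent with a complete
    multi-locus genotype (bit 1 = counted allele, MSB = first SNP)."""
    L = len(row)
    het = np.flatnonzero(row == 1)
    base = 0
    for k, dk in enumerate(row):
        if dk == 2:
            base |= 1 << (L - 1 - k)
    if len(het) == 0:
        return [(base, base)]
    pairs = set()
    for assign in itertools.product((0, 1), repeat=len(het)):
        a, b = base, base
        for bit, k in zip(assign, het):
            if bit:
                a |= 1 << (L - 1 - k)
            else:
                b |= 1 << (L - 1 - k)
        pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def compare_groups(g: GenotypeMatrix, v: pd.DataFrame, s: pd.DataFrame,
                   region: np.ndarray, groups=None, min_group_size: int = 20,
                   focal_rsid: str | None = None,
                   params: GabrielParams | None = None):
    """Per-group block structure over the same region.

    Returns ``(blocks_by_group, summary)`` where the summary lists each
    group's block count, spans, and whether the focal variant falls
    inside a block.  Groups below ``min_group_size`` are skipped.
    """
    region = np.asarray(region)
    if groups is None:
        groups = [grp for grp in s["group"].unique()]
    focal_idx = None
    if focal_rsid is not None:
        hit = np.flatnonzero(v["rsid"].to_numpy()[region] == focal_rsid)
        if len(hit) == 0:
            raise ValueError(f"focal variant {focal_rsid!r} not in region")
        focal_idx = int(region[hit[0]])
    blocks_by_group = {}
    rows = []
    for grp in groups:
        members = np.flatnonzero((s["group"] == grp).to_numpy())
        if len(members) < min_group_size:
            continue
        sub = g.subset(samples=members)
        blocks = gabriel_blocks(sub, v, region, params)
        blocks_by_group[grp] = blocks
        in_block = (any(b.first <= focal_idx <= b.last for b in blocks)
                    if focal_idx is not None else None)
        rows.append({
            "group": grp, "n_samples": len(members),
            "n_blocks": len(blocks),
            "spans": ";".join(f"{b.first}-{b.last}" for b in blocks),
            "mean_block_snps": (float(np.mean([b.n_snps for b in blocks]))
                                if blocks else 0.0),
            "focal_in_block": in_block,
        })
    summary = pd.DataFrame(rows)
    return blocks_by_group, summary
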