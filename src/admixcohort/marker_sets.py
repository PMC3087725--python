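"""Analysis marker sets: sliding-window LD pruning and ancestry-
informative marker (AIM) selection.

Pruning follows the classic genotype-r2 sliding window: within each
50-SNP window (per chromosome), while any retained pair exceeds the r2
ceiling one member is removed — the one with higher missingness, then
lower MAF, then the later position — and the window advances 5 SNPs.
AIM selection scores each SNP by the delta statistic, the sum over the
two alleles of absolute frequency differences between two reference
panels (= 2 |p1 - p2|), filters at a threshold and prunes survivors.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING, allele_frequencies

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MarkerSet:
    name: str
    indices: np.ndarray          # strictly increasing variant indices
    provenance: dict

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) and not (np.diff(self.indices) > 0).all():
            raise ValueError("marker indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def rsids(self, v: pd.DataFrame) -> list[str]:
        return v["rsid"].iloc[self.indices].tolist()

    def write(self, v: pd.DataFrame, path) -> None:
        """One rsid per line (PLINK --extract compatible)."""
        with open(path, "w") as fh:
            for r in self.rsids(v):
                fh.write(r + "\n")


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over complete pairs.

    Undefined (monomorphic overlap or < 2 complete pairs) returns NaN;
    the pruner treats NaN as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = (x != MISSING) & (y != MISSING)
    if both.sum() < 2:
        return np.nan
    xs, ys = x[both], y[both]
    if xs.std() == 0 or ys.std() == 0:
        return np.nan
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise r2 within a dosage window (N x w) honouring missingness,
    via indicator-matrix products; NaN where undefined."""
    valid = (d != MISSING).astype(float)
    z = np.where(d == MISSING, 0.0, d).astype(float)
    n = valid.T @ valid
    sx = z.T @ valid                   # sum of x over joint support
    sy = sx.T
    sxy = z.T @ z
    sxx = (z * z).T @ valid
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sy / n)
        vx = sxx / n - (sx / n) ** 2
        vy = syy / n - (sy / n) ** 2
        r2 = cov ** 2 / (vx * vy)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_prune(g: GenotypeMatrix, v: pd.DataFrame, window_snps: int = 50,
             step_snps: int = 5, r2_max: float = 0.2,
             name: str = "pruned") -> MarkerSet:
    """Greedy sliding-window LD pruning (r2 ceiling ``r2_max``).

    Chromosomes are processed independently; variants must be sorted by
    (chrom, pos).  Within the active window, offending pairs are
    resolved one victim at a time with the deterministic rule
    (missingness, then MAF, then later position).
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    _check_sorted(v)
    miss = g.missing_mask().mean(axis=0)
    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.ones(g.n_variants, dtype=bool)
    chroms = v["chrom"].to_numpy()
    changed = True
    while changed:                      # windows slide over the retained set
        changed = False
        for chrom in v["chrom"].unique():
            idx = np.flatnonzero((chroms == chrom) & keep)
            for start in range(0, len(idx), step_snps):
                win = idx[start:start + window_snps]
                if len(win) >= 2 and _prune_window(g, win, keep, miss, maf,
                                                   r2_max):
                    changed = True
                if start + window_snps >= len(idx):
                    break
    # certify the contract at every retained-sequence distance < window
    while True:
        pairs = _violating_pairs(g, chroms, keep, window_snps, r2_max)
        if not pairs:
            break
        for a, b in pairs:
            if keep[a] and keep[b]:
                keep[_pick_victim(a, b, miss, maf)] = False
    indices = np.flatnonzero(keep)
    return MarkerSet(name, indices, {
        "method": "ld_prune",
        "window_snps": window_snps, "step_snps": step_snps, "r2_max": r2_max,
        "n_before": g.n_variants, "n_after": int(keep.sum()),
    })


def _prune_window(g, win, keep, miss, maf, r2_max) -> int:
    live = win[keep[win]]
    if len(live) < 2:
        return 0
    r2 = _window_r2(g.dosages[:, live])
    over = np.triu(np.nan_to_num(r2, nan=0.0) > r2_max, k=1)
    n_removed = 0
    while over.any():
        a, b = np.argwhere(over)[0]       # first offending pair in scan order
        victim = _pick_victim(live[a], live[b], miss, maf)
        vi = a if live[a] == victim else b
        over[vi, :] = False
        over[:, vi] = False
        keep[victim] = False
        n_removed += 1
    return n_removed


def _violating_pairs(g, chroms, keep, window_snps, r2_max):
    """All retained pairs closer than ``window_snps`` in the retained
    sequence with r2 above the ceiling, in scan order."""
    idx = np.flatnonzero(keep)
    if len(idx) < 2:
        return []
    d = g.dosages[:, idx].astype(float)
    valid = d != MISSING
    z = np.where(valid, d, 0.0)
    ch = chroms[idx]
    pairs = []
    for off in range(1, min(window_snps, len(idx))):
        both = valid[:, :-off] & valid[:, off:]
        n = both.sum(axis=0).astype(float)
        zx = np.where(both, z[:, :-off], 0.0)
        zy = np.where(both, z[:, off:], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = zx.sum(axis=0) / n
            my = zy.sum(axis=0) / n
            cov = (zx * zy).sum(axis=0) / n - mx * my
            vx = (zx * zx).sum(axis=0) / n - mx ** 2
            vy = (zy * zy).sum(axis=0) / n - my ** 2
            r2 = cov ** 2 / (vx * vy)
        hit = ((ch[:-off] == ch[off:]) & (n >= 2) & np.isfinite(r2)
               & (r2 > r2_max))
        for a in np.flatnonzero(hit):
            pairs.append((int(idx[a]), int(idx[a + off])))
    pairs.sort()
    return pairs


def _pick_victim(i: int, j: int, miss: np.ndarray, maf: np.ndarray) -> int:
    """Higher missingness loses; tie -> lower MAF loses; tie -> the later
    position (larger index) loses."""
    if miss[i] != miss[j]:
        return i if miss[i] > miss[j] else j
    if maf[i] != maf[j]:
        return i if maf[i] < maf[j] else j
    return max(i, j)


def _check_sorted(v: pd.DataFrame) -> None:
    for chrom, sub in v.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError(f"variants on chrom {chrom} not sorted by position")


def prune_violations(g: GenotypeMatrix, v: pd.DataFrame, markers: MarkerSet,
                     window_snps: int = 50, r2_max: float = 0.2) -> int:
    """Exhaustive post-scan of the retained sequence: number of retained
    pairs within any ``window_snps`` window whose r2 exceeds the
    ceiling.  Zero certifies the pruning contract."""
    idx = markers.indices
    chrom = v["chrom"].to_numpy()[idx]
    d = g.dosages[:, idx].astype(float)
    valid = d != MISSING
    z = np.where(valid, d, 0.0)
    count = 0
    for off in range(1, window_snps):
        if off >= d.shape[1]:
            break
        both = valid[:, :-off] & valid[:, off:]
        n = both.sum(axis=0).astype(float)
        zx = np.where(both, z[:, :-off], 0.0)
        zy = np.where(both, z[:, off:], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = zx.sum(axis=0) / n
            my = zy.sum(axis=0) / n
            cov = (zx * zy).sum(axis=0) / n - mx * my
            vx = (zx * zx).sum(axis=0) / n - mx ** 2
            vy = (zy * zy).sum(axis=0) / n - my ** 2
            r2 = cov ** 2 / (vx * vy)
        ok = (chrom[:-off] == chrom[off:]) & (n >= 2) & np.isfinite(r2)
        count += int((r2[ok] > r2_max).sum())
    return count


def delta_statistic(freq_panel1: np.ndarray,
                    freq_panel2: np.ndarray) -> np.ndarray:
    """delta_j = |p1 - p2| + |(1-p1) - (1-p2)| = 2 |p1 - p2| in [0, 2]."""
    p1 = np.asarray(freq_panel1, dtype=float)
    p2 = np.asarray(freq_panel2, dtype=float)
    for p in (p1, p2):
        with np.errstate(invalid="ignore"):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("frequencies must lie in [0, 1]")
    return 2.0 * np.abs(p1 - p2)


def select_aims(g: GenotypeMatrix, v: pd.DataFrame, delta: np.ndarray,
                delta_min: float = 0.3, window_snps: int = 50,
                step_snps: int = 5, r2_max: float = 0.2) -> MarkerSet:
    """Keep SNPs with delta >= ``delta_min``, then LD-prune the
    survivors.  The default threshold 0.3 is a package choice exposed in
    configuration."""
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (g.n_variants,):
        raise ValueError("delta must have one score per variant")
    pass_idx = np.flatnonzero(np.nan_to_num(delta, nan=-1.0) >= delta_min)
    if len(pass_idx) == 0:
        raise ValueError(f"no SNPs pass delta >= {delta_min}")
    sub_g = g.subset(variants=pass_idx)
    sub_v = v.iloc[pass_idx].reset_index(drop=True)
    pruned = ld_prune(sub_g, sub_v, window_snps, step_snps, r2_max)
    indices = pass_idx[pruned.indices]
    return MarkerSet("aims", indices, {
        "method": "delta_filter+ld_prune", "delta_min": delta_min,
        "n_before": g.n_variants, "n_after_delta": len(pass_idx),
        "n_after": len(indices),
        "window_snps": window_snps, "step_snps": step_snps, "r2_max": r2_max,
    })
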