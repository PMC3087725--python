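"""End-to-end orchestration of the analysis stages on one cohort.

``run_demo`` simulates a three-group admixed clinical cohort and walks
the full sequence — QC cascade, marker sets, IBS/MDS and PCA, the
local-vs-global ancestry window scan, EM admixture over a range of K,
LD blocks in a focal region per group, and the BMI association scan —
writing every table (tab-delimited, with a provenance comment line)
plus a human-readable summary report.  A fixed seed reproduces the
report byte for byte.
"""
from __future__ import annotations

import dataclasses
import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import bmi_residuals, genomic_inflation, snp_association
from .config import PipelineConfig
from .io_formats import write_metadata, write_plink
from .ld_blocks import compare_groups
from .marker_sets import delta_statistic, ld_prune, prune_violations, select_aims
from .qc import apply_cascade
from .structure_inference import (admixture_em, classical_mds, continuum_sort,
                                  ibs_matrix, local_global_scan, loglik_by_k,
                                  pca)
from .synthetic_cohort import SimulationConfig, simulate_cohort

log = logging.getLogger(__name__)


def default_demo_simulation(seed: int = 0) -> SimulationConfig:
    """The demo cohort: three self-identified groups with distinct
    admixture profiles over K=3 ancestral populations (two groups
    heavily admixed, one nearly unadmixed), LD pools, and every
    nuisance switched on at a modest level."""
    return SimulationConfig(
        n_samples={"groupA": 200, "groupB": 200, "groupC": 200},
        m_variants=20_000,
        n_chromosomes=4,
        chrom_length_bp=120_000_000,
        k_true=3,
        fst=(0.15, 0.15, 0.15),
        alpha={"groupA": (6.0, 2.0, 0.5), "groupB": (0.5, 8.0, 0.5),
               "groupC": (2.0, 2.5, 4.0)},
        ancestry_mode="local",
        switch_rate_per_mb=0.05,
        ld_block_size=10,
        n_haplotypes_per_pool=8,
        missing_rate=0.01,
        diff_missing=("diabetes", 0.05, 0.02),
        batch_distortion=(3, 50, 0.3),
        n_duplicates=3,
        n_parent_child_pairs=1,
        sex_mismatch_rate=0.005,
        x_variants=300,
        beta_age=0.15,
        beta_sex=0.1,
        causal_snps=((100, 0.25),),
        sigma_env=0.15,
        seed=seed,
    )


def _write_table(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# admixcohort {__version__} | {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_demo(seed: int, outdir, cfg: PipelineConfig | None = None,
             write_genotypes: bool = False) -> dict:
    """Run every stage on a simulated cohort; returns a summary dict.

    Raises if any stage invariant fails, so a zero exit certifies the
    whole chain.
    """
    cfg = cfg or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = io.StringIO()

    def say(msg: str) -> None:
        report.write(msg + "\n")
        log.info(msg)

    sim = (default_demo_simulation(seed)
           if cfg.simulation == SimulationConfig()
           else dataclasses.replace(cfg.simulation, seed=seed))
    say(f"admixcohort {__version__} demo | seed={seed}")
    say(f"simulating cohort: {sim.groups()} groups, {sim.m_variants} SNPs, "
        f"K_true={sim.k_true}, mode={sim.ancestry_mode}")
    g, v, s, truth = simulate_cohort(sim)
    if write_genotypes:
        write_plink(g, v, s, outdir / "cohort")
        write_metadata(s, outdir / "cohort.meta.tsv")

    # --- QC -----------------------------------------------------------
    g2, v2, s2, ledger = apply_cascade(g, v, s, cfg.thresholds,
                                       diff_missing_flag="diabetes")
    ledger.validate()
    _write_table(ledger.to_frame(), outdir / "qc_ledger.tsv",
                 f"QC cascade, seed={seed}")
    say(f"QC: {g.n_samples}->{g2.n_samples} samples, "
        f"{g.n_variants}->{g2.n_variants} SNPs (ledger conserves counts)")

    # --- marker sets --------------------------------------------------
    mk = cfg.markers
    pruned = ld_prune(g2, v2, mk.window_snps, mk.step_snps, mk.r2_max)
    violations = prune_violations(g2, v2, pruned, mk.window_snps, mk.r2_max)
    if violations:
        raise RuntimeError(f"pruning contract violated: {violations} pairs")
    say(f"LD pruning: {pruned.provenance['n_before']} -> {len(pruned)} SNPs "
        f"(r2<={mk.r2_max}, contract clean)")
    # delta AIMs scored between the first two ancestral frequency panels
    delta = delta_statistic(truth.freqs_true[0], truth.freqs_true[1])
    delta_full = np.zeros(g2.n_variants)
    rsid_to_col = {r: i for i, r in enumerate(v["rsid"])}
    for col2, rsid in enumerate(v2["rsid"]):
        j = rsid_to_col[rsid]
        delta_full[col2] = delta[j] if j < sim.m_variants else 0.0
    aims = select_aims(g2, v2, delta_full, mk.delta_min, mk.window_snps,
                       mk.step_snps, mk.r2_max)
    say(f"AIM selection: delta>={mk.delta_min} then prune -> {len(aims)} SNPs")

    # --- global structure --------------------------------------------
    ibs = ibs_matrix(g2.subset(variants=pruned.indices))
    mds = classical_mds(ibs, n_dims=4)
    _write_table(pd.DataFrame(mds.coords,
                              columns=[f"dim{i+1}" for i in range(4)])
                 .assign(sample_id=g2.sample_ids, group=s2["group"].values),
                 outdir / "mds_coords.tsv", f"classical MDS on IBS, seed={seed}")
    pc = pca(g2, pruned, n_components=10)
    _write_table(pd.DataFrame(pc.scores[:, :4],
                              columns=[f"PC{i+1}" for i in range(4)])
                 .assign(sample_id=g2.sample_ids, group=s2["group"].values),
                 outdir / "pca_scores.tsv", f"genotype PCA, seed={seed}")
    say(f"structure: MDS eigenvalues {np.round(mds.eigenvalues, 3).tolist()}, "
        f"PCA top eigenvalues {np.round(pc.eigenvalues[:3], 3).tolist()}")

    # --- local vs global scan ----------------------------------------
    scan = local_global_scan(g2, v2, pc.scores, cfg.scan.window_mb,
                             cfg.scan.n_pcs, cfg.scan.n_snps_min)
    _write_table(scan, outdir / "window_scan.tsv",
                 f"local-vs-global rho2 scan, seed={seed}")
    if not scan.empty:
        say(f"scan: {len(scan)} windows, rho2 median "
            f"{scan['rho2'].median():.3f}, IQR "
            f"{scan['rho2'].quantile(0.75) - scan['rho2'].quantile(0.25):.3f}")

    # --- admixture ----------------------------------------------------
    adm = cfg.admixture
    k_table = loglik_by_k(g2, aims, range(adm.k_min, adm.k_max + 1),
                          n_restarts=adm.n_restarts, seed=seed,
                          tol=adm.tol, max_iter=adm.max_iter)
    _write_table(k_table, outdir / "loglik_by_k.tsv",
                 f"admixture loglik profile, seed={seed}")
    model = admixture_em(g2, aims, k=sim.k_true, n_restarts=adm.n_restarts,
                         seed=seed, tol=adm.tol, max_iter=adm.max_iter)
    if np.diff(model.loglik_trace).min() < -1e-9:
        raise RuntimeError("EM log-likelihood decreased")
    order = continuum_sort(model, 0, g2.sample_ids)
    q_df = pd.DataFrame(model.q[order],
                        columns=[f"Q{k+1}" for k in range(model.k)])
    q_df.insert(0, "sample_id", [g2.sample_ids[i] for i in order])
    _write_table(q_df, outdir / "admixture_q.tsv",
                 f"EM admixture K={model.k}, continuum-sorted, seed={seed}")
    say(f"admixture: K={model.k} loglik={model.loglik:.1f}; "
        f"loglik by K: {dict(zip(k_table['k'], k_table['loglik'].round(1)))}")

    # --- LD blocks per group -----------------------------------------
    chrom1 = np.flatnonzero((v2["chrom"] == "1").to_numpy())[:60]
    blocks_by_group, block_summary = compare_groups(
        g2, v2, s2, chrom1, min_group_size=20, params=cfg.gabriel)
    _write_table(block_summary, outdir / "ld_blocks.tsv",
                 f"confidence-interval blocks, chrom1 focal span, seed={seed}")
    say("LD blocks per group: "
        + ", ".join(f"{r.group}={r.n_blocks}"
                    for r in block_summary.itertuples()))

    # --- association --------------------------------------------------
    assoc_frames = []
    pcs_by_group = {}
    for grp in s2["group"].unique():
        res = bmi_residuals(s2, grp)
        members = np.flatnonzero((s2["group"] == grp).to_numpy())
        gp = pca(g2.subset(samples=members), pruned, n_components=2)
        full_scores = np.zeros((g2.n_samples, gp.scores.shape[1]))
        full_scores[members] = gp.scores
        pcs_by_group[grp] = full_scores
        adjusted = grp in set(cfg.association.adjusted_groups) \
            or not cfg.association.adjusted_groups
        table = snp_association(
            res, g2, markers=None,
            pcs=full_scores if adjusted else None,
            n_pcs=cfg.association.n_pcs, group=grp)
        assoc_frames.append(table)
    assoc = pd.concat(assoc_frames, ignore_index=True)
    assoc = assoc.merge(
        v2.reset_index(names="variant")[["variant", "rsid", "chrom", "pos"]],
        on="variant", how="left")
    _write_table(assoc, outdir / "association.tsv",
                 f"log-BMI additive scan, seed={seed}")
    lam = {grp: genomic_inflation(
               assoc.loc[assoc["group"] == grp, "p"].dropna())
           for grp in s2["group"].unique()}
    say("association inflation lambda: "
        + ", ".join(f"{k}={x:.3f}" for k, x in lam.items()))

    (outdir / "report.txt").write_text(report.getvalue())
    return {
        "n_samples_qc": g2.n_samples, "n_snps_qc": g2.n_variants,
        "n_pruned": len(pruned), "n_aims": len(aims),
        "prune_violations": violations,
        "n_scan_windows": int(len(scan)),
        "admixture_loglik": model.loglik,
        "block_counts": {r.group: int(r.n_blocks)
                         for r in block_summary.itertuples()},
        "lambda": lam,
        "report_path": str(outdir / "report.txt"),
    }
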