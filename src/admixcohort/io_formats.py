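"""Genotype cohort I/O and merging.

The in-memory model used throughout the package is a triple

* :class:`GenotypeMatrix` — samples x variants allele-dosage calls,
* a variant table (``pandas.DataFrame``: rsid, chrom, pos, allele_a,
  allele_b, counted),
* a sample table (``pandas.DataFrame``: sample_id, group, sex, age, bmi,
  diagnoses, batch, is_replicate).

Dosages count copies of the *counted* allele and take values 0, 1, 2 or
:data:`MISSING`.  Supported on-disk formats are PLINK binary
(.bed/.bim/.fam), PLINK text (.ped/.map), VCF (GT field only) and a
tab-delimited sample-metadata table.  ``merge_cohorts`` intersects
cohorts on shared rsids and harmonizes allele labels (swap / strand
flip), dropping strand-ambiguous and irreconcilable variants with full
accounting.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.  Kept distinct from every
#: valid count; never imputed except where an operation states otherwise.
MISSING: int = -1

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "0": "0"}

VARIANT_COLUMNS = ["rsid", "chrom", "pos", "allele_a", "allele_b", "counted"]
SAMPLE_COLUMNS = [
    "sample_id", "group", "sex", "age", "bmi", "diagnoses", "batch",
    "is_replicate",
]


class FormatError(ValueError):
    """Raised for malformed or internally inconsistent genotype files."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x variants matrix of counted-allele dosages.

    ``dosages`` is an ``int8`` array with entries in {0, 1, 2, MISSING};
    row ``i`` is the sample ``sample_ids[i]``, column ``j`` the ``j``-th
    row of the accompanying variant table.
    """

    dosages: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length must match dosage rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"invalid dosage values: {bad!r}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def called_float(self) -> np.ndarray:
        """Dosages as float with missing entries set to NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        d = self.dosages
        ids = self.sample_ids
        if samples is not None:
            samples = np.asarray(samples)
            d = d[samples]
            ids = [ids[i] for i in np.atleast_1d(samples)]
        if variants is not None:
            d = d[:, np.asarray(variants)]
        return GenotypeMatrix(d.copy(), list(ids))


@dataclasses.dataclass
class MergeReport:
    n_samples_combined: int
    n_variants_shared: int
    n_flipped: int
    n_dropped_ambiguous: int
    n_dropped_mismatch: int


def variant_table(rsid, chrom, pos, allele_a, allele_b, counted=None) -> pd.DataFrame:
    """Assemble and validate a variant table; ``counted`` defaults to allele_a."""
    v = pd.DataFrame({
        "rsid": [str(r) for r in rsid],
        "chrom": [str(c) for c in chrom],
        "pos": np.asarray(pos, dtype=np.int64),
        "allele_a": [str(a) for a in allele_a],
        "allele_b": [str(b) for b in allele_b],
    })
    v["counted"] = v["allele_a"] if counted is None else [str(c) for c in counted]
    check_variant_table(v)
    return v


def check_variant_table(v: pd.DataFrame) -> None:
    missing_cols = set(VARIANT_COLUMNS) - set(v.columns)
    if missing_cols:
        raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
    if v["rsid"].duplicated().any():
        dup = v.loc[v["rsid"].duplicated(), "rsid"].iloc[0]
        raise ValueError(f"duplicate rsid in variant table: {dup}")
    if (v["pos"] < 0).any():
        raise ValueError("negative base-pair position")


def sample_table(sample_id, group=None, sex=None, age=None, bmi=None,
                 diagnoses=None, batch=None, is_replicate=None) -> pd.DataFrame:
    n = len(sample_id)

    def _fill(x, default):
        return [default] * n if x is None else list(x)

    s = pd.DataFrame({
        "sample_id": [str(i) for i in sample_id],
        "group": _fill(group, "unknown"),
        "sex": _fill(sex, "unknown"),
        "age": np.asarray(_fill(age, np.nan), dtype=float),
        "bmi": np.asarray(_fill(bmi, np.nan), dtype=float),
        "diagnoses": _fill(diagnoses, ""),
        "batch": _fill(batch, "batch0"),
        "is_replicate": np.asarray(_fill(is_replicate, False), dtype=bool),
    })
    check_sample_table(s)
    return s


def check_sample_table(s: pd.DataFrame) -> None:
    missing_cols = set(SAMPLE_COLUMNS) - set(s.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if s["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample table")
    ages = s["age"].dropna()
    if (ages < 0).any():
        raise ValueError("negative age")
    bad_sex = set(s["sex"]) - {"male", "female", "unknown"}
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------
# 2-bit codes in .bed (SNP-major, LSB first within each byte), for the
# allele-A1 dosage convention used by PLINK: 00 = hom A1 (dosage 2),
# 01 = missing, 10 = het (1), 11 = hom A2 (0).  allele_a/counted maps to A1.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}
_FAM_TO_SEX = {"1": "male", "2": "female"}


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "rsid", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "rsid": str, "a1": str, "a2": str})
    return variant_table(bim["rsid"], bim["chrom"], bim["pos"], bim["a1"],
                         bim["a2"])


def _read_fam(path: Path) -> pd.DataFrame:
    if path.stat().st_size == 0:
        return sample_table([])
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype=str)
    return sample_table(
        fam["iid"],
        group=fam["fid"],
        sex=[_FAM_TO_SEX.get(x, "unknown") for x in fam["sex"]],
    )


def _decode_bed(payload: bytes, n_samples: int, n_variants: int) -> np.ndarray:
    bytes_per_var = (n_samples + 3) // 4
    expected = bytes_per_var * n_variants
    if len(payload) != expected:
        raise FormatError(
            f"truncated or oversized .bed payload: {len(payload)} bytes, "
            f"expected {expected}")
    if n_samples == 0 or n_variants == 0:
        return np.zeros((n_samples, n_variants), dtype=np.int8)
    raw = np.frombuffer(payload, dtype=np.uint8).reshape(n_variants,
                                                         bytes_per_var)
    # unpack 4 two-bit codes per byte, LSB first
    codes = np.empty((n_variants, bytes_per_var * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


def _encode_bed(dosages: np.ndarray) -> bytes:
    n_samples, n_variants = dosages.shape
    code_lut = np.zeros(4, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code_lut[d % 4] = c  # MISSING=-1 -> index 3
    codes = code_lut[dosages.T % 4]  # (variants, samples)
    pad = (-n_samples) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((n_variants, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(n_variants, -1, 4)
    packed = (codes[:, :, 0] | (codes[:, :, 1] << 2) | (codes[:, :, 2] << 4)
              | (codes[:, :, 3] << 6)).astype(np.uint8)
    return packed.tobytes()


def read_plink(path_prefix) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Read a PLINK fileset (binary .bed/.bim/.fam or text .ped/.map).

    The counted allele is A1 (column 5 of .bim / first allele of each
    .map variant as written by :func:`write_plink`).
    """
    prefix = Path(path_prefix)
    bed = prefix.with_suffix(".bed")
    ped = prefix.with_suffix(".ped")
    if bed.exists():
        return _read_plink_binary(prefix)
    if ped.exists():
        return _read_plink_text(prefix)
    raise FileNotFoundError(f"no .bed or .ped file with prefix {prefix}")


def _read_plink_binary(prefix: Path):
    v = _read_bim(prefix.with_suffix(".bim"))
    s = _read_fam(prefix.with_suffix(".fam"))
    blob = prefix.with_suffix(".bed").read_bytes()
    if blob[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic number {blob[:3]!r} "
                          "(not a SNP-major PLINK .bed)")
    dos = _decode_bed(blob[3:], len(s), len(v))
    g = GenotypeMatrix(dos, list(s["sample_id"]))
    return g, v, s


def write_plink(g: GenotypeMatrix, v: pd.DataFrame, s: pd.DataFrame,
                path_prefix, fmt: str = "bed") -> list[Path]:
    """Write a cohort as PLINK binary (``fmt="bed"``) or text (``"ped"``).

    Counted allele is written as A1.  Returns the created paths.
    """
    check_variant_table(v)
    check_sample_table(s)
    if g.n_variants != len(v) or g.n_samples != len(s):
        raise ValueError("genotype matrix shape does not match tables")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    counted = v["counted"].to_numpy()
    other = np.where(v["counted"] == v["allele_a"], v["allele_b"],
                     v["allele_a"])
    if fmt == "bed":
        paths = [prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
                 prefix.with_suffix(".fam")]
        with open(paths[0], "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(_encode_bed(g.dosages))
        bim = pd.DataFrame({
            "chrom": v["chrom"], "rsid": v["rsid"], "cm": 0, "pos": v["pos"],
            "a1": counted, "a2": other,
        })
        bim.to_csv(paths[1], sep="\t", header=False, index=False)
        _write_fam(s, paths[2])
        return paths
    if fmt == "ped":
        paths = [prefix.with_suffix(".ped"), prefix.with_suffix(".map")]
        _write_ped(g, s, counted, other, paths[0])
        pd.DataFrame({
            "chrom": v["chrom"], "rsid": v["rsid"], "cm": 0, "pos": v["pos"],
        }).to_csv(paths[1], sep="\t", header=False, index=False)
        # .map carries no alleles; stash them in a sidecar for round trips
        pd.DataFrame({"rsid": v["rsid"], "a1": counted, "a2": other}).to_csv(
            prefix.with_suffix(".alleles"), sep="\t", index=False)
        return paths
    raise ValueError(f"unknown PLINK format {fmt!r}")


def _write_fam(s: pd.DataFrame, path: Path) -> None:
    fam = pd.DataFrame({
        "fid": s["group"], "iid": s["sample_id"], "pat": 0, "mat": 0,
        "sex": [_SEX_TO_FAM[x] for x in s["sex"]], "pheno": -9,
    })
    fam.to_csv(path, sep="\t", header=False, index=False)


def _write_ped(g, s, counted, other, path: Path) -> None:
    n, m = g.dosages.shape
    a1 = np.empty((n, m), dtype=object)
    a2 = np.empty((n, m), dtype=object)
    d = g.dosages
    a1[:] = np.where(d >= 1, counted[None, :], other[None, :])
    a2[:] = np.where(d == 2, counted[None, :], other[None, :])
    a1[d == MISSING] = "0"
    a2[d == MISSING] = "0"
    with open(path, "w") as fh:
        for i in range(n):
            head = [str(s["group"].iloc[i]), s["sample_id"].iloc[i], "0", "0",
                    _SEX_TO_FAM[s["sex"].iloc[i]], "-9"]
            geno = [x for pair in zip(a1[i], a2[i]) for x in pair]
            fh.write("\t".join(head + geno) + "\n")


def _read_plink_text(prefix: Path):
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "rsid", "cm", "pos"],
                     dtype={"chrom": str, "rsid": str})
    m = len(mp)
    rows, ids, groups, sexes = [], [], [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped: expected {6 + 2 * m} fields, got {len(parts)}")
            groups.append(parts[0])
            ids.append(parts[1])
            sexes.append(_FAM_TO_SEX.get(parts[4], "unknown"))
            rows.append(parts[6:])
    alleles_path = prefix.with_suffix(".alleles")
    if alleles_path.exists():
        al = pd.read_csv(alleles_path, sep="\t", dtype=str)
        a1, a2 = al["a1"].to_numpy(), al["a2"].to_numpy()
    else:
        a1, a2 = _infer_alleles(rows, m)
    dos = np.full((len(rows), m), MISSING, dtype=np.int8)
    for i, row in enumerate(rows):
        pair = np.array(row, dtype=object).reshape(m, 2)
        called = (pair != "0").all(axis=1)
        dos[i, called] = ((pair[called, 0] == a1[called]).astype(np.int8)
                          + (pair[called, 1] == a1[called]).astype(np.int8))
    g = GenotypeMatrix(dos, ids)
    v = variant_table(mp["rsid"], mp["chrom"], mp["pos"], a1, a2)
    s = sample_table(ids, group=groups, sex=sexes)
    return g, v, s


def _infer_alleles(rows, m):
    """First-seen allele per variant becomes A1 when no sidecar exists."""
    a1 = np.array(["0"] * m, dtype=object)
    a2 = np.array(["0"] * m, dtype=object)
    for row in rows:
        pair = np.array(row, dtype=object).reshape(m, 2)
        for col in (0, 1):
            seen = pair[:, col]
            new = (a1 == "0") & (seen != "0")
            a1[new] = seen[new]
            other = (seen != "0") & (seen != a1) & (a2 == "0")
            a2[other] = seen[other]
    a2[a2 == "0"] = a1[a2 == "0"]  # monomorphic
    return a1, a2


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, int]:
    """Read a VCF with GT fields; ALT is the counted allele.

    Multi-allelic records are skipped; the number skipped is returned as
    the fourth element.  Phase is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rsids, chroms, poss, refs, alts = [], [], [], [], []
    cols = []
    n_skipped = 0
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes
        if gts is None:
            raise FormatError(f"record {rec.CHROM}:{rec.POS} has no GT field")
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            a = gt[:-1]  # last element is the phased flag
            if len(a) != 2 or -1 in a:
                continue
            col[i] = int(a[0] != 0) + int(a[1] != 0)
        cols.append(col)
        rsids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    dos = (np.stack(cols, axis=1) if cols
           else np.zeros((len(samples), 0), dtype=np.int8))
    g = GenotypeMatrix(dos, samples)
    v = variant_table(rsids, chroms, poss, alts, refs, counted=alts)
    s = sample_table(samples)
    if n_skipped:
        log.info("read_vcf: skipped %d multi-allelic records", n_skipped)
    return g, v, s, n_skipped


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the tab-delimited metadata table (sample_id, group, sex, age,
    bmi, diagnoses as semicolon list, batch, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    rep = df.get("replicate", df.get("is_replicate", False))
    return sample_table(
        df["sample_id"], group=df.get("group"), sex=df.get("sex"),
        age=df.get("age"), bmi=df.get("bmi"), diagnoses=df.get("diagnoses"),
        batch=df.get("batch"),
        is_replicate=np.asarray(rep, dtype=bool) if not np.isscalar(rep) else None,
    )


def write_metadata(s: pd.DataFrame, path) -> None:
    out = s.rename(columns={"is_replicate": "replicate"})
    out.to_csv(path, sep="\t", index=False)


def attach_metadata(s: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Replace metadata columns of ``s`` with those from ``meta``, joined
    on sample_id; samples absent from ``meta`` keep their defaults."""
    merged = s[["sample_id"]].merge(meta, on="sample_id", how="left")
    out = s.copy()
    for col in SAMPLE_COLUMNS[1:]:
        if col in merged:
            filled = merged[col]
            out[col] = filled.where(filled.notna(), s[col])
    out["is_replicate"] = out["is_replicate"].astype(bool)
    check_sample_table(out)
    return out


# ---------------------------------------------------------------------------
# Cohort merging with allele harmonization
# ---------------------------------------------------------------------------

def _is_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a) == b


def merge_cohorts(cohorts, labels=None):
    """Merge >= 2 cohorts on shared rsids with allele harmonization.

    Allele labels are harmonized to the first cohort: same labels pass
    through; swapped labels recode dosage d -> 2 - d; complementary
    labels are strand-flipped (with ``n_flipped`` counting them);
    strand-ambiguous variants (A/T, C/G in the first cohort or any
    other) are dropped, as are irreconcilable allele pairs.  Samples are
    concatenated; colliding sample ids are prefixed with the cohort
    label.  Returns ``(g, v, s, MergeReport)``.
    """
    if len(cohorts) < 2:
        raise ValueError("merge_cohorts needs at least two cohorts")
    if labels is None:
        labels = [f"cohort{i}" for i in range(len(cohorts))]
    base_g, base_v, base_s = cohorts[0]

    shared = set(base_v["rsid"])
    for g, v, s in cohorts[1:]:
        shared &= set(v["rsid"])
    # keep first-cohort order
    order = [r for r in base_v["rsid"] if r in shared]

    n_flipped = 0
    n_ambiguous = 0
    n_mismatch = 0
    keep_rsids = []
    # per-cohort (column index, recode) for each kept rsid
    plans = [[] for _ in cohorts]

    base_idx = {r: i for i, r in enumerate(base_v["rsid"])}
    other_idx = [{r: i for i, r in enumerate(v["rsid"])}
                 for _, v, _ in cohorts]

    for rsid in order:
        j0 = base_idx[rsid]
        a0 = base_v["counted"].iloc[j0]
        b0 = (base_v["allele_b"].iloc[j0]
              if base_v["allele_a"].iloc[j0] == a0
              else base_v["allele_a"].iloc[j0])
        if _is_ambiguous(a0, b0):
            n_ambiguous += 1
            continue
        ok = True
        flips = 0
        plan_row = [(j0, False)]
        for ci in range(1, len(cohorts)):
            _, v, _ = cohorts[ci]
            j = other_idx[ci][rsid]
            a = v["counted"].iloc[j]
            b = (v["allele_b"].iloc[j] if v["allele_a"].iloc[j] == a
                 else v["allele_a"].iloc[j])
            if _is_ambiguous(a, b):
                n_ambiguous += 1
                ok = False
                break
            ca, cb = _COMPLEMENT.get(a), _COMPLEMENT.get(b)
            if (a, b) == (a0, b0):
                plan_row.append((j, False))
            elif (a, b) == (b0, a0):
                plan_row.append((j, True))
            elif (ca, cb) == (a0, b0):
                plan_row.append((j, False))
                flips += 1
            elif (ca, cb) == (b0, a0):
                plan_row.append((j, True))
                flips += 1
            else:
                n_mismatch += 1
                ok = False
                break
        if not ok:
            continue
        keep_rsids.append(rsid)
        n_flipped += flips
        for ci, item in enumerate(plan_row):
            plans[ci].append(item)

    m = len(keep_rsids)
    blocks = []
    sample_frames = []
    all_ids: set[str] = set()
    out_ids: list[str] = []
    for ci, (g, v, s) in enumerate(cohorts):
        idx = np.array([j for j, _ in plans[ci]], dtype=int)
        swap = np.array([sw for _, sw in plans[ci]], dtype=bool)
        d = g.dosages[:, idx].copy() if m else np.zeros(
            (g.n_samples, 0), dtype=np.int8)
        if m and swap.any():
            cols = d[:, swap]
            recoded = np.where(cols == MISSING, MISSING, 2 - cols)
            d[:, swap] = recoded.astype(np.int8)
        blocks.append(d)
        sf = s.copy()
        sf["cohort"] = labels[ci]
        new_ids = []
        for sid in sf["sample_id"]:
            nid = sid if sid not in all_ids else f"{labels[ci]}:{sid}"
            new_ids.append(nid)
        sf["sample_id"] = new_ids
        all_ids.update(new_ids)
        out_ids.extend(new_ids)
        sample_frames.append(sf)

    merged_g = GenotypeMatrix(np.vstack(blocks), out_ids)
    kept_base = [base_idx[r] for r in keep_rsids]
    merged_v = base_v.iloc[kept_base].reset_index(drop=True)
    merged_s = pd.concat(sample_frames, ignore_index=True)
    report = MergeReport(
        n_samples_combined=merged_g.n_samples,
        n_variants_shared=m,
        n_flipped=n_flipped,
        n_dropped_ambiguous=n_ambiguous,
        n_dropped_mismatch=n_mismatch,
    )
    return merged_g, merged_v, merged_s, report


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant counted-allele frequency over called genotypes (NaN if
    no calls)."""
    d = g.called_float()
    with np.errstate(invalid="ignore"):
        return np.nanmean(d, axis=0) / 2.0
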