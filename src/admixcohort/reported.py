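"""Published study-report constants used as *inputs* to accounting
checks.

These are the printed numbers of the source study's quality-control
narrative and cohort table for an urban biobank sample genotyped on a
~900K SNP array: the rsID-mapped SNP total, the ordered per-step SNP
exclusion counts, the final SNP count, and the per-group sample sizes.
The package replays them through its own ledger arithmetic; it does not
treat them as outputs of any computation here.
"""

#: SNPs mapped to a dbSNP rsID at the start of SNP-level QC.
SNPS_MAPPED = 905_384

#: Ordered SNP-level exclusion steps (name, n_excluded) as reported.
SNP_EXCLUSION_STEPS = (
    ("snp_call_rate", 60_869),
    ("maf", 10_889),
    ("batch_effect", 1_236),
    ("differential_missingness", 217),
    ("hwe", 2_587),
)

#: Final quality-controlled SNP count as reported.
SNPS_FINAL = 829_586

#: Per-group sample counts of the final cohort (self-identified groups).
GROUP_SIZES = {
    "African American": 324,
    "European American": 326,
    "Hispanic American": 327,
}

#: Reported total of the final cohort.
SAMPLES_FINAL = 977

#: Sample-level exclusions from the 1030 genotyped subjects, in
#: narrative order.
SAMPLE_EXCLUSION_STEPS = (
    ("broad_genotyping_failure", 36),
    ("sex_mismatch", 5),
    ("sample_call_rate", 7),
    ("inbreeding_outlier", 1),
)

SAMPLES_GENOTYPED = 1030
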