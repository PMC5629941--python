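"""Published reference numbers echoed in reports.

These are reporting constants, not inputs to any computation except the
marker accounting used for the default Bonferroni denominator.
"""

#: marker counts per category in the reference MHC imputation study
#: (post-QC): SNPs, amino-acid residue indicators, classical HLA alleles at
#: two- and four-digit resolution
MARKER_CATEGORY_COUNTS = {
    "snp": 6833,
    "aa_residue": 334,
    "hla_2digit": 71,
    "hla_4digit": 87,
}


def total_marker_count(counts: dict[str, int] | None = None) -> int:
    """Total marker count across the four categories."""
    counts = counts or MARKER_CATEGORY_COUNTS
    return int(sum(counts.values()))


#: published odds ratios at HLA-B position 97 for psoriatic arthritis
#: (case-case) and ankylosing spondylitis, echoed in report tables for the
#: cross-disease effect comparison
AS_PSA_EFFECT_TABLE = {
    "N": {"psa_or": 2.46, "psa_ci": (1.78, 3.42), "as_or": 16.51,
          "as_ci": (15.43, 17.69)},
    "S": {"psa_or": 1.45, "psa_ci": (1.22, 1.74), "as_or": 0.86,
          "as_ci": (0.81, 0.91)},
}
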