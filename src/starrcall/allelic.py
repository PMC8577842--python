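"""Allele-level reporter counts for SNP-bearing amplicons.

Consumes long-format tabular allele counts (one row per SNP, sample, and
base, as emitted by readcount extractors): snp_id, amplicon_id, chrom, pos,
sample_id, base, is_ref, count, mean_base_quality.  Per-read quality and
mapping filters are the extractor's job upstream; this module applies only
the tabular filters — minimum mean base quality, minimum within-sample allele
frequency — and keeps SNPs left with exactly two alleles (biallelic).

Allele summaries pool counts within sample kind (DNA vs RNA), flag SNPs whose
pooled-DNA minor allele frequency exceeds a threshold as eligible for allele
comparison, and report the DNA-RNA reference-allele-frequency correlation over
eligible SNPs.  No allelic significance test is offered: frequencies and
correlations only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .qc import QCError, biological, pairwise_correlation

ALLELE_COLUMNS = [
    "snp_id",
    "amplicon_id",
    "chrom",
    "pos",
    "sample_id",
    "base",
    "is_ref",
    "count",
    "mean_base_quality",
]


def filter_allele_counts(
    table: pd.DataFrame,
    min_base_quality: float = 25.0,
    min_af: float = 0.01,
) -> pd.DataFrame:
    """Quality and frequency filters, then restriction to biallelic SNPs.

    Drops allele observations with mean base quality below the threshold,
    drops alleles below the within-sample frequency floor, and keeps SNPs
    whose surviving alleles (pooled over samples) number exactly two.
    """
    t = table.copy()
    t = t[t["mean_base_quality"] >= min_base_quality]
    totals = t.groupby(["snp_id", "sample_id"])["count"].transform("sum")
    with np.errstate(invalid="ignore"):
        af = t["count"] / totals
    t = t[(totals > 0) & (af >= min_af)]
    n_alleles = t.groupby("snp_id")["base"].transform("nunique")
    return t[n_alleles == 2].reset_index(drop=True)


def allele_summary(
    filtered: pd.DataFrame,
    samples: pd.DataFrame,
    maf_threshold: float = 0.1,
) -> tuple[pd.DataFrame, float]:
    """Per-SNP pooled reference-allele frequencies and the DNA-RNA correlation.

    Reference AF is ref/(ref+alt) pooled over biological samples of each kind.
    SNPs with pooled-DNA minor allele frequency above ``maf_threshold`` are
    flagged comparison-eligible; the returned correlation is the Pearson r of
    ref AF between DNA and RNA over eligible SNPs (NaN if fewer than three).
    SNPs with zero pooled counts in a kind get a missing (NaN) frequency,
    not zero.
    """
    dna_ids = set(biological(samples, "DNA")["sample_id"])
    rna_ids = set(biological(samples, "RNA")["sample_id"])
    if not dna_ids or not rna_ids:
        raise QCError("need at least one DNA and one RNA sample")

    def pooled_ref_af(kind_ids: set) -> pd.Series:
        sub = filtered[filtered["sample_id"].isin(kind_ids)]
        ref = sub[sub["is_ref"]].groupby("snp_id")["count"].sum()
        tot = sub.groupby("snp_id")["count"].sum()
        af = ref.reindex(tot.index).fillna(0) / tot
        return af.where(tot > 0)

    ref_dna = pooled_ref_af(dna_ids)
    ref_rna = pooled_ref_af(rna_ids)
    snps = sorted(set(filtered["snp_id"]))
    out = pd.DataFrame(index=pd.Index(snps, name="snp_id"))
    out["amplicon_id"] = (
        filtered.drop_duplicates("snp_id").set_index("snp_id")["amplicon_id"]
    )
    out["ref_af_dna"] = ref_dna.reindex(snps)
    out["ref_af_rna"] = ref_rna.reindex(snps)
    out["maf_dna"] = np.minimum(out["ref_af_dna"], 1 - out["ref_af_dna"])
    out["eligible"] = out["maf_dna"] > maf_threshold

    eligible = out[out["eligible"]].dropna(subset=["ref_af_dna", "ref_af_rna"])
    if len(eligible) >= 3:
        try:
            corr, _ = pairwise_correlation(
                eligible["ref_af_dna"], eligible["ref_af_rna"]
            )
        except QCError:
            corr = float("nan")
    else:
        corr = float("nan")
    return out.reset_index(), corr
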