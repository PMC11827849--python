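"""Allele-specific expression, qPCR relative quantification, and Mendelian
ratio tests.

In a heterozygous enhancer-deletion animal on a hybrid strain background,
transcribed strain-distinguishing SNPs separate reads from the
deletion-carrying (mutant-linked) and wild-type-linked alleles.  A
depressed mutant/WT allele ratio confined to heterozygotes — with the
wild-type group staying at 1 — indicates the element acts in cis.  This
module estimates per-sample allelic ratios, runs the Welch-t cis test
between genotype groups, computes delta-delta-Ct relative expression from
qPCR cycle thresholds, and tests offspring genotype counts against an
expected Mendelian ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, chi2_gof, welch_t

__all__ = [
    "RatioEstimate",
    "validate_allele_counts",
    "allelic_ratio",
    "cis_trans_test",
    "ddct",
    "mendelian_test",
]

ALLELE_COLUMNS = ["sample_id", "genotype", "snp_id", "allele", "count"]


@dataclass
class RatioEstimate:
    """Mutant-linked / WT-linked expression ratio for one sample.

    ``ratio`` is NaN (flagged undefined) when every WT-linked count is zero.
    ``per_snp_ratios`` covers SNPs where both allele counts are positive.
    """

    sample_id: str
    ratio: float
    total_depth: int
    per_snp_ratios: pd.Series
    genotype: str = ""
    undefined: bool = False


def validate_allele_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy allele-count layout used throughout this module."""
    missing = [c for c in ALLELE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele count table missing columns {missing}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    bad = ~table["allele"].isin(["mut_linked", "wt_linked"])
    if bad.any():
        raise ValueError("allele must be 'mut_linked' or 'wt_linked'")
    pairs = table.groupby(["sample_id", "snp_id"])["allele"].nunique()
    if (pairs < 2).any():
        raise ValueError("each (sample, snp) needs both allele rows")
    return table


def allelic_ratio(table: pd.DataFrame, aggregation: str = "pooled") -> list[RatioEstimate]:
    """Per-sample mutant/WT allelic expression ratio.

    ``pooled`` (default, depth-weighted): sum of mutant-linked counts over
    the sum of WT-linked counts across SNPs.  ``mean_of_snps``: unweighted
    mean of per-SNP ratios over SNPs with both counts positive.
    """
    if aggregation not in ("pooled", "mean_of_snps"):
        raise ValueError("aggregation must be 'pooled' or 'mean_of_snps'")
    validate_allele_counts(table)
    wide = (table.pivot_table(index=["sample_id", "snp_id"], columns="allele",
                              values="count", aggfunc="sum")
            .reindex(columns=["mut_linked", "wt_linked"]).fillna(0))
    out: list[RatioEstimate] = []
    genotypes = table.groupby("sample_id")["genotype"].first() \
        if "genotype" in table.columns else None
    for sid, sub in wide.groupby(level="sample_id"):
        mut = sub["mut_linked"].to_numpy(dtype=float)
        wt = sub["wt_linked"].to_numpy(dtype=float)
        both = (mut > 0) & (wt > 0)
        per_snp = pd.Series(mut[both] / wt[both],
                            index=sub.index.get_level_values("snp_id")[both])
        if aggregation == "pooled":
            ratio = mut.sum() / wt.sum() if wt.sum() > 0 else np.nan
        else:
            ratio = float(per_snp.mean()) if len(per_snp) else np.nan
        out.append(RatioEstimate(
            sample_id=str(sid), ratio=float(ratio) if not np.isnan(ratio) else np.nan,
            total_depth=int(mut.sum() + wt.sum()), per_snp_ratios=per_snp,
            genotype=str(genotypes[sid]) if genotypes is not None else "",
            undefined=bool(np.isnan(ratio))))
    return out


def cis_trans_test(
    wt_ratios: Sequence[float],
    het_ratios: Sequence[float],
    null_tolerance: float = 0.1,
) -> TestResult:
    """Welch t test of per-sample allelic ratios between genotype groups.

    A significant depression of heterozygote ratios while the wild-type
    group stays near 1 is the cis-regulatory signature (a trans factor would
    shift both alleles, leaving each group's ratio at 1).  The verdict is
    attached in ``extra['interpretation']``: ``cis_consistent`` when
    p < 0.05, the het mean is below the WT mean, and the WT group mean lies
    within ``null_tolerance`` of 1; otherwise ``no_cis_effect``.
    """
    wt = np.asarray(wt_ratios, dtype=float)
    het = np.asarray(het_ratios, dtype=float)
    if wt.size < 2 or het.size < 2:
        raise ValueError("need >= 2 samples per genotype group")
    res = welch_t(het, wt)
    cis = (res.p < 0.05 and het.mean() < wt.mean()
           and abs(wt.mean() - 1.0) <= null_tolerance)
    res.extra.update({
        "wt_mean": float(wt.mean()), "het_mean": float(het.mean()),
        "interpretation": "cis_consistent" if cis else "no_cis_effect"})
    return res


def ddct(
    ct: pd.DataFrame,
    reference_group: str,
    housekeeping: str = "HPRT",
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``ct`` has rows (sample_id, group, gene, ct).  For each sample and
    target gene, dCt = Ct(target) - Ct(housekeeping); ddCt subtracts the
    reference group's mean dCt for that gene; fold = 2**(-ddCt).  Every
    sample must carry a housekeeping row with a finite Ct.
    """
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite")
    hk = ct[ct["gene"] == housekeeping].set_index("sample_id")["ct"]
    targets = ct[ct["gene"] != housekeeping].copy()
    missing = set(targets["sample_id"]) - set(hk.index)
    if missing:
        raise ValueError(f"samples missing housekeeping ({housekeeping}) Ct: "
                         f"{sorted(missing)}")
    targets["dct"] = targets["ct"].to_numpy() - hk[targets["sample_id"]].to_numpy()
    ref = targets[targets["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = ref.groupby("gene")["dct"].mean()
    genes_missing_ref = set(targets["gene"]) - set(ref_mean.index)
    if genes_missing_ref:
        raise ValueError(f"no reference-group Ct for genes {sorted(genes_missing_ref)}")
    targets["ddct"] = targets["dct"].to_numpy() - ref_mean[targets["gene"]].to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])
    return targets[["sample_id", "group", "gene", "ct", "dct", "ddct", "fold"]]


def mendelian_test(
    observed: Mapping[str, int],
    expected_ratio: Mapping[str, float],
) -> TestResult:
    """Chi-square goodness of fit of offspring genotype counts.

    ``expected_ratio`` gives the Mendelian weights (e.g. {"+/+": 1,
    "del/+": 2, "del/del": 1} for a heterozygous intercross); weights are
    normalized to the observed total.  Categories are matched by key.
    """
    keys = list(observed)
    if set(expected_ratio) != set(keys):
        raise ValueError("observed and expected_ratio must share genotype keys")
    obs = [observed[k] for k in keys]
    weights = [expected_ratio[k] for k in keys]
    res = chi2_gof(obs, weights)
    res.extra["genotypes"] = keys
    return res
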