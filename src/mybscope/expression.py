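"""qPCR relative quantification and RNA-seq expression filtering.

Relative expression follows the Livak 2^-ddCt method: technical replicates
are averaged per biological replicate, dCt = Ct_target - Ct_reference per
biological replicate, ddCt = mean dCt(stressed) - mean dCt(control), and
the fold change is 2^-ddCt.  Significance is a two-sample Student's t test
on the per-replicate dCt sets, tiered at p < 0.1 (*), 0.05 (**) and
0.01 (***).

The RNA-seq side provides the expressed-gene filter (TPM > 5 in at least
one sample), the replicate filter (>= 3 biological replicates per study
condition), a display summary (log2(TPM + 1) of replicate means), and a
stand-in differential-expression test (median-of-ratios normalisation,
Welch t on log2(normalised count + 1), Benjamini-Hochberg adjustment).
The DE stand-in is deliberately not a negative-binomial model; its output
table has the same columns an external DESeq2 result would provide.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

TIER_CUTOFFS = (0.1, 0.05, 0.01)


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "ns"


def delta_delta_ct(table: pd.DataFrame, gene: str,
                   reference_gene: str) -> pd.DataFrame:
    """2^-ddCt relative expression of *gene* per (tissue, time_h).

    *table* holds columns (gene, tissue, condition, time_h, bio_rep,
    tech_rep, ct) with conditions 'control' and 'stressed'; undetected
    wells carry NaN Ct.  Returns one row per (tissue, time_h) with columns
    rel, sd, p_value, tier, status and the per-condition replicate counts.

    Status is 'quantified' when both conditions are detected,
    'not_quantifiable' when exactly one is (the ratio has no finite value),
    and 'not_expressed' when neither is.  The fold-scale sd is the
    fold-equivalent of the ddCt standard error, ``rel * (2**se - 1)``.
    """
    sub = table[table.gene.isin([gene, reference_gene])]
    if gene not in set(sub.gene):
        raise ValueError(f"gene {gene!r} absent from table")
    rows = []
    for (tissue, time_h), block in sub.groupby(["tissue", "time_h"]):
        # technical replicates averaged per biological replicate
        bio = (block.groupby(["gene", "condition", "bio_rep"])["ct"]
               .mean().reset_index())
        piv = bio.pivot_table(index=["condition", "bio_rep"], columns="gene",
                              values="ct", dropna=False)
        if gene not in piv.columns:
            continue  # gene not measured in this (tissue, time) block
        if reference_gene not in piv.columns:
            raise ValueError("reference gene missing in block "
                             f"({tissue}, {time_h})")
        dct = piv[gene] - piv[reference_gene]
        ctrl = dct.loc["control"].dropna() if "control" in dct.index else pd.Series(dtype=float)
        strs = dct.loc["stressed"].dropna() if "stressed" in dct.index else pd.Series(dtype=float)
        ctrl_detected = len(ctrl) > 0
        strs_detected = len(strs) > 0
        if not ctrl_detected and not strs_detected:
            status, rel, sd, p = "not_expressed", np.nan, np.nan, np.nan
        elif not ctrl_detected or not strs_detected:
            status, rel, sd, p = "not_quantifiable", np.nan, np.nan, np.nan
        else:
            status = "quantified"
            ddct = strs.mean() - ctrl.mean()
            rel = float(2.0 ** -ddct)
            se = np.sqrt(strs.var(ddof=1) / len(strs)
                         + ctrl.var(ddof=1) / len(ctrl)) \
                if len(strs) > 1 and len(ctrl) > 1 else np.nan
            sd = float(rel * (2.0 ** se - 1.0)) if np.isfinite(se) else np.nan
            if len(strs) >= 2 and len(ctrl) >= 2:
                p = float(stats.ttest_ind(strs, ctrl, equal_var=True).pvalue)
            else:
                warnings.warn("fewer than 2 biological replicates per "
                              "condition; p undefined")
                p = np.nan
        rows.append(dict(gene=gene, tissue=tissue, time_h=time_h, rel=rel,
                         sd=sd, p_value=p, tier=_tier(p), status=status,
                         n_control=len(ctrl), n_stressed=len(strs)))
    return pd.DataFrame(rows)


def filter_expressed(matrix: pd.DataFrame,
                     tpm_threshold: float = 5.0) -> pd.DataFrame:
    """Keep genes with TPM strictly above the threshold in >= 1 sample."""
    return matrix[matrix.max(axis=1) > tpm_threshold]


def filter_studies_by_replicates(metadata: pd.DataFrame,
                                 min_reps: int = 3) -> pd.DataFrame:
    """Retain samples of (study, condition) groups with >= min_reps replicates.

    *metadata* carries one row per sample with columns (sample, study,
    condition, replicate).
    """
    counts = (metadata.groupby(["study", "condition"])["replicate"]
              .nunique())
    keep = counts[counts >= min_reps].index
    mask = metadata.set_index(["study", "condition"]).index.isin(keep)
    return metadata[mask]


def summarize_for_display(matrix: pd.DataFrame,
                          sample_conditions: dict[str, str] | pd.Series,
                          ) -> pd.DataFrame:
    """Per-condition log2(TPM + 1) of the replicate means.

    Replicate TPMs are averaged within each condition first; the log
    transform is applied to the mean.
    """
    cond = pd.Series(sample_conditions)
    out = {}
    for c in sorted(cond.unique()):
        samples = cond[cond == c].index
        if len(samples) == 0:
            raise ValueError(f"condition {c!r} has no samples")
        out[c] = np.log2(matrix[samples].mean(axis=1) + 1.0)
    return pd.DataFrame(out)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style library size factors.

    Geometric means are taken over genes with no zero counts; each sample's
    factor is the median ratio of its counts to those means.
    """
    log_counts = np.log(counts.replace(0, np.nan))
    log_gmean = log_counts.mean(axis=1)
    usable = np.isfinite(log_gmean) & counts.notna().all(axis=1)
    if not usable.any():
        raise ValueError("no gene without zeros; cannot estimate size factors")
    ratios = np.log(counts.loc[usable]).sub(log_gmean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(counts: pd.DataFrame,
                            groups: dict[str, str] | pd.Series,
                            reference: str | None = None,
                            fc_threshold: float = 2.0,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Stand-in two-group differential expression test.

    Median-of-ratios normalisation, Welch's t on log2(normalised count + 1)
    per gene, Benjamini-Hochberg adjustment.  A gene is flagged DE iff its
    fold change is strictly greater than *fc_threshold* in either direction
    (``|log2FC| > log2(fc_threshold)``) and its adjusted p is below *alpha*.
    Genes with no variance and no difference get p = 1.
    """
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if reference is None:
        reference = levels[0]
    other = next(l for l in levels if l != reference)
    g_ref = groups[groups == reference].index
    g_oth = groups[groups == other].index
    if len(g_ref) < 2 or len(g_oth) < 2:
        raise ValueError("each group needs >= 2 replicates")
    for g, name in ((g_ref, reference), (g_oth, other)):
        if counts[g].to_numpy().sum() == 0:
            raise ValueError(f"group {name!r} has zero total counts")
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    logx = np.log2(norm + 1.0)
    a = logx[g_oth].to_numpy()
    b = logx[g_ref].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    de = (np.abs(log2fc) > np.log2(fc_threshold)) & (padj < alpha)
    return pd.DataFrame(dict(log2fc=log2fc, p_value=p, p_adj=padj, de=de),
                        index=counts.index)
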